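import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rade.perturbation import ConditionKey, FoldChangeVector
from rade.signatures import label_tissue_genes

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def eq2_oracle(e1_label: int, fc2: float, mode: str = "symmetric",
               reversal_threshold: float = 2.0, adverse_threshold: float = 15.0) -> str:
    """Independent gene-by-gene evaluation of the effect-taxonomy branches.

    Deliberately written as literal branch checks (no vectorisation, no
    shared code with the implementation) so it can serve as an oracle.
    """
    if e1_label == 1 and fc2 < -reversal_threshold:
        return "reversed"
    if e1_label == -1 and fc2 > reversal_threshold:
        return "reversed"
    if e1_label == 0 and fc2 > adverse_threshold:
        return "adverse"
    if e1_label == 1 and fc2 > adverse_threshold:
        return "adverse"
    if e1_label == -1 and fc2 < -adverse_threshold:
        return "adverse"
    if mode == "symmetric" and e1_label == 0 and fc2 < -adverse_threshold:
        return "adverse"
    return "none"


def bh_stepup_oracle(p):
    """Textbook Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j)*n/j, capped at 1."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q_sorted = [0.0] * n
    running = 1.0
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        q_sorted[rank] = running
    q = [0.0] * n
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def make_signature(labels: dict[str, int], name: str = "toy"):
    """Build a TissueSignature whose labels equal the given dict exactly."""
    genes = list(labels)
    fc = [3.0 if v == 1 else (-3.0 if v == -1 else 1.0) for v in labels.values()]
    p = [1e-6 if v != 0 else 0.5 for v in labels.values()]
    de = pd.DataFrame({"fc": fc, "p_value": p}, index=pd.Index(genes, name="gene_id"))
    sig = label_tissue_genes(de, name=name)
    assert dict(sig.labels) == labels
    return sig


def make_fc_vector(values: dict[str, float], compound: str = "cpd",
                   cell_line: str = "CL1") -> FoldChangeVector:
    return FoldChangeVector(
        key=ConditionKey(compound, cell_line, "10 uM", "24 h"),
        fc=pd.Series(values, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
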