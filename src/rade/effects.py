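"""Reversed/adverse effect classification and the RADE score.

A compound's action on each gene is judged by crossing the disease label
(E1: cancer vs normal, in {-1, 0, +1}) with the perturbation fold-change
(E2: treated vs vehicle):

* **reversed** -- the compound pushes a disease-signature gene in the
  opposite direction beyond the reversal threshold: E1 = +1 with
  FC2 < -2, or E1 = -1 with FC2 > 2.  Reversal is the desired,
  corrective action.
* **adverse** -- the compound pushes a gene strongly (|FC2| > 15) in the
  disease direction (E1 = +1 with FC2 > 15, E1 = -1 with FC2 < -15), or
  strongly perturbs a gene the disease leaves unchanged (E1 = 0 with
  FC2 > 15; in the default ``symmetric`` mode also FC2 < -15).
* everything else is neither.

The much higher adverse threshold (15 vs 2) reflects that an adverse call
flags a drastic deviation, not any same-direction drift.  These
transcriptomic adverse effects are a safety proxy and are distinct from
clinical adverse drug reactions.

The RADE score for one perturbation condition is

    RADE = (#Ad / #Re) * (#Mu / #Re)

where #Ad and #Re count adverse and reversed genes and #Mu is the size of
the disease signature.  The first factor weighs harm against correction,
the second how much of the disease signature remains uncorrected; lower
is better.  A compound with no adverse genes scores exactly 0 regardless
of #Re; a compound with adverse genes but no reversed ones has no finite
score and is reported as undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .perturbation import ConditionKey, FoldChangeVector
from .signatures import TissueSignature

logger = logging.getLogger(__name__)

STRICT_PAPER = "strict_paper"
SYMMETRIC = "symmetric"


class RadeStatus(str, Enum):
    DEFINED = "defined"
    ZERO_ADVERSE = "zero_adverse"
    UNDEFINED_NO_REVERSAL = "undefined_no_reversal"


@dataclass(frozen=True)
class EffectSets:
    """Reversed and adverse gene sets for one condition against one signature."""

    key: ConditionKey
    reversed_genes: frozenset[str]
    adverse_genes: frozenset[str]
    universe: frozenset[str]
    signature_name: str | None = None

    def __post_init__(self) -> None:
        overlap = self.reversed_genes & self.adverse_genes
        if overlap:
            raise InputError(f"reversed and adverse sets overlap: {sorted(overlap)[:5]}")
        stray = (self.reversed_genes | self.adverse_genes) - self.universe
        if stray:
            raise InputError(f"effect genes outside the universe: {sorted(stray)[:5]}")

    @property
    def n_reversed(self) -> int:
        return len(self.reversed_genes)

    @property
    def n_adverse(self) -> int:
        return len(self.adverse_genes)


@dataclass(frozen=True)
class RadeResult:
    """RADE score with its components for one perturbation condition.

    ``score`` is ``None`` exactly when ``status`` is undefined_no_reversal.
    """

    key: ConditionKey
    score: float | None
    n_adverse: int
    n_reversed: int
    n_signature: int
    status: RadeStatus
    signature_name: str | None = None
    rank: int | None = None

    def to_dict(self) -> dict:
        return {
            "compound_id": self.key.compound_id,
            "cell_line_id": self.key.cell_line_id,
            "dose": self.key.dose,
            "duration": self.key.duration,
            "rade": self.score,
            "n_adverse": self.n_adverse,
            "n_reversed": self.n_reversed,
            "n_signature": self.n_signature,
            "status": self.status.value,
            "rank": self.rank,
        }


def classify_effects(
    signature: TissueSignature,
    fc2: FoldChangeVector,
    reversal_threshold: float = 2.0,
    adverse_threshold: float = 15.0,
    adverse_mode: str = SYMMETRIC,
) -> EffectSets:
    """Partition the shared gene universe into reversed / adverse / neither.

    The gene universe is the intersection of the signature's genes and the
    fold-change vector's genes; genes on only one side are dropped (and the
    drop is logged).  ``strict_paper`` mode omits the (E1 = 0, FC2 < -15)
    adverse branch; ``symmetric`` (default) includes it so that strong
    perturbations of disease-neutral genes count as adverse in both
    directions.
    """
    if adverse_mode not in (STRICT_PAPER, SYMMETRIC):
        raise ConfigError(f"unknown adverse_mode {adverse_mode!r}")
    if adverse_threshold <= reversal_threshold:
        raise ConfigError(
            "adverse_threshold must exceed reversal_threshold "
            f"(got {adverse_threshold} <= {reversal_threshold}); the effect "
            "taxonomy degenerates otherwise"
        )

    shared = signature.genes.intersection(fc2.genes)
    dropped = (len(signature.genes) - len(shared)) + (len(fc2.genes) - len(shared))
    if dropped:
        logger.info(
            "classify_effects %s: universe=%d shared genes (%d dropped as unshared)",
            fc2.key, len(shared), dropped,
        )
    e1 = signature.labels.loc[shared].to_numpy(dtype=int)
    e2 = fc2.fc.loc[shared].to_numpy(dtype=float)

    rev = ((e1 == 1) & (e2 < -reversal_threshold)) | ((e1 == -1) & (e2 > reversal_threshold))
    adv = (
        ((e1 == 1) & (e2 > adverse_threshold))
        | ((e1 == -1) & (e2 < -adverse_threshold))
        | ((e1 == 0) & (e2 > adverse_threshold))
    )
    if adverse_mode == SYMMETRIC:
        adv |= (e1 == 0) & (e2 < -adverse_threshold)

    genes = np.asarray(shared)
    return EffectSets(
        key=fc2.key,
        reversed_genes=frozenset(genes[rev]),
        adverse_genes=frozenset(genes[adv]),
        universe=frozenset(genes),
        signature_name=signature.name,
    )


def rade_from_counts(
    n_adverse: int,
    n_reversed: int,
    n_signature: int,
    key: ConditionKey | None = None,
    signature_name: str | None = None,
) -> RadeResult:
    """RADE score from the three counts, applying the zero-adverse convention.

    #Ad = 0 yields score 0 with status zero_adverse unconditionally (even
    when #Re = 0 as well).  #Re = 0 with #Ad > 0 has no finite score and is
    reported with status undefined_no_reversal and score ``None``.
    """
    if min(n_adverse, n_reversed, n_signature) < 0:
        raise InputError("effect counts must be non-negative")
    key = key or ConditionKey("", "", "", "")
    if n_adverse == 0:
        score, status = 0.0, RadeStatus.ZERO_ADVERSE
    elif n_reversed == 0:
        score, status = None, RadeStatus.UNDEFINED_NO_REVERSAL
    else:
        score = (n_adverse / n_reversed) * (n_signature / n_reversed)
        status = RadeStatus.DEFINED
    return RadeResult(
        key=key,
        score=score,
        n_adverse=n_adverse,
        n_reversed=n_reversed,
        n_signature=n_signature,
        status=status,
        signature_name=signature_name,
    )


def rade_score(effects: EffectSets, signature: TissueSignature) -> RadeResult:
    """Score one condition's effect sets against the disease signature."""
    return rade_from_counts(
        n_adverse=effects.n_adverse,
        n_reversed=effects.n_reversed,
        n_signature=signature.n_signature,
        key=effects.key,
        signature_name=signature.name,
    )


def rank_compounds(results: list[RadeResult]) -> list[RadeResult]:
    """Totally order RADE results and attach 1-based ranks.

    Ascending by score; zero-adverse results (score 0) therefore sit at the
    top and undefined ones sort last.  Ties break by larger reversed count
    (more corrective action preferred), then lexicographically by condition
    key so the order is deterministic.
    """
    if not results:
        return []
    sig_names = {r.signature_name for r in results}
    if len(sig_names) > 1:
        raise InputError(
            f"cannot rank results scored against different signatures: {sorted(map(str, sig_names))}"
        )

    def sort_key(r: RadeResult):
        undefined = r.status is RadeStatus.UNDEFINED_NO_REVERSAL
        return (
            1 if undefined else 0,
            r.score if r.score is not None else 0.0,
            -r.n_reversed,
            r.key.as_tuple(),
        )

    ordered = sorted(results, key=sort_key)
    return [
        RadeResult(
            key=r.key,
            score=r.score,
            n_adverse=r.n_adverse,
            n_reversed=r.n_reversed,
            n_signature=r.n_signature,
            status=r.status,
            signature_name=r.signature_name,
            rank=i + 1,
        )
        for i, r in enumerate(ordered)
    ]


def effect_table(effects: EffectSets, signature: TissueSignature, fc2: FoldChangeVector) -> pd.DataFrame:
    """Per-gene table of E1 label, E2 fold-change and the assigned effect."""
    genes = sorted(effects.universe)
    call = []
    for g in genes:
        if g in effects.reversed_genes:
            call.append("reversed")
        elif g in effects.adverse_genes:
            call.append("adverse")
        else:
            call.append("none")
    return pd.DataFrame(
        {
            "gene_id": genes,
            "e1_label": signature.labels.loc[genes].to_numpy(dtype=int),
            "e2_fc": fc2.fc.loc[genes].to_numpy(dtype=float),
            "effect": call,
        }
    )
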