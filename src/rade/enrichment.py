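"""Hypergeometric pathway enrichment and drug-combination set comparison.

Reversed and adverse gene sets are tested for over-representation in
pathway collections (KEGG/GO/PID/REACTOME-style GMT files) with the
upper-tail hypergeometric test

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n),

where N is the analyzable transcriptome (by default the genes shared by
the tissue signature and the perturbation profile, not the whole genome),
M the pathway's genes within it, n the query genes within it and m the
overlap.  P-values across one collection are corrected with the
Benjamini-Hochberg step-up and a pathway is called significant at
q < 0.05.

The drug-combination comparison partitions two compounds' reversed (and
adverse) gene sets into shared / A-only / B-only, as shown in a Venn
diagram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .effects import EffectSets
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayCollection:
    """Named, non-empty gene sets (one GMT file's worth)."""

    pathways: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.pathways.items() if not genes]
        if empty:
            raise InputError(f"empty pathway gene set(s): {empty[:5]}")

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class ComboComparison:
    """Three-way partition of two compounds' reversed and adverse sets."""

    drug_a: str
    drug_b: str
    reversed_only_a: frozenset[str]
    reversed_only_b: frozenset[str]
    reversed_shared: frozenset[str]
    adverse_only_a: frozenset[str]
    adverse_only_b: frozenset[str]
    adverse_shared: frozenset[str]

    def to_dict(self) -> dict:
        out = {"drug_a": self.drug_a, "drug_b": self.drug_b}
        for part in (
            "reversed_only_a", "reversed_only_b", "reversed_shared",
            "adverse_only_a", "adverse_only_b", "adverse_shared",
        ):
            genes = sorted(getattr(self, part))
            out[part] = genes
            out[f"n_{part}"] = len(genes)
        return out


def hypergeom_pvalue(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail probability of drawing >= m pathway genes in n draws.

    Computed via the hypergeometric survival function (log-space stable
    for large N); m = 0 is exactly 1 by the empty-sum convention.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise InputError(
            f"invalid hypergeometric parameters N={N}, M={M}, n={n}, m={m}: "
            "need 0 <= M <= N, 0 <= n <= N, 0 <= m <= min(n, M)"
        )
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: set[str],
    collection: PathwayCollection,
    universe: set[str],
    alpha: float = 0.05,
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Test each pathway for enrichment of the query set within the universe.

    Query genes outside the universe are dropped (count logged).  Returns
    one row per pathway, sorted by q then p, with columns
    ``pathway N M n m p_value q_value significant``; significance is on
    the FDR-adjusted q at ``alpha`` unless ``use_raw_p``.
    """
    if not universe:
        raise InputError("enrichment universe is empty")
    universe = set(universe)
    q_in = set(query) & universe
    dropped = len(set(query)) - len(q_in)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe", dropped)

    rows = []
    for name in sorted(collection.pathways):
        pw = collection.pathways[name] & universe
        overlap = q_in & pw
        p = hypergeom_pvalue(len(universe), len(pw), len(q_in), len(overlap))
        rows.append((name, len(universe), len(pw), len(q_in), len(overlap), p))
    df = pd.DataFrame(rows, columns=["pathway", "N", "M", "n", "m", "p_value"])
    if df.empty:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["q_value"] = bh_fdr(df["p_value"])
    df["significant"] = (df["p_value"] if use_raw_p else df["q_value"]) < alpha
    return df.sort_values(["q_value", "p_value", "pathway"], kind="stable").reset_index(drop=True)


def compare_combination(effects_a: EffectSets, effects_b: EffectSets) -> ComboComparison:
    """Partition two compounds' effect sets on the same cell line and signature."""
    if effects_a.key.cell_line_id != effects_b.key.cell_line_id:
        raise InputError(
            "combination comparison requires the same cell line "
            f"({effects_a.key.cell_line_id!r} vs {effects_b.key.cell_line_id!r})"
        )
    if effects_a.signature_name != effects_b.signature_name:
        raise InputError(
            "combination comparison requires effect sets from the same signature "
            f"({effects_a.signature_name!r} vs {effects_b.signature_name!r})"
        )
    ra, rb = effects_a.reversed_genes, effects_b.reversed_genes
    aa, ab = effects_a.adverse_genes, effects_b.adverse_genes
    return ComboComparison(
        drug_a=effects_a.key.compound_id,
        drug_b=effects_b.key.compound_id,
        reversed_only_a=ra - rb,
        reversed_only_b=rb - ra,
        reversed_shared=ra & rb,
        adverse_only_a=aa - ab,
        adverse_only_b=ab - aa,
        adverse_shared=aa & ab,
    )


def plot_combination(combo: ComboComparison, path: str, which: str = "reversed") -> None:
    """Write a two-circle Venn diagram of the shared/only counts to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if which == "reversed":
        na = len(combo.reversed_only_a)
        nb = len(combo.reversed_only_b)
        ns = len(combo.reversed_shared)
    elif which == "adverse":
        na = len(combo.adverse_only_a)
        nb = len(combo.adverse_only_b)
        ns = len(combo.adverse_shared)
    else:
        raise InputError(f"which must be 'reversed' or 'adverse', got {which!r}")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.add_patch(Circle((-0.5, 0), 1.0, alpha=0.4, color="tab:blue"))
    ax.add_patch(Circle((0.5, 0), 1.0, alpha=0.4, color="tab:orange"))
    ax.text(-1.0, 0, str(na), ha="center", va="center", fontsize=14)
    ax.text(1.0, 0, str(nb), ha="center", va="center", fontsize=14)
    ax.text(0, 0, str(ns), ha="center", va="center", fontsize=14)
    ax.text(-0.8, 1.15, combo.drug_a, ha="center", fontsize=11)
    ax.text(0.8, 1.15, combo.drug_b, ha="center", fontsize=11)
    ax.set_xlim(-2, 2)
    ax.set_ylim(-1.5, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"{which} genes")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
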