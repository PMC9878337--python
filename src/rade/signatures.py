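"""Disease expression signatures from cancer-vs-normal differential expression.

The first differential comparison (E1) contrasts cancer tissue with matched
normal tissue.  A gene enters the disease signature when its fold-change
exceeds +2 (upregulated, label +1) or falls below -2 (downregulated, label
-1) with p < 0.001; everything else is labelled 0.  Upstream of labelling, a
low-count prefilter drops genes whose raw counts are too low in either the
cancer or the normal sample group to support a differential call.

Differential-expression estimation itself (e.g. a DESeq2 run) is an input
contract, not something this module performs: it consumes the resulting
table of per-gene fold-changes and p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

CANCER = "cancer"
NORMAL = "normal"


@dataclass(frozen=True)
class CountMatrix:
    """Raw RNA-seq counts, genes x samples, with a cancer/normal group label.

    Parameters
    ----------
    counts
        Integer DataFrame indexed by gene id with one column per sample.
    groups
        Series mapping each sample (column of ``counts``) to ``"cancer"``
        or ``"normal"``.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise InputError(f"duplicate gene ids in count matrix: {list(dups)[:5]}")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise InputError(f"samples without a group label: {missing[:5]}")
        bad = set(self.groups.loc[list(self.counts.columns)]) - {CANCER, NORMAL}
        if bad:
            raise InputError(f"unknown group labels {sorted(bad)}; expected cancer/normal")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("negative counts are not allowed")

    def group_samples(self, group: str) -> list[str]:
        labels = self.groups.loc[list(self.counts.columns)]
        return [s for s, g in labels.items() if g == group]


@dataclass(frozen=True)
class TissueSignature:
    """Labelled disease signature for one cancer cohort.

    ``table`` is indexed by gene id and carries ``fc`` (signed-ratio
    fold-change), ``p_value`` and ``label`` in {-1, 0, +1}.  The signature
    set Mu -- genes significantly changed in the cancer -- is every gene
    with a non-zero label.
    """

    table: pd.DataFrame
    fc_threshold: float = 2.0
    p_threshold: float = 0.001
    name: str | None = None
    cancer_signature_set: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        sig = frozenset(self.table.index[self.table["label"] != 0])
        object.__setattr__(self, "cancer_signature_set", sig)

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def n_signature(self) -> int:
        return len(self.cancer_signature_set)


def log2_to_signed_ratio(x: np.ndarray | pd.Series | float):
    """Convert log2 fold-change to the signed-ratio convention.

    A log2 fold-change of ``x >= 0`` maps to the ratio ``2**x``; a negative
    one maps to ``-(2**(-x))``, so e.g. log2FC = -1 becomes -2 ("halved").
    On this scale the +/-2 thresholds of the labelling rule apply directly.
    """
    arr = np.asarray(x, dtype=float)
    out = np.where(arr >= 0, np.exp2(arr), -np.exp2(-arr))
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def signed_ratio_to_log2(x: np.ndarray | pd.Series | float):
    """Inverse of :func:`log2_to_signed_ratio`; defined for |x| >= 1 only."""
    arr = np.asarray(x, dtype=float)
    if (np.abs(arr) < 1).any():
        raise InputError("signed-ratio fold-changes must satisfy |fc| >= 1 to map to log2")
    out = np.sign(arr) * np.log2(np.abs(arr))
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def prefilter_low_counts(matrix: CountMatrix, min_group_total: int = 10) -> list[str]:
    """Return gene ids whose group-wise total count passes the low-count filter.

    A gene is retained only when the total raw count across the cancer
    samples AND across the normal samples are both >= ``min_group_total``
    (default 10).  Order of the input matrix is preserved.
    """
    cancer = matrix.group_samples(CANCER)
    normal = matrix.group_samples(NORMAL)
    if not cancer or not normal:
        raise InputError("count matrix needs at least one cancer and one normal sample")
    cancer_tot = matrix.counts[cancer].sum(axis=1)
    normal_tot = matrix.counts[normal].sum(axis=1)
    keep = (cancer_tot >= min_group_total) & (normal_tot >= min_group_total)
    return list(matrix.counts.index[keep])


def validate_de_table(de: pd.DataFrame) -> None:
    """Check a DE table's contract: unique genes, finite fc, p in [0, 1]."""
    if de.empty:
        raise InputError("empty differential-expression table")
    if de.index.has_duplicates:
        dups = de.index[de.index.duplicated()].unique()
        raise InputError(f"duplicate gene ids in DE table: {list(dups)[:5]}")
    bad_fc = de.index[~np.isfinite(de["fc"].to_numpy(dtype=float))]
    if len(bad_fc):
        raise InputError(f"non-finite fold-change for gene(s) {list(bad_fc)[:5]}")
    p = de["p_value"].to_numpy(dtype=float)
    bad_p = de.index[~((p >= 0) & (p <= 1))]
    if len(bad_p):
        raise InputError(f"p-value outside [0, 1] for gene(s) {list(bad_p)[:5]}")


def label_tissue_genes(
    de: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.001,
    name: str | None = None,
) -> TissueSignature:
    """Label each gene of a DE table as up (+1), down (-1) or unchanged (0).

    ``de`` is indexed by gene id with columns ``fc`` (signed-ratio
    fold-change) and ``p_value``.  Label +1 requires fc > fc_threshold and
    p < p_threshold, -1 requires fc < -fc_threshold and p < p_threshold;
    all inequalities are strict, so a gene sitting exactly on a threshold
    stays 0.  The p-value is used raw; multiple-testing correction belongs
    to the enrichment stage, not here.
    """
    if fc_threshold <= 0 or not (0 < p_threshold < 1):
        raise ConfigError(
            f"thresholds must satisfy fc_threshold > 0 and 0 < p_threshold < 1; "
            f"got fc_threshold={fc_threshold}, p_threshold={p_threshold}"
        )
    validate_de_table(de)
    fc = de["fc"].to_numpy(dtype=float)
    p = de["p_value"].to_numpy(dtype=float)
    sig = p < p_threshold
    label = np.zeros(len(de), dtype=int)
    label[(fc > fc_threshold) & sig] = 1
    label[(fc < -fc_threshold) & sig] = -1
    table = pd.DataFrame(
        {"fc": fc, "p_value": p, "label": label}, index=de.index.copy()
    )
    return TissueSignature(
        table=table, fc_threshold=fc_threshold, p_threshold=p_threshold, name=name
    )
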