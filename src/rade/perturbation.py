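"""Compound-perturbation response: treated-vs-vehicle fold-changes (E2).

The second differential comparison (E2) contrasts a compound-treated cell
line with its DMSO (vehicle) control, one record per
(compound, cell line, dose, duration) condition.  The per-gene fold-change
is

    FC_j = (T_j - D_j) / max(|D_j|, floor)

with a floor (default 0.1) on the denominator so that weakly expressed
control genes cannot blow the ratio up to infinity.  Genes are then
labelled +1 / -1 when |FC| exceeds 2, mirroring the tissue-side rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError


@dataclass(frozen=True)
class ConditionKey:
    """Identity of one perturbation condition; dose/duration kept verbatim."""

    compound_id: str
    cell_line_id: str
    dose: str
    duration: str

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.compound_id, self.cell_line_id, self.dose, self.duration)

    def __str__(self) -> str:
        return "|".join(self.as_tuple())


@dataclass(frozen=True)
class PerturbationProfile:
    """Treated and control expression vectors for one condition.

    ``treated`` and ``control`` are gene-indexed Series sharing one index.
    If replicates are supplied per condition they must be collapsed (mean
    per gene) before constructing the profile; the long-format reader in
    :mod:`rade.io` does this and logs it.
    """

    key: ConditionKey
    treated: pd.Series
    control: pd.Series

    def __post_init__(self) -> None:
        t_idx, c_idx = self.treated.index, self.control.index
        if not t_idx.equals(c_idx):
            only_t = sorted(set(t_idx) - set(c_idx))
            only_c = sorted(set(c_idx) - set(t_idx))
            raise InputError(
                f"treated/control gene sets differ for {self.key}: "
                f"treated-only {only_t[:5]}, control-only {only_c[:5]}"
            )
        if t_idx.has_duplicates:
            raise InputError(f"duplicate gene ids in profile {self.key}")
        for name, vec in (("treated", self.treated), ("control", self.control)):
            bad = vec.index[~np.isfinite(vec.to_numpy(dtype=float))]
            if len(bad):
                raise InputError(
                    f"non-finite {name} expression for gene(s) {list(bad)[:5]} in {self.key}"
                )


@dataclass(frozen=True)
class FoldChangeVector:
    """Per-gene signed fold-changes for one condition plus the floor used."""

    key: ConditionKey
    fc: pd.Series
    floor: float = 0.1

    @property
    def genes(self) -> pd.Index:
        return self.fc.index


def perturbation_fold_change(
    profile: PerturbationProfile, floor: float = 0.1
) -> FoldChangeVector:
    """Per-gene fold-change of treated vs control with a floored denominator.

    FC_j = (T_j - D_j) / max(|D_j|, floor).  The result is exact arithmetic:
    no clipping or winsorising is applied to the output.  Negative control
    values are tolerated (the denominator uses |D|), and treated == control
    always yields exactly 0.
    """
    if floor <= 0:
        raise ConfigError(f"floor must be positive, got {floor}")
    t = profile.treated.to_numpy(dtype=float)
    d = profile.control.to_numpy(dtype=float)
    fc = (t - d) / np.maximum(np.abs(d), floor)
    return FoldChangeVector(
        key=profile.key,
        fc=pd.Series(fc, index=profile.treated.index.copy()),
        floor=floor,
    )


def label_perturbation_genes(fc: FoldChangeVector, threshold: float = 2.0) -> pd.Series:
    """Label genes +1 / -1 / 0 by strict comparison of |FC| with the threshold."""
    if threshold <= 0:
        raise ConfigError(f"threshold must be positive, got {threshold}")
    vals = fc.fc.to_numpy(dtype=float)
    label = np.zeros(len(vals), dtype=int)
    label[vals > threshold] = 1
    label[vals < -threshold] = -1
    return pd.Series(label, index=fc.genes.copy())
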