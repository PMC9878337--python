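"""Synthetic fixtures with planted ground truth for every pipeline stage.

Nothing here downloads or imitates real cohorts; the generators emit small
worlds whose true signature genes, reversed/adverse genes, sample-to-cell-
line assignments and enriched pathway are known by construction, so each
stage of the pipeline can be verified against a recorded truth object.

What is emulated and what is not:

* the tissue cohort generator produces negative-binomial raw counts (for
  exercising the low-count prefilter) and a differential-expression table
  with exact planted fold-changes for signal genes, near-unity fold-
  changes for null genes, small p-values for signal and uniform p-values
  for null.  Real DE tables carry estimation noise on the fold-changes;
  this one does not, by design, so that recovery tests are deterministic.
* the perturbation generator plants exact treated-vs-control fold-changes
  (opposite-direction beyond +/-2 for reversed genes, same-direction
  beyond +/-15 for adverse genes) plus optional additive Gaussian noise
  on the treated channel.  This is a stand-in, not a model of L1000-style
  assay noise, and it carries no transcriptome covariance structure.
* the mutation generator draws each sample's mutated genes mostly from
  its assigned cell line's (disjoint) mutation set plus private noise
  genes.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .matching import MutationProfile
from .enrichment import PathwayCollection
from .perturbation import ConditionKey, PerturbationProfile
from .signatures import CountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TissueTruth:
    seed: int
    gene_ids: tuple[str, ...]
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    effect_size: float

    @property
    def signature_genes(self) -> frozenset[str]:
        return self.up_genes | self.down_genes


@dataclass(frozen=True)
class PerturbationTruth:
    seed: int
    key: ConditionKey
    reversed_genes: frozenset[str]
    adverse_genes: frozenset[str]
    reversal_fraction: float
    adverse_fraction: float
    noise_sd: float


@dataclass(frozen=True)
class MutationTruth:
    seed: int
    assignments: dict[str, str]  # sample id -> planted cell line id


@dataclass(frozen=True)
class PathwayTruth:
    seed: int
    enriched_pathway: str


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_tissue_cohort(
    n_genes: int = 2000,
    n_up: int = 50,
    n_down: int = 50,
    n_cancer: int = 20,
    n_normal: int = 20,
    effect_size: float = 4.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame, TissueTruth]:
    """Simulate a cancer-vs-normal cohort with a planted expression signature.

    Returns raw counts (genes x samples, negative binomial around gene-level
    base means), a DE table indexed by gene id with signed-ratio ``fc`` and
    ``p_value``, and the truth object.  Signal genes carry fc exactly
    ``+effect_size`` (up) or ``-effect_size`` (down) with p ~ 10^-U(4, 8);
    null genes carry |fc| near 1 with p ~ U(0, 1).  ``effect_size=1`` means
    no planted change anywhere.
    """
    if n_up + n_down > n_genes:
        raise InputError(f"n_up + n_down = {n_up + n_down} exceeds n_genes = {n_genes}")
    if min(n_genes, n_cancer, n_normal) < 1 or n_up < 0 or n_down < 0:
        raise InputError("cohort sizes must be positive")
    if effect_size < 1 or dispersion <= 0:
        raise InputError("effect_size must be >= 1 and dispersion > 0")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    idx = rng.permutation(n_genes)
    up = np.asarray(genes)[idx[:n_up]]
    down = np.asarray(genes)[idx[n_up : n_up + n_down]]
    up_set, down_set = frozenset(up), frozenset(down)

    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n_genes)
    cancer_mean = base.copy()
    is_up = np.isin(genes, up)
    is_down = np.isin(genes, down)
    cancer_mean[is_up] *= effect_size
    cancer_mean[is_down] /= effect_size

    r = 1.0 / dispersion  # NB size parameter; variance = mu + dispersion * mu^2
    def _nb(mean: np.ndarray, n_samples: int) -> np.ndarray:
        p = r / (r + mean)
        return rng.negative_binomial(r, p[:, None], size=(n_genes, n_samples))

    counts = np.hstack([_nb(cancer_mean, n_cancer), _nb(base, n_normal)])
    sample_ids = [f"C{i:03d}" for i in range(n_cancer)] + [f"N{i:03d}" for i in range(n_normal)]
    groups = pd.Series(
        ["cancer"] * n_cancer + ["normal"] * n_normal, index=sample_ids, name="group"
    )
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=sample_ids),
        groups=groups,
    )

    fc = np.empty(n_genes)
    null_ratio = np.exp2(rng.normal(0.0, 0.15, size=n_genes))
    fc[:] = np.where(null_ratio >= 1, null_ratio, -1.0 / null_ratio)
    fc[is_up] = effect_size
    fc[is_down] = -effect_size
    p = rng.uniform(0.0, 1.0, size=n_genes)
    signal = is_up | is_down
    p[signal] = 10.0 ** rng.uniform(-8.0, -4.0, size=int(signal.sum()))

    de = pd.DataFrame({"fc": fc, "p_value": p}, index=pd.Index(genes, name="gene_id"))
    truth = TissueTruth(
        seed=seed,
        gene_ids=tuple(genes),
        up_genes=up_set,
        down_genes=down_set,
        effect_size=effect_size,
    )
    return matrix, de, truth


def simulate_perturbation(
    tissue_truth: TissueTruth,
    reversal_fraction: float,
    adverse_fraction: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    compound_id: str = "cpd_A",
    cell_line_id: str = "CL1",
    dose: str = "10 uM",
    duration: str = "24 h",
    reversed_fc: float = 3.0,
    adverse_fc: float = 16.0,
    floor: float = 0.1,
) -> tuple[PerturbationProfile, PerturbationTruth]:
    """Simulate one compound perturbation against a planted tissue signature.

    A ``reversal_fraction`` of the signature genes receive a treated-vs-
    control fold-change of ``reversed_fc`` magnitude in the direction
    opposite their disease change; an ``adverse_fraction`` of the
    non-signature genes receive ``adverse_fc`` (strong perturbation of a
    disease-neutral gene, adverse in either classification mode).  The
    remaining genes move only by the additive Gaussian noise on the
    treated channel.  At ``noise_sd=0`` the classification of the emitted
    profile equals the planted truth exactly.
    """
    if not (0.0 <= reversal_fraction <= 1.0 and 0.0 <= adverse_fraction <= 1.0):
        raise InputError("reversal_fraction and adverse_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(tissue_truth.gene_ids)
    n = len(genes)
    gene_arr = np.asarray(genes)

    sig_genes = sorted(tissue_truth.signature_genes)
    null_genes = sorted(set(genes) - tissue_truth.signature_genes)

    n_rev = int(round(reversal_fraction * len(sig_genes)))
    if reversal_fraction > 0 and n_rev < 1:
        warnings.warn(
            "reversal_fraction too small for the signature size; planting 0 reversed genes",
            stacklevel=2,
        )
    rev_pick = rng.choice(sig_genes, size=n_rev, replace=False) if n_rev else np.array([], dtype=object)
    n_adv = int(round(adverse_fraction * len(null_genes)))
    adv_pick = rng.choice(null_genes, size=n_adv, replace=False) if n_adv else np.array([], dtype=object)

    control = rng.uniform(5.0, 15.0, size=n)
    fc_target = np.zeros(n)
    rev_set = set(rev_pick)
    for i, g in enumerate(genes):
        if g in rev_set:
            # push opposite the disease direction, beyond the reversal threshold
            fc_target[i] = -reversed_fc if g in tissue_truth.up_genes else reversed_fc
    adv_idx = np.isin(gene_arr, adv_pick)
    fc_target[adv_idx] = adverse_fc

    treated = control + fc_target * np.maximum(np.abs(control), floor)
    if noise_sd > 0:
        treated = treated + rng.normal(0.0, noise_sd, size=n)

    key = ConditionKey(compound_id, cell_line_id, dose, duration)
    profile = PerturbationProfile(
        key=key,
        treated=pd.Series(treated, index=pd.Index(genes, name="gene_id")),
        control=pd.Series(control, index=pd.Index(genes, name="gene_id")),
    )
    truth = PerturbationTruth(
        seed=seed,
        key=key,
        reversed_genes=frozenset(rev_pick),
        adverse_genes=frozenset(adv_pick),
        reversal_fraction=reversal_fraction,
        adverse_fraction=adverse_fraction,
        noise_sd=noise_sd,
    )
    return profile, truth


def simulate_mutation_world(
    n_cell_lines: int = 10,
    genes_per_line: int = 50,
    samples_per_line: int = 20,
    private_fraction: float = 0.1,
    seed: int = 0,
    sample_coverage: float = 0.8,
) -> tuple[list[MutationProfile], list[MutationProfile], MutationTruth]:
    """Simulate cell-line mutation sets and tumor samples assigned to them.

    Cell lines carry disjoint mutated-gene sets.  Each sample draws
    ``sample_coverage`` of its assigned line's genes plus private noise
    genes (a ``private_fraction`` of its set, from a pool no cell line
    carries).  With ``private_fraction=0`` every sample is a subset of its
    line, so argmax matching recovers the planted assignment exactly.
    """
    if min(n_cell_lines, genes_per_line, samples_per_line) < 1:
        raise InputError("world sizes must be positive")
    if not (0.0 <= private_fraction < 1.0):
        raise InputError("private_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    cell_lines = []
    for i in range(n_cell_lines):
        genes = frozenset(f"MUT_{i:02d}_{j:03d}" for j in range(genes_per_line))
        cell_lines.append(MutationProfile(id=f"CL{i:02d}", genes=genes, kind="cell_line"))

    samples: list[MutationProfile] = []
    assignments: dict[str, str] = {}
    n_core = max(1, int(round(sample_coverage * genes_per_line)))
    n_private = int(round(private_fraction * n_core))
    for i, cl in enumerate(cell_lines):
        pool = sorted(cl.genes)
        for j in range(samples_per_line):
            sid = f"S{i:02d}_{j:03d}"
            core = rng.choice(pool, size=n_core, replace=False)
            private = {f"PRIV_{sid}_{k}" for k in range(n_private)}
            samples.append(MutationProfile(id=sid, genes=frozenset(core) | private, kind="sample"))
            assignments[sid] = cl.id
    truth = MutationTruth(seed=seed, assignments=assignments)
    return samples, cell_lines, truth


def simulate_pathways(
    query_genes: set[str],
    universe: set[str],
    n_pathways: int = 10,
    pathway_size: int = 25,
    enriched_overlap: float = 0.8,
    seed: int = 0,
) -> tuple[PathwayCollection, PathwayTruth]:
    """Toy GMT-style collection with one pathway enriched for the query set.

    The planted pathway draws ``enriched_overlap`` of its genes from the
    query; background pathways draw uniformly from the non-query universe.
    """
    universe = set(universe)
    query = set(query_genes) & universe
    background_pool = sorted(universe - query)
    if not query or len(background_pool) < pathway_size:
        raise InputError("universe too small or query empty for pathway simulation")
    rng = np.random.default_rng(seed)

    n_hit = min(int(round(enriched_overlap * pathway_size)), len(query))
    planted = set(rng.choice(sorted(query), size=n_hit, replace=False))
    planted |= set(rng.choice(background_pool, size=pathway_size - n_hit, replace=False))

    pathways = {"PW_PLANTED": frozenset(planted)}
    for i in range(n_pathways - 1):
        pathways[f"PW_BG{i:02d}"] = frozenset(
            rng.choice(background_pool, size=pathway_size, replace=False)
        )
    return (
        PathwayCollection(pathways=pathways, source="synthetic"),
        PathwayTruth(seed=seed, enriched_pathway="PW_PLANTED"),
    )


def write_fixture_dir(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 2000,
    reversal_fractions: tuple[float, ...] = (0.8, 0.5, 0.2),
    adverse_fraction: float = 0.05,
    noise_sd: float = 0.0,
) -> Path:
    """Write a complete synthetic fixture directory in the package's file dialects.

    Emits counts + group sidecar, a DE table, one long-format perturbation
    file covering one compound per reversal fraction, mutation long files
    for samples and cell lines, a toy GMT, and ``truth.json`` recording
    every planted set.  Byte-identical under a fixed seed.
    """
    from . import io as rio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, de, t_truth = simulate_tissue_cohort(n_genes=n_genes, seed=seed)
    rio.write_count_matrix(matrix, out / "counts.tsv", out / "groups.tsv")
    rio.write_de_table(de, out / "de_table.tsv")

    profiles, p_truths = [], []
    for i, rho in enumerate(reversal_fractions):
        prof, pt = simulate_perturbation(
            t_truth,
            reversal_fraction=rho,
            adverse_fraction=adverse_fraction,
            noise_sd=noise_sd,
            seed=seed + 1 + i,
            compound_id=f"cpd_{chr(ord('A') + i)}",
        )
        profiles.append(prof)
        p_truths.append(pt)
    rio.write_perturbations_long(profiles, out / "perturbations.tsv")

    samples, lines, m_truth = simulate_mutation_world(seed=seed)
    rio.write_mutations_long(samples, out / "sample_mutations.tsv")
    rio.write_mutations_long(lines, out / "cell_line_mutations.tsv")

    sig_genes = t_truth.signature_genes
    collection, pw_truth = simulate_pathways(
        query_genes=set(p_truths[0].reversed_genes),
        universe=set(t_truth.gene_ids),
        seed=seed,
    )
    rio.write_gmt(collection, out / "pathways.gmt")

    truth = {
        "seed": seed,
        "up_genes": sorted(t_truth.up_genes),
        "down_genes": sorted(t_truth.down_genes),
        "signature_genes": sorted(sig_genes),
        "perturbations": [
            {
                "compound_id": pt.key.compound_id,
                "cell_line_id": pt.key.cell_line_id,
                "dose": pt.key.dose,
                "duration": pt.key.duration,
                "reversal_fraction": pt.reversal_fraction,
                "adverse_fraction": pt.adverse_fraction,
                "noise_sd": pt.noise_sd,
                "reversed_genes": sorted(pt.reversed_genes),
                "adverse_genes": sorted(pt.adverse_genes),
            }
            for pt in p_truths
        ],
        "assignments": m_truth.assignments,
        "enriched_pathway": pw_truth.enriched_pathway,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    logger.info("wrote synthetic fixture to %s (seed=%d)", out, seed)
    return out
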