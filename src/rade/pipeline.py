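"""End-to-end pipeline: signature → perturbation → scoring → enrichment.

One :func:`run_pipeline` call reads the configured inputs, executes every
applicable stage and leaves a run directory with per-stage text outputs
plus a machine-readable ``summary.json``.  Optional stages (cohort
selection, enrichment, combination comparison) run only when their inputs
are configured.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import io as rio
from .config import RunConfig
from .effects import classify_effects, effect_table, rade_score, rank_compounds
from .enrichment import compare_combination, enrich
from .errors import InputError
from .matching import best_match, select_cohort
from .perturbation import perturbation_fold_change
from .signatures import label_tissue_genes, prefilter_low_counts

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage and return the output directory.

    Required paths in ``config.paths``: ``de_table``, ``perturbations``,
    ``outdir``.  Optional: ``counts`` + ``groups`` (prefilter applied to
    the DE table), ``sample_mutations`` + ``cell_line_mutations`` (cohort
    stage), ``gmt`` (enrichment of the top-ranked condition's reversed and
    adverse sets).
    """
    config.validate()
    config.log_resolved()
    paths = config.paths
    for required in ("de_table", "perturbations", "outdir"):
        if required not in paths:
            raise InputError(f"config.paths is missing required entry {required!r}")
    out = Path(paths["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    # --- stage 1: disease signature
    de = rio.read_de_table(paths["de_table"], fc_scale=config.fc_scale)
    if "counts" in paths and "groups" in paths:
        matrix = rio.read_count_matrix(paths["counts"], paths["groups"])
        retained = prefilter_low_counts(matrix)
        de = de.loc[de.index.intersection(retained)]
        logger.info("prefilter retained %d/%d genes", len(de), len(matrix.counts))
    signature = label_tissue_genes(
        de,
        fc_threshold=config.fc_threshold,
        p_threshold=config.p_threshold,
        name=Path(paths["de_table"]).stem,
    )
    rio.write_signature(signature, out / "signature.tsv")

    # --- stage 2+3: perturbation fold-changes, classification, scoring
    profiles = rio.read_perturbations_long(paths["perturbations"])
    results, effect_sets = [], {}
    for profile in profiles:
        fc2 = perturbation_fold_change(profile, floor=config.floor)
        effects = classify_effects(
            signature,
            fc2,
            reversal_threshold=config.reversal_threshold,
            adverse_threshold=config.adverse_threshold,
            adverse_mode=config.adverse_mode,
        )
        effect_sets[effects.key.as_tuple()] = effects
        results.append(rade_score(effects, signature))
        rio.write_effect_table(
            effect_table(effects, signature, fc2),
            out / f"effects_{profile.key.compound_id}.tsv",
        )
    ranked = rank_compounds(results)
    rio.write_rade_results(ranked, out / "rade_results.tsv")

    # --- stage 4 (optional): patient matching and cohort selection
    cohort_ids = None
    if "sample_mutations" in paths and "cell_line_mutations" in paths:
        samples = rio.read_mutations_long(paths["sample_mutations"], kind="sample")
        lines = rio.read_mutations_long(paths["cell_line_mutations"], kind="cell_line")
        matches = [best_match(s, lines) for s in samples]
        rio.write_json(
            {m.sample_id: {"best": m.best, "tied": m.tied, "scores": m.scores} for m in matches},
            out / "match_scores.json",
        )
        cell_line = config.cohort_cell_line or ranked[0].key.cell_line_id
        cohort_ids = select_cohort(
            config.cohort_strategy,
            samples,
            cell_line,
            cell_lines=lines,
            specific_gene=config.cohort_specific_gene,
            min_score=config.cohort_min_score,
        )
        (out / "cohort.txt").write_text("".join(f"{s}\n" for s in sorted(cohort_ids)))

    # --- stage 5 (optional): enrichment of the top-ranked condition
    if "gmt" in paths and ranked:
        collection = rio.read_gmt(paths["gmt"])
        top = effect_sets[ranked[0].key.as_tuple()]
        universe = set(top.universe)
        for label, query in (("reversed", top.reversed_genes), ("adverse", top.adverse_genes)):
            table = enrich(set(query), collection, universe, alpha=config.alpha)
            table.to_csv(
                out / f"enrichment_{label}.tsv", sep="\t", index=False,
                float_format=rio.FLOAT_FMT,
            )

    # --- stage 6 (optional): combination comparison of the two top compounds
    if len(ranked) >= 2:
        a = effect_sets[ranked[0].key.as_tuple()]
        b = effect_sets[ranked[1].key.as_tuple()]
        if a.key.cell_line_id == b.key.cell_line_id:
            rio.write_json(compare_combination(a, b).to_dict(), out / "combination.json")

    summary = {
        "config": config.to_dict(),
        "n_signature": signature.n_signature,
        "n_conditions": len(ranked),
        "results": [r.to_dict() for r in ranked],
        "cohort": sorted(cohort_ids) if cohort_ids is not None else None,
    }
    rio.write_json(summary, out / "summary.json")
    return out
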