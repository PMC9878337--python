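"""Tumor-to-cell-line matching by mutation-set similarity.

Cell lines of one cancer type differ genetically and respond differently
to the same drug, so a patient is mapped to the cell line whose mutated
genes their tumor best recapitulates.  The match score of sample s on
cell line k is the fraction of the cell line's mutated genes also mutated
in the sample,

    Match_k(s) = |DE(s) n Mucl(k)| / |Mucl(k)|,

and L(s) is the argmax cell line.  Identity is at the gene level (gene
symbols), not the variant level.

Three reference-cohort strategies select which tumor samples define the
disease signature for a cell line: ``all`` (every sample of the cancer
type), ``mutation_match`` (samples whose best-matching cell line is k)
and ``specific_mutation`` (samples carrying one particular mutated gene
that the cell line also carries).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError, InputError

STRATEGIES = ("all", "mutation_match", "specific_mutation")


@dataclass(frozen=True)
class MutationProfile:
    """A named set of mutated genes for a tumor sample or a cell line."""

    id: str
    genes: frozenset[str]
    kind: str = "sample"  # "sample" or "cell_line"

    def __post_init__(self) -> None:
        if self.kind not in ("sample", "cell_line"):
            raise InputError(f"unknown profile kind {self.kind!r}")


@dataclass(frozen=True)
class MatchResult:
    sample_id: str
    scores: dict[str, float]
    best: str
    tied: bool = False

    @property
    def best_score(self) -> float:
        return self.scores[self.best]


def match_score(sample: MutationProfile, cell_line: MutationProfile) -> float:
    """Fraction of the cell line's mutated genes shared by the sample."""
    if not cell_line.genes:
        raise InputError(
            f"cell line {cell_line.id!r} has an empty mutation set; match score undefined"
        )
    return len(sample.genes & cell_line.genes) / len(cell_line.genes)


def best_match(sample: MutationProfile, cell_lines: list[MutationProfile]) -> MatchResult:
    """Argmax cell line for a sample; ties go to the lexicographically smallest id.

    A sample with an empty mutation set scores 0 against every cell line;
    it is still assigned (to the tie-break winner) with ``tied=True`` so
    that callers can flag rather than drop it.
    """
    if not cell_lines:
        raise InputError("best_match requires at least one cell line")
    scores = {cl.id: match_score(sample, cl) for cl in cell_lines}
    top = max(scores.values())
    winners = sorted(k for k, v in scores.items() if v == top)
    return MatchResult(
        sample_id=sample.id, scores=scores, best=winners[0], tied=len(winners) > 1
    )


def select_cohort(
    strategy: str,
    samples: list[MutationProfile],
    cell_line: str,
    cell_lines: list[MutationProfile] | None = None,
    specific_gene: str | None = None,
    min_score: float = 0.0,
) -> list[str]:
    """Select the tumor-sample cohort for cell line ``cell_line``.

    ``mutation_match`` assigns each sample to its best-matching cell line
    and keeps those assigned to ``cell_line`` with best score >=
    ``min_score`` (default 0, i.e. no floor).  ``specific_mutation`` keeps
    samples carrying ``specific_gene``, which the chosen cell line must
    itself carry.
    """
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown cohort strategy {strategy!r}; expected one of {STRATEGIES}")

    if strategy == "all":
        return [s.id for s in samples]

    if strategy == "mutation_match":
        if not cell_lines:
            raise InputError("mutation_match strategy requires the cell-line profiles")
        chosen = []
        for s in samples:
            res = best_match(s, cell_lines)
            if res.best == cell_line and res.best_score >= min_score:
                chosen.append(s.id)
        return chosen

    # specific_mutation
    if specific_gene is None:
        raise InputError("specific_mutation strategy requires specific_gene")
    if cell_lines is None:
        raise InputError("specific_mutation strategy requires the cell-line profiles")
    by_id = {cl.id: cl for cl in cell_lines}
    if cell_line not in by_id:
        raise InputError(f"unknown cell line {cell_line!r}")
    if specific_gene not in by_id[cell_line].genes:
        raise InputError(
            f"cell line {cell_line!r} does not carry the specific mutation {specific_gene!r}"
        )
    return [s.id for s in samples if specific_gene in s.genes]
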