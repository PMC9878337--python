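"""Readers and writers for the package's plain-text file dialects.

All tabular files are tab-delimited with a single header row; floats are
printed with 6 significant digits; gene-set outputs are sorted
lexicographically so reruns diff cleanly.  Genes are matched by exact
string identifier everywhere — no symbol aliasing or ID mapping.

Supported inputs: DE tables (``gene_id  fc|log2fc  p_value``), count
matrices with a two-column sample→group sidecar, long-format perturbation
tables, GCT #1.2/#1.3 expression matrices, long-format or MAF-lite
mutation files, and GMT pathway collections.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import EffectSets, RadeResult
from .enrichment import PathwayCollection
from .errors import InputError
from .matching import MutationProfile
from .perturbation import ConditionKey, PerturbationProfile
from .signatures import (
    CountMatrix,
    TissueSignature,
    log2_to_signed_ratio,
    signed_ratio_to_log2,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise InputError(f"failed to parse {path}: {exc}") from exc


# ---------------------------------------------------------------- DE tables

def read_de_table(path: str | Path, fc_scale: str = "log2") -> pd.DataFrame:
    """Read a DE table into a gene-indexed frame with signed-ratio ``fc``.

    A ``log2fc`` column is always converted to the signed-ratio scale.  A
    plain ``fc`` column is converted only when ``fc_scale == "log2"``;
    pass ``fc_scale="signed_ratio"`` if the column already holds signed
    ratios.
    """
    if fc_scale not in ("log2", "signed_ratio"):
        raise InputError(f"unknown fc_scale {fc_scale!r}")
    df = _read_tsv(path)
    cols = set(df.columns)
    if "gene_id" not in cols or "p_value" not in cols:
        raise InputError(f"{path}: DE table needs gene_id and p_value columns, got {sorted(cols)}")
    if "log2fc" in cols:
        fc = log2_to_signed_ratio(df["log2fc"].to_numpy(dtype=float))
    elif "fc" in cols:
        raw = df["fc"].to_numpy(dtype=float)
        fc = log2_to_signed_ratio(raw) if fc_scale == "log2" else raw
    else:
        raise InputError(f"{path}: DE table needs an fc or log2fc column")
    out = pd.DataFrame(
        {"fc": fc, "p_value": df["p_value"].to_numpy(dtype=float)},
        index=pd.Index(df["gene_id"].astype(str), name="gene_id"),
    )
    return out


def write_de_table(de: pd.DataFrame, path: str | Path, fc_scale: str = "log2") -> None:
    """Write a gene-indexed DE table; signed-ratio fc is stored as log2fc by default."""
    df = de.copy()
    if fc_scale == "log2":
        df = pd.DataFrame(
            {"log2fc": signed_ratio_to_log2(de["fc"]), "p_value": de["p_value"]},
            index=de.index,
        )
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


# ------------------------------------------------------------ count matrices

def read_count_matrix(counts_path: str | Path, groups_path: str | Path) -> CountMatrix:
    """Read a genes x samples count TSV plus its sample→group sidecar."""
    counts = _read_tsv(counts_path, index_col=0)
    counts.index = counts.index.astype(str)
    groups_df = _read_tsv(groups_path)
    if groups_df.shape[1] < 2:
        raise InputError(f"{groups_path}: expected two columns (sample_id, group)")
    groups = pd.Series(
        groups_df.iloc[:, 1].astype(str).to_numpy(),
        index=groups_df.iloc[:, 0].astype(str),
        name="group",
    )
    return CountMatrix(counts=counts, groups=groups)


def write_count_matrix(matrix: CountMatrix, counts_path: str | Path, groups_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    matrix.groups.rename_axis("sample_id").to_frame().to_csv(groups_path, sep="\t")


# ------------------------------------------------------------- perturbations

PERTURBATION_COLS = [
    "compound_id", "cell_line_id", "dose", "duration", "gene_id", "treated", "control",
]


def read_perturbations_long(path: str | Path) -> list[PerturbationProfile]:
    """Read a long-format perturbation table into one profile per condition.

    Replicate rows (same condition and gene) are collapsed by the mean of
    treated and control before fold-change computation; collapsing is
    logged per condition.
    """
    df = _read_tsv(path, dtype={c: str for c in PERTURBATION_COLS[:5]})
    missing = [c for c in PERTURBATION_COLS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing perturbation columns {missing}")
    profiles = []
    key_cols = PERTURBATION_COLS[:4]
    for key_vals, grp in df.groupby(key_cols, sort=True):
        key = ConditionKey(*key_vals)
        n_rows = len(grp)
        collapsed = grp.groupby("gene_id", sort=True)[["treated", "control"]].mean()
        if len(collapsed) < n_rows:
            logger.info(
                "replicates collapsed by mean for %s: %d rows -> %d genes",
                key, n_rows, len(collapsed),
            )
        profiles.append(
            PerturbationProfile(
                key=key,
                treated=collapsed["treated"].astype(float),
                control=collapsed["control"].astype(float),
            )
        )
    return profiles


def write_perturbations_long(profiles: list[PerturbationProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "compound_id": p.key.compound_id,
                    "cell_line_id": p.key.cell_line_id,
                    "dose": p.key.dose,
                    "duration": p.key.duration,
                    "gene_id": p.treated.index,
                    "treated": p.treated.to_numpy(),
                    "control": p.control.to_numpy(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT #1.2 or #1.3 text matrix into a gene-indexed DataFrame.

    Only the data block is used: row metadata columns (#1.3) are dropped,
    and the first column supplies gene identifiers.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        dims = fh.readline().split()
        if not version.startswith("#1."):
            raise InputError(f"{path}: not a GCT file (version line {version!r})")
        if len(dims) < 2:
            raise InputError(f"{path}: malformed GCT dimensions line")
        n_row_meta = int(dims[2]) if version == "#1.3" and len(dims) >= 4 else 0
        df = pd.read_csv(fh, sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if n_row_meta:
        df = df.iloc[:, n_row_meta:]
    return df.astype(float)


# ----------------------------------------------------------------- mutations

def read_mutations_long(path: str | Path, kind: str = "sample") -> list[MutationProfile]:
    """Read two-column long format ``profile_id  gene_id`` into profiles."""
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected columns profile_id and gene_id")
    id_col, gene_col = df.columns[:2]
    return [
        MutationProfile(id=str(pid), genes=frozenset(grp[gene_col].astype(str)), kind=kind)
        for pid, grp in df.groupby(id_col, sort=True)
    ]


def read_maf(path: str | Path, kind: str = "sample") -> list[MutationProfile]:
    """Read MAF-lite: only Hugo_Symbol and Tumor_Sample_Barcode are honored."""
    df = _read_tsv(path, comment="#", dtype=str)
    needed = {"Hugo_Symbol", "Tumor_Sample_Barcode"}
    if not needed <= set(df.columns):
        raise InputError(f"{path}: MAF input needs columns {sorted(needed)}")
    return [
        MutationProfile(id=str(sid), genes=frozenset(grp["Hugo_Symbol"].astype(str)), kind=kind)
        for sid, grp in df.groupby("Tumor_Sample_Barcode", sort=True)
    ]


def write_mutations_long(profiles: list[MutationProfile], path: str | Path) -> None:
    rows = [(p.id, g) for p in profiles for g in sorted(p.genes)]
    pd.DataFrame(rows, columns=["profile_id", "gene_id"]).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- pathways

def read_gmt(path: str | Path, source: str | None = None) -> PathwayCollection:
    """Read a GMT file: one ``name<TAB>description<TAB>gene...`` set per line."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in pathways:
                raise InputError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            pathways[name] = frozenset(g for g in parts[2:] if g)
    return PathwayCollection(pathways=pathways, source=source or path.stem)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.pathways):
            genes = "\t".join(sorted(collection.pathways[name]))
            fh.write(f"{name}\t{collection.source or 'na'}\t{genes}\n")


# ------------------------------------------------------------------ outputs

def write_signature(sig: TissueSignature, path: str | Path) -> None:
    sig.table.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def read_signature(path: str | Path, name: str | None = None) -> TissueSignature:
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    if not {"fc", "p_value", "label"} <= set(df.columns):
        raise InputError(f"{path}: signature table needs fc, p_value and label columns")
    df["label"] = df["label"].astype(int)
    return TissueSignature(table=df[["fc", "p_value", "label"]], name=name)


def write_effect_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_rade_results(results: list[RadeResult], path: str | Path) -> None:
    pd.DataFrame([r.to_dict() for r in results]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_effect_sets_json(effects: EffectSets, result: RadeResult, path: str | Path) -> None:
    payload = {
        "condition": effects.key.as_tuple(),
        "signature_name": effects.signature_name,
        "n_reversed": effects.n_reversed,
        "n_adverse": effects.n_adverse,
        "n_signature": result.n_signature,
        "rade": result.score,
        "status": result.status.value,
        "rank": result.rank,
        "reversed_genes": sorted(effects.reversed_genes),
        "adverse_genes": sorted(effects.adverse_genes),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def read_effect_sets_json(path: str | Path) -> EffectSets:
    """Rebuild an EffectSets from a classify JSON (universe = union of the sets)."""
    with open(path) as fh:
        payload = json.load(fh)
    rev = frozenset(payload["reversed_genes"])
    adv = frozenset(payload["adverse_genes"])
    return EffectSets(
        key=ConditionKey(*payload["condition"]),
        reversed_genes=rev,
        adverse_genes=adv,
        universe=rev | adv,
        signature_name=payload.get("signature_name"),
    )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
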