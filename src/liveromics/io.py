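"""Readers and writers for the pipeline's file formats.

Formats
-------
- Matrices: TSV; first column is the feature ID, header row holds sample
  IDs, missing entries are the literal token ``NA``.
- Pathways: standard GMT (name <tab> description <tab> gene ...).
- Clinical: CSV with columns sample, rfs_months, rfs_event, tnm_stage,
  afp_high, thrombus, phenotype.
- Regions: header-less BED-like TSV (chrom, start, end, region_id,
  linked_gene), 0-based half-open.
- Gene model: TSV with header (gene, chrom, tss, strand, start, end),
  0-based.

All readers validate and raise :class:`ValidationError` naming the
offending row/cell rather than silently coercing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    OmicsMatrix,
    PathwayDB,
    ValidationError,
)

MISSING_TOKEN = "NA"


def read_matrix(path, value_domain: str = "log-abundance") -> OmicsMatrix:
    """Read a feature x sample TSV matrix; ``NA`` marks missing entries."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValidationError(
                    f"{path.name}:{lineno}: expected {n_cols} fields, got {len(parts)}"
                )
            feature_ids.append(parts[0])
            row = []
            for j, tok in enumerate(parts[1:], start=1):
                if tok == MISSING_TOKEN:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(tok))
                    except ValueError:
                        raise ValidationError(
                            f"{path.name}:{lineno}: non-numeric value {tok!r} "
                            f"in column {header[j]!r}"
                        ) from None
            rows.append(row)
    values = pd.DataFrame(rows, index=feature_ids, columns=header[1:], dtype=float)
    return OmicsMatrix(values=values, value_domain=value_domain)


def write_matrix(m: OmicsMatrix, path) -> None:
    df = m.values.copy()
    df.insert(0, "feature", df.index)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_gmt(path) -> PathwayDB:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {lineno}: needs name, description and >=1 gene"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValidationError(f"GMT line {lineno}: pathway {name!r} has no genes")
            if name in sets:
                raise ValidationError(f"GMT line {lineno}: duplicate pathway {name!r}")
            sets[name] = (desc, frozenset(genes))
    return PathwayDB(sets=sets)


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in db.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(
        path,
        dtype={"sample": str, "tnm_stage": str, "phenotype": str},
        na_values=[MISSING_TOKEN, ""],
        keep_default_na=False,
    )
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"clinical CSV missing columns: {sorted(missing)}")
    return ClinicalTable(df[list(CLINICAL_COLUMNS)].copy())


def write_clinical(t: ClinicalTable, path) -> None:
    t.frame.to_csv(path, index=False, na_rep=MISSING_TOKEN)


REGION_COLUMNS = ("chrom", "start", "end", "region_id", "linked_gene")


def read_regions(path) -> pd.DataFrame:
    """Header-less BED-like region table, 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, names=REGION_COLUMNS,
                     dtype={"chrom": str, "region_id": str, "linked_gene": str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["start"] >= df["end"]
    if bad.any():
        rid = df.loc[bad, "region_id"].iloc[0]
        raise ValidationError(f"region {rid!r}: start >= end")
    if df["region_id"].duplicated().any():
        rid = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValidationError(f"duplicate region_id {rid!r}")
    return df


def write_regions(df: pd.DataFrame, path) -> None:
    df[list(REGION_COLUMNS)].to_csv(path, sep="\t", index=False, header=False)


GENE_MODEL_COLUMNS = ("gene", "chrom", "tss", "strand", "start", "end")


def read_gene_model(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    missing = set(GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"gene model missing columns: {sorted(missing)}")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError("gene model strand must be + or -")
    if df["gene"].duplicated().any():
        g = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"duplicate gene {g!r} in gene model")
    for col in ("tss", "start", "end"):
        df[col] = df[col].astype(int)
    return df[list(GENE_MODEL_COLUMNS)].copy()


def write_gene_model(df: pd.DataFrame, path) -> None:
    df[list(GENE_MODEL_COLUMNS)].to_csv(path, sep="\t", index=False)


def validate_file(path, kind: str) -> dict:
    """Validate a file of the given kind; returns a small summary dict.

    ``kind`` is one of matrix, beta-matrix, gmt, clinical, bed, gene-model.
    """
    if kind == "matrix":
        m = read_matrix(path)
        return {"kind": kind, "features": m.n_features, "samples": m.n_samples}
    if kind == "beta-matrix":
        m = read_matrix(path, value_domain="beta")
        return {"kind": kind, "features": m.n_features, "samples": m.n_samples}
    if kind == "gmt":
        db = read_gmt(path)
        return {"kind": kind, "pathways": len(db)}
    if kind == "clinical":
        t = read_clinical(path)
        return {"kind": kind, "samples": len(t.frame)}
    if kind == "bed":
        df = read_regions(path)
        return {"kind": kind, "regions": len(df)}
    if kind == "gene-model":
        df = read_gene_model(path)
        return {"kind": kind, "genes": len(df)}
    raise ValidationError(f"unknown validation kind {kind!r}")
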