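"""Readers and writers for every external format the pipeline touches.

All tabular formats are TSV with a header row; BED and GFF3 gene
annotations are accepted and converted to the internal 0-based half-open
convention (GFF3 starts are decremented by one at this boundary).  Output
files round-trip bit-exactly through the matching reader, with floats
serialized at 6 significant digits.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GENE_COLUMNS, PAIR_COLUMNS, SUBGENOMES

FLOAT_FORMAT = "%.6g"

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "k_meth", "n_total"]
KAKS_COLUMNS = ["pair_id", "ka", "ks", "ka_ks"]


def _infer_subgenome(chrom: str) -> str | None:
    """Subgenome from the chromosome-name suffix (e.g. hcp01R -> R)."""
    return chrom[-1] if chrom and chrom[-1] in SUBGENOMES else None


def read_gene_annotation(path: str | Path, dialect: str = "BED") -> pd.DataFrame:
    """Read gene models from BED or GFF3 into a gene table.

    Returns a DataFrame with columns ``gene_id, chrom, start, end, strand,
    subgenome`` in 0-based half-open coordinates.  A missing strand column
    defaults to "+" with a warning; an inverted interval raises with the
    offending line number.
    """
    dialect = dialect.upper()
    if dialect == "BED":
        return _read_bed_genes(path)
    if dialect == "GFF3":
        return _read_gff3_genes(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_bed_genes(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "gene_id", "score", "strand"]
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    df.columns = names[: df.shape[1]]
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: BED gene annotation needs at least 4 columns")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if "strand" not in df.columns:
        warnings.warn(f"{path}: no strand column; assuming '+'", stacklevel=2)
        df["strand"] = "+"
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"{path} line {bad[0] + 1}: end <= start")
    df["subgenome"] = df["chrom"].map(_infer_subgenome)
    return df[GENE_COLUMNS].reset_index(drop=True)


def _read_gff3_genes(path: str | Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    featuretypes = set(db.featuretypes())
    wanted = "gene" if "gene" in featuretypes else None
    features = db.features_of_type(wanted) if wanted else db.all_features()
    for feat in features:
        start = feat.start - 1  # GFF3 is 1-based inclusive
        end = feat.end
        if end <= start:
            raise ValueError(f"{path}: feature {feat.id}: end <= start after conversion")
        strand = feat.strand if feat.strand in ("+", "-") else None
        if strand is None:
            warnings.warn(f"{path}: feature {feat.id} has no strand; assuming '+'", stacklevel=2)
            strand = "+"
        rows.append((feat.id, feat.seqid, start, end, strand, _infer_subgenome(feat.seqid)))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "role", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    if "tissue" not in sheet.columns:
        sheet["tissue"] = "NA"
    return sheet.set_index("sample_id")


def read_matrix(path: str | Path, kind: str, sample_sheet: str | Path | None = None):
    """Read one of the pipeline's typed tables.

    kind: ``counts`` (returns :class:`ExpressionMatrix`; needs a sample
    sheet), ``cytosines``, ``intervals``, ``pairs`` or ``kaks`` (return
    DataFrames).
    """
    if kind == "counts":
        if sample_sheet is None:
            raise ValueError("kind='counts' requires a sample_sheet")
        counts = pd.read_csv(path, sep="\t", index_col=0)
        if (counts.to_numpy() < 0).any():
            raise ValueError(f"{path}: negative counts")
        if not np.issubdtype(counts.to_numpy().dtype, np.integer):
            if not np.allclose(counts.to_numpy() % 1, 0):
                raise ValueError(f"{path}: counts must be integers")
            counts = counts.astype(np.int64)
        sheet = read_sample_sheet(sample_sheet)
        absent = [c for c in counts.columns if c not in sheet.index]
        if absent:
            raise ValueError(f"{path}: sample columns absent from sheet: {absent}")
        return ExpressionMatrix(counts=counts, samples=sheet)
    if kind == "cytosines":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in CYTOSINE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: cytosine table lacks columns {missing}")
        if (df["k_meth"] < 0).any() or (df["n_total"] < 0).any():
            raise ValueError(f"{path}: negative methylation counts")
        if (df["k_meth"] > df["n_total"]).any():
            bad = df.index[df["k_meth"] > df["n_total"]][0]
            raise ValueError(f"{path} row {bad + 1}: k_meth > n_total")
        return df
    if kind == "intervals":
        names = ["chrom", "start", "end", "name", "score", "strand"]
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
        df.columns = names[: df.shape[1]]
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["end"] <= df["start"]).any():
            bad = df.index[df["end"] <= df["start"]][0]
            raise ValueError(f"{path} line {bad + 1}: end <= start")
        return df
    if kind == "pairs":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in PAIR_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: pair map lacks columns {missing}")
        df["order_index"] = df["order_index"].astype(int)
        return df
    if kind == "kaks":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in KAKS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: Ka/Ks table lacks columns {missing}")
        if (df[["ka", "ks", "ka_ks"]] < 0).to_numpy().any():
            raise ValueError(f"{path}: negative Ka/Ks values")
        return df
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_records(records, path: str | Path, empty_ok: bool = False) -> None:
    """Write a result collection as TSV (header + one row per record).

    Floats are serialized with 6 significant digits so that write/read
    round-trips are exact at that precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([getattr(r, "__dict__", r) for r in records])
    if df.empty and not empty_ok:
        raise ValueError(f"refusing to write empty record collection to {path}")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_records(path: str | Path) -> pd.DataFrame:
    """Generic reader matching :func:`write_records` output."""
    return pd.read_csv(path, sep="\t")


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    cols = [df["chrom"], df["start"], df["end"]]
    header = ["chrom", "start", "end"]
    if name_col is not None:
        cols.append(df[name_col])
        header.append(name_col)
        if "score" in df.columns:
            cols.append(df["score"])
            header.append("score")
        if "strand" in df.columns:
            cols.append(df["strand"])
            header.append("strand")
    pd.concat(cols, axis=1).to_csv(path, sep="\t", index=False, header=False)
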