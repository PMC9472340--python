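"""Shared genomic types for homoeolog-level analysis.

All genomic intervals are 0-based, half-open throughout the package; GFF3
input is converted at the boundary (see :mod:`homoeokit.io`).  A
:class:`HomoeologPair` joins one gene of subgenome R (goldfish-derived) with
its counterpart of subgenome C (common-carp-derived), or the corresponding
parental orthologs; the pair is the unit of every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
SUBGENOMES = ("R", "C")

#: canonical column order for gene tables
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "subgenome"]
#: canonical column order for homoeolog-pair tables
PAIR_COLUMNS = ["pair_id", "r_gene", "c_gene", "chrom_pair", "order_index"]

REGIONS = ("up2k", "body", "down2k")
FLANK = 2000  # bp of promoter/terminator flank profiled around each gene


@dataclass(frozen=True)
class GeneModel:
    """A gene locus; ``start``/``end`` are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    subgenome: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be one of {STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HomoeologPair:
    """One R-subgenome gene paired with its C-subgenome homoeolog."""

    pair_id: str
    r_gene: str
    c_gene: str
    chrom_pair: str
    order_index: int


def region_span(gene: GeneModel | pd.Series, region: str, flank: int = FLANK) -> tuple[int, int]:
    """Strand-aware coordinates of a profiling region around a gene.

    ``up2k`` is the ``flank`` bp 5' of the TSS, ``down2k`` the ``flank`` bp
    3' of the TTS, ``body`` the gene itself.  For "-" genes upstream lies at
    higher chromosome coordinates.  Spans are clipped at 0.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    start, end, strand = int(gene.start), int(gene.end), gene.strand
    if region == "body":
        return start, end
    if (region == "up2k") == (strand == "+"):
        return max(0, start - flank), start
    return end, end + flank


def genes_to_frame(genes: Iterable[GeneModel]) -> pd.DataFrame:
    df = pd.DataFrame([g.__dict__ for g in genes], columns=GENE_COLUMNS)
    return df


def pairs_to_frame(pairs: Iterable[HomoeologPair]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs], columns=PAIR_COLUMNS)


@dataclass
class ExpressionMatrix:
    """Per-gene, per-sample read counts with sample metadata.

    ``counts`` holds raw non-negative integers (genes x samples); the sample
    sheet carries one row per sample with ``group`` (free label, e.g. F1),
    ``role`` (one of parent_R / parent_C / hybrid), ``replicate`` and
    ``tissue``.  ``normalized`` and ``norm_factors`` are attached by
    :func:`homoeokit.expression.normalize` and stay ``None`` until then.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    norm_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"sample sheet is missing count columns: {missing}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts are not allowed")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.samples["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def group_samples(self, group: str) -> list[str]:
        """Sample ids of one group, in sheet order."""
        sel = self.samples.index[self.samples["group"] == group]
        ids = [s for s in sel if s in self.counts.columns]
        if not ids:
            raise KeyError(f"no samples for group {group!r}")
        return ids

    def group_role(self, group: str) -> str:
        roles = set(self.samples.loc[self.group_samples(group), "role"])
        if len(roles) != 1:
            raise ValueError(f"group {group!r} mixes roles {sorted(roles)}")
        return roles.pop()

    def values(self, genes, samples, normalized: bool = False) -> np.ndarray:
        src = self.normalized if normalized else self.counts
        if normalized and src is None:
            raise ValueError("matrix has not been normalized")
        missing = [g for g in np.atleast_1d(genes) if g not in src.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return src.loc[genes, samples].to_numpy(dtype=float)
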