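"""5mC calling, region methylation profiles, DMR/DMG and MRG detection.

A cytosine is methylated when its methylated-read count exceeds what the
null error rate p0 explains (one-sided binomial upper tail), at depth
> 4X (n_total >= 5) and Benjamini-Hochberg FDR < 0.05 across all tested
sites.  Gene-level methylation is profiled over the 2-kb promoter, gene
body and 2-kb terminator, each cut into 20 strand-aware windows; only CpG
records enter profiles (CHG/CHH are parsed and counted but ignored).

The region-level differential test here is a deliberately simplified DMR
surrogate — a Fisher exact test on pooled (methylated, total) counts with a
|delta ML| > 0.1 effect gate — standing in for multi-stage DMR callers;
downstream DMG logic only needs the region-level decision.  DMG classes
follow fixed thresholds: hyper-DMG when the parental promoter |DM|
exceeds 0.6 while the hybrid homoeolog |DM| stays below 0.3; hypo-DMG when
0 < |DM| < 0.6 in parents and < 0.2 in hybrids.  A methylation-regulated
gene (MRG) couples |DM| > 0.4 with an opposite-signed expression change of
more than 4-fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .core import GeneModel, REGIONS, region_span

logger = logging.getLogger(__name__)


def call_5mc(k_meth, n_total, p0_error: float):
    """One-sided upper-tail binomial probability P(X >= k | n, p0)."""
    k = np.asarray(k_meth)
    n = np.asarray(n_total)
    if (k > n).any():
        raise ValueError("k_meth cannot exceed n_total")
    if not (0.0 < p0_error < 1.0):
        raise ValueError("p0_error must lie in (0, 1)")
    p = stats.binom.sf(k - 1, n, p0_error)
    return p.item() if p.ndim == 0 else p


def call_5mc_batch(cytosines: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Per-site 5mC calls with BH adjustment across all tested sites.

    Sites below the depth gate (n_total < min_depth_5mc) are untested: their
    q stays NaN and they are never called methylated.
    """
    out = cytosines.copy()
    n = out["n_total"].to_numpy()
    k = out["k_meth"].to_numpy()
    tested = n >= config.min_depth_5mc
    p = np.full(len(out), np.nan)
    q = np.full(len(out), np.nan)
    if tested.any():
        p[tested] = call_5mc(k[tested], n[tested], config.p0_error)
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out["p"] = p
    out["q"] = q
    out["is_methylated"] = tested & (q < config.fdr_5mc)
    return out


@dataclass
class RegionProfile:
    gene_id: str
    region: str
    window_ml: np.ndarray      # n_windows values in [0,1]; NaN where empty
    mean_ml: float             # coverage-weighted over the region's CpGs
    n_cytosines: int


def region_profile(
    cytosines: pd.DataFrame, gene: GeneModel | pd.Series, region: str, config: AnalysisConfig
) -> RegionProfile:
    """Methylation profile of one gene region in ``n_windows`` equal windows.

    Window ML is sum(k)/sum(n) over the window's CpGs; windows are ordered
    5' to 3' (reversed relative to chromosome coordinates for "-" genes).
    Empty windows are NaN and excluded from the mean.  A body shorter than
    n_windows bp falls back to a single window with a warning.
    """
    start, end = region_span(gene, region)
    n_windows = config.n_windows
    if end - start < n_windows:
        logger.warning(
            "gene %s %s span %d bp shorter than %d windows; single-window fallback",
            gene.gene_id, region, end - start, n_windows,
        )
        n_windows = 1
    sel = cytosines[
        (cytosines["chrom"] == gene.chrom)
        & (cytosines["pos"] >= start)
        & (cytosines["pos"] < end)
        & (cytosines["context"] == "CpG")
    ]
    edges = np.linspace(start, end, n_windows + 1)
    idx = np.clip(
        np.searchsorted(edges, sel["pos"].to_numpy(), side="right") - 1, 0, n_windows - 1
    )
    ksum = np.bincount(idx, weights=sel["k_meth"].to_numpy(dtype=float), minlength=n_windows)
    nsum = np.bincount(idx, weights=sel["n_total"].to_numpy(dtype=float), minlength=n_windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        window_ml = np.where(nsum > 0, ksum / np.where(nsum > 0, nsum, 1), np.nan)
    if gene.strand == "-":
        window_ml = window_ml[::-1]
    total_n = nsum.sum()
    mean_ml = float(ksum.sum() / total_n) if total_n > 0 else float("nan")
    return RegionProfile(
        gene_id=gene.gene_id,
        region=region,
        window_ml=window_ml,
        mean_ml=mean_ml,
        n_cytosines=int(len(sel)),
    )


def region_mean_levels(
    cytosines: pd.DataFrame, genes: pd.DataFrame, region: str, config: AnalysisConfig
) -> pd.DataFrame:
    """Coverage-weighted CpG methylation level per gene for one region.

    Vectorized companion of :func:`region_profile` used by the DMG/MRG
    pipeline; returns gene_id, k_sum, n_sum and ml (NaN when uncovered).
    """
    cpg = cytosines[cytosines["context"] == "CpG"]
    n_other = len(cytosines) - len(cpg)
    if n_other:
        logger.info("ignoring %d non-CpG cytosine records", n_other)
    rows = []
    by_chrom = {c: g.sort_values("pos") for c, g in cpg.groupby("chrom")}
    for gene in genes.itertuples(index=False):
        start, end = region_span(gene, region)
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            rows.append((gene.gene_id, 0.0, 0.0))
            continue
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end])
        rows.append(
            (
                gene.gene_id,
                float(sub["k_meth"].to_numpy()[lo:hi].sum()),
                float(sub["n_total"].to_numpy()[lo:hi].sum()),
            )
        )
    out = pd.DataFrame(rows, columns=["gene_id", "k_sum", "n_sum"])
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ml"] = np.where(out["n_sum"] > 0, out["k_sum"] / out["n_sum"], np.nan)
    return out


def dm_value(ml_first: float, ml_second: float) -> float:
    """Methylation-level difference, first minus second."""
    return ml_first - ml_second


def dmr_test(region_a: tuple, region_b: tuple, config: AnalysisConfig) -> tuple[float, bool]:
    """Simplified DMR surrogate: Fisher exact test on pooled region counts.

    ``region_a``/``region_b`` are (sum_k, sum_n).  The DMR flag requires
    p < dmr_alpha and |delta ML| > 0.1.
    """
    ka, na = region_a
    kb, nb = region_b
    if na <= 0 or nb <= 0:
        raise ValueError("dmr_test requires positive total counts")
    table = np.array([[ka, na - ka], [kb, nb - kb]])
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    delta = abs(ka / na - kb / nb)
    return p, bool(p < config.dmr_alpha and delta > 0.1)


def classify_dmg(dm_parents: float, dm_hybrid: float, config: AnalysisConfig) -> str:
    """Hyper/hypo DMG class from parental and hybrid |DM| values."""
    dp, dh = abs(dm_parents), abs(dm_hybrid)
    if dp > config.dm_dmg_hyper and dh < config.dm_dmg_hybrid_hyper:
        return "hyper_dmg"
    if 0.0 < dp < config.dm_dmg_hyper and dh < config.dm_dmg_hybrid_hypo:
        return "hypo_dmg"
    return "none"


def detect_mrg(dm: float, log2fc: float, config: AnalysisConfig) -> bool:
    """MRG rule: large, opposite-signed methylation and expression changes."""
    if not (np.isfinite(dm) and np.isfinite(log2fc)):
        return False
    return bool(
        abs(dm) > config.mrg_dm
        and abs(log2fc) > np.log2(config.mrg_fc)
        and np.sign(dm) != np.sign(log2fc)
        and np.sign(dm) != 0
        and np.sign(log2fc) != 0
    )


def pair_dm_table(
    cytosines: pd.DataFrame,
    genes: pd.DataFrame,
    pairs: pd.DataFrame,
    config: AnalysisConfig,
    region: str = "up2k",
    parent_r_sample: str = "parent_R",
    parent_c_sample: str = "parent_C",
    hybrid_sample: str = "F1",
) -> pd.DataFrame:
    """Promoter DM per pair: parental ortholog DM and hybrid homoeolog DM.

    The sign convention is first-named minus second-named: R-parent minus
    C-parent for the ortholog comparison, R minus C homoeolog within the
    hybrid.  Adds the DMG class per pair.
    """
    def levels(sample: str) -> pd.Series:
        sub = cytosines[cytosines["sample"] == sample]
        tab = region_mean_levels(sub, genes, region, config)
        return tab.set_index("gene_id")["ml"]

    ml_pr = levels(parent_r_sample)
    ml_pc = levels(parent_c_sample)
    ml_h = levels(hybrid_sample)
    dm_parents = (
        ml_pr.reindex(pairs["r_gene"]).to_numpy()
        - ml_pc.reindex(pairs["c_gene"]).to_numpy()
    )
    dm_hybrid = (
        ml_h.reindex(pairs["r_gene"]).to_numpy() - ml_h.reindex(pairs["c_gene"]).to_numpy()
    )
    out = pd.DataFrame(
        {
            "pair_id": pairs["pair_id"],
            "comparison": f"{parent_r_sample}-{parent_c_sample}/{hybrid_sample}",
            "dm_parents": dm_parents,
            "dm_hybrid": dm_hybrid,
        }
    )
    out["dmg_class"] = [
        classify_dmg(dp, dh, config) if np.isfinite(dp) and np.isfinite(dh) else "none"
        for dp, dh in zip(dm_parents, dm_hybrid)
    ]
    return out
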