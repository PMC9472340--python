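"""Parental-genome divergence summaries and the TE–SV association.

Per orthologous chromosome pair (OCP) the module reports the fraction of
genes with an ortholog on the other side and the difference in TE coverage.
Structural variants are classified TE-proximal (< 1 kb from the nearest TE)
or no-TE, and their window-level counts are correlated with TE density
(Pearson r with the exact t-based p-value); both a correlation test and a
two-sample test on class frequencies are emitted because either reading of
a "t test" on such data is defensible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals as sorted non-overlapping intervals."""
    if len(starts) == 0:
        return np.array([], dtype=float), np.array([], dtype=float)
    order = np.argsort(starts)
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.asarray(out_s), np.asarray(out_e)


def te_fraction(te: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Fraction of [start, end) covered by the union of TE intervals."""
    if end <= start:
        raise ValueError("span must have positive length")
    sub = te[te["chrom"] == chrom]
    if sub.empty:
        return 0.0
    s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
    clipped = np.minimum(e, end) - np.maximum(s, start)
    return float(np.clip(clipped, 0, None).sum() / (end - start))


def ocp_summary(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    te_a: pd.DataFrame,
    te_b: pd.DataFrame,
    chrom_lengths: dict,
    chrom_pair_of: dict | None = None,
) -> pd.DataFrame:
    """Per-OCP gene/ortholog counts, orthologous fractions and TE difference.

    ``ortholog_map`` uses the pair-table schema (r_gene = side A, c_gene =
    side B, chrom_pair).  ``chrom_pair_of`` maps each chromosome to its OCP;
    by default the chromosome name minus its trailing subgenome letter.
    """
    if chrom_pair_of is None:
        chrom_pair_of = {
            c: c[:-1] if c and c[-1] in ("R", "C") else c for c in chrom_lengths
        }
    missing = [
        g
        for g in pd.concat([ortholog_map["r_gene"], ortholog_map["c_gene"]])
        if g not in set(genes_a["gene_id"]) | set(genes_b["gene_id"])
    ]
    if missing:
        raise ValueError(f"ortholog map references unknown genes: {missing[:5]}")
    rows = []
    cps = sorted(set(chrom_pair_of.values()))
    for cp in cps:
        chroms = [c for c, p in chrom_pair_of.items() if p == cp]
        ga = genes_a[genes_a["chrom"].isin(chroms)]
        gb = genes_b[genes_b["chrom"].isin(chroms)]
        n_orth = int((ortholog_map["chrom_pair"] == cp).sum())
        def tefrac(te, genes):
            fr = []
            for c in chroms:
                if (genes["chrom"] == c).any():
                    fr.append(te_fraction(te, c, 0, int(chrom_lengths[c])))
            return float(np.mean(fr)) if fr else np.nan
        te_fa = tefrac(te_a, ga)
        te_fb = tefrac(te_b, gb)
        rows.append(
            {
                "chrom_pair": cp,
                "n_genes_A": len(ga),
                "n_genes_B": len(gb),
                "n_orthologs": n_orth,
                "ortho_fraction_A": n_orth / len(ga) if len(ga) else np.nan,
                "ortho_fraction_B": n_orth / len(gb) if len(gb) else np.nan,
                "te_fraction_A": te_fa,
                "te_fraction_B": te_fb,
                "te_difference": te_fa - te_fb,
            }
        )
    return pd.DataFrame(rows)


def sv_te_classify(sv: pd.DataFrame, te: pd.DataFrame, config: AnalysisConfig) -> pd.Series:
    """TE_proximal / no_TE label per SV (strict < te_proximity bp distance).

    Distance is 0 inside a TE.  SVs on chromosomes without TE annotation are
    no_TE.
    """
    labels = np.full(len(sv), "no_TE", dtype=object)
    for chrom, sub in sv.groupby("chrom"):
        tsub = te[te["chrom"] == chrom]
        if tsub.empty:
            continue
        ms, me = merge_intervals(tsub["start"].to_numpy(), tsub["end"].to_numpy())
        pos = sub["start"].to_numpy()
        i = np.searchsorted(ms, pos, side="right") - 1
        inside = (i >= 0) & (pos < me[np.clip(i, 0, None)])
        d_left = np.where(i >= 0, pos - me[np.clip(i, 0, None)] + 1, np.inf)
        j = np.clip(i + 1, 0, len(ms) - 1)
        d_right = np.where(i + 1 < len(ms), ms[j] - pos, np.inf)
        dist = np.where(inside, 0, np.minimum(np.clip(d_left, 0, None), d_right))
        labels[sv.index.get_indexer(sub.index)] = np.where(
            dist < config.te_proximity, "TE_proximal", "no_TE"
        )
    return pd.Series(labels, index=sv.index, name="te_class")


def window_track(
    te: pd.DataFrame,
    sv: pd.DataFrame,
    chrom_lengths: dict,
    window_size: int = 100_000,
    superfamily: str | None = None,
) -> pd.DataFrame:
    """Tile the genome into windows with TE density and SV count.

    ``superfamily`` restricts TE density to intervals whose name matches
    (the BED name field carries the superfamily label).
    """
    tsel = te if superfamily is None else te[te["name"] == superfamily]
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = sv.loc[sv["chrom"] == chrom, "start"].to_numpy()
        for wstart in range(0, int(length), window_size):
            wend = min(wstart + window_size, int(length))
            dens = te_fraction(tsel, chrom, wstart, wend) if len(tsel) else 0.0
            count = int(((pos >= wstart) & (pos < wend)).sum())
            rows.append((chrom, wstart, wend, dens, count))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "te_density", "sv_count"])


def sv_te_correlation(track: pd.DataFrame) -> tuple[float, float, float]:
    """Pearson correlation of TE density and SV count across windows.

    Returns (r, t, p) with t = r sqrt(n-2)/sqrt(1-r^2) and the two-sided
    p-value on n-2 degrees of freedom.
    """
    dens = track["te_density"].to_numpy(dtype=float)
    count = track["sv_count"].to_numpy(dtype=float)
    n = len(track)
    if n < 3:
        raise ValueError("sv_te_correlation needs >= 3 windows")
    if np.allclose(dens, dens[0]):
        raise ValueError("undefined correlation: constant TE density")
    r, p = stats.pearsonr(dens, count)
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(r), float(t), float(p)


def sv_class_frequency_test(
    sv: pd.DataFrame,
    te: pd.DataFrame,
    chrom_lengths: dict,
    config: AnalysisConfig,
    window_size: int = 100_000,
) -> dict:
    """Welch t-test of per-window TE-proximal vs no-TE SV counts.

    The alternative reading of a "t test" on such data: compare SV frequency
    between TE(<1 kb) and TE-free territory, window by window.
    """
    labels = sv_te_classify(sv, te, config)
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = sv.loc[sv["chrom"] == chrom, "start"].to_numpy()
        lab = labels[sv["chrom"] == chrom].to_numpy()
        for wstart in range(0, int(length), window_size):
            wend = min(wstart + window_size, int(length))
            inw = (pos >= wstart) & (pos < wend)
            rows.append(
                (
                    int((inw & (lab == "TE_proximal")).sum()),
                    int((inw & (lab == "no_TE")).sum()),
                )
            )
    arr = np.asarray(rows, dtype=float)
    res = stats.ttest_ind(arr[:, 0], arr[:, 1], equal_var=False)
    return {
        "n_windows": len(arr),
        "n_te_proximal": int(arr[:, 0].sum()),
        "n_no_te": int(arr[:, 1].sum()),
        "mean_te_proximal_per_window": float(arr[:, 0].mean()),
        "mean_no_te_per_window": float(arr[:, 1].mean()),
        "t": float(res.statistic),
        "p": float(res.pvalue),
    }
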