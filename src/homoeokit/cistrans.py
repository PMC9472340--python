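"""Cis/trans decomposition of homoeolog expression divergence.

Following the classical allele-specific-expression scheme, each homoeolog
pair is summarized by the parental ortholog ratio P = log2(R/C), the hybrid
homoeolog ratio H, and the trans component T = P - H.  Three significance
calls — parental count difference (sig_P), hybrid count difference (sig_H)
and parents-vs-hybrid ratio difference (sig_T) — map each pair onto seven
regulatory categories:

    (sig_P, sig_H, sig_T)
    (F, F, F) -> conserved
    (T, T, F) -> cis only
    (T, F, T) -> trans only
    (T, T, T) -> cis + trans (sign(H) == sign(T)) or cis x trans (opposite)
    (F, T, T) -> compensatory
    otherwise -> ambiguous

The scalar tests are Welch t-tests on log2(count + 0.5).  The batch
classifier shrinks per-pair variances across all pairs (empirical-Bayes
moderated t, Smyth 2004): with three replicates per group the per-pair
variance estimate is too noisy for raw t-tests to have useful power, and
variance moderation is the standard remedy for count designs of this size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import AnalysisConfig
from .core import ExpressionMatrix
from .expression import filter_pairs, in_silico_hybrid

CATEGORIES7 = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_x_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)

SIGN_EPS = 1e-9  # tie rule: |x| <= eps has no usable sign

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class CountDiffResult:
    log2fc: float
    p: float
    significant: bool


def _jitter_if_degenerate(x: np.ndarray) -> np.ndarray:
    """Deterministic 1e-9 log-scale jitter for zero-variance replicate sets."""
    if np.var(x) == 0:
        return x + 1e-9 * np.arange(len(x))
    return x


def count_diff_test(counts_a, counts_b, config: AnalysisConfig) -> CountDiffResult:
    """Two-sided Welch t-test on log2(count + 0.5) replicate values.

    log2FC uses a 0.5 pseudocount on the replicate means.  Significance is
    p < alpha_count_test; when ``config.fc_gate`` is set, a fold-change gate
    |log2FC| > log2(fc_threshold) is required as well.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("count_diff_test needs >= 2 replicates per side")
    log2fc = float(np.log2((a.mean() + PSEUDOCOUNT) / (b.mean() + PSEUDOCOUNT)))
    la = _jitter_if_degenerate(np.log2(a + PSEUDOCOUNT))
    lb = _jitter_if_degenerate(np.log2(b + PSEUDOCOUNT))
    p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
    sig = p < config.alpha_count_test
    if config.fc_gate:
        sig = sig and abs(log2fc) > np.log2(config.fc_threshold)
    return CountDiffResult(log2fc=log2fc, p=p, significant=sig)


def ratio_diff_test(parent_ratios, hybrid_ratios, config: AnalysisConfig) -> float:
    """Two-sided two-sample t-test of parental vs hybrid log2(R/C) values."""
    a = np.asarray(parent_ratios, dtype=float)
    b = np.asarray(hybrid_ratios, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("ratio_diff_test needs >= 2 ratios per side")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("ratio_diff_test requires finite ratios")
    a = _jitter_if_degenerate(a)
    b = _jitter_if_degenerate(b)
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _sign(x: float) -> int:
    if x > SIGN_EPS:
        return 1
    if x < -SIGN_EPS:
        return -1
    return 0


def classify7(sig_p: bool, sig_h: bool, sig_t: bool, h: float, t: float) -> str:
    """Map the three significance flags (and signs of H, T) to a category.

    A needed-but-undefined sign (|x| <= 1e-9) sends the pair to ambiguous.
    """
    key = (bool(sig_p), bool(sig_h), bool(sig_t))
    if key == (False, False, False):
        return "conserved"
    if key == (True, True, False):
        return "cis_only"
    if key == (True, False, True):
        return "trans_only"
    if key == (True, True, True):
        sh, st = _sign(h), _sign(t)
        if sh == 0 or st == 0:
            return "ambiguous"
        return "cis_plus_trans" if sh == st else "cis_x_trans"
    if key == (False, True, True):
        return "compensatory"
    return "ambiguous"


def subpattern13(
    category7: str, p: float, h: float, dm: float, config: AnalysisConfig
) -> tuple[str, bool]:
    """Directional split of the seven categories into 13 patterns.

    Conserved stays single; cis-driven categories split _toR/_toC by the
    sign of the hybrid ratio H, while trans_only and compensatory split by
    the sign of the trans component T = P - H (the component that carries
    their direction).  The "strong" flag marks pairs beyond a 4-fold
    expression ratio or a methylation difference above ``dm_subpattern``.
    """
    if category7 not in CATEGORIES7:
        raise ValueError(f"unknown category {category7!r}")
    t = p - h
    strong = (
        abs(h) > np.log2(config.fc_threshold)
        or abs(p) > np.log2(config.fc_threshold)
        or (np.isfinite(dm) and dm > config.dm_subpattern)
    )
    if category7 == "conserved":
        return "conserved", bool(strong)
    if category7 in ("trans_only", "compensatory"):
        direction = t
    elif category7 == "ambiguous" and abs(h) <= SIGN_EPS:
        direction = t
    else:
        direction = h
    suffix = "_toR" if direction >= 0 else "_toC"
    return category7 + suffix, bool(strong)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation (Smyth 2004 moment estimators)


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink per-pair variances toward a common prior; returns (s2_post, d0).

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    variances by matching the moments of log s^2, then returns the usual
    posterior combination (d0 s0^2 + df s2) / (d0 + df).  d0 = inf means the
    variances are consistent with a single shared value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("squeeze_variances needs >= 2 positive variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1))
    target = evar - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        s02 = float(np.exp(np.mean(e)))
        return np.full_like(s2, s02), np.inf
    half_d0 = _trigamma_inverse(target)
    d0 = 2.0 * half_d0
    s02 = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0


def moderated_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise moderated two-sample t-test; returns (diff, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df
    post, d0 = squeeze_variances(s2, df)
    df_total = 1e6 if np.isinf(d0) else df + d0
    diff = a.mean(axis=1) - b.mean(axis=1)
    se = np.sqrt(post * (1.0 / na + 1.0 / nb))
    tstat = diff / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    return diff, p


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return a.mean(axis=1) - b.mean(axis=1), np.asarray(res.pvalue)


def classify_pairs(
    matrix: ExpressionMatrix,
    pairs: pd.DataFrame,
    generation: str,
    config: AnalysisConfig,
    dm: pd.Series | None = None,
) -> pd.DataFrame:
    """Regulatory calls for every eligible pair of one hybrid generation.

    Eligibility requires the 5-read filter in both parents and the hybrid
    generation; ineligible pairs are skipped, not errors.  ``dm`` optionally
    supplies a per-pair methylation difference consumed by the 13-pattern
    "strong" flag.
    """
    if matrix.normalized is None:
        raise ValueError("normalize the matrix first")
    roles = matrix.samples["group"].groupby(matrix.samples["role"]).unique()
    pr_group = roles.get("parent_R", [None])[0]
    pc_group = roles.get("parent_C", [None])[0]
    if pr_group is None or pc_group is None:
        raise ValueError("matrix lacks parental groups")
    elig = filter_pairs(matrix, pairs, config)
    eligible = elig[pr_group] & elig[pc_group] & elig[generation]
    sel = pairs[pairs["pair_id"].isin(eligible)].reset_index(drop=True)
    if sel.empty:
        return _empty_calls()

    sr = matrix.group_samples(pr_group)
    sc = matrix.group_samples(pc_group)
    sh = matrix.group_samples(generation)
    pr = matrix.values(sel["r_gene"].to_numpy(), sr, normalized=True)
    pc = matrix.values(sel["c_gene"].to_numpy(), sc, normalized=True)
    hr = matrix.values(sel["r_gene"].to_numpy(), sh, normalized=True)
    hc = matrix.values(sel["c_gene"].to_numpy(), sh, normalized=True)

    lpr, lpc = np.log2(pr + PSEUDOCOUNT), np.log2(pc + PSEUDOCOUNT)
    lhr, lhc = np.log2(hr + PSEUDOCOUNT), np.log2(hc + PSEUDOCOUNT)
    parent_ratios = lpr - lpc  # replicate pairing in sheet order
    hybrid_ratios = lhr - lhc

    test = moderated_two_sample if config.moderated else _welch_rows
    _, p_p = test(lpr, lpc)
    _, p_h = test(lhr, lhc)
    _, p_t = test(parent_ratios, hybrid_ratios)
    if config.bh_correction:
        from statsmodels.stats.multitest import multipletests

        p_p = multipletests(p_p, method="fdr_bh")[1]
        p_h = multipletests(p_h, method="fdr_bh")[1]
        p_t = multipletests(p_t, method="fdr_bh")[1]

    log2fc_p = np.log2((pr.mean(axis=1) + PSEUDOCOUNT) / (pc.mean(axis=1) + PSEUDOCOUNT))
    log2fc_h = np.log2((hr.mean(axis=1) + PSEUDOCOUNT) / (hc.mean(axis=1) + PSEUDOCOUNT))
    P = np.log2(pr.mean(axis=1) / pc.mean(axis=1))
    H = np.log2(hr.mean(axis=1) / hc.mean(axis=1))
    T = P - H

    sig_p = p_p < config.alpha_count_test
    sig_h = p_h < config.alpha_count_test
    sig_t = p_t < config.alpha_ratio_test
    if config.fc_gate:
        gate = np.log2(config.fc_threshold)
        sig_p &= np.abs(log2fc_p) > gate
        sig_h &= np.abs(log2fc_h) > gate

    dm_values = np.full(len(sel), np.nan)
    if dm is not None:
        dm_values = sel["pair_id"].map(dm).to_numpy(dtype=float)

    cats, subs, strongs = [], [], []
    for i in range(len(sel)):
        cat = classify7(sig_p[i], sig_h[i], sig_t[i], H[i], T[i])
        sub, strong = subpattern13(cat, P[i], H[i], dm_values[i], config)
        cats.append(cat)
        subs.append(sub)
        strongs.append(strong)

    return pd.DataFrame(
        {
            "pair_id": sel["pair_id"],
            "generation": generation,
            "P": P,
            "H": H,
            "T": T,
            "p_P": p_p,
            "p_H": p_h,
            "p_T": p_t,
            "fc_P": 2.0 ** log2fc_p,
            "fc_H": 2.0 ** log2fc_h,
            "sig_P": sig_p,
            "sig_H": sig_h,
            "sig_T": sig_t,
            "category7": cats,
            "subpattern13": subs,
            "strong": strongs,
        }
    )


def _empty_calls() -> pd.DataFrame:
    cols = [
        "pair_id", "generation", "P", "H", "T", "p_P", "p_H", "p_T",
        "fc_P", "fc_H", "sig_P", "sig_H", "sig_T", "category7", "subpattern13", "strong",
    ]
    return pd.DataFrame(columns=cols)


def classify_pair(
    matrix: ExpressionMatrix,
    pairs: pd.DataFrame,
    pair_id: str,
    generation: str,
    config: AnalysisConfig,
    dm: float = float("nan"),
) -> pd.Series | None:
    """Single-pair regulatory call using the scalar (Welch) test route.

    Returns None (with no error) when the pair fails the eligibility
    filter.
    """
    one = pairs[pairs["pair_id"] == pair_id]
    if one.empty:
        raise KeyError(f"unknown pair {pair_id!r}")
    cfg_scalar = config
    calls = classify_pairs(
        matrix, one, generation,
        _with(config, moderated=False),
        dm=pd.Series({pair_id: dm}) if np.isfinite(dm) else None,
    )
    if calls.empty:
        return None
    return calls.iloc[0]


def _with(config: AnalysisConfig, **kw) -> AnalysisConfig:
    import dataclasses

    return dataclasses.replace(config, **kw)


def category_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Tally of the seven categories per generation."""
    out = (
        calls.groupby(["generation", "category7"]).size().rename("n").reset_index()
    )
    return out


def kaks_group_stats(
    kaks: pd.DataFrame, calls: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Ka/Ks summaries per regulatory category with tests against all genes.

    Welch t-tests compare cis_only and trans_only against the full gene set;
    single-member categories get a summary but no test.
    """
    merged = calls.merge(kaks, on="pair_id", how="inner")
    all_values = merged["ka_ks"].to_numpy(dtype=float)
    rows = []
    for cat in CATEGORIES7:
        vals = merged.loc[merged["category7"] == cat, "ka_ks"].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        p = np.nan
        if cat in ("cis_only", "trans_only") and len(vals) >= 2:
            p = float(stats.ttest_ind(vals, all_values, equal_var=False).pvalue)
        rows.append(
            {
                "category7": cat,
                "n": len(vals),
                "mean_ka_ks": float(vals.mean()),
                "median_ka_ks": float(np.median(vals)),
                "p_vs_all": p,
            }
        )
    rows.append(
        {
            "category7": "all",
            "n": len(all_values),
            "mean_ka_ks": float(all_values.mean()),
            "median_ka_ks": float(np.median(all_values)),
            "p_vs_all": np.nan,
        }
    )
    return pd.DataFrame(rows)


def binary_association(flags_a, flags_b) -> tuple[float, float]:
    """Phi coefficient between two binary gene flags, with a chi-square p.

    phi is the Pearson correlation of the 0/1 vectors; the p-value comes
    from the 2x2 chi-square test with continuity correction.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("binary_association needs equal-length vectors of >= 3")
    if a.all() or (~a).all() or b.all() or (~b).all():
        raise ValueError("undefined association: constant vector")
    phi = float(np.corrcoef(a.astype(float), b.astype(float))[0, 1])
    table = np.array(
        [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ]
    )
    p = float(stats.chi2_contingency(table, correction=True).pvalue)
    return phi, p
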