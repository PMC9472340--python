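"""Homoeolog expression bias (HEB): normalization, filtering, log2(R/C).

Expression divergence between the R and C homoeologs of a pair is measured
as log2(R/C) of normalized counts; |log2(R/C)| > 1 calls a biased pair and
0 < |log2(R/C)| <= 1 a potentially biased one.  The parental ortholog ratio
plays the role of the "in silico hybrid" reference against which hybrid
ratios are compared in the cis/trans decomposition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import ExpressionMatrix

HEB_CATEGORIES = ("R_biased", "C_biased", "potential_R", "potential_C", "balanced")
SILENCING_STATES = ("silenced", "expressed", "indeterminate")

IN_SILICO = "in_silico"  # group label for the parental reference ratios


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to the mean library total across all samples.

    The factor for sample s is mean(totals) / total_s; raw counts are
    retained alongside the scaled ones.  Within-sample ratios (R/C of the
    same sample) are unchanged by construction.
    """
    totals = matrix.counts.sum(axis=0).astype(float)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero)}")
    factors = totals.mean() / totals
    return ExpressionMatrix(
        counts=matrix.counts,
        samples=matrix.samples,
        norm_factors=factors,
        normalized=matrix.counts.mul(factors, axis=1),
    )


def filter_pairs(
    matrix: ExpressionMatrix, pairs: pd.DataFrame, config: AnalysisConfig
) -> dict[str, set]:
    """Eligible pair ids per group (raw count >= min_reads in every replicate).

    In hybrid groups both homoeologs must pass in every replicate; in a
    parental group the requirement applies to the homoeolog that parent
    actually carries (the R ortholog in parent_R samples, the C ortholog in
    parent_C samples).
    """
    missing = [
        g
        for g in pd.concat([pairs["r_gene"], pairs["c_gene"]])
        if g not in matrix.counts.index
    ]
    if missing:
        raise ValueError(f"pair map references genes absent from the matrix: {missing[:5]}")
    r = matrix.counts.loc[pairs["r_gene"]].to_numpy()
    c = matrix.counts.loc[pairs["c_gene"]].to_numpy()
    out: dict[str, set] = {}
    for group in matrix.groups:
        cols = [matrix.counts.columns.get_loc(s) for s in matrix.group_samples(group)]
        role = matrix.group_role(group)
        ok = np.ones(len(pairs), dtype=bool)
        if role in ("parent_R", "hybrid"):
            ok &= (r[:, cols] >= config.min_reads).all(axis=1)
        if role in ("parent_C", "hybrid"):
            ok &= (c[:, cols] >= config.min_reads).all(axis=1)
        out[group] = set(pairs.loc[ok, "pair_id"])
    return out


def log2_ratio(r_mean, c_mean):
    """log2(R/C); inputs must be positive (apply filter_pairs first)."""
    r = np.asarray(r_mean, dtype=float)
    c = np.asarray(c_mean, dtype=float)
    if (r <= 0).any() or (c <= 0).any():
        raise ValueError("log2_ratio requires positive expression values")
    out = np.log2(r / c)
    return out.item() if out.ndim == 0 else out


def heb_call(log2rc: float, config: AnalysisConfig) -> str:
    """HEB category from one log2(R/C) value (threshold strict '>')."""
    if not np.isfinite(log2rc):
        raise ValueError("log2rc must be finite")
    t = config.heb_threshold
    if log2rc > t:
        return "R_biased"
    if log2rc < -t:
        return "C_biased"
    if log2rc > 0:
        return "potential_R"
    if log2rc < 0:
        return "potential_C"
    return "balanced"


def heb_call_array(log2rc: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    log2rc = np.asarray(log2rc, dtype=float)
    t = config.heb_threshold
    out = np.where(
        log2rc > t,
        "R_biased",
        np.where(
            log2rc < -t,
            "C_biased",
            np.where(log2rc > 0, "potential_R", np.where(log2rc < 0, "potential_C", "balanced")),
        ),
    )
    return out


def _per_replicate_string(values: np.ndarray) -> str:
    return ",".join(format(v, ".6g") for v in values)


def parse_per_replicate(text: str) -> np.ndarray:
    return np.array([float(x) for x in str(text).split(",")])


def ratio_records(
    matrix: ExpressionMatrix,
    pairs: pd.DataFrame,
    group: str,
    config: AnalysisConfig,
    eligible: set | None = None,
) -> pd.DataFrame:
    """Per-pair log2(R/C) for one hybrid group.

    The headline log2rc is the ratio of replicate-mean normalized counts;
    per-replicate ratios are kept (comma-joined) for the downstream t-test.
    """
    if matrix.normalized is None:
        raise ValueError("normalize the matrix first")
    if matrix.group_role(group) != "hybrid":
        raise ValueError(f"group {group!r} is not a hybrid group; use in_silico_hybrid")
    if eligible is None:
        eligible = filter_pairs(matrix, pairs, config)[group]
    sel = pairs[pairs["pair_id"].isin(eligible)]
    samples = matrix.group_samples(group)
    r = matrix.values(sel["r_gene"].to_numpy(), samples, normalized=True)
    c = matrix.values(sel["c_gene"].to_numpy(), samples, normalized=True)
    r_mean, c_mean = r.mean(axis=1), c.mean(axis=1)
    log2rc = log2_ratio(r_mean, c_mean)
    per_rep = np.log2(r / c)
    return pd.DataFrame(
        {
            "pair_id": sel["pair_id"].to_numpy(),
            "group": group,
            "r_mean": r_mean,
            "c_mean": c_mean,
            "log2rc": np.atleast_1d(log2rc),
            "per_replicate_log2rc": [_per_replicate_string(v) for v in per_rep],
        }
    )


def in_silico_hybrid(
    matrix: ExpressionMatrix,
    pairs: pd.DataFrame,
    config: AnalysisConfig,
    parent_r_group: str | None = None,
    parent_c_group: str | None = None,
    eligible: set | None = None,
) -> pd.DataFrame:
    """Parental ortholog ratio P = log2(parent_R / parent_C) per pair.

    Per-replicate ratios pair replicate i of each parent in sample-sheet
    order; the downstream two-sample t-test is invariant to that pairing.
    """
    if matrix.normalized is None:
        raise ValueError("normalize the matrix first")
    roles = matrix.samples["group"].groupby(matrix.samples["role"]).unique()
    if parent_r_group is None:
        parent_r_group = roles.get("parent_R", [None])[0]
    if parent_c_group is None:
        parent_c_group = roles.get("parent_C", [None])[0]
    if parent_r_group is None or parent_c_group is None:
        raise ValueError("matrix lacks parent_R/parent_C groups")
    if eligible is None:
        elig = filter_pairs(matrix, pairs, config)
        eligible = elig[parent_r_group] & elig[parent_c_group]
    sel = pairs[pairs["pair_id"].isin(eligible)]
    sr = matrix.group_samples(parent_r_group)
    sc = matrix.group_samples(parent_c_group)
    if len(sr) != len(sc):
        raise ValueError(
            f"unequal replicate numbers: {parent_r_group} has {len(sr)}, "
            f"{parent_c_group} has {len(sc)}"
        )
    r = matrix.values(sel["r_gene"].to_numpy(), sr, normalized=True)
    c = matrix.values(sel["c_gene"].to_numpy(), sc, normalized=True)
    r_mean, c_mean = r.mean(axis=1), c.mean(axis=1)
    per_rep = np.log2(r / c)
    return pd.DataFrame(
        {
            "pair_id": sel["pair_id"].to_numpy(),
            "group": IN_SILICO,
            "r_mean": r_mean,
            "c_mean": c_mean,
            "log2rc": np.atleast_1d(log2_ratio(r_mean, c_mean)),
            "per_replicate_log2rc": [_per_replicate_string(v) for v in per_rep],
        }
    )


def heb_distribution(ratios: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Mean log2(R/C), mean |log2(R/C)| and HEB category counts for a group."""
    if ratios.empty:
        raise ValueError("heb_distribution needs at least one ratio record")
    values = ratios["log2rc"].to_numpy(dtype=float)
    cats = heb_call_array(values, config)
    counts = {c: int((cats == c).sum()) for c in HEB_CATEGORIES}
    return {
        "n": len(values),
        "mean_log2rc": float(values.mean()),
        "mean_abs_log2rc": float(np.abs(values).mean()),
        "category_counts": counts,
    }


def heb_calls(ratios: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": ratios["pair_id"],
            "group": ratios["group"],
            "category": heb_call_array(ratios["log2rc"].to_numpy(dtype=float), config),
        }
    )


def silencing_call(raw_counts, config: AnalysisConfig | None = None) -> str:
    """Silencing state of one gene in one group from raw replicate counts."""
    counts = np.asarray(raw_counts)
    if counts.size == 0:
        raise ValueError("silencing_call needs at least one replicate")
    if (counts == 0).all():
        return "silenced"
    if (counts >= 5).all():
        return "expressed"
    return "indeterminate"


def silencing_table(matrix: ExpressionMatrix, config: AnalysisConfig) -> pd.DataFrame:
    """Silencing state per gene per group (all zeros / all >= 5 / otherwise)."""
    rows = []
    for group in matrix.groups:
        cols = matrix.group_samples(group)
        raw = matrix.counts[cols].to_numpy()
        silenced = (raw == 0).all(axis=1)
        expressed = (raw >= 5).all(axis=1)
        state = np.where(silenced, "silenced", np.where(expressed, "expressed", "indeterminate"))
        rows.append(
            pd.DataFrame(
                {"gene_id": matrix.counts.index, "group": group, "state": state}
            )
        )
    return pd.concat(rows, ignore_index=True)
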