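"""Unequal homoeologous recombination (HR) from read-depth ratios.

For each homoeolog pair the copy-ratio statistic is

    log10( (R_reads / R_length) / (C_reads / C_length) )

which is 0 at balanced 2:2 copies, log10(2) = 0.30103 at a 3:1 gain of R
and -0.30103 at 1:3.  States beyond those thresholds mark genes as
copy-shifted; a maximal run of at least ``min_run`` (default 3) contiguous
genes shifted in the same direction is called an HR segment.  Zero counts
produce +/-inf sentinels rather than pseudocount ratios: complete
replacement of one homoeolog block is a distinct biological state (an
optional pseudocount mode exists for noisy data).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig

STATES = ("balanced", "R_gain", "C_gain", "R_absent", "C_absent")

#: states consistent with the R subgenome gaining copies, and with C gaining
TOWARD_R = ("R_gain", "C_absent")
TOWARD_C = ("C_gain", "R_absent")

HR_COLUMNS = ["pair_id", "chrom_pair", "order_index", "r_reads", "c_reads", "r_len", "c_len", "sample"]


def copy_ratio(r_reads, r_len, c_reads, c_len, pseudocount: bool = False):
    """Length-normalized log10 depth ratio of the R vs C homoeolog.

    Zero counts give -inf (R absent) / +inf (C absent); both-zero gives NaN
    (untestable).  With ``pseudocount`` 0.5 reads are added to both sides.
    """
    r_reads = np.asarray(r_reads, dtype=float)
    c_reads = np.asarray(c_reads, dtype=float)
    r_len = np.asarray(r_len, dtype=float)
    c_len = np.asarray(c_len, dtype=float)
    if (r_len <= 0).any() or (c_len <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (r_reads < 0).any() or (c_reads < 0).any():
        raise ValueError("read counts must be non-negative")
    if pseudocount:
        r_reads = r_reads + 0.5
        c_reads = c_reads + 0.5
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log10((r_reads / r_len) / (c_reads / c_len))
    out = np.where(
        (r_reads == 0) & (c_reads == 0),
        np.nan,
        np.where(
            r_reads == 0, -np.inf, np.where(c_reads == 0, np.inf, ratio)
        ),
    )
    return out.item() if out.ndim == 0 else out


def call_copy_state(log10_ratio, config: AnalysisConfig):
    """Copy state from the log10 ratio (thresholds strict: |x| must exceed).

    -inf means no R reads (R_absent), +inf no C reads (C_absent), NaN is
    untestable and reported as the empty string.
    """
    x = np.asarray(log10_ratio, dtype=float)
    t = config.copy_log10_threshold
    out = np.where(
        np.isnan(x),
        "",
        np.where(
            np.isneginf(x),
            "R_absent",
            np.where(
                np.isposinf(x),
                "C_absent",
                np.where(x > t, "R_gain", np.where(x < -t, "C_gain", "balanced")),
            ),
        ),
    )
    return out.item() if out.ndim == 0 else out


def copy_ratio_table(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Attach log10_ratio and state columns to an HR count table."""
    missing = [c for c in HR_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"HR count table lacks columns {missing}")
    out = records.copy()
    out["log10_ratio"] = copy_ratio(
        out["r_reads"], out["r_len"], out["c_reads"], out["c_len"],
        pseudocount=config.hr_pseudocount,
    )
    out["state"] = call_copy_state(out["log10_ratio"].to_numpy(), config)
    return out


def _direction(state: str) -> str | None:
    if state in TOWARD_R:
        return "toward_R"
    if state in TOWARD_C:
        return "toward_C"
    return None


def detect_segments(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Maximal runs of >= min_run contiguous same-direction copy shifts.

    ``records`` must carry one row per pair for a single sample, with
    ``state`` assigned, sorted by order_index within each chrom_pair;
    contiguity means consecutive order_index.  Balanced or untestable genes
    break runs, as do direction changes.
    """
    needed = {"chrom_pair", "order_index", "state", "sample"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"detect_segments needs columns {sorted(missing)}")
    segments = []
    for (sample, cp), grp in records.groupby(["sample", "chrom_pair"], sort=False):
        idx = grp["order_index"].to_numpy()
        if (np.diff(idx) <= 0).any():
            raise ValueError(f"records for {cp} ({sample}) are not sorted by order_index")
        states = grp["state"].to_numpy()
        run_start = None
        run_dir = None
        prev_idx = None

        def flush(end_idx):
            if run_start is not None and end_idx - run_start + 1 >= config.min_run:
                segments.append(
                    {
                        "chrom_pair": cp,
                        "start_index": int(run_start),
                        "end_index": int(end_idx),
                        "n_genes": int(end_idx - run_start + 1),
                        "direction": run_dir,
                        "sample": sample,
                    }
                )

        for oi, st in zip(idx, states):
            d = _direction(st)
            contiguous = prev_idx is not None and oi == prev_idx + 1
            if d is None or d != run_dir or not contiguous:
                flush(prev_idx if prev_idx is not None else oi)
                run_start = oi if d is not None else None
                run_dir = d
            prev_idx = oi
        flush(prev_idx if prev_idx is not None else None)
    return pd.DataFrame(
        segments,
        columns=["chrom_pair", "start_index", "end_index", "n_genes", "direction", "sample"],
    )


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def compare_samples(segments: pd.DataFrame, min_reciprocal: float = 0.5) -> pd.DataFrame:
    """Classify each segment as shared across samples or sample-specific.

    A segment is shared when some same-direction segment of another sample
    on the same chrom_pair overlaps it by at least ``min_reciprocal`` of the
    gene count of *both* segments (boundary inclusive: 50% counts).
    """
    samples = segments["sample"].unique()
    if len(samples) < 2:
        raise ValueError("compare_samples needs segments from >= 2 samples")
    out = segments.copy()
    classes = []
    for row in segments.itertuples(index=False):
        others = segments[
            (segments["sample"] != row.sample)
            & (segments["chrom_pair"] == row.chrom_pair)
            & (segments["direction"] == row.direction)
        ]
        shared = False
        for o in others.itertuples(index=False):
            ov = _overlap(row.start_index, row.end_index, o.start_index, o.end_index)
            if ov >= min_reciprocal * row.n_genes and ov >= min_reciprocal * o.n_genes:
                shared = True
                break
        classes.append("shared" if shared else "sample_specific")
    out["class"] = classes
    return out


def sample_summary(compared: pd.DataFrame) -> pd.DataFrame:
    """Counts of shared / sample-specific segments per sample."""
    return (
        compared.groupby(["sample", "class"]).size().rename("n").reset_index()
    )
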