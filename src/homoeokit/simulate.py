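"""Synthetic allopolyploid datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes, at
the count/interval level (no sequences):

* homoeolog read counts for the two inbred parents, F1 and F22, drawn
  negative-binomially around a shared per-pair baseline, with planted cis
  and trans effects.  The generative identity is the one underlying the
  cis/trans decomposition: the parental log2 ratio is P = cis + trans and
  the hybrid ratio is H = cis; F22 uses H' = cis * (1 - trans_compensation),
  modelling the observed post-polyploidization decay of expression bias as
  a tunable trans-compensation mechanism.
* per-cytosine bisulfite counts per gene region (promoter / body /
  terminator), binomial around region-level methylation levels, with
  differential methylation planted between the parents on a fraction of
  promoters.
* per-gene whole-genome-sequencing depth for the homoeologous-recombination
  scan, Poisson in gene length and copy number, with planted copy-number
  segments.
* structural-variant positions whose per-window intensity is log-linear in
  TE density.

Every generator is a deterministic function of (params, params.seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GENE_COLUMNS, PAIR_COLUMNS, REGIONS, region_span
from . import io as hio

#: the seven regulatory categories; "ambiguous" is never planted
CATEGORIES7 = (
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "cis_x_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)

DEFAULT_PROPORTIONS = {
    "conserved": 0.40,
    "cis_only": 0.15,
    "trans_only": 0.15,
    "cis_plus_trans": 0.10,
    "cis_x_trans": 0.10,
    "compensatory": 0.10,
}

TE_SUPERFAMILIES = ("CACTA", "hAT", "Gypsy", "Copia", "Tc1-Mariner")


@dataclass
class SimulationParams:
    n_pairs: int = 500
    n_chrom_pairs: int = 5
    replicates: int = 3
    depth_mean: float = 100.0           # expected counts per gene
    nb_dispersion: float = 0.05         # NB dispersion shared across genes
    category_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    cis_effect: float = 2.0             # log2 units
    trans_effect: float = 2.0           # log2 units
    trans_compensation_F22: float = 0.5
    meth_depth: float = 30.0            # reads per cytosine
    cytosines_per_region: int = 50
    dm_effect: float = 0.7              # planted parental promoter DM
    dm_fraction: float = 0.2            # fraction of pairs with planted DM
    hybrid_dm_effect: float = 0.05      # residual homoeolog DM in hybrids
    p0_error: float = 0.01              # bisulfite non-conversion noise floor
    hr_segments: list | None = None     # (chrom_pair, start_index, n_genes, r_copies, c_copies)
    cn_samples: tuple = ("muscle", "gonad")
    sv_te_slope: float = 3.0            # per-unit-TE-density log-rate coefficient
    sv_mean_per_window: float = 2.0
    window_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < self.n_chrom_pairs:
            raise ValueError("n_pairs must be >= n_chrom_pairs")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_proportions must sum to 1; got {total}")
        if self.category_proportions.get("ambiguous", 0.0) > 0:
            raise ValueError("'ambiguous' cannot be planted")
        unknown = set(self.category_proportions) - set(CATEGORIES7)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        for key in ("cis_effect", "trans_effect", "dm_effect", "hybrid_dm_effect"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be >= 0")
        if not (0.0 <= self.trans_compensation_F22 <= 1.0):
            raise ValueError("trans_compensation_F22 must lie in [0, 1]")
        if not (0.0 <= self.dm_fraction <= 1.0):
            raise ValueError("dm_fraction must lie in [0, 1]")


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed & 0x7FFFFFFF, stream])


@dataclass
class SimulatedGenome:
    genes: pd.DataFrame          # GENE_COLUMNS
    pairs: pd.DataFrame          # PAIR_COLUMNS
    te: pd.DataFrame             # chrom, start, end, name (superfamily)
    chrom_lengths: dict          # chrom -> bp


def simulate_genome(params: SimulationParams) -> SimulatedGenome:
    """Lay out homoeologous chromosome pairs, genes and TE annotations.

    Pairs are distributed evenly over chromosome pairs with consecutive
    order_index; gene lengths are log-uniform in [500, 5000] bp and genes
    never overlap (intergenic gaps leave room for the 2-kb flanks).  TE
    intervals are placed so each window has a coverage density in [0, 0.6].
    """
    rng = _rng(params, 1)
    per_chrom = np.full(params.n_chrom_pairs, params.n_pairs // params.n_chrom_pairs)
    per_chrom[: params.n_pairs % params.n_chrom_pairs] += 1

    genes, pairs = [], []
    chrom_lengths: dict[str, int] = {}
    pair_no = 0
    for ci, n_here in enumerate(per_chrom):
        cp = f"hcp{ci + 1:02d}"
        for sub in ("R", "C"):
            chrom = cp + sub
            lengths = np.exp(rng.uniform(math.log(500), math.log(5000), n_here)).astype(int)
            gaps = rng.integers(4200, 6000, n_here)
            starts = 2500 + np.concatenate(([0], np.cumsum(lengths[:-1] + gaps[:-1])))
            ends = starts + lengths
            strands = rng.choice(["+", "-"], n_here)
            for k in range(n_here):
                gid = f"p{pair_no + k + 1:05d}{sub}"
                genes.append((gid, chrom, int(starts[k]), int(ends[k]), strands[k], sub))
            span = int(ends[-1]) + 2500
            chrom_lengths[chrom] = int(math.ceil(span / params.window_size) * params.window_size)
        for k in range(n_here):
            pid = f"p{pair_no + k + 1:05d}"
            pairs.append((pid, pid + "R", pid + "C", cp, k))
        pair_no += n_here

    te_rows = []
    for chrom, length in chrom_lengths.items():
        for wstart in range(0, length, params.window_size):
            wend = min(wstart + params.window_size, length)
            density = rng.uniform(0.0, 0.6)
            covered = 0
            pos = wstart
            target = density * (wend - wstart)
            while covered < target:
                gap = int(rng.integers(200, 2000))
                te_len = int(rng.integers(500, 3000))
                start = pos + gap
                end = min(start + te_len, wend)
                if start >= wend:
                    break
                fam = TE_SUPERFAMILIES[int(rng.integers(len(TE_SUPERFAMILIES)))]
                te_rows.append((chrom, start, end, fam))
                covered += end - start
                pos = end
    te = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "name"])
    return SimulatedGenome(
        genes=pd.DataFrame(genes, columns=GENE_COLUMNS),
        pairs=pd.DataFrame(pairs, columns=PAIR_COLUMNS),
        te=te,
        chrom_lengths=chrom_lengths,
    )


def _plant_effects(params: SimulationParams, rng: np.random.Generator):
    """Draw a category and (cis, trans) pair per homoeolog pair.

    cis x trans is planted with |trans| = trans_effect / 2 so that the
    parental ratio P = cis + trans stays away from zero; with equal
    magnitudes it would coincide exactly with the compensatory pattern.
    """
    cats = list(params.category_proportions)
    probs = np.array([params.category_proportions[c] for c in cats])
    chosen = rng.choice(len(cats), params.n_pairs, p=probs)
    signs = rng.choice([-1.0, 1.0], params.n_pairs)
    cis = np.zeros(params.n_pairs)
    trans = np.zeros(params.n_pairs)
    for i, ci in enumerate(chosen):
        cat, s = cats[ci], signs[i]
        if cat == "cis_only":
            cis[i] = s * params.cis_effect
        elif cat == "trans_only":
            trans[i] = s * params.trans_effect
        elif cat == "cis_plus_trans":
            cis[i] = s * params.cis_effect
            trans[i] = s * params.trans_effect
        elif cat == "cis_x_trans":
            cis[i] = s * params.cis_effect
            trans[i] = -s * params.trans_effect / 2.0
        elif cat == "compensatory":
            cis[i] = s * params.cis_effect
            trans[i] = -s * params.cis_effect
    return np.array([cats[c] for c in chosen]), cis, trans


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_expression(pairs: pd.DataFrame, params: SimulationParams):
    """Counts for parent_R, parent_C, F1 and F22 plus the expression truth."""
    rng = _rng(params, 2)
    n = len(pairs)
    if n != params.n_pairs:
        params = dataclasses_replace(params, n_pairs=n)
    category, cis, trans = _plant_effects(params, rng)
    P = cis + trans
    H1 = cis
    H22 = cis * (1.0 - params.trans_compensation_F22)
    baseline = rng.lognormal(math.log(params.depth_mean), 0.5, n)

    groups = [
        ("parent_R", "parent_R", P / 2.0, None),
        ("parent_C", "parent_C", -P / 2.0, None),
        ("F1", "hybrid", H1 / 2.0, -H1 / 2.0),
        ("F22", "hybrid", H22 / 2.0, -H22 / 2.0),
    ]
    r_genes = pairs["r_gene"].to_numpy()
    c_genes = pairs["c_gene"].to_numpy()
    gene_index = list(r_genes) + list(c_genes)
    counts = {}
    sheet_rows = []
    for group, role, r_expo, c_expo in groups:
        for rep in range(1, params.replicates + 1):
            sid = f"{group}_rep{rep}"
            sheet_rows.append((sid, group, role, rep, "embryo"))
            col = np.zeros(2 * n, dtype=np.int64)
            if role == "hybrid":
                col[:n] = _nb_draw(rng, baseline * 2.0 ** r_expo, params.nb_dispersion)
                col[n:] = _nb_draw(rng, baseline * 2.0 ** c_expo, params.nb_dispersion)
            elif role == "parent_R":
                col[:n] = _nb_draw(rng, baseline * 2.0 ** r_expo, params.nb_dispersion)
            else:
                col[n:] = _nb_draw(rng, baseline * 2.0 ** r_expo, params.nb_dispersion)
            counts[sid] = col
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_index, name="gene_id"))
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "group", "role", "replicate", "tissue"]
    ).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "pair_id": pairs["pair_id"].to_numpy(),
            "true_category7": category,
            "true_cis": cis,
            "true_trans": trans,
            "true_P": P,
            "true_H_F1": H1,
            "true_H_F22": H22,
            "baseline": baseline,
        }
    )
    return ExpressionMatrix(counts=counts_df, samples=sheet), truth


def dataclasses_replace(params, **kw):
    import dataclasses

    return dataclasses.replace(params, **kw)


def simulate_methylation(pairs: pd.DataFrame, genes: pd.DataFrame, params: SimulationParams):
    """Per-cytosine counts per group and the methylation ground truth.

    Region-level methylation (ML) is Beta(2,2) and shared between homoeologs
    except on a planted fraction of promoters, where the parental MLs differ
    by ``dm_effect`` (the carp-side ML is rescaled into [0, 1 - dm_effect]
    so the planted difference survives clamping).  Hybrid homoeologs sit at
    the parental mean separated by ``hybrid_dm_effect``.  Each cytosine gets
    depth ~ Poisson(meth_depth) and methylated reads ~ Binomial(depth,
    clip(ML + p0_error, 0, 1)).
    """
    rng = _rng(params, 3)
    gene_info = genes.set_index("gene_id")
    n = len(pairs)
    planted = rng.random(n) < params.dm_fraction

    cols: dict[str, list] = {k: [] for k in ("sample", "chrom", "pos", "context", "k_meth", "n_total")}
    truth_rows = []
    for i, pair in enumerate(pairs.itertuples(index=False)):
        ml = {}
        for region in REGIONS:
            base = rng.beta(2.0, 2.0)
            if region == "up2k" and planted[i]:
                ml_c = base * (1.0 - params.dm_effect)
                ml_r = ml_c + params.dm_effect
                dm_h = params.hybrid_dm_effect
            else:
                ml_c = ml_r = base
                dm_h = 0.0
            mid = (ml_r + ml_c) / 2.0
            hyb_r = min(1.0, mid + dm_h / 2.0)
            hyb_c = max(0.0, mid - dm_h / 2.0)
            ml[region] = {
                "parent_R": {"R": ml_r},
                "parent_C": {"C": ml_c},
                "F1": {"R": hyb_r, "C": hyb_c},
                "F22": {"R": hyb_r, "C": hyb_c},
            }
            if region == "up2k":
                truth_rows.append(
                    (pair.pair_id, bool(planted[i]), ml_r - ml_c, hyb_r - hyb_c)
                )
        for region in REGIONS:
            for sample, sub_ml in ml[region].items():
                for sub, level in sub_ml.items():
                    gid = pair.r_gene if sub == "R" else pair.c_gene
                    gene = gene_info.loc[gid]
                    start, end = region_span(gene, region)
                    span = end - start
                    k = min(params.cytosines_per_region, span)
                    pos = np.sort(rng.choice(span, size=k, replace=False)) + start
                    depth = rng.poisson(params.meth_depth, k)
                    p = min(1.0, max(0.0, level + params.p0_error))
                    meth = rng.binomial(depth, p)
                    ctx = np.where(rng.random(k) < 0.9, "CpG", "CHH")
                    cols["sample"].append(np.full(k, sample))
                    cols["chrom"].append(np.full(k, gene.chrom))
                    cols["pos"].append(pos)
                    cols["context"].append(ctx)
                    cols["k_meth"].append(meth)
                    cols["n_total"].append(depth)
    cyt = pd.DataFrame(
        {
            "sample": np.concatenate(cols["sample"]),
            "chrom": np.concatenate(cols["chrom"]),
            "pos": np.concatenate(cols["pos"]).astype(int),
            "strand": "+",
            "context": np.concatenate(cols["context"]),
            "k_meth": np.concatenate(cols["k_meth"]).astype(int),
            "n_total": np.concatenate(cols["n_total"]).astype(int),
        }
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["pair_id", "dm_planted", "true_dm_parents", "true_dm_hybrid"],
    )
    return cyt, truth


def default_hr_segments(params: SimulationParams) -> list:
    """Two planted copy-number segments if the genome has room for them."""
    per_chrom = params.n_pairs // params.n_chrom_pairs
    segs = []
    if per_chrom >= 15:
        segs.append(("hcp01", 5, 5, 3, 1))
    if params.n_chrom_pairs >= 2 and per_chrom >= 20:
        segs.append(("hcp02", 8, 8, 1, 3))
    return segs


def simulate_copy_number(
    pairs: pd.DataFrame, params: SimulationParams, genes: pd.DataFrame | None = None
):
    """Per-gene WGS read counts for the recombination scan, plus truth.

    Default copy state is (2, 2); inside a planted segment it is the
    segment's (r_copies, c_copies) — (0, 4) models complete replacement of
    the R block and yields structurally zero R counts.  Counts are
    Poisson(depth_mean * copies / 2 * length_kb).
    """
    rng = _rng(params, 4)
    segments = params.hr_segments
    if segments is None:
        segments = default_hr_segments(params)
    order = pairs.sort_values(["chrom_pair", "order_index"]).reset_index(drop=True)
    n = len(order)
    if genes is not None:
        lens = genes.set_index("gene_id")
        r_len = (lens.loc[order["r_gene"], "end"] - lens.loc[order["r_gene"], "start"]).to_numpy()
        c_len = (lens.loc[order["c_gene"], "end"] - lens.loc[order["c_gene"], "start"]).to_numpy()
    else:
        r_len = np.exp(rng.uniform(math.log(500), math.log(5000), n)).astype(int)
        c_len = np.exp(rng.uniform(math.log(500), math.log(5000), n)).astype(int)

    r_copies = np.full(n, 2, dtype=int)
    c_copies = np.full(n, 2, dtype=int)
    truth_segs = []
    seen: dict[str, list[tuple[int, int]]] = {}
    for cp, start_idx, n_genes, rc, cc in segments:
        mask = (order["chrom_pair"] == cp) & (
            order["order_index"].between(start_idx, start_idx + n_genes - 1)
        )
        if mask.sum() != n_genes:
            raise ValueError(f"segment {cp}:{start_idx}+{n_genes} exceeds the gene track")
        for s, e in seen.get(cp, []):
            if start_idx <= e and s <= start_idx + n_genes - 1:
                raise ValueError(f"overlapping planted segments on {cp}")
        seen.setdefault(cp, []).append((start_idx, start_idx + n_genes - 1))
        r_copies[mask.to_numpy()] = rc
        c_copies[mask.to_numpy()] = cc
        direction = "toward_R" if rc > cc else "toward_C"
        truth_segs.append((cp, start_idx, start_idx + n_genes - 1, n_genes, rc, cc, direction))

    frames = []
    state_rows = []
    for sample in params.cn_samples:
        r_reads = rng.poisson(params.depth_mean * r_copies / 2.0 * r_len / 1000.0)
        c_reads = rng.poisson(params.depth_mean * c_copies / 2.0 * c_len / 1000.0)
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": order["pair_id"],
                    "chrom_pair": order["chrom_pair"],
                    "order_index": order["order_index"],
                    "r_reads": r_reads,
                    "c_reads": c_reads,
                    "r_len": r_len,
                    "c_len": c_len,
                    "sample": sample,
                }
            )
        )
        state_rows.append(
            pd.DataFrame(
                {
                    "pair_id": order["pair_id"],
                    "sample": sample,
                    "r_copies": r_copies,
                    "c_copies": c_copies,
                }
            )
        )
    hr_counts = pd.concat(frames, ignore_index=True)
    truth_states = pd.concat(state_rows, ignore_index=True)
    truth_segments = pd.DataFrame(
        truth_segs,
        columns=[
            "chrom_pair",
            "start_index",
            "end_index",
            "n_genes",
            "r_copies",
            "c_copies",
            "direction",
        ],
    )
    return hr_counts, truth_states, truth_segments


def simulate_sv(te: pd.DataFrame, chrom_lengths: dict, params: SimulationParams):
    """SV positions with per-window intensity exp(alpha + slope * TE density).

    alpha is chosen so the genome-wide mean SV count per window equals
    ``sv_mean_per_window``.
    """
    rng = _rng(params, 5)
    from .divergence import te_fraction

    windows = []
    for chrom, length in chrom_lengths.items():
        for wstart in range(0, int(length), params.window_size):
            wend = min(wstart + params.window_size, int(length))
            dens = te_fraction(te, chrom, wstart, wend)
            windows.append((chrom, wstart, wend, dens))
    wdf = pd.DataFrame(windows, columns=["chrom", "start", "end", "te_density"])
    rel = np.exp(params.sv_te_slope * wdf["te_density"].to_numpy())
    alpha = math.log(params.sv_mean_per_window) - math.log(rel.mean())
    lam = np.exp(alpha + params.sv_te_slope * wdf["te_density"].to_numpy())
    counts = rng.poisson(lam)
    rows = []
    for (chrom, wstart, wend, _), c in zip(windows, counts):
        if c:
            pos = np.sort(rng.integers(wstart, wend, c))
            rows.extend((chrom, int(p), int(p) + 1, "SV") for p in pos)
    sv = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    wdf["sv_lambda"] = lam
    wdf["true_sv_count"] = counts
    return sv, wdf


@dataclass
class SimulatedDataset:
    params: SimulationParams
    genome: SimulatedGenome
    expression: ExpressionMatrix
    truth_pairs: pd.DataFrame
    cytosines: pd.DataFrame
    hr_counts: pd.DataFrame
    truth_copy_states: pd.DataFrame
    truth_segments: pd.DataFrame
    sv: pd.DataFrame
    truth_windows: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        counts = self.expression.counts.copy()
        counts.index.name = "gene_id"
        counts.to_csv(out / "counts.tsv", sep="\t")
        sheet = self.expression.samples.reset_index()
        hio.write_records(sheet, out / "samples.tsv")
        g = self.genome.genes.copy()
        g["score"] = 0
        hio.write_bed(g, out / "genes.bed", name_col="gene_id")
        hio.write_records(self.genome.pairs, out / "pairs.tsv")
        hio.write_records(self.cytosines, out / "cytosines.tsv")
        hio.write_bed(self.genome.te, out / "te.bed", name_col="name")
        hio.write_bed(self.sv, out / "sv.bed", name_col="name", )
        hio.write_records(self.hr_counts, out / "hr_counts.tsv")
        lengths = pd.DataFrame(
            sorted(self.genome.chrom_lengths.items()), columns=["chrom", "length"]
        )
        hio.write_records(lengths, out / "chrom_lengths.tsv")
        hio.write_records(self.truth_pairs, out / "truth.tsv")
        hio.write_records(self.truth_segments, out / "truth_segments.tsv", empty_ok=True)
        hio.write_records(self.truth_copy_states, out / "truth_copy_states.tsv")
        hio.write_records(self.truth_windows, out / "truth_windows.tsv")


def simulate_all(params: SimulationParams) -> SimulatedDataset:
    """Run every generator and bundle outputs with a complete ground truth."""
    genome = simulate_genome(params)
    matrix, truth_expr = simulate_expression(genome.pairs, params)
    cyt, truth_meth = simulate_methylation(genome.pairs, genome.genes, params)
    hr_counts, truth_states, truth_segments = simulate_copy_number(
        genome.pairs, params, genes=genome.genes
    )
    sv, truth_windows = simulate_sv(genome.te, genome.chrom_lengths, params)
    truth_pairs = truth_expr.merge(truth_meth, on="pair_id", validate="one_to_one")
    return SimulatedDataset(
        params=params,
        genome=genome,
        expression=matrix,
        truth_pairs=truth_pairs,
        cytosines=cyt,
        hr_counts=hr_counts,
        truth_copy_states=truth_states,
        truth_segments=truth_segments,
        sv=sv,
        truth_windows=truth_windows,
    )
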