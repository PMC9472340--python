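import numpy as np
import pandas as pd
import pytest

from homoeokit import expression as ex
from homoeokit.config import AnalysisConfig
from homoeokit.simulate import (
    SimulationParams,
    simulate_copy_number,
    simulate_expression,
    simulate_genome,
    simulate_methylation,
    simulate_sv,
)


def test_genome_layout_and_order_index():
    params = SimulationParams(n_pairs=10, n_chrom_pairs=2, seed=1)
    g = simulate_genome(params)
    assert len(g.pairs) == 10
    for cp, grp in g.pairs.groupby("chrom_pair"):
        assert list(grp["order_index"]) == list(range(5))
    # genes non-overlapping per chromosome, lengths within the declared range
    for chrom, grp in g.genes.sort_values("start").groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()
        assert ((ends - starts) >= 500).all() and ((ends - starts) <= 5000).all()


def test_genome_determinism():
    params = SimulationParams(n_pairs=12, n_chrom_pairs=3, seed=5)
    a = simulate_genome(params)
    b = simulate_genome(params)
    pd.testing.assert_frame_equal(a.genes, b.genes)
    pd.testing.assert_frame_equal(a.te, b.te)


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError):
        SimulationParams(n_pairs=1, n_chrom_pairs=2)


def test_ambiguous_cannot_be_planted():
    with pytest.raises(ValueError, match="ambiguous"):
        SimulationParams(
            n_pairs=10,
            n_chrom_pairs=2,
            category_proportions={"conserved": 0.5, "ambiguous": 0.5},
        )


def test_conserved_high_depth_ratios_near_zero():
    """Law of large numbers: at depth 1e6 and zero dispersion, |log2(R/C)| < 0.05."""
    params = SimulationParams(
        n_pairs=50,
        n_chrom_pairs=2,
        depth_mean=1e6,
        nb_dispersion=0.0,
        category_proportions={"conserved": 1.0},
        seed=3,
    )
    g = simulate_genome(params)
    mat, truth = simulate_expression(g.pairs, params)
    cfg = AnalysisConfig()
    mat = ex.normalize(mat)
    for group in ("F1", "F22"):
        ratios = ex.ratio_records(mat, g.pairs, group, cfg)
        assert np.abs(ratios["log2rc"]).max() < 0.05
    assert (truth["true_category7"] == "conserved").all()


def test_model_identity_cis_only_and_compensation():
    """P = cis + trans and H = cis; full trans compensation flattens F22."""
    params = SimulationParams(
        n_pairs=40,
        n_chrom_pairs=2,
        depth_mean=1e6,
        nb_dispersion=0.0,
        category_proportions={"cis_only": 1.0},
        trans_compensation_F22=1.0,
        seed=4,
    )
    g = simulate_genome(params)
    mat, truth = simulate_expression(g.pairs, params)
    assert np.allclose(truth["true_P"], truth["true_cis"])
    assert np.allclose(truth["true_H_F1"], truth["true_cis"])
    assert np.allclose(truth["true_H_F22"], 0.0)
    cfg = AnalysisConfig()
    mat = ex.normalize(mat)
    f22 = ex.ratio_records(mat, g.pairs, "F22", cfg)
    assert np.abs(f22["log2rc"]).max() < 0.05
    # the generative identity on raw counts: log2(parent_R / parent_C) = P
    pr = mat.counts[mat.group_samples("parent_R")].loc[g.pairs["r_gene"]].mean(axis=1)
    pc = mat.counts[mat.group_samples("parent_C")].loc[g.pairs["c_gene"]].mean(axis=1)
    np.testing.assert_allclose(
        np.log2(pr.to_numpy() / pc.to_numpy()), truth["true_P"], atol=0.05
    )
    # after library normalization the same identity holds up to one common
    # library-size offset (the panel here is deliberately all-cis, so the
    # two parental library totals differ systematically)
    isx = ex.in_silico_hybrid(mat, g.pairs, cfg)
    merged = isx.merge(truth, on="pair_id")
    offset = (merged["log2rc"] - merged["true_P"]).mean()
    np.testing.assert_allclose(
        merged["log2rc"] - offset, merged["true_P"], atol=0.05
    )


def test_expression_determinism_and_truth_completeness():
    params = SimulationParams(n_pairs=20, n_chrom_pairs=2, seed=11)
    g = simulate_genome(params)
    m1, t1 = simulate_expression(g.pairs, params)
    m2, t2 = simulate_expression(g.pairs, params)
    pd.testing.assert_frame_equal(m1.counts, m2.counts)
    pd.testing.assert_frame_equal(t1, t2)
    assert t1["pair_id"].is_unique and len(t1) == len(g.pairs)


def test_methylation_planted_difference_recovered_at_high_depth():
    """Binomial concentration: planted promoter DM recovered within 0.03."""
    params = SimulationParams(
        n_pairs=30,
        n_chrom_pairs=2,
        meth_depth=1000,
        dm_fraction=1.0,
        dm_effect=0.7,
        seed=9,
    )
    g = simulate_genome(params)
    cyt, truth = simulate_methylation(g.pairs, g.genes, params)
    from homoeokit.methylation import region_mean_levels

    cfg = AnalysisConfig()
    pr = cyt[cyt["sample"] == "parent_R"]
    pc = cyt[cyt["sample"] == "parent_C"]
    ml_r = region_mean_levels(pr, g.genes, "up2k", cfg).set_index("gene_id")["ml"]
    ml_c = region_mean_levels(pc, g.genes, "up2k", cfg).set_index("gene_id")["ml"]
    dm = (
        ml_r.reindex(g.pairs["r_gene"]).to_numpy()
        - ml_c.reindex(g.pairs["c_gene"]).to_numpy()
    )
    np.testing.assert_allclose(dm, truth["true_dm_parents"], atol=0.03)
    assert truth["true_dm_parents"].min() >= 0.69


def test_methylation_determinism():
    params = SimulationParams(n_pairs=6, n_chrom_pairs=2, cytosines_per_region=10, seed=2)
    g = simulate_genome(params)
    a, ta = simulate_methylation(g.pairs, g.genes, params)
    b, tb = simulate_methylation(g.pairs, g.genes, params)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(ta, tb)


def test_copy_number_segments_and_sentinel_states():
    params = SimulationParams(
        n_pairs=60,
        n_chrom_pairs=2,
        depth_mean=2000.0,
        hr_segments=[("hcp01", 10, 5, 3, 1), ("hcp02", 3, 4, 0, 4)],
        seed=6,
    )
    g = simulate_genome(params)
    counts, states, segs = simulate_copy_number(g.pairs, params, genes=g.genes)
    one = counts[counts["sample"] == params.cn_samples[0]]
    seg1 = one[(one["chrom_pair"] == "hcp01") & one["order_index"].between(10, 14)]
    ratio = np.log10(
        (seg1["r_reads"] / seg1["r_len"]) / (seg1["c_reads"] / seg1["c_len"])
    )
    # Poisson mean ratio log10(3) ~ 0.477 at high depth
    np.testing.assert_allclose(ratio, np.log10(3), atol=0.1)
    seg2 = one[(one["chrom_pair"] == "hcp02") & one["order_index"].between(3, 6)]
    assert (seg2["r_reads"] == 0).all()
    background = one[(one["chrom_pair"] == "hcp01") & (one["order_index"] > 20)]
    np.testing.assert_allclose(
        np.log10((background["r_reads"] / background["r_len"]) / (background["c_reads"] / background["c_len"])),
        0.0,
        atol=0.1,
    )
    assert set(segs["direction"]) == {"toward_R", "toward_C"}


def test_overlapping_segments_rejected():
    params = SimulationParams(
        n_pairs=40,
        n_chrom_pairs=2,
        hr_segments=[("hcp01", 3, 5, 3, 1), ("hcp01", 6, 4, 1, 3)],
        seed=6,
    )
    g = simulate_genome(params)
    with pytest.raises(ValueError, match="overlap"):
        simulate_copy_number(g.pairs, params, genes=g.genes)


def test_sv_null_and_power():
    base = dict(n_pairs=40, n_chrom_pairs=2, window_size=2000, seed=8)
    g = simulate_genome(SimulationParams(**base))
    null_params = SimulationParams(**base, sv_te_slope=0.0)
    sv0, w0 = simulate_sv(g.te, g.chrom_lengths, null_params)
    assert len(w0) >= 200
    r0 = np.corrcoef(w0["te_density"], w0["true_sv_count"])[0, 1]
    assert abs(r0) < 0.1
    alt_params = SimulationParams(**base, sv_te_slope=3.0)
    sv1, w1 = simulate_sv(g.te, g.chrom_lengths, alt_params)
    from scipy.stats import pearsonr

    r1, p1 = pearsonr(w1["te_density"], w1["true_sv_count"])
    assert r1 > 0 and p1 < 0.001
    # determinism
    sv1b, _ = simulate_sv(g.te, g.chrom_lengths, alt_params)
    pd.testing.assert_frame_equal(sv1, sv1b)
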