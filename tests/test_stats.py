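import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tracerval.stats import (
    anova_across_depths,
    build_connectivity_table,
    classify_fp_fn,
    correlate,
    export_backbone,
    fit_proportional,
    regional_counts,
    streamline_sensitivity,
    topk_spearman,
    voxelwise_pearson,
)
from tracerval.tracking import StreamlineSet
from tracerval.transfer import InterfaceSet, SurfaceDDM


def _surface(density, roi_ids):
    vox = np.array([[i, 0, 0] for i in range(len(density))])
    iface = InterfaceSet(voxels=vox, shape=(len(density), 1, 1), voxel_size=(1, 1, 1))
    return SurfaceDDM(density=np.asarray(density, float), interface=iface, provenance="t"), np.asarray(roi_ids)


def test_regional_counts_basic():
    sddm, ids = _surface([1, 2, 3, 0, 5], [1, 1, 2, 2, 0])
    totals = regional_counts(sddm, ids)
    assert totals[1] == 3 and totals[2] == 3
    empty, ids2 = _surface([0, 0, 0], [1, 2, 2])
    assert (regional_counts(empty, ids2) == 0).all()


def test_fit_proportional_selects_origin_model_on_exact_proportionality():
    x = np.array([1.0, 5.0, 10.0, 50.0, 100.0])
    fit = fit_proportional(x, 3.0 * x)
    assert fit.model_used == 2
    assert fit.a == 0.0
    assert fit.b == pytest.approx(3.0, abs=1e-10)
    assert fit.r == pytest.approx(1.0, abs=1e-12)


def test_fit_proportional_keeps_intercept_when_required():
    rng = np.random.default_rng(0)
    x = np.linspace(1, 100, 20)
    y = 100.0 + 0.0 * x + rng.normal(0, 0.5, 20)
    fit = fit_proportional(x, y)
    assert fit.model_used == 1
    assert not (fit.ci_a[0] <= 0.0 <= fit.ci_a[1])


def test_fit_proportional_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        fit_proportional(np.ones(5), np.arange(5.0))


def test_correlations_match_definitional_oracles():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = int(rng.integers(4, 12))
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert correlate(x, y, "pearson")[0] == pytest.approx(sps.pearsonr(x, y)[0], abs=1e-12)
        assert correlate(x, y, "spearman")[0] == pytest.approx(sps.spearmanr(x, y)[0], abs=1e-12)
        # p-values from the same t transform
        assert correlate(x, y, "pearson")[1] == pytest.approx(sps.pearsonr(x, y)[1], abs=1e-9)


def test_correlation_special_cases():
    x = np.arange(10.0)
    assert correlate(x, 2 * x + 1)[0] == pytest.approx(1.0)
    r_s, _ = correlate(x, np.exp(x), "spearman")
    r_p, _ = correlate(x, np.exp(x), "pearson")
    assert r_s == pytest.approx(1.0) and r_p < 1.0
    r, p = correlate(x, np.ones(10))
    assert np.isnan(r) and p == 1.0


def test_permutation_pvalue_small_n():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=6), rng.normal(size=6)
    r_t, _ = correlate(x, y, "pearson")
    r_p, p_perm = correlate(x, y, "pearson", pvalue="permutation")
    assert r_p == r_t
    assert 0.0 <= p_perm <= 1.0


def test_topk_spearman_rules_and_errors():
    nb = np.array([5.0, 20, 150, 300, 800, 2000, 40, 120, 900, 110, 101, 250])
    nd = nb * 2
    r, p, n = topk_spearman(nb, nd, rule="threshold", threshold=100)
    assert r == pytest.approx(1.0) and n == int((nb > 100).sum())
    r, p, n = topk_spearman(nb, nd, rule="largest", k=10)
    assert n == 10
    with pytest.raises(ValueError, match="< 3"):
        topk_spearman(np.array([1.0, 2, 3, 4]), np.ones(4), rule="threshold", threshold=100)


def test_topk_selection_can_beat_full_spearman():
    """Noise confined to weak connections: the top-k rank correlation exceeds
    the all-regions one (constructed example)."""
    rng = np.random.default_rng(3)
    nb = np.array([10.0, 12, 15, 18, 22, 500, 900, 1500, 2500, 4000, 6000, 9000])
    nd = nb.copy()
    nd[:5] = rng.permutation(nd[:5])  # scramble the small ones
    while np.array_equal(nd[:5], nb[:5]):
        nd[:5] = rng.permutation(nd[:5])
    r_full, _ = correlate(nb, nd, "spearman")
    r_top, _, _ = topk_spearman(nb, nd, rule="threshold", threshold=100)
    assert r_top > r_full
    assert r_top == pytest.approx(1.0)


def test_voxelwise_pearson_contract():
    rng = np.random.default_rng(4)
    b = rng.uniform(0, 5, 30)
    r, p, n = voxelwise_pearson(b, 4.0 * b)
    assert r == pytest.approx(1.0) and n == 30
    r, p, n = voxelwise_pearson(b, np.full(30, 2.0))
    assert np.isnan(r) and p == 1.0
    d = rng.normal(size=30)
    assert voxelwise_pearson(b, d)[0] == pytest.approx(sps.pearsonr(b, d)[0], abs=1e-12)


def test_classify_fp_fn():
    table = build_connectivity_table(
        n_b=pd.Series({1: 50.0, 2: 0.0, 3: 120.0, 4: 0.0}),
        n_d=pd.Series({1: 0.0, 2: 12.0, 3: 80.0, 4: 0.0}),
    )
    fn, fp = classify_fp_fn(table)
    assert fn == [1] and fp == [2]


def _streams_visiting(roi_lists, roi_map_shape=(4, 4, 4)):
    roi_map = np.zeros(roi_map_shape, dtype=int)
    roi_map[0, 0, 0] = 1
    roi_map[1, 1, 1] = 2
    coords = {1: (0, 0, 0), 2: (1, 1, 1), 0: (3, 3, 3)}
    visited = []
    for rois in roi_lists:
        visited.append(np.array(sorted(
            np.ravel_multi_index(coords[r], roi_map_shape) for r in rois
        ), dtype=np.int64))
    ss = StreamlineSet(streamlines=[np.zeros((2, 3))] * len(roi_lists), step_length=1.0,
                       provenance="DS", visited=visited, shape=roi_map_shape, voxel_size=(1, 1, 1))
    return ss, roi_map


def test_sensitivity_fractions():
    ss, roi_map = _streams_visiting([[1], [1], [2], [0]])
    assert streamline_sensitivity(ss, [1], roi_map) == pytest.approx(2 / 3)
    assert streamline_sensitivity(ss, [1, 2], roi_map) == 1.0
    occluded, roi_map = _streams_visiting([[2], [2], [0]])
    clean, _ = _streams_visiting([[1], [1], [2]])
    # spurious-region traffic strictly lowers sensitivity
    assert streamline_sensitivity(occluded, [1], roi_map) < streamline_sensitivity(clean, [1], roi_map)


def test_sensitivity_undefined_when_no_roi_reached():
    ss, roi_map = _streams_visiting([[0], [0]])
    with pytest.warns(UserWarning, match="undefined"):
        assert np.isnan(streamline_sensitivity(ss, [1], roi_map))


def test_backbone_graph_weights():
    table = build_connectivity_table(
        n_b=pd.Series({1: 10.0, 2: 10.0, 3: 0.0}),
        n_d=pd.Series({1: 100.0, 2: 100.0, 3: 0.0}),
    )
    geometry = {1: {"volume": 2.0}, 2: {"volume": 4.0}, 3: {"volume": 1.0}}
    g = export_backbone(table, geometry)
    assert g.number_of_edges() == 2  # zero strength omitted
    w1 = g.edges["injection", 1]["connection_weight"]
    w2 = g.edges["injection", 2]["connection_weight"]
    assert w1 / w2 == pytest.approx(2.0)
    assert g.edges["injection", 1]["weight"] == pytest.approx(np.log10(100.0))


def test_anova_across_depths():
    rng = np.random.default_rng(5)
    groups = {0.0: rng.normal(0.3, 0.05, 12), 0.3: rng.normal(0.3, 0.05, 12),
              0.6: rng.normal(0.3, 0.05, 12)}
    f, p = anova_across_depths(groups)
    oracle = sps.f_oneway(*groups.values())
    assert f == pytest.approx(oracle.statistic)
    assert p == pytest.approx(oracle.pvalue)
    with pytest.raises(ValueError):
        anova_across_depths({0.0: [1.0, 2.0]})
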