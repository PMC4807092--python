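import itertools

import numpy as np
import pandas as pd
import pytest

from tumorpool import (
    SimulationConfig,
    classify,
    concordance_fractions,
    make_truth,
    pca_variant_profiles,
    pooled_detection_stats,
    simulate_region_counts,
    vaf_correlation,
    vaf_distribution_by_class,
)
from tests.conftest import make_callset_from_detection


def _summary_from_matrix(det: np.ndarray, vaf: np.ndarray | None = None):
    callsets = [
        make_callset_from_detection(
            det[:, j], f"r{j}", None if vaf is None else vaf[:, j]
        )
        for j in range(det.shape[1])
    ]
    return classify(callsets)


@pytest.mark.parametrize(
    "vector, label",
    [
        ((1, 1, 1, 1), "common"),
        ((1, 0, 0, 0), "private"),
        ((0, 1, 0, 0), "private"),
        ((1, 1, 0, 0), "shared"),
        ((1, 1, 1, 0), "shared"),
        ((0, 0, 0, 0), "absent"),
    ],
)
def test_detection_vector_labels(vector, label):
    det = np.array([vector], dtype=bool).reshape(1, 4)
    summary = _summary_from_matrix(det)
    assert summary.per_variant["label"].iloc[0] == label


def test_partition_property_random_callsets():
    rng = np.random.default_rng(0)
    for _ in range(100):
        det = rng.random((rng.integers(5, 60), 4)) < rng.uniform(0.1, 0.9)
        s = _summary_from_matrix(det)
        counts = s.aggregate["class_counts"]
        n_any = int(det.any(axis=1).sum())
        assert counts["common"] + counts["shared"] + counts["private"] == n_any
        assert counts["absent"] == det.shape[0] - n_any


def test_concordance_fractions_match_brute_force_tally():
    rng = np.random.default_rng(1)
    det = rng.random((200, 4)) < 0.5
    s = _summary_from_matrix(det)
    fr = concordance_fractions(s)
    n_det = det.sum(axis=1)
    denom = (n_det > 0).sum()
    assert fr["common"] == pytest.approx((n_det == 4).sum() / denom)
    assert fr["private"] == pytest.approx((n_det == 1).sum() / denom)
    assert fr["shared"] == pytest.approx(((n_det >= 2) & (n_det <= 3)).sum() / denom)


def test_private_fraction_sixteen_of_hundred_two():
    # 16 private out of 102 regionally detected variants -> 0.157
    det = np.zeros((102, 4), dtype=bool)
    det[:16, 0] = True           # private
    det[16:, :] = True           # common
    s = _summary_from_matrix(det)
    fr = concordance_fractions(s)
    assert fr["private"] == pytest.approx(0.157, abs=5e-4)


def test_pooled_identical_to_union_gives_full_detection():
    rng = np.random.default_rng(2)
    det = rng.random((150, 4)) < 0.5
    s = _summary_from_matrix(det)
    pooled = make_callset_from_detection(det.any(axis=1), "pooled")
    stats = pooled_detection_stats(s, pooled)
    for c in ("common", "shared", "private"):
        rate = stats["pooled_detection_rate"][c]
        assert rate == 1.0 or np.isnan(rate)
    assert stats["missed_moderate_vaf_fraction"] in (0.0,) or np.isnan(
        stats["missed_moderate_vaf_fraction"]
    )


def test_single_biopsy_expectation_is_one_quarter_by_enumeration():
    # a private variant uniformly assigned to one of four regions is present
    # in a randomly chosen biopsy with probability exactly 1/4
    det = np.eye(4, dtype=bool)  # 4 private variants, one per region
    s = _summary_from_matrix(det)
    pooled = make_callset_from_detection(np.ones(4, dtype=bool), "pooled")
    stats = pooled_detection_stats(s, pooled)
    assert stats["single_biopsy_expectation"] == pytest.approx(0.25)
    # enumeration oracle: all (variant-region, biopsy) combinations
    hits = sum(
        1
        for region, biopsy in itertools.product(range(4), repeat=2)
        if region == biopsy
    )
    assert hits / 16 == 0.25


def test_vaf_correlation_perfect_when_pool_equals_mean():
    rng = np.random.default_rng(3)
    n = 50
    vaf = rng.uniform(0.1, 0.6, (n, 4))
    det = np.ones((n, 4), dtype=bool)
    s = _summary_from_matrix(det, vaf)
    pooled = make_callset_from_detection(
        np.ones(n, dtype=bool), "pooled", vaf.mean(axis=1)
    )
    pooled_detection_stats(s, pooled)
    r = vaf_correlation(s)
    assert r["pooled"] == pytest.approx(1.0, abs=1e-12)


def test_vaf_correlation_degenerate_is_nan_with_warning():
    n = 10
    det = np.ones((n, 4), dtype=bool)
    vaf = np.full((n, 4), 0.3)
    s = _summary_from_matrix(det, vaf)
    pooled = make_callset_from_detection(np.ones(n, dtype=bool), "pooled",
                                         np.full(n, 0.3))
    pooled_detection_stats(s, pooled)
    with pytest.warns(UserWarning, match="zero variance"):
        r = vaf_correlation(s)
    assert np.isnan(r["pooled"])


def test_vaf_correlation_matches_textbook_formula():
    rng = np.random.default_rng(4)
    n = 80
    vaf = rng.uniform(0, 0.5, (n, 4))
    det = rng.random((n, 4)) < 0.8
    s = _summary_from_matrix(det, vaf)
    pooled_vaf = vaf.mean(axis=1) + rng.normal(0, 0.03, n)
    pooled = make_callset_from_detection(
        np.ones(n, dtype=bool), "pooled", np.clip(pooled_vaf, 0, 1)
    )
    pooled_detection_stats(s, pooled)
    r = vaf_correlation(s)["pooled"]
    keep = s.per_variant["label"] != "absent"
    x = s.per_variant.loc[keep, "mean_regional_vaf"].to_numpy()
    y = s.per_variant.loc[keep, "pooled_vaf"].to_numpy()
    xc, yc = x - x.mean(), y - y.mean()
    oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert r == pytest.approx(oracle, abs=1e-12)


def test_vaf_quartiles_match_sorting_oracle():
    rng = np.random.default_rng(5)
    n = 60
    vaf = rng.uniform(0, 0.9, (n, 4))
    det = rng.random((n, 4)) < 0.6
    s = _summary_from_matrix(det, vaf)
    table = vaf_distribution_by_class(s)
    for c in ("common", "shared", "private"):
        vals = np.sort(
            s.per_variant.loc[s.per_variant["label"] == c, "max_regional_vaf"].to_numpy()
        )
        if len(vals) == 0:
            assert np.isnan(table.loc[c, "median"])
            continue
        assert table.loc[c, "median"] == pytest.approx(np.percentile(vals, 50))
        assert table.loc[c, "q1"] == pytest.approx(np.percentile(vals, 25))
        assert table.loc[c, "q3"] == pytest.approx(np.percentile(vals, 75))


def test_vaf_ordering_common_above_subclonal(small_truth, small_regions):
    from tumorpool import apply_filters, detect

    flags = small_truth.flags_frame()
    callsets = [apply_filters(detect(r), flags) for r in small_regions]
    s = classify(callsets)
    table = vaf_distribution_by_class(s)
    assert table.loc["common", "median"] > table.loc["shared", "median"]
    assert table.loc["common", "median"] > table.loc["private", "median"]
    # truncal VAFs centered near 40%
    assert abs(table.loc["common", "median"] - 0.40) < 0.08


def test_pca_identical_samples_coincide():
    rng = np.random.default_rng(6)
    vaf = rng.uniform(0, 0.5, (30, 1))
    det = np.ones((30, 1), dtype=bool)
    a = make_callset_from_detection(det[:, 0], "a", vaf[:, 0])
    b = make_callset_from_detection(det[:, 0], "b", vaf[:, 0])
    c = make_callset_from_detection(det[:, 0], "c", rng.uniform(0, 0.5, 30))
    coords = pca_variant_profiles([a, b, c])
    np.testing.assert_allclose(coords.loc["a"], coords.loc["b"], atol=1e-12)


def test_pca_distances_match_svd_oracle():
    rng = np.random.default_rng(7)
    n, m = 40, 6
    vaf = rng.uniform(0, 0.6, (n, m))
    callsets = [
        make_callset_from_detection(np.ones(n, dtype=bool), f"s{j}", vaf[:, j])
        for j in range(m)
    ]
    coords = pca_variant_profiles(callsets).to_numpy()
    X = vaf.T - vaf.T.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    oracle = U[:, :2] * S[:2]
    d = lambda M: np.linalg.norm(M[:, None, :] - M[None, :, :], axis=-1)
    np.testing.assert_allclose(d(coords), d(oracle), atol=1e-8)


def test_pca_groups_samples_by_tumor():
    # two tumors simulated independently over a joint variant universe:
    # within-tumor distances must be smaller than between-tumor ones
    from tumorpool import CallSet, apply_filters, detect

    per_tumor = {}
    for seed in (21, 22):
        cfg = SimulationConfig(n_truncal=40, n_shared=10, n_private=10,
                               n_germline_het=0, n_germline_hom=0,
                               n_genes=10, seed=seed)
        truth = make_truth(cfg)
        flags = truth.flags_frame()
        css = []
        for r in range(4):
            rs = simulate_region_counts(truth, r)
            cs = apply_filters(detect(rs), flags)
            df = cs.df.copy()
            df["variant_id"] = [f"t{seed}_{v}" for v in df["variant_id"]]
            css.append(CallSet(f"t{seed}_r{r}", df))
        per_tumor[seed] = css

    def pad(cs: CallSet, other_ids):
        absent = pd.DataFrame(
            {
                "variant_id": other_ids,
                "depth": 100,
                "alt_count": 0,
                "vaf": 0.0,
                "detected": False,
                "filter_status": "NOT_DETECTED",
            }
        )
        df = pd.concat([cs.df, absent]).sort_values("variant_id").reset_index(drop=True)
        return CallSet(cs.sample_id, df)

    ids = {s: list(per_tumor[s][0].df["variant_id"]) for s in per_tumor}
    callsets = [pad(cs, ids[22]) for cs in per_tumor[21]] + [
        pad(cs, ids[21]) for cs in per_tumor[22]
    ]
    coords = pca_variant_profiles(callsets)
    X = coords.to_numpy()
    within, between = [], []
    for i in range(8):
        for j in range(i + 1, 8):
            dist = np.linalg.norm(X[i] - X[j])
            (within if (i < 4) == (j < 4) else between).append(dist)
    assert max(within) < min(between)
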