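import itertools
import math

import numpy as np
import pandas as pd
import pytest

from editome import differential as dif


# ---------------------------------------------------------------------------
# Mann–Whitney


def _enumeration_oracle(x, y):
    """Two-sided permutation p via pairwise-count U (independent of the
    rank-sum implementation path)."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum(
            (1.0 if a > b else 0.5 if a == b else 0.0) for a in xs for b in ys
        )

    u_obs = u_of(tuple(range(nx)))
    us = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), nx)]
    le = sum(u <= u_obs + 1e-12 for u in us)
    ge = sum(u >= u_obs - 1e-12 for u in us)
    return u_obs, min(1.0, 2 * min(le, ge) / len(us))


def test_mann_whitney_separated_triples():
    res = dif.mann_whitney_u([0.8, 0.9, 0.7], [0.1, 0.2, 0.3])
    assert res.u == 9 and res.p == pytest.approx(0.1)  # 2/20 assignments
    assert res.method == "exact"


def test_mann_whitney_complete_ties_give_p_one():
    res = dif.mann_whitney_u([0.5, 0.5], [0.5, 0.5])
    assert res.p == pytest.approx(1.0)


def test_mann_whitney_exact_equals_enumeration_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(25):
        nx, ny = rng.integers(2, 7), rng.integers(2, 7)
        # discrete values force ties
        x = rng.integers(0, 5, nx) / 4
        y = rng.integers(0, 5, ny) / 4
        res = dif.mann_whitney_u(list(x), list(y))
        u_ref, p_ref = _enumeration_oracle(list(x), list(y))
        assert res.u == pytest.approx(u_ref)
        assert res.p == pytest.approx(p_ref)


def test_mann_whitney_asymptotic_close_to_exact_without_ties():
    # the corrected normal approximation at n=8 vs 8 tracks the exact
    # permutation p closely; its worst error (~0.011) sits near p ≈ 0.5,
    # far from any decision boundary
    rng = np.random.default_rng(1)
    for _ in range(50):
        x = list(rng.normal(0, 1, 8))
        y = list(rng.normal(0.3, 1, 8))
        exact = dif.mann_whitney_u(x, y, exact_max_n=16)
        approx = dif.mann_whitney_u(x, y, exact_max_n=0)
        assert approx.method == "asymptotic"
        assert abs(exact.p - approx.p) <= 0.015
        if exact.p < 0.3:
            assert abs(exact.p - approx.p) <= 0.01


def test_mann_whitney_rejects_empty_group():
    with pytest.raises(ValueError):
        dif.mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# BH


def _bh_oracle(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        j = m - rank_from_top  # rank of p[i] among sorted, 1-based
        prev = min(prev, p[i] * m / j)
        q[i] = prev
    return q


def test_bh_hand_examples():
    assert dif.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert dif.bh_fdr([0.5]) == pytest.approx([0.5])
    assert dif.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)


def test_bh_matches_step_up_oracle_on_random_vectors():
    rng = np.random.default_rng(2)
    for _ in range(30):
        p = rng.random(int(rng.integers(1, 200)))
        assert dif.bh_fdr(p) == pytest.approx(_bh_oracle(p), abs=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        dif.bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# group summaries and the three-criterion call


def _mk_calls(site_specs, depth=30):
    """site_specs: {pos: (control ratios, tumor ratios)} -> calls frame."""
    rows = []
    manifest = {}
    for pos, (ctrl, tum) in site_specs.items():
        for grp, ratios in (("control", ctrl), ("tumor", tum)):
            for i, r in enumerate(ratios):
                s = f"{grp}_{i+1:02d}"
                manifest[s] = grp
                d = 0 if r is None else depth
                rows.append(
                    {
                        "sample": s, "chrom": "chr1", "pos": pos,
                        "ref": "A", "alt": "G",
                        "total_depth": d,
                        "alt_depth": 0 if r is None else round(r * d),
                        "editing_ratio": math.nan if r is None else r,
                    }
                )
    return pd.DataFrame(rows), manifest


def test_group_summary_means_and_percentages():
    df, manifest = _mk_calls({1: ([0.8, 0.8, 0.8, 0.8, 0.8], [0.1, 0.1, 0.3, 0.1, 0.1])})
    summaries = dif.summarize_site_by_group(df, manifest)
    ctrl, tum = summaries["control"], summaries["tumor"]
    assert ctrl.mean_ratio == pytest.approx(0.8)
    assert ctrl.pct_edited == pytest.approx(100.0)
    assert tum.n_covered == 5 and tum.n_edited == 1
    assert tum.pct_edited == pytest.approx(20.0)


def test_summary_rejects_sample_missing_from_manifest():
    df, manifest = _mk_calls({1: ([0.5] * 3, [0.5] * 3)})
    del manifest["tumor_01"]
    with pytest.raises(KeyError):
        dif.summarize_site_by_group(df, manifest)


def test_low_coverage_site_is_untestable():
    df, manifest = _mk_calls(
        {1: ([0.9] * 4, [0.1] * 8)}  # only 4 covered control samples
    )
    out = dif.call_differential(df, manifest, "tumor", "control")
    assert not out.loc[0, "testable"]
    assert not out.loc[0, "significant"]


def test_three_criteria_must_all_hold():
    # strong site: huge separation; weak-mean site: big pct change, small Δmean
    df, manifest = _mk_calls(
        {
            1: ([0.9] * 8, [0.05] * 8),
            2: ([0.25] * 8, [0.15] * 8),  # |Δmean| = 0.1 < 0.2
        }
    )
    out = dif.call_differential(df, manifest, "tumor", "control").set_index("pos")
    assert out.loc[1, "significant"]
    assert out.loc[1, "direction"] == "down"
    assert not out.loc[2, "significant"]  # fails the Δmean criterion
    assert out.loc[2, "q"] < 0.05  # even though the test itself is significant


def test_significance_invariant_and_threshold_monotonicity():
    rng = np.random.default_rng(3)
    specs = {}
    for pos in range(1, 40):
        shift = rng.random() < 0.5
        specs[pos] = (
            list(rng.beta(8, 2, 10)),
            list(rng.beta(2, 6, 10) if shift else rng.beta(8, 2, 10)),
        )
    df, manifest = _mk_calls(specs)
    out = dif.call_differential(df, manifest, "tumor", "control")
    sig = out[out["significant"]]
    assert (sig["q"] < 0.05).all()
    assert (sig["delta_mean"].abs() > 0.2).all()
    assert (sig["delta_pct"].abs() > 10).all()
    for kwargs in (
        {"fdr_alpha": 0.01},
        {"delta_mean_min": 0.4},
        {"delta_pct_min": 40.0},
        {"min_covered": 11},
    ):
        tighter = dif.call_differential(df, manifest, "tumor", "control", **kwargs)
        assert set(tighter[tighter["significant"]]["pos"]) <= set(sig["pos"])


def test_direction_bookkeeping_swaps_with_group_roles():
    rng = np.random.default_rng(4)
    specs = {
        pos: (list(rng.beta(8, 2, 10)), list(rng.beta(2, 6, 10))) for pos in range(1, 15)
    }
    df, manifest = _mk_calls(specs)
    fwd = dif.call_differential(df, manifest, "tumor", "control")
    rev = dif.call_differential(df, manifest, "control", "tumor")
    f_sig = fwd[fwd["significant"]]
    r_sig = rev[rev["significant"]]
    assert (f_sig["direction"] == "down").sum() == (r_sig["direction"] == "up").sum()
    assert len(f_sig) == len(r_sig)
    assert np.allclose(
        fwd.sort_values("pos")["delta_mean"].to_numpy(),
        -rev.sort_values("pos")["delta_mean"].to_numpy(),
        equal_nan=True,
    )


# ---------------------------------------------------------------------------
# concordance


def _diff_frame(keys):
    return pd.DataFrame(
        [
            {"chrom": "chr1", "pos": p, "ref": "A", "alt": "G",
             "direction": d, "significant": True}
            for p, d in keys
        ]
    )


def test_concordance_set_arithmetic():
    a = _diff_frame([(1, "down"), (2, "down"), (3, "up")])
    b = _diff_frame([(2, "down"), (3, "up"), (4, "down")])
    out = dif.compare_cohorts(a, b)
    assert out["n_overlap"] == 2
    assert out["pct_b_in_a"] == pytest.approx(100 * 2 / 3)
    assert out["pct_a_in_b"] == pytest.approx(100 * 2 / 3)
    assert out["by_direction"]["down"]["n_overlap"] == 1


def test_concordance_disjoint_and_identical():
    a = _diff_frame([(1, "down"), (2, "up")])
    assert dif.compare_cohorts(a, _diff_frame([(9, "down")]))["pct_b_in_a"] == 0.0
    both = dif.compare_cohorts(a, a)
    assert both["pct_b_in_a"] == both["pct_a_in_b"] == 100.0


def test_concordance_direction_mismatch_does_not_count():
    a = _diff_frame([(1, "down")])
    b = _diff_frame([(1, "up")])
    assert dif.compare_cohorts(a, b)["n_overlap"] == 0


# ---------------------------------------------------------------------------
# editing–expression


def test_perfect_linearity_gives_r_one():
    x = np.linspace(0.1, 0.9, 10)
    r, p = dif.correlate_editing_expression(x, 2 * x)
    assert r == pytest.approx(1.0)
    assert p < 1e-6


def test_constant_vector_gives_na():
    r, p = dif.correlate_editing_expression([0.1, 0.5, 0.9], [2.0, 2.0, 2.0])
    assert math.isnan(r) and math.isnan(p)


def test_pearson_matches_covariance_formula_oracle():
    rng = np.random.default_rng(5)
    x, y = rng.random(20), rng.random(20)
    r, _ = dif.correlate_editing_expression(x, y)
    xc, yc = x - x.mean(), y - y.mean()
    r_ref = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
    assert r == pytest.approx(r_ref, abs=1e-12)


def test_na_ratios_are_dropped_pairwise():
    x = [0.1, math.nan, 0.5, 0.9]
    y = [1.0, 99.0, 5.0, 9.0]
    r, _ = dif.correlate_editing_expression(x, y)
    r_ref, _ = dif.correlate_editing_expression([0.1, 0.5, 0.9], [1.0, 5.0, 9.0])
    assert r == pytest.approx(r_ref)


def test_expression_group_comparison_fully_separated():
    res = dif.compare_expression_groups([5.0, 6, 7, 8, 9], [1.0, 2, 3, 4, 4.5])
    assert res.p == pytest.approx(2 / math.comb(10, 5))
    same = dif.compare_expression_groups([1.0, 2.0], [1.0, 2.0])
    assert same.p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        dif.compare_expression_groups([], [1.0])


def test_editing_matrix_shape():
    df, _manifest = _mk_calls({1: ([0.8, 0.7], [0.2, 0.1]), 2: ([0.5, 0.5], [0.5, 0.5])})
    mat = dif.editing_matrix(df)
    assert mat.shape == (2, 4)
    assert mat.loc["chr1:1:A>G", "control_01"] == pytest.approx(0.8)
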