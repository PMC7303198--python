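"""Within-subject ANOVA, Holm correction, paired t tests, hypothesis report.

The repeated-measures ANOVA is cross-checked against an independent
cell-means decomposition oracle (classic sums of squares with the
effect-by-subject interaction as the error term), against pingouin, and
against collapsed paired t tests.
"""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmnkit.stats import (
    EffectResult,
    StatsError,
    holm_adjust,
    hypothesis_report,
    posthoc_paired_t,
    rm_anova_2k,
    rm_anova_2x2_latency,
)


# ---------------------------------------------------------------------------
# Brute-force oracle: classic RM-ANOVA sums of squares via marginal means
# ---------------------------------------------------------------------------

def _ss_term(y, dims):
    """n_total * mean^2 summed over the marginal table collapsed onto `dims`
    (subject axis 0, factor axes 1..k of a (n, 2, 2, ...) array)."""
    axes = tuple(i for i in range(y.ndim) if i not in dims)
    marg = y.mean(axis=axes)
    cell_n = np.prod([y.shape[i] for i in axes])
    return cell_n * np.sum(marg**2)


def anova_oracle(y):
    """F statistics for all within-subject effects of a (n_subj, 2, ..., 2)
    data array, each tested against its effect-by-subject interaction."""
    k = y.ndim - 1
    factor_axes = list(range(1, k + 1))

    def ss_effect(dims):
        # Moebius inclusion-exclusion over sub-margins
        total = 0.0
        dims = tuple(dims)
        for r in range(len(dims) + 1):
            for sub in combinations(dims, r):
                total += (-1) ** (len(dims) - len(sub)) * _ss_term(y, set(sub))
        return total

    out = {}
    for order in range(1, k + 1):
        for combo in combinations(factor_axes, order):
            ss_a = ss_effect(combo)
            ss_ax_s = ss_effect((0,) + combo)
            df_a = 1.0
            df_err = y.shape[0] - 1
            out[combo] = (ss_a / df_a) / (ss_ax_s / df_err)
    return out


def _table_from_array(y, factors):
    n = y.shape[0]
    rows = []
    for s in range(n):
        for idx in product(range(2), repeat=len(factors)):
            rows.append(
                {"subject": f"s{s:02d}", "value": y[(s, *idx)],
                 **{f: f"{f}_{'AB'[i]}" for f, i in zip(factors, idx)}}
            )
    return pd.DataFrame(rows)


@pytest.mark.parametrize("n_subj,k,seed", [(3, 2, 0), (8, 3, 1), (24, 4, 2), (5, 4, 3)])
def test_anova_matches_cell_means_oracle(n_subj, k, seed):
    rng = np.random.default_rng(seed)
    factors = ["f1", "f2", "f3", "f4"][:k]
    y = rng.normal(0, 1, size=(n_subj,) + (2,) * k)
    res = {e.name: e for e in rm_anova_2k(_table_from_array(y, factors), factors=factors)}
    oracle = anova_oracle(y)
    for combo, f_oracle in oracle.items():
        name = " x ".join(factors[i - 1] for i in combo)
        assert res[name].statistic == pytest.approx(f_oracle, abs=1e-9, rel=1e-9)


def test_main_effect_equals_squared_collapsed_paired_t():
    rng = np.random.default_rng(4)
    y = rng.normal(0, 1, size=(12, 2, 2))
    res = {e.name: e for e in rm_anova_2k(_table_from_array(y, ["f1", "f2"]), factors=["f1", "f2"])}
    a = y[:, 0, :].mean(axis=1)
    b = y[:, 1, :].mean(axis=1)
    t = posthoc_paired_t(a, b)
    assert res["f1"].statistic == pytest.approx(t.statistic**2, rel=1e-12)
    assert res["f1"].p_raw == pytest.approx(t.p_raw, rel=1e-9)


def test_two_factor_case_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    y = rng.normal(0, 1, size=(10, 2, 2))
    tab = _table_from_array(y, ["f1", "f2"])
    ours = {e.name: e for e in rm_anova_2x2_latency(tab, dv="value", factors=("f1", "f2"))}
    ref = pg.rm_anova(data=tab, dv="value", within=["f1", "f2"], subject="subject", detailed=True)
    for name, key in [("f1", "f1"), ("f2", "f2"), ("f1 x f2", "f1 * f2")]:
        row = ref[ref["Source"] == key].iloc[0]
        assert ours[name].statistic == pytest.approx(row["F"], rel=1e-6)
        assert ours[name].p_raw == pytest.approx(row["p_unc"], rel=1e-6)


def test_column_order_irrelevant():
    rng = np.random.default_rng(6)
    y = rng.normal(0, 1, size=(6, 2, 2))
    tab = _table_from_array(y, ["f1", "f2"])
    shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = rm_anova_2k(tab, factors=["f1", "f2"])
    b = rm_anova_2k(shuffled, factors=["f1", "f2"])
    for ea, eb in zip(a, b):
        assert ea.statistic == pytest.approx(eb.statistic, rel=1e-12)


def test_degenerate_constant_difference():
    """deviant = standard - 1 exactly: Cond F is infinite-like (p=0,
    flagged); orthogonal effects are 0/0 reported as 0 with flag."""
    rows = []
    for s in range(6):
        for pp in ("HPP", "LPP"):
            for cond in ("Deviant", "Standard"):
                rows.append({"subject": s, "pp": pp, "cond": cond,
                             "value": (5.0 if cond == "Standard" else 4.0)})
    res = {e.name: e for e in rm_anova_2k(pd.DataFrame(rows), factors=["pp", "cond"])}
    assert res["cond"].degenerate and res["cond"].p_raw == 0.0
    assert np.isinf(res["cond"].statistic)
    assert res["pp"].degenerate and res["pp"].statistic == 0.0


def test_missing_cells_and_small_n_raise():
    rows = [{"subject": 0, "f": "a", "value": 1.0}, {"subject": 0, "f": "b", "value": 2.0}]
    with pytest.raises(StatsError, match="2 subjects"):
        rm_anova_2k(pd.DataFrame(rows), factors=["f"])
    rows = [
        {"subject": s, "f": lv, "value": 1.0}
        for s in range(3) for lv in ("a", "b")
    ][:-1]  # drop one cell
    with pytest.raises(StatsError, match="missing"):
        rm_anova_2k(pd.DataFrame(rows), factors=["f"])


class TestHolm:
    def test_hand_checked_triple(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04], atol=1e-12
        )

    def test_single_p_unchanged_and_all_ones(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, size=9)
        ours = holm_adjust(p)
        ref = sm.multipletests(p, method="holm")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            holm_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_properties(self, pvals):
        adj = holm_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in p

    def test_larger_family_size(self):
        np.testing.assert_allclose(holm_adjust([0.01], m=5)[0], 0.05)


class TestPairedT:
    def test_identical_vectors_give_t0_p1(self):
        r = posthoc_paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_matches_scipy_on_small_sample(self):
        from scipy import stats as sps

        x = np.array([2.1, 3.4, 1.8, 2.9])
        y = np.array([1.9, 3.9, 1.2, 2.2])
        r = posthoc_paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert r.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert r.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_bonferroni_doubles_and_caps(self):
        x = np.array([2.1, 3.4, 1.8, 2.9]); y = np.array([1.9, 3.9, 1.2, 2.2])
        r1 = posthoc_paired_t(x, y, n_comparisons=2)
        assert r1.p_holm == pytest.approx(min(1.0, 2 * r1.p_raw))
        r2 = posthoc_paired_t([1, 2, 3.0], [1.1, 1.9, 3.05], n_comparisons=10)
        assert r2.p_holm == 1.0

    def test_n1_rejected(self):
        with pytest.raises(StatsError):
            posthoc_paired_t([1.0], [2.0])


def _fake_effects(p_cond, p_int=0.5, p_three=0.5, p_lat_main=0.5, p_lat_int=0.5):
    amp = [
        EffectResult("cond", 10.0, "F", (1, 23), p_cond),
        EffectResult("phonprob x cond", 1.0, "F", (1, 23), p_int),
        EffectResult("sylstr x cond", 1.0, "F", (1, 23), p_int),
        EffectResult("phonprob x sylstr x cond", 1.0, "F", (1, 23), p_three),
    ]
    lat = [
        EffectResult("phonprob", 1.0, "F", (1, 23), p_lat_main),
        EffectResult("sylstr", 1.0, "F", (1, 23), p_lat_main),
        EffectResult("phonprob x sylstr", 1.0, "F", (1, 23), p_lat_int),
    ]
    return {"FD": amp, "TD": amp}, {"FD": lat, "TD": lat}


class TestHypothesisReport:
    def test_pure_cond_effect_supports_only_h1(self):
        amp, lat = _fake_effects(p_cond=1e-6)
        rep = hypothesis_report(amp, lat)
        fd = rep[rep["deviant_type"] == "FD"].set_index("effect")
        assert fd.loc["cond", "significant"]
        assert not fd.loc["phonprob x cond", "significant"]
        assert not fd.loc["phonprob x sylstr x cond", "significant"]
        assert (fd["m"] == 5).all()

    def test_holm_within_family(self):
        amp, lat = _fake_effects(p_cond=0.01, p_int=0.5, p_three=0.5,
                                 p_lat_main=0.5, p_lat_int=0.5)
        rep = hypothesis_report(amp, lat)
        fd = rep[rep["deviant_type"] == "FD"].set_index("effect")
        assert fd.loc["cond", "p_holm"] == pytest.approx(0.05)

    def test_empty_inputs_give_empty_report(self):
        rep = hypothesis_report({}, {})
        assert len(rep) == 0

    def test_familywise_error_controlled_on_null(self):
        """Null simulation on cell means: the chance of any false positive
        in a Holm-corrected 5-test family stays near/below alpha."""
        rng = np.random.default_rng(8)
        n_reps, hits = 400, 0
        for _ in range(n_reps):
            p = rng.uniform(0, 1, size=5)  # null: p ~ U(0,1)
            hits += np.any(holm_adjust(p) < 0.05)
        assert hits / n_reps <= 0.07
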