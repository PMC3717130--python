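"""Subgroup contrasts, scenario re-statting, and biomarker selection."""

import numpy as np
import pandas as pd
import pytest

from mapel import (
    AxesWeightSolution,
    EnsembleMember,
    PrevalenceWeights,
    SyntheticSpec,
    TrialBin,
    TrialTarget,
    VPopEnsemble,
    analyte_selection_frequency,
    best_subset_regression,
    compute_axis_binning,
    compute_weights,
    contrast_groups,
    default_acr_bins,
    generate_cohort,
    population_stats,
    prune_correlated_mediators,
    restat_scenario,
    split_ensemble_by_response,
)
from mapel.errors import AlignmentError, MapelError, SubsetBudgetError

from conftest import make_cohort


def member(member_id, p, w_vp, vp_ids, axis_names=None):
    names = axis_names or [f"ax{j}" for j in range(len(p))]
    return EnsembleMember(
        member_id=member_id,
        solution=AxesWeightSolution(p=np.asarray(p, float), axis_names=names),
        weights=PrevalenceWeights(vp_ids=list(vp_ids), w=np.asarray(w_vp, float)),
        composite=0.5,
        seed=member_id,
    )


@pytest.fixture
def two_vp_cohort():
    # responses 0 and 100: a member with weight w on vp2 has mean 100 w
    return make_cohort({"ax0": [0.2, 0.8]}, {("rtx", 6.0): [0.0, 100.0]})


class TestSplitByResponse:
    def test_toy_partition(self, two_vp_cohort):
        ids = two_vp_cohort.vp_ids
        ens = VPopEnsemble(
            members=[
                member(0, [0.4], [0.6, 0.4], ids),  # mean 40 -> weak
                member(1, [0.46], [0.54, 0.46], ids),  # mean 46 -> excluded
                member(2, [0.5], [0.5, 0.5], ids),  # mean 50 -> strong
            ],
            threshold=0.05,
        )
        strong, weak = split_ensemble_by_response(
            ens, two_vp_cohort, "rtx", 6.0, hi_cut=48.0, lo_cut=44.75
        )
        assert [m.member_id for m in strong] == [2]
        assert [m.member_id for m in weak] == [0]

    def test_equal_cuts_partition_everything_but_ties(self, two_vp_cohort):
        ids = two_vp_cohort.vp_ids
        ens = VPopEnsemble(
            members=[member(i, [w], [1 - w, w], ids) for i, w in enumerate([0.3, 0.45, 0.45, 0.7])],
            threshold=0.05,
        )
        strong, weak = split_ensemble_by_response(
            ens, two_vp_cohort, "rtx", 6.0, hi_cut=45.0, lo_cut=45.0
        )
        assert len(strong) + len(weak) == 2  # the two members exactly at 45 drop out

    def test_empty_group_warns(self, two_vp_cohort):
        ids = two_vp_cohort.vp_ids
        ens = VPopEnsemble(members=[member(0, [0.3], [0.7, 0.3], ids)], threshold=0.05)
        with pytest.warns(UserWarning, match="strong"):
            split_ensemble_by_response(ens, two_vp_cohort, "rtx", 6.0)


def _quantile_type7(values, q):
    """Independent linear-interpolation quantile (R type 7)."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestContrastGroups:
    def test_identical_groups_have_zero_differences(self):
        ids = ["vp1", "vp2"]
        grp = [member(i, [0.2, 0.8], [0.5, 0.5], ids) for i in range(4)]
        contrast = contrast_groups(grp, grp)
        np.testing.assert_allclose(contrast.table["median_diff"], 0.0)

    def test_separated_axis_ranked_first(self):
        ids = ["vp1", "vp2"]
        rng = np.random.default_rng(0)
        strong = [member(i, [0.9, rng.uniform(0.4, 0.6)], [0.5, 0.5], ids) for i in range(5)]
        weak = [member(10 + i, [0.1, rng.uniform(0.4, 0.6)], [0.5, 0.5], ids) for i in range(5)]
        contrast = contrast_groups(strong, weak)
        assert contrast.ordered_axes[0] == "ax0"
        top = contrast.table.iloc[0]
        assert top["median_diff"] == pytest.approx(0.8)

    def test_median_iqr_match_independent_quantiles(self):
        ids = ["vp1", "vp2"]
        rng = np.random.default_rng(3)
        ps = rng.uniform(0, 1, size=(7, 2))
        strong = [member(i, ps[i], [0.5, 0.5], ids) for i in range(7)]
        weak = [member(20 + i, 1 - ps[i], [0.5, 0.5], ids) for i in range(7)]
        table = contrast_groups(strong, weak).table.set_index("axis")
        for j, axis in enumerate(["ax0", "ax1"]):
            assert table.loc[axis, "median_strong"] == pytest.approx(
                _quantile_type7(ps[:, j], 0.5), abs=1e-12
            )
            assert table.loc[axis, "iqr_lo_strong"] == pytest.approx(
                _quantile_type7(ps[:, j], 0.25), abs=1e-12
            )
            assert table.loc[axis, "iqr_hi_weak"] == pytest.approx(
                _quantile_type7(1 - ps[:, j], 0.75), abs=1e-12
            )

    def test_empty_group_rejected(self):
        with pytest.raises(MapelError):
            contrast_groups([], [member(0, [0.5], [1.0], ["vp1"])])


class TestRestatScenario:
    def test_baseline_scenario_is_identity(self):
        spec = SyntheticSpec(n_vps=40, n_axes=3, seed=2)
        cohort = generate_cohort(spec)
        binning = compute_axis_binning(cohort)
        sol = AxesWeightSolution.from_cohort(cohort, [0.3, 0.6, 0.8])
        w = compute_weights(cohort, binning, sol)
        target = TrialTarget("rituximab", 6.0, 100, bins=default_acr_bins([25, 25, 25, 25]))
        baseline = population_stats(
            cohort.response_vector("rituximab", 6.0), w, target, n_vps=cohort.n_vps
        )
        series = cohort.responses[("rituximab", 6.0)]
        restat = restat_scenario(w, series, target, n_vps=cohort.n_vps)
        assert restat.mean == baseline.mean
        assert restat.sd == baseline.sd
        np.testing.assert_array_equal(restat.fractions, baseline.fractions)

    def test_alignment_is_by_vp_id_not_order(self):
        w = PrevalenceWeights(vp_ids=["vp1", "vp2"], w=np.array([0.7, 0.3]))
        series = pd.Series([20.0, 10.0], index=pd.Index(["vp2", "vp1"], name="vp_id"))
        target = TrialTarget(
            "rtx", 6.0, 100, bins=[TrialBin("all", -np.inf, np.inf, 15.0, 100)]
        )
        stats = restat_scenario(w, series, target, n_vps=2)
        assert stats.mean == pytest.approx(0.7 * 10 + 0.3 * 20)

    def test_vp_mismatch_raises(self):
        w = PrevalenceWeights(vp_ids=["vp1", "vp2"], w=np.array([0.5, 0.5]))
        series = pd.Series([1.0, 2.0], index=["vp1", "vp9"])
        target = TrialTarget(
            "rtx", 6.0, 100, bins=[TrialBin("all", -np.inf, np.inf, 1.0, 100)]
        )
        with pytest.raises(AlignmentError):
            restat_scenario(w, series, target)


def correlated_panel(n=24):
    """Panel with exact sample correlations rho(A,B)=0.9, rho(A,C)=0.1, rho(B,C)=0.5."""
    rng = np.random.default_rng(8)
    raw = rng.normal(size=(n, 3))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)  # orthonormal, zero-mean columns
    e1, e2, e3 = q.T
    a = e1
    b = 0.9 * e1 + np.sqrt(1 - 0.81) * e2
    c2 = (0.5 - 0.9 * 0.1) / np.sqrt(1 - 0.81)
    c = 0.1 * e1 + c2 * e2 + np.sqrt(1 - 0.01 - c2**2) * e3
    return pd.DataFrame({"A": a, "B": b, "C": c})


class TestPruneCorrelatedMediators:
    def test_duplicate_columns_collapse(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        panel = pd.DataFrame({"A": x, "B": x.copy(), "C": rng.normal(size=30)})
        retained = prune_correlated_mediators(panel, rho_cut=0.8)
        assert "C" in retained
        assert len([c for c in retained if c in ("A", "B")]) == 1

    def test_uncorrelated_panel_untouched(self):
        n = 40
        rng = np.random.default_rng(1)
        panel = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("WXYZ"))
        assert prune_correlated_mediators(panel, rho_cut=0.95) == list("WXYZ")

    def test_lowest_average_correlation_retained(self):
        panel = correlated_panel()
        corr = panel.corr()
        assert corr.loc["A", "B"] == pytest.approx(0.9, abs=1e-10)
        assert corr.loc["A", "C"] == pytest.approx(0.1, abs=1e-10)
        assert corr.loc["B", "C"] == pytest.approx(0.5, abs=1e-10)
        # component {A, B}; mean |rho| vs others: A -> 0.5, B -> 0.7; keep A
        assert prune_correlated_mediators(panel, rho_cut=0.8) == ["A", "C"]

    def test_invariance_to_sign_flip_and_row_permutation(self):
        panel = correlated_panel()
        base = prune_correlated_mediators(panel, rho_cut=0.8)
        flipped = panel.copy()
        flipped["B"] = -flipped["B"]
        assert prune_correlated_mediators(flipped, rho_cut=0.8) == base
        perm = np.random.default_rng(2).permutation(len(panel))
        assert prune_correlated_mediators(panel.iloc[perm], rho_cut=0.8) == base

    def test_constant_column_flagged_and_retained(self):
        rng = np.random.default_rng(3)
        panel = pd.DataFrame({"A": rng.normal(size=20), "K": np.ones(20)})
        with pytest.warns(UserWarning, match="K"):
            retained = prune_correlated_mediators(panel, rho_cut=0.8)
        assert "K" in retained


class TestBestSubsetRegression:
    def _panel(self, n=60, m=6, seed=4):
        rng = np.random.default_rng(seed)
        panel = pd.DataFrame(
            rng.normal(size=(n, m)), columns=[f"m{j}" for j in range(m)]
        )
        return panel, rng

    def test_exact_linear_truth_recovered(self):
        panel, _ = self._panel()
        y = 2.0 * panel["m0"] - 3.0 * panel["m1"]
        w = np.full(len(panel), 1 / len(panel))
        model = best_subset_regression(panel, y, w, k=2)
        assert sorted(model.analytes) == ["m0", "m1"]
        assert model.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_k1_uniform_matches_correlation_ranking(self):
        panel, rng = self._panel()
        y = 0.8 * panel["m2"] + rng.normal(0, 1, len(panel))
        w = np.full(len(panel), 1 / len(panel))
        model = best_subset_regression(panel, y, w, k=1)
        corrs = panel.corrwith(pd.Series(y.to_numpy(), index=panel.index)) ** 2
        assert model.analytes == [corrs.idxmax()]

    def test_budget_error(self):
        panel, _ = self._panel(m=6)
        y = panel["m0"]
        w = np.full(len(panel), 1 / len(panel))
        with pytest.raises(SubsetBudgetError):
            best_subset_regression(panel, y, w, k=3, budget=5)

    def test_raw_r2_monotone_in_k(self):
        panel, rng = self._panel()
        y = panel["m0"] - panel["m3"] + rng.normal(0, 0.5, len(panel))
        w = np.asarray(np.random.default_rng(9).dirichlet(np.ones(len(panel))))
        r2s = [
            best_subset_regression(panel, y, w, k=k).r2 for k in (1, 2, 3)
        ]
        assert r2s[0] <= r2s[1] + 1e-12 <= r2s[2] + 2e-12

    def test_weighted_selection_matches_statsmodels_enumeration(self):
        """Dual route: exhaustive WLS via statsmodels agrees on the best subset."""
        import itertools

        import statsmodels.api as sm

        panel, rng = self._panel(n=40, m=6, seed=10)
        y = (1.5 * panel["m1"] - 2.0 * panel["m4"] + rng.normal(0, 1.0, 40)).to_numpy()
        w = np.random.default_rng(11).dirichlet(np.ones(40))
        model = best_subset_regression(panel, y, w, k=2)

        best_r2, best_subset = -np.inf, None
        for subset in itertools.combinations(panel.columns, 2):
            X = sm.add_constant(panel[list(subset)].to_numpy())
            fit = sm.WLS(y, X, weights=w).fit()
            resid = y - fit.predict(X)
            ybar = w @ y
            r2 = 1 - (w @ resid**2) / (w @ (y - ybar) ** 2)
            if r2 > best_r2:
                best_r2, best_subset = r2, subset
        assert tuple(model.analytes) == best_subset
        assert model.r2 == pytest.approx(best_r2, abs=1e-10)


class TestSelectionFrequency:
    def _model(self, analytes, vpop_id=0):
        from mapel import BiomarkerModel

        return BiomarkerModel(
            analytes=list(analytes), coefficients=np.zeros(len(analytes)),
            intercept=0.0, r2=0.9, adj_r2=0.9, bic=0.0, k=len(analytes),
            vpop_id=vpop_id,
        )

    def test_unanimity(self):
        models = [self._model(["a", "b", "c"], i) for i in range(4)]
        freq = analyte_selection_frequency(models).set_index("analyte")
        assert (freq["fraction"] == 1.0).all()

    def test_partial_overlap(self):
        m1 = self._model(["a", "b", "c", "d", "e"], 0)
        m2 = self._model(["a", "b", "c", "x", "y"], 1)
        freq = analyte_selection_frequency([m1, m2]).set_index("analyte")
        assert freq.loc["a", "fraction"] == 1.0
        assert freq.loc["x", "fraction"] == 0.5
        assert int(freq["count"].sum()) == 5 * 2
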