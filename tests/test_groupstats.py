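import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from roiconn.connectivity import METRIC_NAMES
from roiconn.groupstats import (
    ancova,
    apply_exclusions,
    fdr_bh,
    lsd_posthoc,
    run_group_analysis,
    sensitivity,
    severity_correlations,
)

from conftest import make_cohort_frame


def anova_oracle(groups):
    """Brute-force one-way ANOVA F from group means and sums of squares."""
    grand = np.mean(np.concatenate(groups))
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return (ssb / df1) / (ssw / df2), df1, df2


def bh_oracle(p):
    """Literal min-formula BH: adj_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j for j in range(rank, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestAncova:
    def test_default_cohort_degrees_of_freedom(self, cohort_frame):
        res = ancova(cohort_frame, "within_CON")
        n = len(cohort_frame)
        assert (res.df1, res.df2) == (2, n - 3 - 2)

    def test_eta2p_identity(self, cohort_frame):
        for metric in METRIC_NAMES:
            r = ancova(cohort_frame, metric)
            ident = r.F * r.df1 / (r.F * r.df1 + r.df2)
            assert r.eta2p == pytest.approx(ident, abs=1e-10)

    def test_covariate_free_equals_plain_anova(self):
        rng = np.random.default_rng(20)
        cohort = make_cohort_frame(rng, n_per_group=(4, 4, 4), covariate_free=True)
        res = ancova(cohort, "within_DMN", covariates=())
        groups = [cohort.loc[cohort["group"] == g, "within_DMN"].to_numpy()
                  for g in ("OCD", "AC", "HC")]
        F, df1, df2 = anova_oracle(groups)
        assert (res.df1, res.df2) == (df1, df2)
        assert res.F == pytest.approx(F, abs=1e-8)
        # adjusted means reduce to raw group means without covariates
        for g, vals in zip(("OCD", "AC", "HC"), groups):
            assert res.emmeans[g][0] == pytest.approx(np.mean(vals), abs=1e-10)

    def test_omnibus_f_invariant_to_group_relabelling(self, cohort_frame):
        base = ancova(cohort_frame, "within_CON")
        relabelled = cohort_frame.copy()
        relabelled["group"] = relabelled["group"].map(
            {"OCD": "HC", "HC": "AC", "AC": "OCD"})
        swapped = ancova(relabelled, "within_CON")
        assert swapped.F == pytest.approx(base.F, abs=1e-8)
        assert swapped.p == pytest.approx(base.p, abs=1e-10)

    def test_matches_pingouin(self, cohort_frame):
        pingouin = pytest.importorskip("pingouin")
        res = ancova(cohort_frame, "between_OST_CON")
        pg = pingouin.ancova(data=cohort_frame, dv="between_OST_CON",
                             between="group", covar=["age", "mean_fd"])
        row = pg[pg["Source"] == "group"].iloc[0]
        assert res.F == pytest.approx(float(row["F"]), rel=1e-6)
        assert res.p == pytest.approx(float(row["p_unc"]), rel=1e-6)
        assert res.eta2p == pytest.approx(float(row["np2"]), rel=1e-4)

    def test_constant_covariate_rejected(self, cohort_frame):
        bad = cohort_frame.copy()
        bad["mean_fd"] = 0.31
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova(bad, "within_CON")

    def test_tiny_cohort_without_error_df_rejected(self):
        rng = np.random.default_rng(21)
        cohort = make_cohort_frame(rng, n_per_group=(2, 2, 2))
        cohort["extra"] = rng.normal(size=len(cohort))
        with pytest.raises(ValueError, match="error df"):
            ancova(cohort, "within_CON", covariates=("age", "mean_fd", "extra"))


class TestLsdPosthoc:
    def test_duplicated_group_has_zero_difference(self):
        rng = np.random.default_rng(22)
        base = make_cohort_frame(rng, n_per_group=(6, 6, 6), covariate_free=True)
        # make AC an exact copy of OCD's data
        vals = base.loc[base["group"] == "OCD", list(METRIC_NAMES)].to_numpy()
        base.loc[base["group"] == "AC", list(METRIC_NAMES)] = vals
        res = ancova(base, "within_OST", covariates=())
        pair = [p for p in lsd_posthoc(res) if set(p.pair) == {"OCD", "AC"}][0]
        assert pair.diff == pytest.approx(0.0, abs=1e-12)
        assert pair.p == pytest.approx(1.0, abs=1e-9)

    def test_matches_pooled_mse_contrast_oracle(self):
        """LSD t equals the classical two-sample contrast with the 3-group MSE."""
        rng = np.random.default_rng(23)
        cohort = make_cohort_frame(rng, n_per_group=(4, 4, 4), covariate_free=True)
        res = ancova(cohort, "within_CON", covariates=())
        groups = {g: cohort.loc[cohort["group"] == g, "within_CON"].to_numpy()
                  for g in ("OCD", "AC", "HC")}
        mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (12 - 3)
        for ph in lsd_posthoc(res):
            a, b = ph.pair
            diff = groups[a].mean() - groups[b].mean()
            t = diff / np.sqrt(mse * (1 / len(groups[a]) + 1 / len(groups[b])))
            assert ph.diff == pytest.approx(diff, abs=1e-10)
            assert ph.t == pytest.approx(t, abs=1e-8)
            assert ph.df == 9
            assert ph.p == pytest.approx(2 * st.t.sf(abs(t), 9), abs=1e-10)

    def test_gate_reports_omnibus_significance(self, cohort_frame):
        res = ancova(cohort_frame, "within_CON")
        phs = lsd_posthoc(res)
        assert len(phs) == 3
        assert all(ph.omnibus_significant == (res.p < 0.05) for ph in phs)


class TestFdrBh:
    def test_smallest_two_of_study_family_adjust_together(self):
        raw = [0.010, 0.015, 0.30, 0.40, 0.50, 0.60]
        adj = fdr_bh(raw)
        assert adj[0] == pytest.approx(0.045, abs=1e-12)
        assert adj[1] == pytest.approx(0.045, abs=1e-12)
        assert np.all(adj[2:] > 0.214)

    def test_ties_adjust_equally(self):
        adj = fdr_bh([0.2] * 6)
        assert np.allclose(adj, 0.2)

    def test_matches_min_formula_oracle_on_random_vectors(self):
        rng = np.random.default_rng(24)
        for _ in range(1000):
            p = rng.uniform(size=6)
            assert np.allclose(fdr_bh(p), bh_oracle(p), atol=1e-12)

    def test_never_below_raw_and_order_equivariant(self):
        rng = np.random.default_rng(25)
        p = rng.uniform(size=6)
        adj = fdr_bh(p)
        assert np.all(adj >= p)
        perm = rng.permutation(6)
        assert np.allclose(fdr_bh(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            fdr_bh([0.1, 1.2])


class TestSeverityCorrelations:
    def test_perfect_linear_relation(self, cohort_frame):
        cohort = cohort_frame.copy()
        cohort["cybocs"] = np.nan
        ocd = cohort["group"] == "OCD"
        cohort.loc[ocd, "cybocs"] = (cohort.loc[ocd, "within_CON"] - 3) / 2
        out = severity_correlations(cohort, "cybocs")
        row = out[out["metric"] == "within_CON"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["n"] == int(ocd.sum())

    def test_pairwise_deletion_reduces_n_by_one(self, cohort_frame):
        cohort = cohort_frame.copy()
        cohort["masc"] = np.linspace(20, 80, len(cohort))
        full = severity_correlations(cohort, "masc")
        cohort.loc[cohort.index[4], "masc"] = np.nan
        dropped = severity_correlations(cohort, "masc")
        assert np.all(dropped["n"] == full["n"] - 1)

    def test_null_correlation_stays_moderate(self):
        """Metric independent of the scale at n = 23: |r| < 0.55 in >= 99%
        of seeded replicates (true null rate is ~0.9934)."""
        hits = 0
        reps = 2000
        rng = np.random.default_rng(28)
        base = pd.DataFrame({
            "subject_id": [f"OCD{i}" for i in range(23)], "group": "OCD"})
        for _ in range(reps):
            cohort = base.copy()
            cohort["cybocs"] = rng.normal(23.03, 6.41, size=23)
            cohort["within_CON"] = rng.normal(0.54, 0.1, size=23)
            out = severity_correlations(cohort, "cybocs",
                                        metrics=["within_CON"])
            hits += abs(out["r"].iloc[0]) < 0.55
        assert hits / reps >= 0.99

    def test_missing_scale_column_rejected(self, cohort_frame):
        with pytest.raises(ValueError, match="no column"):
            severity_correlations(cohort_frame, "cybocs")


class TestSensitivity:
    def test_empty_age_filter_reproduces_primary_analysis(self, cohort_frame):
        cohort = cohort_frame.copy()
        cohort["age"] = np.clip(cohort["age"], 8, 18)
        primary, _ = run_group_analysis(cohort)
        held, _ = sensitivity(cohort, "exclude_over_18")
        for a, b in zip(primary, held):
            assert b.F == pytest.approx(a.F, abs=1e-12)
            assert b.p_fdr == pytest.approx(a.p_fdr, abs=1e-12)

    def test_all_zero_depress_flag_is_degenerate(self, cohort_frame):
        cohort = cohort_frame.copy()
        cohort["depress_flag"] = 0
        with pytest.raises(ValueError, match="rank-deficient"):
            sensitivity(cohort, "add_depress_covariate")

    def test_depress_covariate_costs_one_error_df(self, cohort_frame):
        cohort = cohort_frame.copy()
        rng = np.random.default_rng(26)
        cohort["depress_flag"] = rng.integers(0, 2, size=len(cohort))
        primary, _ = run_group_analysis(cohort)
        refit, _ = sensitivity(cohort, "add_depress_covariate")
        assert refit[0].df2 == primary[0].df2 - 1

    def test_age_exclusion_recomputes_df_from_reduced_n(self):
        rng = np.random.default_rng(27)
        cohort = make_cohort_frame(rng, n_per_group=(23, 26, 44))
        cohort["age"] = rng.uniform(8, 18, size=93)
        cohort.loc[cohort.index[:5], "age"] = 20.0  # exactly 5 over-18 subjects
        results, _ = sensitivity(cohort, "exclude_over_18")
        assert all(r.df2 == 93 - 5 - 3 - 2 for r in results)

    def test_unknown_mode_rejected(self, cohort_frame):
        with pytest.raises(ValueError, match="unknown sensitivity mode"):
            sensitivity(cohort_frame, "bootstrap")


class TestFamilyAndBookkeeping:
    def test_family_adjustment_spans_exactly_six_tests(self, cohort_frame):
        results, posthocs = run_group_analysis(cohort_frame)
        assert [r.metric for r in results] == list(METRIC_NAMES)
        assert np.allclose(fdr_bh([r.p for r in results]),
                           [r.p_fdr for r in results])
        assert len(posthocs) == 18  # 3 pairs x 6 metrics

    def test_retained_counts_after_exclusions(self):
        retained = apply_exclusions(
            {"OCD": 25, "AC": 27, "HC": 45}, {"OCD": 2, "AC": 1, "HC": 1})
        assert retained == {"OCD": 23, "AC": 26, "HC": 44}
        assert sum(retained.values()) == 93

    def test_impossible_exclusions_rejected(self):
        with pytest.raises(ValueError, match="more exclusions"):
            apply_exclusions({"OCD": 2}, {"OCD": 3})
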