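"""Cohort simulation and the paired comparison orchestration."""

import numpy as np
import pytest

from calmito.simulate import CohortSimParams, simulate_cohort
from calmito.stats import cohort_frame, compare_metric, paired_wilcoxon, run_cohort_comparison


def _null_cohort(seed=0, n_pairs=15):
    return cohort_frame(simulate_cohort(CohortSimParams(n_pairs=n_pairs, seed=seed)))


class TestSimulateCohort:
    def test_structure_one_pd_one_control_per_pair(self):
        df = _null_cohort()
        counts = df.groupby(["pair_id", "group"]).size().unstack()
        assert (counts == 1).all().all()
        assert len(df) == 30

    def test_determinism(self):
        assert _null_cohort(seed=4).equals(_null_cohort(seed=4))

    def test_shift_applied_to_pd_group_only(self):
        params = CohortSimParams(
            n_pairs=200, pd_shift={"pct_responders": -20.0}, seed=5
        )
        df = cohort_frame(simulate_cohort(params))
        diff = (
            df[df.group == "PD"]["pct_responders"].mean()
            - df[df.group == "control"]["pct_responders"].mean()
        )
        assert diff == pytest.approx(-20.0, abs=3.0)

    def test_metrics_respect_bounds(self):
        df = _null_cohort(seed=6)
        assert df["pct_responders"].between(0, 100).all()
        assert df["volume_ratio"].between(0, 1).all()

    def test_pd_only_covariates(self):
        df = _null_cohort()
        assert df.loc[df.group == "PD", "disease_duration_years"].notna().all()
        assert df.loc[df.group == "control", "disease_duration_years"].isna().all()


class TestRunCohortComparison:
    def test_identical_groups_flagged_not_significant(self):
        df = _null_cohort()
        # force PD values identical to the control partner's
        for metric in ("pct_responders", "volume_ratio"):
            vals = df.loc[df.group == "control", metric].to_numpy()
            df.loc[df.group == "PD", metric] = vals
        res = run_cohort_comparison(df)
        degenerate = res[(res.covariate == "") & res.metric.isin(
            ["pct_responders", "volume_ratio"])]
        assert (degenerate.test == "degenerate").all()
        assert not degenerate.significant.any()

    def test_results_table_covers_all_families(self):
        res = run_cohort_comparison(_null_cohort())
        group_rows = res[res.covariate == ""]
        assert set(group_rows.family) == {"calcium", "mito"}
        assert len(group_rows) == 6
        corr_rows = res[res.covariate != ""]
        # 6 metrics x 4 covariates
        assert len(corr_rows) == 24

    def test_bonferroni_family_sizes(self):
        res = run_cohort_comparison(_null_cohort())
        grp = res[res.covariate == ""]
        for _, r in grp.iterrows():
            m = 2 if r.family == "calcium" else 4
            assert r.corrected_p == pytest.approx(min(1.0, m * r.p_value))

    def test_unpaired_cohort_rejected(self):
        df = _null_cohort().iloc[:-1]  # drop one subject
        with pytest.raises(ValueError, match="one PD and one control"):
            run_cohort_comparison(df)

    def test_shifted_cohort_detected(self):
        params = CohortSimParams(
            n_pairs=15, pd_shift={"pct_responders": -20.0}, seed=77
        )
        res = compare_metric(
            cohort_frame(simulate_cohort(params)), "pct_responders",
            force_nonparametric=True,
        )
        assert res.p_value < 0.05

    def test_power_and_type_I_at_study_scale(self):
        """20-point responder shift, 15 pairs: detected at p < 0.05 in at
        least 80% of replicate cohorts; matched null cohorts stay at or
        below a 5% rejection rate after correction."""
        hits = 0
        null_hits = 0
        n_rep = 100
        for rep in range(n_rep):
            shifted = CohortSimParams(
                n_pairs=15, pd_shift={"pct_responders": -20.0}, seed=3000 + rep
            )
            df = cohort_frame(simulate_cohort(shifted))
            wide = df.pivot(index="pair_id", columns="group", values="pct_responders")
            res = paired_wilcoxon(wide["PD"].to_numpy(), wide["control"].to_numpy())
            hits += res.p_value < 0.05
            null = CohortSimParams(n_pairs=15, seed=9000 + rep)
            dfn = cohort_frame(simulate_cohort(null))
            widen = dfn.pivot(index="pair_id", columns="group", values="pct_responders")
            resn = paired_wilcoxon(widen["PD"].to_numpy(), widen["control"].to_numpy())
            # Bonferroni over the 2-metric calcium family
            null_hits += min(1.0, 2 * resn.p_value) < 0.05
        assert hits / n_rep >= 0.80
        assert null_hits / n_rep <= 0.05
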