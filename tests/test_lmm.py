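"""Mixed-effects inference: design construction, estimation, FDR, effect
sizes, interaction probing, and agreement with lmerTest."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conncohort import (
    ModelSpec, build_design, effect_size, fdr_correct, fit_lmm,
    group_contrast_vector, probe_interactions,
)
from conncohort.lmm import DesignInfo, LmmFit
from oracles import bh_stepup


def synth_phenotype(n_participants=60, seed=0, chronic_day=None):
    """Two scans per participant: post-acute + chronic."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_participants):
        pid = f"P{k:03d}"
        group = "TBI" if k < int(0.65 * n_participants) else "OI"
        sex = "M" if rng.random() < 0.6 else "F"
        age = float(rng.uniform(8, 16.99))
        site = f"S{1 + k % 5}"
        d1 = float(rng.uniform(2, 33))
        d2 = chronic_day if chronic_day is not None else \
            float(rng.choice([90.0, 180.0]) + rng.normal(0, 7))
        rows.append((pid, f"{pid}_postacute", group, site, sex, age, d1, "postacute"))
        label = "3month" if d2 < 135 else "6month"
        rows.append((pid, f"{pid}_{label}", group, site, sex, age, d2, label))
    return pd.DataFrame(rows, columns=[
        "participant_id", "scan_id", "group", "site", "sex", "age_at_injury",
        "days_post_injury", "visit"])


def global_metric_long(phenotype, values, metric="Cp"):
    return pd.DataFrame({
        "scan_id": phenotype["scan_id"], "level": "global", "region": "NA",
        "hemisphere": "NA", "metric": metric, "value": values,
    })


def design_matrix(frame):
    terms = [c for c in frame.columns
             if c not in ("scan_id", "participant_id", "visit", "value")]
    x = np.column_stack([np.ones(len(frame))]
                        + [frame[c].to_numpy(float) for c in terms])
    return x, ["Intercept"] + terms


class TestBuildDesign:
    def test_global_row_count_and_centring(self):
        ph = synth_phenotype(40, seed=1)
        ml = global_metric_long(ph, np.zeros(len(ph)))
        frame, info = build_design(ml, ph, ModelSpec(metric="Cp"))
        assert len(frame) == len(ph)
        assert frame["time"].mean() == pytest.approx(0.0, abs=1e-12)
        assert frame["age_c"].mean() == pytest.approx(0.0, abs=1e-12)
        assert set(info.visit_mean_days) <= {"postacute", "3month", "6month"}

    def test_nodal_rows_double_scans(self):
        ph = synth_phenotype(20, seed=2)
        rows = []
        for sid in ph["scan_id"]:
            for h in ("L", "R"):
                rows.append((sid, "nodal", "THA", h, "Ne", 0.3))
        ml = pd.DataFrame(rows, columns=["scan_id", "level", "region",
                                         "hemisphere", "metric", "value"])
        frame, _ = build_design(ml, ph, ModelSpec(metric="Ne", level="nodal",
                                                  region="THA"))
        assert len(frame) == 2 * len(ph)
        assert "hemi_r" in frame.columns

    def test_full_interaction_expansion(self):
        ph = synth_phenotype(20, seed=3)
        ml = global_metric_long(ph, np.zeros(len(ph)))
        frame, info = build_design(ml, ph, ModelSpec(metric="Cp"))
        # Group x (Time + Time^2) x (Age + Sex): 17 fixed terms
        assert len(info.columns) == 17
        np.testing.assert_allclose(
            frame["group_tbi:time2:sex_f"],
            frame["group_tbi"] * frame["time2"] * frame["sex_f"], atol=1e-12)

    def test_missing_phenotype_scans_error(self):
        ph = synth_phenotype(10, seed=4)
        ml = global_metric_long(ph, np.zeros(len(ph)))
        ml.loc[0, "scan_id"] = "GHOST"
        with pytest.raises(ValueError, match="missing"):
            build_design(ml, ph, ModelSpec(metric="Cp"))


class TestFitLmm:
    def test_noiseless_recovers_generating_coefficients(self):
        ph = synth_phenotype(50, seed=5)
        ml = global_metric_long(ph, np.zeros(len(ph)))
        spec = ModelSpec(metric="Cp")
        frame, info = build_design(ml, ph, spec)
        x, terms = design_matrix(frame)
        rng = np.random.default_rng(6)
        beta = rng.normal(0, 0.5, x.shape[1])
        frame = frame.assign(value=x @ beta)
        fit = fit_lmm(frame, spec, design_info=info)
        np.testing.assert_allclose(fit.estimates, beta, atol=1e-8)

    def test_random_intercept_variance_recovered(self):
        ph = synth_phenotype(200, seed=7)
        spec = ModelSpec(metric="Cp")
        ml = global_metric_long(ph, np.zeros(len(ph)))
        frame, info = build_design(ml, ph, spec)
        rng = np.random.default_rng(8)
        b = rng.normal(0, 0.5, ph["participant_id"].nunique())
        pid_codes = pd.factorize(frame["participant_id"])[0]
        y = 1.0 + b[pid_codes] + rng.normal(0, 0.3, len(frame))
        fit = fit_lmm(frame.assign(value=y), spec, design_info=info)
        assert np.sqrt(fit.sigma_b2) == pytest.approx(0.5, rel=0.25)
        assert np.sqrt(fit.sigma_e2) == pytest.approx(0.3, rel=0.15)

    def test_participant_relabelling_invariance(self):
        ph = synth_phenotype(40, seed=9)
        rng = np.random.default_rng(10)
        y = rng.normal(0.4, 0.05, len(ph))
        spec = ModelSpec(metric="Cp")
        frame, info = build_design(global_metric_long(ph, y), ph, spec)
        fit1 = fit_lmm(frame, spec, design_info=info)
        relabel = {p: f"Z{hash(p) % 10000:04d}_{p}"
                   for p in ph["participant_id"].unique()}
        frame2 = frame.assign(participant_id=frame["participant_id"].map(relabel))
        fit2 = fit_lmm(frame2, spec, design_info=info)
        np.testing.assert_allclose(fit2.estimates, fit1.estimates, atol=1e-8)
        np.testing.assert_allclose(fit2.pvalues, fit1.pvalues, atol=1e-6)

    def test_single_scan_participants_fall_back_to_ols(self):
        ph = synth_phenotype(30, seed=11).groupby("participant_id").head(1)
        rng = np.random.default_rng(12)
        spec = ModelSpec(metric="Cp")
        ml = global_metric_long(ph, rng.normal(0.4, 0.05, len(ph)))
        frame, info = build_design(ml, ph, spec)
        with pytest.warns(UserWarning, match="repeated scans"):
            fit = fit_lmm(frame, spec, design_info=info)
        assert fit.sigma_b2 == 0.0


class TestHemisphereModeration:
    def test_reports_group_by_hemisphere_terms(self):
        from conncohort.lmm import hemisphere_moderation_check
        ph = synth_phenotype(40, seed=21)
        rng = np.random.default_rng(22)
        rows = []
        for sid in ph["scan_id"]:
            for h in ("L", "R"):
                rows.append((sid, "nodal", "THA", h, "Ne",
                             float(rng.normal(0.25, 0.01))))
        ml = pd.DataFrame(rows, columns=["scan_id", "level", "region",
                                         "hemisphere", "metric", "value"])
        spec = ModelSpec(metric="Ne", level="nodal", region="THA")
        frame, info = build_design(ml, ph, spec)
        report = hemisphere_moderation_check(frame, spec, design_info=info)
        assert set(report) == {"group_tbi:hemi_r"}
        assert 0.0 <= report["group_tbi:hemi_r"]["p"] <= 1.0

    def test_rejects_global_frames(self):
        from conncohort.lmm import hemisphere_moderation_check
        ph = synth_phenotype(10, seed=23)
        ml = global_metric_long(ph, np.zeros(len(ph)))
        spec = ModelSpec(metric="Cp")
        frame, info = build_design(ml, ph, spec)
        with pytest.raises(ValueError, match="nodal"):
            hemisphere_moderation_check(frame, spec)


class TestAgainstLmerTest:
    def test_estimates_se_df_p_match(self, tmp_path):
        """Satterthwaite inference agrees with lmerTest on the same frame."""
        ph = synth_phenotype(60, seed=13)
        rng = np.random.default_rng(14)
        spec = ModelSpec(metric="Cp")
        frame, info = build_design(global_metric_long(ph, np.zeros(len(ph))),
                                   ph, spec)
        x, _ = design_matrix(frame)
        b = rng.normal(0, 0.03, ph["participant_id"].nunique())
        pid = pd.factorize(frame["participant_id"])[0]
        beta = rng.normal(0, 0.02, x.shape[1])
        y = x @ beta + b[pid] + rng.normal(0, 0.03, len(frame))
        frame = frame.assign(value=y)
        fit = fit_lmm(frame, spec, design_info=info)

        frame.to_csv(tmp_path / "frame.csv", index=False)
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(lmerTest))\n'
            f'setwd("{tmp_path}")\n'
            'd <- read.csv("frame.csv")\n'
            'cols <- setdiff(colnames(d), c("scan_id","participant_id","visit","value"))\n'
            'f <- as.formula(paste("value ~", paste(cols, collapse="+"),'
            ' "+ (1|participant_id)"))\n'
            'm <- lmer(f, data=d, REML=TRUE)\n'
            's <- summary(m)$coefficients\n'
            'write.csv(data.frame(term=rownames(s), s), "ref.csv", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv").set_index("term")
        mine = pd.DataFrame({"est": fit.estimates, "se": fit.se, "df": fit.df,
                             "p": fit.pvalues},
                            index=[t.replace(":", ".") for t in fit.terms])
        mine = mine.rename(index={"Intercept": "(Intercept)"})
        ref = ref.rename(index={"X.Intercept.": "(Intercept)"})
        for term in ref.index:
            r = ref.loc[term]
            m = mine.loc[term]
            assert m["est"] == pytest.approx(r["Estimate"], rel=1e-4, abs=1e-8)
            assert m["se"] == pytest.approx(r["Std..Error"], rel=1e-3)
            assert m["df"] == pytest.approx(r["df"], rel=0.02)
            assert m["p"] == pytest.approx(r["Pr...t.."], abs=1e-3)


class TestFdr:
    def test_bh_examples(self):
        rej, _ = fdr_correct([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert rej.all()
        rej, _ = fdr_correct([1.0, 1.0, 1.0], alpha=0.05)
        assert not rej.any()
        rej, _ = fdr_correct([0.04], alpha=0.05)
        assert rej.all()
        rej, _ = fdr_correct([0.04], alpha=0.025)
        assert not rej.any()

    def test_matches_literal_stepup_definition(self):
        rng = np.random.default_rng(15)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(0, 1, m)
            if rng.random() < 0.3:
                p[: m // 2] *= 0.05  # sprinkle signal
            alpha = float(rng.choice([0.01, 0.025, 0.05, 0.1]))
            rej, _ = fdr_correct(p, alpha=alpha)
            np.testing.assert_array_equal(rej, bh_stepup(p, alpha))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                   min_size=1, max_size=45),
        alpha=st.sampled_from([0.01, 0.025, 0.05, 0.1]),
    )
    def test_bh_property_any_pvector(self, p, alpha):
        rej, p_adj = fdr_correct(p, alpha=alpha)
        np.testing.assert_array_equal(rej, bh_stepup(np.asarray(p), alpha))
        assert np.all((p_adj >= 0) & (p_adj <= 1))

    def test_invalid_families(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_correct([], alpha=0.05)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_correct([0.5, 1.4], alpha=0.05)


def make_manual_fit(estimates, se, sigma_b2=0.5, sigma_e2=0.5,
                    terms=None, info=None):
    terms = terms or [f"b{k}" for k in range(len(estimates))]
    n = 100
    fit = LmmFit(
        spec=ModelSpec(metric="Cp", df_method="residual"),
        terms=terms, estimates=np.asarray(estimates, float),
        se=np.asarray(se, float), df=np.full(len(terms), 90.0),
        tvalues=np.zeros(len(terms)), pvalues=np.ones(len(terms)),
        sigma_b2=sigma_b2, sigma_e2=sigma_e2, converged=True, n_obs=n,
        n_participants=50, design_info=info,
        _cov_beta=np.diag(np.asarray(se, float) ** 2),
    )
    return fit


class TestEffectSize:
    def test_zero_estimate_never_robust(self):
        fit = make_manual_fit([0.0], [0.2], sigma_b2=0.5, sigma_e2=0.5)
        es = effect_size(fit, "b0")
        assert es.d == 0.0 and not es.robust and es.band == "negligible"

    def test_band_and_robust_flags(self):
        # d = 0.35 with CI [0.10, 0.60]: small and robust
        sd = 1.0  # sigma_b2 + sigma_e2 = 1
        est = 0.35
        se = (0.35 - 0.10) / 1.96
        fit = make_manual_fit([est], [se], sigma_b2=0.4, sigma_e2=0.6)
        es = effect_size(fit, "b0")
        assert es.d == pytest.approx(0.35)
        assert es.ci95[0] == pytest.approx(0.10, abs=1e-9)
        assert es.ci95[1] == pytest.approx(0.60, abs=1e-9)
        assert es.band == "small" and es.robust

    @pytest.mark.parametrize("d,band", [
        (0.1, "negligible"), (0.2, "small"), (-0.49, "small"),
        (0.5, "medium"), (-0.79, "medium"), (0.8, "large"), (-2.0, "large"),
    ])
    def test_band_boundaries(self, d, band):
        fit = make_manual_fit([d], [10.0], sigma_b2=0.5, sigma_e2=0.5)
        assert effect_size(fit, "b0").band == band

    def test_zero_variance_rejected(self):
        fit = make_manual_fit([1.0], [0.1], sigma_b2=0.0, sigma_e2=0.0)
        with pytest.raises(ValueError, match="variance"):
            effect_size(fit, "b0")


class TestProbing:
    def _info(self):
        return DesignInfo(time_mean=60.0, time_sd=70.0, age_mean=12.5,
                          columns=[], visit_mean_days={"postacute": 12.0,
                                                       "3month": 92.0,
                                                       "6month": 182.0},
                          age_percentiles=(9.0, 16.0))

    def _flat_fit(self):
        terms = ["Intercept", "group_tbi", "time", "time2", "age_c", "sex_f",
                 "group_tbi:time", "group_tbi:time2", "group_tbi:age_c",
                 "group_tbi:sex_f", "group_tbi:time:age_c",
                 "group_tbi:time:sex_f", "group_tbi:time2:age_c",
                 "group_tbi:time2:sex_f", "time:age_c", "time:sex_f",
                 "time2:age_c", "time2:sex_f"]
        est = np.zeros(len(terms))
        est[terms.index("group_tbi")] = 0.4
        return make_manual_fit(est, np.full(len(terms), 0.05), terms=terms,
                               info=self._info())

    def test_no_significant_interactions_empty_probe_list(self):
        fit = self._flat_fit()
        assert probe_interactions(fit, ["group_tbi"]) == []
        assert probe_interactions(fit, []) == []

    def test_flat_interactions_give_identical_contrasts(self):
        fit = self._flat_fit()
        probes = probe_interactions(
            fit, ["group_tbi:time", "group_tbi:sex_f", "group_tbi:age_c"])
        assert len(probes) == 3 * 2 * 2
        ds = {round(p.d, 12) for p in probes}
        assert len(ds) == 1  # only the main effect contributes everywhere

    def test_contrast_vector_at_reference_point(self):
        fit = self._flat_fit()
        c = group_contrast_vector(fit, days=60.0, sex="M", age=12.5)
        expect = np.zeros(len(fit.terms))
        expect[fit.terms.index("group_tbi")] = 1.0
        np.testing.assert_allclose(c, expect, atol=1e-12)

    def test_contrast_includes_interaction_terms_away_from_reference(self):
        fit = self._flat_fit()
        c = group_contrast_vector(fit, days=130.0, sex="F", age=14.5)
        t = (130.0 - 60.0) / 70.0
        assert c[fit.terms.index("group_tbi:time")] == pytest.approx(t)
        assert c[fit.terms.index("group_tbi:time2")] == pytest.approx(t * t)
        assert c[fit.terms.index("group_tbi:sex_f")] == 1.0
        assert c[fit.terms.index("group_tbi:age_c")] == pytest.approx(2.0)
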