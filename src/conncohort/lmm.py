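"""Longitudinal mixed-effects inference on harmonized network metrics.

Global metrics are modelled as

    metric ~ Group x (Time + Time^2) x (Age + Sex) + (1 | participant)

and nodal metrics additionally include a Hemisphere main effect, with rows
per scan x hemisphere.  Group is either the 2-level injury grouping
(TBI vs. OI, OI reference) or the 3-level symptom-status grouping
(TBI-persistent / TBI-nonpersistent / OI, OI reference, separately per
rater).  Time is days post-injury centred and scaled before squaring; age
is centred; Sex reference is male, Hemisphere reference is left.

Per-term inference uses REML estimates with Satterthwaite-type degrees of
freedom (computed from the curvature of the restricted likelihood in the
two variance components); "residual" df are available as a cross-check
mode.  Families of group-involving p-values are corrected with the
Benjamini-Hochberg FDR, and group contrasts are reported as Cohen's d
(estimate divided by the total random SD) with a 95% CI; effects whose CI
excludes 0 are flagged robust, with bands at |0.20|, |0.50| and |0.80|.
Significant interactions are probed as group-difference contrasts at the
mean days post-injury of each visit, in each sex, and at the 10th/90th
age percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

GROUPINGS = ("injury", "symptom")
D_BANDS = ((0.80, "large"), (0.50, "medium"), (0.20, "small"), (0.0, "negligible"))


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, grouping, level, and inference settings."""

    metric: str
    level: str = "global"               # "global" | "nodal"
    grouping: str = "injury"            # "injury" | "symptom"
    rater: str | None = None            # required for grouping="symptom"
    region: str | None = None           # required for level="nodal"
    fdr_alpha: float = 0.05
    df_method: str = "satterthwaite"    # or "residual"

    def __post_init__(self) -> None:
        if self.grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if self.grouping == "symptom" and self.rater is None:
            raise ValueError("symptom grouping requires a rater")
        if self.level == "nodal" and self.region is None:
            raise ValueError("nodal models require a region")

    @property
    def group_columns(self) -> tuple[str, ...]:
        if self.grouping == "injury":
            return ("group_tbi",)
        return ("group_pers", "group_nonpers")


@dataclass
class DesignInfo:
    """Centring/scaling constants needed to map raw covariates to columns."""

    time_mean: float
    time_sd: float
    age_mean: float
    columns: list[str]
    visit_mean_days: dict[str, float]
    age_percentiles: tuple[float, float]


def _interaction_columns(group_cols: tuple[str, ...]) -> list[str]:
    cols = list(group_cols) + ["time", "time2", "age_c", "sex_f"]
    for g in group_cols:
        for t in ("", "time", "time2"):
            for a in ("", "age_c", "sex_f"):
                parts = [g] + ([t] if t else []) + ([a] if a else [])
                if len(parts) > 1:
                    cols.append(":".join(parts))
    for t in ("time", "time2"):
        for a in ("age_c", "sex_f"):
            cols.append(f"{t}:{a}")
    return cols


def build_design(
    metrics_long: pd.DataFrame,
    phenotype: pd.DataFrame,
    spec: ModelSpec,
    symptom_groups: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, DesignInfo]:
    """Model frame for one outcome: response, design columns, participant id.

    Global models get one row per scan; nodal models one row per scan x
    hemisphere (the two homologous nodes of ``spec.region``).
    """
    if spec.level == "global":
        vals = metrics_long.query("level == 'global' and metric == @spec.metric")
        vals = vals[["scan_id", "value"]]
    else:
        vals = metrics_long.query(
            "level == 'nodal' and metric == @spec.metric and region == @spec.region"
        )[["scan_id", "hemisphere", "value"]]
    if vals.empty:
        raise ValueError(f"no rows for metric {spec.metric!r} ({spec.level})")

    frame = vals.merge(phenotype, on="scan_id", how="left", validate="many_to_one")
    if frame[["group", "site", "sex", "age_at_injury", "days_post_injury"]].isna().any().any():
        raise ValueError("metric table contains scans missing from the phenotype")

    if spec.grouping == "symptom":
        if symptom_groups is None:
            raise ValueError("symptom grouping requires symptom_groups")
        sg = symptom_groups.query("rater == @spec.rater")[["participant_id", "symptom_group"]]
        frame = frame.merge(sg, on="participant_id", how="left")
        frame = frame[frame["symptom_group"].isin(["OI", "TBI-persistent", "TBI-nonpersistent"])]
        if frame.empty:
            raise ValueError("no classifiable participants for symptom grouping")

    days = frame["days_post_injury"].astype(float)
    t_mean, t_sd = float(days.mean()), float(days.std(ddof=0))
    if t_sd == 0:
        raise ValueError("days post-injury has zero variance")
    age = frame["age_at_injury"].astype(float)
    a_mean = float(age.mean())

    d = pd.DataFrame(index=frame.index)
    d["time"] = (days - t_mean) / t_sd
    d["time2"] = d["time"] ** 2
    d["age_c"] = age - a_mean
    d["sex_f"] = (frame["sex"] == "F").astype(float)
    if spec.grouping == "injury":
        d["group_tbi"] = (frame["group"] == "TBI").astype(float)
    else:
        d["group_pers"] = (frame["symptom_group"] == "TBI-persistent").astype(float)
        d["group_nonpers"] = (frame["symptom_group"] == "TBI-nonpersistent").astype(float)

    cols = _interaction_columns(spec.group_columns)
    for c in cols:
        parts = c.split(":")
        if len(parts) > 1:
            d[c] = d[parts[0]]
            for p in parts[1:]:
                d[c] = d[c] * d[p]
    if spec.level == "nodal":
        d["hemi_r"] = (frame["hemisphere"] == "R").astype(float)
        cols = cols + ["hemi_r"]

    out = pd.concat(
        [frame[["scan_id", "participant_id", "visit"]].reset_index(drop=True),
         frame[["value"]].reset_index(drop=True),
         d[cols].reset_index(drop=True)],
        axis=1,
    )
    visit_means = (
        frame.groupby("visit")["days_post_injury"].mean().astype(float).to_dict()
    )
    # age percentiles over unique participants, not scans
    uages = frame.drop_duplicates("participant_id")["age_at_injury"].astype(float)
    pct = (float(np.percentile(uages, 10)), float(np.percentile(uages, 90)))
    info = DesignInfo(time_mean=t_mean, time_sd=t_sd, age_mean=a_mean,
                      columns=cols, visit_mean_days=visit_means,
                      age_percentiles=pct)
    return out, info


# ---------------------------------------------------------------------------
# REML machinery for the random-intercept model

class _RandomInterceptREML:
    """Profiled quantities of y = X b + u_participant + e under REML."""

    def __init__(self, x: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.x = x[order]
        self.y = y[order]
        g = groups[order]
        _, starts = np.unique(g, return_index=True)
        self.slices = [slice(s, e) for s, e in
                       zip(starts, list(starts[1:]) + [len(g)])]
        self.n, self.p = x.shape

    def _per_group(self, theta):
        sb2, se2 = theta
        xtvx = np.zeros((self.p, self.p))
        xtvy = np.zeros(self.p)
        logdet = 0.0
        for sl in self.slices:
            xg, yg = self.x[sl], self.y[sl]
            ng = xg.shape[0]
            shrink = sb2 / (se2 + ng * sb2)
            sx = xg.sum(axis=0)
            sy = yg.sum()
            xtvx += (xg.T @ xg - shrink * np.outer(sx, sx)) / se2
            xtvy += (xg.T @ yg - shrink * sx * sy) / se2
            logdet += (ng - 1) * np.log(se2) + np.log(se2 + ng * sb2)
        return xtvx, xtvy, logdet

    def beta_cov(self, theta):
        xtvx, xtvy, _ = self._per_group(theta)
        cov = np.linalg.inv(xtvx)
        return cov @ xtvy, cov

    def reml_loglik(self, theta) -> float:
        sb2, se2 = theta
        if se2 <= 0 or sb2 < 0:
            return -np.inf
        xtvx, xtvy, logdet = self._per_group(theta)
        cov = np.linalg.inv(xtvx)
        beta = cov @ xtvy
        quad = 0.0
        for sl in self.slices:
            rg = self.y[sl] - self.x[sl] @ beta
            ng = rg.shape[0]
            shrink = sb2 / (se2 + ng * sb2)
            quad += (rg @ rg - shrink * rg.sum() ** 2) / se2
        sign, ld2 = np.linalg.slogdet(xtvx)
        return -0.5 * (logdet + ld2 + quad)


@dataclass
class LmmFit:
    """Fixed-effect estimates and variance components for one model."""

    spec: ModelSpec
    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    df: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma_b2: float
    sigma_e2: float
    converged: bool
    n_obs: int
    n_participants: int
    design_info: DesignInfo | None = None
    _reml: _RandomInterceptREML | None = field(default=None, repr=False)
    _cov_beta: np.ndarray | None = field(default=None, repr=False)
    _theta_cov: np.ndarray | None = field(default=None, repr=False)
    _cov_pert: list | None = field(default=None, repr=False)  # [(step_i, C+, C-)]

    @property
    def total_sd(self) -> float:
        return float(np.sqrt(self.sigma_b2 + self.sigma_e2))

    def term_index(self, term: str) -> int:
        return self.terms.index(term)

    def contrast(self, c: np.ndarray) -> tuple[float, float, float, float]:
        """(estimate, SE, df, p) for a linear combination of fixed effects."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.estimates)
        se = float(np.sqrt(c @ self._cov_beta @ c))
        df = self._contrast_df(c)
        t = est / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), df))
        return est, se, df, p

    def _contrast_df(self, c: np.ndarray) -> float:
        resid_df = float(self.n_obs - len(self.terms))
        if self.spec.df_method == "residual" or self._theta_cov is None:
            return resid_df
        theta = np.array([self.sigma_b2, self.sigma_e2])
        f0 = float(c @ self._cov_beta @ c)
        if self._cov_pert is None:
            pert = []
            for i in range(2):
                h = max(1e-10, 1e-5 * theta[i])
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h
                tm[i] = max(tm[i] - h, 0.0 if i == 0 else 1e-12)
                _, cp = self._reml.beta_cov(tp)
                _, cm = self._reml.beta_cov(tm)
                pert.append((tp[i] - tm[i], cp, cm))
            self._cov_pert = pert
        grad = np.empty(2)
        for i, (span, cp, cm) in enumerate(self._cov_pert):
            grad[i] = (float(c @ cp @ c) - float(c @ cm @ c)) / span
        denom = float(grad @ self._theta_cov @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return resid_df
        df = 2.0 * f0**2 / denom
        return float(np.clip(df, 1.0, resid_df))


def fit_lmm(frame: pd.DataFrame, spec: ModelSpec,
            design_info: DesignInfo | None = None) -> LmmFit:
    """REML random-intercept fit of a model frame from :func:`build_design`."""
    terms = [c for c in frame.columns
             if c not in ("scan_id", "participant_id", "visit", "value")]
    x = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(float) for c in terms])
    all_terms = ["Intercept"] + terms
    y = frame["value"].to_numpy(float)
    codes = pd.factorize(frame["participant_id"])[0]
    counts = np.bincount(codes)
    n_repeated = int((counts >= 2).sum())
    sd_y = float(y.std(ddof=0))
    if sd_y <= 0:
        raise ValueError("constant outcome; model unidentifiable")

    ols_beta = np.linalg.lstsq(x, y, rcond=None)[0]
    ols_resid = y - x @ ols_beta
    noiseless = float(ols_resid @ ols_resid) < 1e-18 * max(len(y) * sd_y**2, 1e-300)
    if noiseless:
        # noiseless fixed-effect data: GLS equals OLS for any variance split
        n_repeated = 0
    elif n_repeated < 2:
        warnings.warn("fewer than 2 participants with repeated scans; "
                      "participant variance set to 0", stacklevel=2)

    if n_repeated >= 2:
        # optimize on the z-scored outcome for conditioning, then map the
        # variance components back to the metric scale
        res = fallback = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM((y - y.mean()) / sd_y, x, groups=codes)
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    cand = model.fit(reml=True, method=method)
                except np.linalg.LinAlgError:
                    continue
                finite = (np.all(np.isfinite(cand.fe_params))
                          and np.isfinite(cand.scale)
                          and np.isfinite(np.asarray(cand.cov_re)[0, 0]))
                if not finite:
                    continue
                if cand.converged:
                    res = cand
                    break
                fallback = fallback or cand
        # a finite optimum that the optimizer flags (typically the sigma_b=0
        # boundary) is still usable; only a fit with no finite solution fails
        converged = res is not None or fallback is not None
        res = res or fallback
        if res is None:
            raise np.linalg.LinAlgError("REML optimization failed")
        sb2 = float(np.asarray(res.cov_re)[0, 0]) * sd_y**2
        se2 = float(res.scale) * sd_y**2
    else:
        sb2 = 0.0
        se2 = float(ols_resid @ ols_resid / max(len(y) - x.shape[1], 1))
        converged = True
    se2 = max(se2, 1e-12 * sd_y**2)  # keep V invertible for degenerate fits

    reml = _RandomInterceptREML(x, y, codes)
    beta, cov_beta = reml.beta_cov((sb2, se2))

    theta_cov = None
    if spec.df_method == "satterthwaite" and sb2 > 1e-6 * max(se2, 1e-300):
        theta = np.array([sb2, se2])
        h = 1e-4 * theta
        hess = np.empty((2, 2))
        ll = reml.reml_loglik
        with np.errstate(all="ignore"):
            for i in range(2):
                for j in range(i, 2):
                    ei = np.eye(2)[i] * h[i]
                    ej = np.eye(2)[j] * h[j]
                    hess[i, j] = hess[j, i] = (
                        ll(theta + ei + ej) - ll(theta + ei - ej)
                        - ll(theta - ei + ej) + ll(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            if np.all(np.isfinite(hess)):
                theta_cov = np.linalg.inv(-hess)
            if theta_cov is not None and not np.all(np.isfinite(theta_cov)):
                theta_cov = None
        except np.linalg.LinAlgError:
            theta_cov = None

    fit = LmmFit(
        spec=spec, terms=all_terms, estimates=beta,
        se=np.sqrt(np.diag(cov_beta)), df=np.empty(len(all_terms)),
        tvalues=np.empty(len(all_terms)), pvalues=np.empty(len(all_terms)),
        sigma_b2=sb2, sigma_e2=se2, converged=converged,
        n_obs=len(y), n_participants=len(counts), design_info=design_info,
        _reml=reml, _cov_beta=cov_beta, _theta_cov=theta_cov,
    )
    eye = np.eye(len(all_terms))
    for k in range(len(all_terms)):
        _, _, df_k, p_k = fit.contrast(eye[k])
        fit.df[k] = df_k
        fit.tvalues[k] = fit.estimates[k] / fit.se[k] if fit.se[k] > 0 else 0.0
        fit.pvalues[k] = p_k
    return fit


def hemisphere_moderation_check(frame: pd.DataFrame, spec: ModelSpec,
                                design_info: DesignInfo | None = None) -> dict:
    """Diagnostic: does Hemisphere moderate the group difference?

    Refits the nodal model with Group x Hemisphere interaction column(s)
    added and reports their estimates and p-values.  This is a pre-check
    only; the analysis models keep Hemisphere as a main effect regardless.
    """
    if "hemi_r" not in frame.columns:
        raise ValueError("hemisphere check requires a nodal model frame")
    aug = frame.copy()
    added = []
    for g in spec.group_columns:
        name = f"{g}:hemi_r"
        aug[name] = aug[g] * aug["hemi_r"]
        added.append(name)
    fit = fit_lmm(aug, spec, design_info=design_info)
    return {name: {"estimate": float(fit.estimates[fit.term_index(name)]),
                   "p": float(fit.pvalues[fit.term_index(name)])}
            for name in added}


# ---------------------------------------------------------------------------
# FDR, effect sizes, probing

def fdr_correct(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected mask, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


@dataclass(frozen=True)
class EffectSize:
    label: str
    d: float
    ci95: tuple[float, float]
    robust: bool
    band: str
    estimate: float = np.nan
    se: float = np.nan
    df: float = np.nan
    p: float = np.nan


def _band(d: float) -> str:
    for cut, name in D_BANDS:
        if abs(d) >= cut:
            return name
    return "negligible"


def effect_size(fit: LmmFit, term_or_contrast, label: str | None = None) -> EffectSize:
    """Cohen's d with 95% CI for a fixed-effect term or contrast vector.

    d = estimate / total random SD (participant + residual); the CI is the
    Wald interval of the estimate mapped onto the d scale.
    """
    sd = fit.total_sd
    if sd <= 0:
        raise ValueError("zero total variance; d undefined")
    if isinstance(term_or_contrast, str):
        c = np.zeros(len(fit.terms))
        c[fit.term_index(term_or_contrast)] = 1.0
        label = label or term_or_contrast
    else:
        c = np.asarray(term_or_contrast, dtype=float)
        label = label or "contrast"
    est, se, df, p = fit.contrast(c)
    d = est / sd
    lo, hi = (est - 1.96 * se) / sd, (est + 1.96 * se) / sd
    return EffectSize(label=label, d=d, ci95=(lo, hi), robust=not (lo <= 0.0 <= hi),
                      band=_band(d), estimate=est, se=se, df=df, p=p)


def group_contrast_vector(
    fit: LmmFit,
    days: float,
    sex: str,
    age: float,
    pair: tuple[str, str | None] = ("group_tbi", None),
) -> np.ndarray:
    """Contrast for the group difference at raw (days, sex, age).

    ``pair=(a, b)`` gives group-a minus group-b, where each is a group
    indicator column name and ``None`` denotes the reference (OI).
    """
    info = fit.design_info
    t = (days - info.time_mean) / info.time_sd
    a = age - info.age_mean
    s = 1.0 if sex == "F" else 0.0
    vals = {"": 1.0, "time": t, "time2": t * t, "age_c": a, "sex_f": s}
    c = np.zeros(len(fit.terms))
    for g, sign in ((pair[0], 1.0), (pair[1], -1.0)):
        if g is None:
            continue
        for tkey in ("", "time", "time2"):
            for akey in ("", "age_c", "sex_f"):
                parts = [g] + ([tkey] if tkey else []) + ([akey] if akey else [])
                name = ":".join(parts)
                if name in fit.terms:
                    c[fit.term_index(name)] += sign * vals[tkey] * vals[akey]
    return c


def probe_interactions(
    fit: LmmFit,
    significant_terms: list[str],
    pair: tuple[str, str | None] = ("group_tbi", None),
    pair_label: str = "TBI-OI",
) -> list[EffectSize]:
    """Group-difference effect sizes on the probe grid implied by the
    significant interaction terms.

    Interactions with time are probed at the mean days post-injury of each
    visit; with sex in males and females; with age at the 10th and 90th age
    percentiles.  Dimensions without a significant interaction stay at the
    sample mean (time), reference male (sex) and mean age.  Returns an empty
    list when no group-involving interaction is significant.
    """
    info = fit.design_info
    ga, gb = pair
    involved = [t for t in significant_terms
                if ga in t.split(":") or (gb is not None and gb in t.split(":"))]
    probe_time = any("time" in t.split(":") or "time2" in t.split(":") for t in involved)
    probe_sex = any("sex_f" in t.split(":") for t in involved)
    probe_age = any("age_c" in t.split(":") for t in involved)
    if not (probe_time or probe_sex or probe_age):
        return []

    times = (sorted(info.visit_mean_days.items())
             if probe_time else [("mean", info.time_mean)])
    sexes = ["M", "F"] if probe_sex else ["M"]
    ages = ([("age10", info.age_percentiles[0]), ("age90", info.age_percentiles[1])]
            if probe_age else [("agemean", info.age_mean)])
    out = []
    for vlabel, days in times:
        for sex in sexes:
            for alabel, age in ages:
                c = group_contrast_vector(fit, days, sex, age, pair=pair)
                label = f"{pair_label}@{vlabel}({days:.0f}d),{sex},{alabel}({age:.1f}y)"
                out.append(effect_size(fit, c, label=label))
    return out
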