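"""Empirical-Bayes batch (site/scanner) harmonization of metric tables.

Implements the parametric ComBat location/scale model: per feature v and
site i,

    y_ivj = alpha_v + x_j' beta_v + gamma_iv + delta_iv * eps_ivj

Feature values are standardized against the covariate fit, site location
(gamma) and scale (delta) estimates are shrunk toward their across-feature
prior moments (normal prior for location, inverse-gamma for scale) by the
standard iterative conditional updates, and data are adjusted so modelled
biological covariates (group, time, age, sex) are preserved while site
differences are removed.

Conventions follow the reference R implementation (sva::ComBat with a
covariate model matrix): pooled variance uses the 1/N denominator, per-site
scale estimates use n_i - 1.  A single-site table is returned unchanged
(there is no second batch to harmonize against); the model then carries
zero location and unit scale effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class HarmonizationModel:
    features: list[str]
    covariate_names: list[str]
    sites: list[str]
    n_per_site: dict[str, int]
    grand_mean: np.ndarray          # (V,)
    beta: np.ndarray                # (n_cov, V)
    var_pooled: np.ndarray          # (V,)
    gamma_star: np.ndarray          # (n_sites, V)
    delta_star_sq: np.ndarray       # (n_sites, V)
    n_iter: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "features": self.features,
            "covariate_names": self.covariate_names,
            "sites": self.sites,
            "n_per_site": self.n_per_site,
            "grand_mean": self.grand_mean.tolist(),
            "beta": self.beta.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star_sq": self.delta_star_sq.tolist(),
            "n_iter": self.n_iter,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            features=obj["features"],
            covariate_names=obj["covariate_names"],
            sites=obj["sites"],
            n_per_site={k: int(v) for k, v in obj["n_per_site"].items()},
            grand_mean=np.asarray(obj["grand_mean"]),
            beta=np.asarray(obj["beta"]),
            var_pooled=np.asarray(obj["var_pooled"]),
            gamma_star=np.asarray(obj["gamma_star"]),
            delta_star_sq=np.asarray(obj["delta_star_sq"]),
            n_iter={k: int(v) for k, v in obj.get("n_iter", {}).items()},
        )


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _aprior(d_hat: np.ndarray) -> float:
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(d_hat: np.ndarray) -> float:
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a, b, tol=1e-6, max_iter=100):
    """EB iterative conditional updates for one site's gamma*, delta*^2."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
            np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old, it


def fit_harmonization(
    data: pd.DataFrame,
    covariates: pd.DataFrame,
    batch: pd.Series,
    eb: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> HarmonizationModel:
    """Fit the ComBat model on a samples x features table.

    Parameters
    ----------
    data:
        Numeric table, one row per scan, one column per feature
        (metric x region combination).
    covariates:
        Numeric design columns to preserve (group/time/time^2/age/sex
        codings); no intercept, no batch column.
    batch:
        Site (scanner) label per scan, aligned with ``data``.
    eb:
        Apply empirical-Bayes shrinkage across features (default); with a
        single feature shrinkage is skipped automatically.
    """
    y = data.to_numpy(dtype=float).T            # V x N
    v, n = y.shape
    batch = pd.Series(np.asarray(batch), index=data.index)
    sites = sorted(batch.unique().tolist())
    counts = batch.value_counts()
    if any(counts[s] < 2 for s in sites):
        raise ValueError("each site needs >= 2 observations")

    bdesign = np.column_stack([(batch == s).to_numpy(float) for s in sites])
    x_cov = covariates.to_numpy(dtype=float) if covariates is not None and covariates.shape[1] else np.empty((n, 0))
    design = np.hstack([bdesign, x_cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates/batches)")

    b_hat, *_ = np.linalg.lstsq(design, y.T, rcond=None)   # (n_b + n_cov) x V
    n_b = len(sites)
    frac = np.array([counts[s] / n for s in sites])
    grand_mean = frac @ b_hat[:n_b]                         # (V,)
    fitted = design @ b_hat
    var_pooled = ((y.T - fitted) ** 2).mean(axis=0)         # (V,)
    if np.any(var_pooled <= 0):
        raise ValueError("zero pooled variance for some feature")

    stand_mean = grand_mean[None, :] + x_cov @ b_hat[n_b:]
    z = (y.T - stand_mean) / np.sqrt(var_pooled)[None, :]   # N x V

    if n_b == 1:
        model = HarmonizationModel(
            features=list(data.columns), covariate_names=list(covariates.columns),
            sites=sites, n_per_site={s: int(counts[s]) for s in sites},
            grand_mean=grand_mean, beta=b_hat[n_b:], var_pooled=var_pooled,
            gamma_star=np.zeros((1, v)), delta_star_sq=np.ones((1, v)),
        )
        warnings.warn("single-site table: harmonization is a no-op", stacklevel=2)
        return model

    gamma_star = np.empty((n_b, v))
    delta_star_sq = np.empty((n_b, v))
    n_iter: dict[str, int] = {}
    for i, s in enumerate(sites):
        zb = z[(batch == s).to_numpy()]
        g_hat = zb.mean(axis=0)
        d_hat = zb.var(axis=0, ddof=1)
        if eb and v >= 2 and d_hat.var(ddof=1) > 0:
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            a, b = _aprior(d_hat), _bprior(d_hat)
            g_star, d_star, it = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, b,
                                         tol=tol, max_iter=max_iter)
        else:
            g_star, d_star, it = g_hat, d_hat, 0
        gamma_star[i] = g_star
        delta_star_sq[i] = d_star
        n_iter[s] = it

    return HarmonizationModel(
        features=list(data.columns), covariate_names=list(covariates.columns),
        sites=sites, n_per_site={s: int(counts[s]) for s in sites},
        grand_mean=grand_mean, beta=b_hat[n_b:], var_pooled=var_pooled,
        gamma_star=gamma_star, delta_star_sq=delta_star_sq, n_iter=n_iter,
    )


def apply_harmonization(
    data: pd.DataFrame,
    covariates: pd.DataFrame,
    batch: pd.Series,
    model: HarmonizationModel,
) -> pd.DataFrame:
    """Remove fitted site effects; output schema identical to the input."""
    if list(data.columns) != model.features:
        raise ValueError("feature columns do not match the fitted model")
    batch = pd.Series(np.asarray(batch), index=data.index)
    unseen = set(batch.unique()) - set(model.sites)
    if unseen:
        raise KeyError(f"unseen site labels {sorted(unseen)}")
    y = data.to_numpy(dtype=float)
    x_cov = covariates.to_numpy(dtype=float) if covariates is not None and covariates.shape[1] else np.empty((len(data), 0))
    stand_mean = model.grand_mean[None, :] + x_cov @ model.beta
    z = (y - stand_mean) / np.sqrt(model.var_pooled)[None, :]
    site_idx = np.array([model.sites.index(s) for s in batch])
    adj = (z - model.gamma_star[site_idx]) / np.sqrt(model.delta_star_sq[site_idx])
    out = adj * np.sqrt(model.var_pooled)[None, :] + stand_mean
    return pd.DataFrame(out, index=data.index, columns=data.columns)


# ---------------------------------------------------------------------------
# Long-format plumbing for the metrics table

FEATURE_SEP = "|"


def long_to_wide(metrics_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long metrics table to scans x features."""
    t = metrics_long.copy()
    t["feature"] = (
        t["level"].astype(str) + FEATURE_SEP + t["metric"].astype(str)
        + FEATURE_SEP + t["region"].astype(str) + FEATURE_SEP + t["hemisphere"].astype(str)
    )
    wide = t.pivot(index="scan_id", columns="feature", values="value")
    return wide.sort_index(axis=0).sort_index(axis=1)


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`long_to_wide`."""
    rows = []
    for feature in wide.columns:
        level, metric, region, hemi = feature.split(FEATURE_SEP)
        for scan_id, val in wide[feature].items():
            rows.append((scan_id, level, region, hemi, metric, val))
    return pd.DataFrame(
        rows, columns=["scan_id", "level", "region", "hemisphere", "metric", "value"]
    ).sort_values(["scan_id", "level", "metric", "region", "hemisphere"], kind="stable").reset_index(drop=True)


def build_covariates(phenotype: pd.DataFrame) -> pd.DataFrame:
    """Standard preserved-covariate design: group, days, days^2, age, sex.

    Group and sex enter as single indicator columns (TBI=1, female=1); time
    enters as days post-injury plus its square.
    """
    ph = phenotype.set_index("scan_id")
    return pd.DataFrame({
        "group_tbi": (ph["group"] == "TBI").astype(float),
        "days": ph["days_post_injury"].astype(float),
        "days_sq": ph["days_post_injury"].astype(float) ** 2,
        "age": ph["age_at_injury"].astype(float),
        "sex_f": (ph["sex"] == "F").astype(float),
    })


def harmonize_metrics(
    metrics_long: pd.DataFrame,
    phenotype: pd.DataFrame,
    batch_column: str = "site",
    eb: bool = True,
) -> tuple[pd.DataFrame, HarmonizationModel]:
    """Harmonize a long metrics table across sites in one pooled run."""
    wide = long_to_wide(metrics_long)
    ph = phenotype.set_index("scan_id").loc[wide.index]
    cov = build_covariates(phenotype).loc[wide.index]
    # constant features (e.g. degree under a fixed topology) carry no site
    # signal and would degenerate the standardization; pass them through
    variable = wide.columns[wide.std(ddof=0) > 0]
    constant = [c for c in wide.columns if c not in set(variable)]
    if constant:
        warnings.warn(f"{len(constant)} constant feature(s) passed through "
                      "unharmonized", stacklevel=2)
    model = fit_harmonization(wide[variable], cov, ph[batch_column], eb=eb)
    adj = apply_harmonization(wide[variable], cov, ph[batch_column], model)
    out = wide.copy()
    out[variable] = adj
    return wide_to_long(out), model
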