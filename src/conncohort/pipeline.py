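"""End-to-end pipeline: simulate -> build/filter -> metrics -> harmonize
-> reliable change -> mixed-effects inference -> results tables.

Every stage writes plain-text artifacts plus a manifest; the whole run is
reproducible byte-for-byte from the config and a single seed (per-scan null
ensembles draw from sub-seeds derived deterministically from scan ids).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, write_cohort
from .connectome import ConnectivityMatrix, filter_scans, read_matrix
from .harmonize import harmonize_metrics
from .lmm import (
    GROUPINGS, LmmFit, ModelSpec, build_design, effect_size, fdr_correct,
    fit_lmm, probe_interactions,
)
from .metrics import (
    GLOBAL_METRICS, NODAL_METRICS, compute_metrics, metrics_to_long,
)
from .parcellation import REGIONS_45
from .rci import assign_symptom_groups, classify_cohort

log = logging.getLogger("conncohort")

RESULTS_COLUMNS = [
    "metric", "level", "region", "grouping", "rater", "term", "estimate",
    "se", "df", "t", "p", "p_fdr", "d", "d_lo", "d_hi", "robust", "band",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending item."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage
        self.detail = detail


@dataclass
class RunConfig:
    outdir: str = "run"
    simulate: bool = True
    input_dir: str | None = None        # for non-simulated runs
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_null: int = 1000
    batch_column: str = "site"
    harmonize: bool = True
    rci_threshold: float = 1.645
    rci_reference: str = "all"
    fdr_alpha_injury: float = 0.05
    fdr_alpha_symptom: float = 0.025
    groupings: tuple[str, ...] = ("injury", "symptom")
    global_metrics: tuple[str, ...] = tuple(GLOBAL_METRICS)
    nodal_metrics: tuple[str, ...] = tuple(NODAL_METRICS)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        for a in (self.fdr_alpha_injury, self.fdr_alpha_symptom):
            if not 0.0 < a < 1.0:
                raise ValueError("FDR alphas must lie in (0, 1)")
        for g in self.groupings:
            if g not in GROUPINGS:
                raise ValueError(f"unknown grouping {g!r}")
        if not self.simulate:
            if self.input_dir is None or not Path(self.input_dir).exists():
                raise ValueError("non-simulated runs need an existing input_dir")
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**obj)


def _scan_null_seed(global_seed: int, scan_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([global_seed, 5, zlib.crc32(scan_id.encode()) & 0x7FFFFFFF])


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: RunConfig, outdir: Path) -> Path:
    data_dir = outdir / "data"
    write_cohort(cfg.cohort, data_dir)
    log.info("simulated cohort written to %s", data_dir)
    return data_dir


def stage_build(cfg: RunConfig, data_dir: Path, outdir: Path
                ) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    phenotype = pd.read_csv(data_dir / "phenotype.csv")
    mats = []
    for sid in phenotype["scan_id"]:
        path = data_dir / "matrices" / f"{sid}.txt"
        if not path.exists():
            raise StageError("build", f"missing matrix file for scan {sid}")
        try:
            mats.append(read_matrix(path, scan_id=sid))
        except ValueError as e:
            raise StageError("build", f"scan {sid}: {e}") from e
    kept, excluded = filter_scans(mats)
    _csv(pd.DataFrame(excluded, columns=["scan_id", "reason"]),
         outdir / "exclusions.csv")
    log.info("connectedness filter: kept %d, excluded %d", len(kept), len(excluded))
    kept_ids = {m.scan_id for m in kept}
    analyzed = phenotype[phenotype["scan_id"].isin(kept_ids)].reset_index(drop=True)
    _csv(analyzed, outdir / "phenotype_analyzed.csv")
    return kept, analyzed


def stage_metrics(cfg: RunConfig, kept: list[ConnectivityMatrix], outdir: Path) -> pd.DataFrame:
    all_metrics = []
    for m in kept:
        rng = np.random.default_rng(_scan_null_seed(cfg.seed, m.scan_id))
        all_metrics.append(compute_metrics(m, n_null=cfg.n_null, seed=rng))
    table = metrics_to_long(all_metrics)
    _csv(table, outdir / "metrics.csv")
    return table


def stage_harmonize(cfg: RunConfig, metrics_long: pd.DataFrame,
                    phenotype: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    if not cfg.harmonize:
        _csv(metrics_long, outdir / "metrics_harmonized.csv")
        return metrics_long
    adjusted, model = harmonize_metrics(metrics_long, phenotype,
                                        batch_column=cfg.batch_column)
    model.to_json(outdir / "harmonization_model.json")
    _csv(adjusted, outdir / "metrics_harmonized.csv")
    return adjusted


def stage_rci(cfg: RunConfig, data_dir: Path, phenotype: pd.DataFrame,
              outdir: Path) -> pd.DataFrame:
    symptoms = pd.read_csv(data_dir / "symptoms.csv")
    oi_ids = set(phenotype.loc[phenotype["group"] == "OI", "participant_id"])
    cls, models = classify_cohort(symptoms, reference=cfg.rci_reference,
                                  oi_ids=oi_ids, threshold_z=cfg.rci_threshold)
    _csv(cls, outdir / "classifications.csv")
    (outdir / "rci_models.json").write_text(json.dumps(
        {r: dataclasses.asdict(m) for r, m in models.items()}, indent=1))
    sg = assign_symptom_groups(cls, phenotype)
    _csv(sg, outdir / "symptom_groups.csv")
    return sg


def _family_results(
    metrics_long: pd.DataFrame,
    phenotype: pd.DataFrame,
    metric: str,
    level: str,
    grouping: str,
    rater: str | None,
    alpha: float,
    symptom_groups: pd.DataFrame | None,
) -> list[dict]:
    """Fit one metric's model(s), FDR-correct its group-involving terms
    within the family, attach effect sizes, probe significant interactions."""
    regions = REGIONS_45 if level == "nodal" else [None]
    fits: list[tuple[str | None, LmmFit]] = []
    for region in regions:
        spec = ModelSpec(metric=metric, level=level, grouping=grouping,
                         rater=rater, region=region, fdr_alpha=alpha)
        frame, info = build_design(metrics_long, phenotype, spec,
                                   symptom_groups=symptom_groups)
        if frame["value"].std(ddof=0) <= 0:
            log.info("constant outcome for %s/%s region=%s; model skipped",
                     metric, grouping, region)
            continue
        try:
            fit = fit_lmm(frame, spec, design_info=info)
        except Exception as e:  # noqa: BLE001 - convergence failures are logged, not fatal
            log.warning("fit failed for %s/%s region=%s: %s", metric, grouping, region, e)
            continue
        if not fit.converged:
            log.warning("non-convergence for %s/%s region=%s; excluded from FDR family",
                        metric, grouping, region)
            continue
        fits.append((region, fit))

    group_cols = ("group_tbi",) if grouping == "injury" else ("group_pers", "group_nonpers")
    fam_p, fam_key = [], []
    for region, fit in fits:
        for k, term in enumerate(fit.terms):
            if any(g in term.split(":") for g in group_cols):
                fam_p.append(fit.pvalues[k])
                fam_key.append((region, term))
    rejected = {}
    p_adj_map = {}
    if fam_p:
        rej, p_adj = fdr_correct(fam_p, alpha=alpha)
        rejected = {k: bool(r) for k, r in zip(fam_key, rej)}
        p_adj_map = {k: float(a) for k, a in zip(fam_key, p_adj)}

    rows = []
    for region, fit in fits:
        for k, term in enumerate(fit.terms):
            key = (region, term)
            is_group = key in p_adj_map
            es = effect_size(fit, term) if is_group else None
            rows.append({
                "metric": metric, "level": level, "region": region or "NA",
                "grouping": grouping, "rater": rater or "NA", "term": term,
                "estimate": fit.estimates[k], "se": fit.se[k], "df": fit.df[k],
                "t": fit.tvalues[k], "p": fit.pvalues[k],
                "p_fdr": p_adj_map.get(key, np.nan),
                "d": es.d if es else np.nan,
                "d_lo": es.ci95[0] if es else np.nan,
                "d_hi": es.ci95[1] if es else np.nan,
                "robust": es.robust if es else "",
                "band": es.band if es else "",
            })
        sig_terms = [t for (r, t), rj in rejected.items() if r == region and rj]
        pairs = ([("group_tbi", None, "TBI-OI")] if grouping == "injury" else
                 [("group_pers", None, "pers-OI"), ("group_nonpers", None, "nonpers-OI"),
                  ("group_pers", "group_nonpers", "pers-nonpers")])
        for ga, gb, plab in pairs:
            for es in probe_interactions(fit, sig_terms, pair=(ga, gb), pair_label=plab):
                rows.append({
                    "metric": metric, "level": level, "region": region or "NA",
                    "grouping": grouping, "rater": rater or "NA",
                    "term": f"probe:{es.label}", "estimate": es.estimate,
                    "se": es.se, "df": es.df, "t": np.nan, "p": es.p,
                    "p_fdr": np.nan, "d": es.d, "d_lo": es.ci95[0],
                    "d_hi": es.ci95[1], "robust": es.robust, "band": es.band,
                })
    return rows


def stage_fit(cfg: RunConfig, metrics_long: pd.DataFrame, phenotype: pd.DataFrame,
              symptom_groups: pd.DataFrame | None, outdir: Path) -> pd.DataFrame:
    rows: list[dict] = []
    for grouping in cfg.groupings:
        alpha = cfg.fdr_alpha_injury if grouping == "injury" else cfg.fdr_alpha_symptom
        raters = [None] if grouping == "injury" else ["parent", "child"]
        for rater in raters:
            for metric in cfg.global_metrics:
                rows += _family_results(metrics_long, phenotype, metric, "global",
                                        grouping, rater, alpha, symptom_groups)
            for metric in cfg.nodal_metrics:
                rows += _family_results(metrics_long, phenotype, metric, "nodal",
                                        grouping, rater, alpha, symptom_groups)
    results = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    _csv(results, outdir / "results.csv")
    return results


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        data_dir = stage_simulate(cfg, outdir)
    else:
        data_dir = Path(cfg.input_dir)
    kept, analyzed = stage_build(cfg, data_dir, outdir)
    if not kept:
        raise StageError("build", "no fully connected scans to analyze")
    metrics_long = stage_metrics(cfg, kept, outdir)
    harmonized = stage_harmonize(cfg, metrics_long, analyzed, outdir)
    symptom_groups = None
    if (data_dir / "symptoms.csv").exists():
        symptom_groups = stage_rci(cfg, data_dir, analyzed, outdir)
    groupings = tuple(g for g in cfg.groupings
                      if g == "injury" or symptom_groups is not None)
    cfg_run = dataclasses.replace(cfg, groupings=groupings)
    stage_fit(cfg_run, harmonized, analyzed, symptom_groups, outdir)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
        "n_scans_analyzed": int(len(analyzed)),
        "stages": ["simulate" if cfg.simulate else "load", "build", "metrics",
                   "harmonize" if cfg.harmonize else "harmonize(skipped)",
                   "rci" if symptom_groups is not None else "rci(skipped)", "fit"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


# ---------------------------------------------------------------------------
# Input validation (report-only)

def validate_inputs(data_dir: str | Path) -> list[dict]:
    """Schema and range checks for phenotype/symptoms/matrix files.

    Returns a list of issue records (empty when everything is well formed);
    never raises on malformed content.
    """
    data_dir = Path(data_dir)
    issues: list[dict] = []

    def issue(file: str, kind: str, detail: str) -> None:
        issues.append({"file": file, "kind": kind, "detail": detail})

    ph_path = data_dir / "phenotype.csv"
    phenotype = None
    if not ph_path.exists():
        issue("phenotype.csv", "missing_file", "phenotype table not found")
    else:
        phenotype = pd.read_csv(ph_path)
        needed = {"participant_id", "scan_id", "group", "site", "sex",
                  "age_at_injury", "days_post_injury", "visit"}
        missing = needed - set(phenotype.columns)
        if missing:
            issue("phenotype.csv", "missing_columns", str(sorted(missing)))
            phenotype = None
        else:
            bad = phenotype[~phenotype["group"].isin(["TBI", "OI"])]
            for r in bad.itertuples():
                issue("phenotype.csv", "bad_group", f"scan {r.scan_id}: {r.group}")
            bad = phenotype[~phenotype["sex"].isin(["M", "F"])]
            for r in bad.itertuples():
                issue("phenotype.csv", "bad_sex", f"scan {r.scan_id}: {r.sex}")

    sy_path = data_dir / "symptoms.csv"
    if sy_path.exists():
        sym = pd.read_csv(sy_path)
        needed = {"participant_id", "rater", "timepoint", "total_score"}
        missing = needed - set(sym.columns)
        if missing:
            issue("symptoms.csv", "missing_columns", str(sorted(missing)))
        else:
            for r in sym[sym["total_score"] < 0].itertuples():
                issue("symptoms.csv", "negative_score",
                      f"{r.participant_id}/{r.rater}/{r.timepoint}: {r.total_score}")

    mat_dir = data_dir / "matrices"
    scan_ids = (list(phenotype["scan_id"]) if phenotype is not None
                else [p.stem for p in sorted(mat_dir.glob("*.txt"))] if mat_dir.exists() else [])
    for sid in scan_ids:
        path = mat_dir / f"{sid}.txt"
        if not path.exists():
            issue(f"matrices/{sid}.txt", "missing_file", "matrix not found")
            continue
        try:
            w = np.loadtxt(path)
        except Exception as e:  # noqa: BLE001
            issue(f"matrices/{sid}.txt", "unreadable", str(e))
            continue
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            issue(f"matrices/{sid}.txt", "not_square", str(getattr(w, "shape", "?")))
            continue
        if not np.allclose(w, w.T, atol=1e-12):
            issue(f"matrices/{sid}.txt", "asymmetric", "w(i,j) != w(j,i)")
        if np.any(np.diag(w) != 0):
            issue(f"matrices/{sid}.txt", "nonzero_diagonal", "self-loop weight")
        if np.any((w < 0) | (w > 1)):
            issue(f"matrices/{sid}.txt", "fa_out_of_range",
                  f"min={w.min():.4g} max={w.max():.4g}")
    return issues
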