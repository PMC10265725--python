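"""Regression-based reliable change index (RCI) for symptom ratings.

Post-injury symptom totals (parent- and child-rated, separately) are
regressed onto parent-rated premorbid totals in a reference sample; the
standardized change score for a participant is

    z = (post - (intercept + slope * premorbid)) / SEE

where SEE = sqrt(SS_resid / (n - 2)) is the regression's standard error of
the estimate.  TBI participants with z at or above the cutoff (default
1.645, one-tailed 5%: "persistent" means a reliable *increase*) are
classified as having persistent symptoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD_Z = 1.645


@dataclass(frozen=True)
class RCIModel:
    rater: str
    slope: float
    intercept: float
    see: float
    n_reference: int
    threshold_z: float = DEFAULT_THRESHOLD_Z

    def predict(self, premorbid):
        return self.intercept + self.slope * np.asarray(premorbid, dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass(frozen=True)
class SymptomClassification:
    participant_id: str
    rater: str
    z: float
    status: str  # "persistent" / "nonpersistent"


def fit_rci(
    premorbid,
    post,
    rater: str = "parent",
    threshold_z: float = DEFAULT_THRESHOLD_Z,
) -> RCIModel:
    """OLS of post-injury on premorbid scores; SEE from n-2 denominator."""
    x = np.asarray(premorbid, dtype=float)
    y = np.asarray(post, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("premorbid and post must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 reference pairs")
    if np.var(x) == 0:
        raise ValueError("premorbid scores are constant; slope unidentifiable")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    see = float(np.sqrt((resid**2).sum() / (n - 2)))
    if see <= 1e-10 * max(1.0, float(np.abs(y).max())):
        raise ValueError("zero standard error of the estimate (degenerate reference)")
    return RCIModel(rater=rater, slope=float(slope), intercept=float(intercept),
                    see=see, n_reference=n, threshold_z=threshold_z)


def score_and_classify(
    model: RCIModel, participant_id: str, premorbid: float, post: float
) -> SymptomClassification:
    """Standardized change score and persistent/nonpersistent label."""
    z = float((post - model.predict(premorbid)) / model.see)
    status = "persistent" if z >= model.threshold_z else "nonpersistent"
    return SymptomClassification(participant_id=participant_id, rater=model.rater,
                                 z=z, status=status)


def classify_cohort(
    symptoms: pd.DataFrame,
    tbi_ids: set[str] | None = None,
    reference: str = "all",
    oi_ids: set[str] | None = None,
    threshold_z: float = DEFAULT_THRESHOLD_Z,
) -> tuple[pd.DataFrame, dict[str, RCIModel]]:
    """Fit per-rater RCI models and classify every rated participant.

    ``symptoms`` follows the long schema (participant_id, rater, timepoint,
    total_score) with parent premorbid plus parent and child 1-month totals.
    ``reference`` selects the fitting sample: "all" complete pairs, or "oi"
    to restrict the reference regression to OI participants (requires
    ``oi_ids``).
    """
    pre = (symptoms.query("rater == 'parent' and timepoint == 'premorbid'")
           .set_index("participant_id")["total_score"])
    models: dict[str, RCIModel] = {}
    rows = []
    for rater in ("parent", "child"):
        post = (symptoms.query("rater == @rater and timepoint == '1month'")
                .set_index("participant_id")["total_score"])
        ids = pre.index.intersection(post.index)
        ref_ids = ids
        if reference == "oi":
            if oi_ids is None:
                raise ValueError("reference='oi' requires oi_ids")
            ref_ids = ids.intersection(sorted(oi_ids))
        elif reference != "all":
            raise ValueError(f"unknown reference sample {reference!r}")
        model = fit_rci(pre.loc[ref_ids], post.loc[ref_ids], rater=rater,
                        threshold_z=threshold_z)
        models[rater] = model
        for pid in ids:
            c = score_and_classify(model, pid, pre.loc[pid], post.loc[pid])
            rows.append((c.participant_id, c.rater, c.z, c.status))
    table = pd.DataFrame(rows, columns=["participant_id", "rater", "z", "status"])
    return table, models


def assign_symptom_groups(
    classifications: pd.DataFrame,
    phenotype: pd.DataFrame,
) -> pd.DataFrame:
    """Per-rater 3-level grouping: TBI-persistent / TBI-nonpersistent / OI.

    OI participants are never reclassified.  TBI participants without a
    1-month rating for a rater are excluded from that rater's symptom-group
    analyses (symptom_group = NA).
    """
    groups = phenotype[["participant_id", "group"]].drop_duplicates()
    out = []
    for rater in ("parent", "child"):
        cls = classifications.query("rater == @rater").set_index("participant_id")["status"]
        for r in groups.itertuples():
            if r.group == "OI":
                label = "OI"
            elif r.participant_id in cls.index:
                label = "TBI-" + cls.loc[r.participant_id]
            else:
                label = "NA"
            out.append((r.participant_id, rater, label))
    return pd.DataFrame(out, columns=["participant_id", "rater", "symptom_group"])
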