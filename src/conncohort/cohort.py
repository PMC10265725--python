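"""Synthetic longitudinal cohort generator with known ground truth.

Emulates the data structure of a two-group (mild TBI vs. orthopaedic
injury), five-site paediatric study: a post-acute MRI at 2-33 days
post-injury, one chronic MRI randomly assigned to ~3 or ~6 months,
parent-rated premorbid and parent/child-rated 1-month symptom totals, and
per-scan 90-node FA-weighted connectomes derived from a shared small-world
template with site, age and injected group effects applied at the edge
level.

Everything is drawn from a single integer seed; identical config + seed
reproduces byte-identical outputs.  All generator choices that the study
conditions do not pin down (template topology, edge-weight distribution,
symptom score model) are config-exposed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, write_matrix
from .parcellation import N_NODES, NODE_LABELS, nodes_of_region

# stream tags for deriving independent substreams from the master seed
_TAG_COHORT, _TAG_TEMPLATE, _TAG_SYMPTOMS, _TAG_SCAN = 1, 2, 3, 4


@dataclass(frozen=True)
class InjectedEffect:
    """Ground-truth edge-weight delta applied to edges incident to target regions.

    The condition is a conjunction of the optional fields; ``None`` means
    "any".  Ages are in years, days in days post-injury.
    """

    target_regions: tuple[str, ...]
    direction: int = -1
    magnitude: float = 0.0
    group: str | None = None            # "TBI" or "OI"
    symptom_status: str | None = None   # "persistent" / "nonpersistent"
    sex: str | None = None              # "M" / "F"
    age_min: float | None = None
    age_max: float | None = None
    min_days: float | None = None
    max_days: float | None = None

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("effect magnitude must be >= 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        for r in self.target_regions:
            nodes_of_region(r)  # raises KeyError for unknown regions

    def matches(self, p: "Participant", days: float) -> bool:
        if self.group is not None and p.group != self.group:
            return False
        if self.symptom_status is not None and p.latent_symptom_status != self.symptom_status:
            return False
        if self.sex is not None and p.sex != self.sex:
            return False
        if self.age_min is not None and p.age_at_injury < self.age_min:
            return False
        if self.age_max is not None and p.age_at_injury > self.age_max:
            return False
        if self.min_days is not None and days < self.min_days:
            return False
        if self.max_days is not None and days > self.max_days:
            return False
        return True


@dataclass(frozen=True)
class SiteEffect:
    """Additive shift (FA units) and multiplicative scale on edge weights."""

    shift: float = 0.0
    scale: float = 1.0


@dataclass(frozen=True)
class SymptomModel:
    """Generating model for symptom totals (rating-scale units).

    premorbid ~ round(Gamma(shape, scale)); 1-month post-injury total =
    intercept + slope * premorbid + TBI shift (+ persistent shift, in SEE
    units of the rater noise) + Gaussian noise, floored at 0.
    """

    premorbid_shape: float = 2.0
    premorbid_scale: float = 2.5
    slope: float = 0.8
    intercept: float = 1.0
    noise_sd: float = 3.0
    tbi_shift: float = 1.0
    persistent_shift_see: float = 2.0   # shift for latent-persistent, x noise_sd
    round_scores: bool = True


@dataclass
class CohortConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_tbi: int = 65
    n_oi: int = 35
    sites: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5")
    male_fraction: float = 0.60
    age_range: tuple[float, float] = (8.0, 16.99)
    postacute_day_range: tuple[float, float] = (2.0, 33.0)
    chronic_days: tuple[float, float] = (90.0, 180.0)
    chronic_assignment_prob: float = 0.5
    chronic_day_jitter_sd: float = 7.0
    attrition_chronic: float = 0.25
    persistent_fraction: float = 0.25
    site_effects: dict = field(default_factory=lambda: {
        "S1": SiteEffect(0.0, 1.0),
        "S2": SiteEffect(+0.02, 1.05),
        "S3": SiteEffect(-0.02, 0.95),
        "S4": SiteEffect(+0.01, 1.02),
        "S5": SiteEffect(-0.01, 0.98),
    })
    effect_spec: list = field(default_factory=list)
    noise_sd_edge: float = 0.02
    age_slope: float = 0.003            # FA units per year on every edge
    age_reference: float = 12.5         # years; edge shift is slope*(age - ref)
    # small-world template
    template_degree: int = 12
    template_rewire_p: float = 0.1
    template_beta: tuple[float, float] = (8.0, 8.0)
    template_weight_range: tuple[float, float] = (0.2, 0.8)
    isolation_rate: float = 0.0         # P(scan has one node's edges zeroed)
    symptoms: SymptomModel = field(default_factory=SymptomModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tbi <= 0 or self.n_oi <= 0:
            raise ValueError("group sizes must be positive")
        if not self.sites:
            raise ValueError("site list must not be empty")
        for p in (self.male_fraction, self.attrition_chronic,
                  self.persistent_fraction, self.chronic_assignment_prob,
                  self.isolation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        lo, hi = self.age_range
        if not (8.0 <= lo <= hi <= 16.99):
            raise ValueError("age_range must lie within [8, 16.99] years")
        if isinstance(self.symptoms, dict):
            self.symptoms = SymptomModel(**self.symptoms)
        self.site_effects = {
            k: (v if isinstance(v, SiteEffect) else SiteEffect(**v))
            for k, v in self.site_effects.items()
        }
        self.effect_spec = [
            e if isinstance(e, InjectedEffect)
            else InjectedEffect(**{**e, "target_regions": tuple(e["target_regions"])})
            for e in self.effect_spec
        ]


@dataclass(frozen=True)
class Participant:
    id: str
    group: str                      # "TBI" / "OI"
    site: str
    sex: str                        # "M" / "F"
    age_at_injury: float
    latent_symptom_status: str | None   # persistent/nonpersistent; None for OI


def _rng(config: CohortConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *tags]))


def _scan_rng(config: CohortConfig, scan_id: str) -> np.random.Generator:
    key = zlib.crc32(scan_id.encode()) & 0x7FFFFFFF
    return _rng(config, _TAG_SCAN, key)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int | None = None) -> np.ndarray | float:
    """Rejection-sampled truncated normal (cheap at these bounds)."""
    n = 1 if size is None else size
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return float(out[0]) if size is None else out


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[Participant], pd.DataFrame, pd.DataFrame]:
    """Draw participants, visits and symptom ratings.

    Returns ``(participants, phenotype, symptoms)`` where phenotype has one
    row per scan (participant_id, scan_id, group, site, sex, age_at_injury,
    days_post_injury, visit) and symptoms one row per rating
    (participant_id, rater, timepoint, total_score).
    """
    rng = _rng(config, _TAG_COHORT)
    n = config.n_tbi + config.n_oi
    width = max(4, len(str(n)))
    participants: list[Participant] = []
    for k in range(n):
        group = "TBI" if k < config.n_tbi else "OI"
        status = None
        if group == "TBI":
            status = ("persistent" if rng.random() < config.persistent_fraction
                      else "nonpersistent")
        participants.append(Participant(
            id=f"P{k + 1:0{width}d}",
            group=group,
            site=str(config.sites[rng.integers(0, len(config.sites))]),
            sex="M" if rng.random() < config.male_fraction else "F",
            age_at_injury=float(rng.uniform(*config.age_range)),
            latent_symptom_status=status,
        ))

    lo, hi = config.postacute_day_range
    rows = []
    for p in participants:
        day_pa = _truncnorm(rng, 11.0, 6.0, lo, hi)
        rows.append((p.id, f"{p.id}_postacute", p.group, p.site, p.sex,
                     p.age_at_injury, day_pa, "postacute"))
        drop = rng.random() < config.attrition_chronic
        target = (config.chronic_days[0]
                  if rng.random() < config.chronic_assignment_prob
                  else config.chronic_days[1])
        jitter = rng.normal(0.0, config.chronic_day_jitter_sd)
        if not drop:
            label = "3month" if target == config.chronic_days[0] else "6month"
            day = max(45.0, target + jitter)
            rows.append((p.id, f"{p.id}_{label}", p.group, p.site, p.sex,
                         p.age_at_injury, day, label))
    phenotype = pd.DataFrame(rows, columns=[
        "participant_id", "scan_id", "group", "site", "sex",
        "age_at_injury", "days_post_injury", "visit",
    ])

    symptoms = _generate_symptoms(config, participants)
    return participants, phenotype, symptoms


def _generate_symptoms(config: CohortConfig, participants: list[Participant]) -> pd.DataFrame:
    sm = config.symptoms
    rng = _rng(config, _TAG_SYMPTOMS)
    rows = []
    for p in participants:
        pre = rng.gamma(sm.premorbid_shape, sm.premorbid_scale)
        if sm.round_scores:
            pre = float(np.round(pre))
        shift = sm.tbi_shift if p.group == "TBI" else 0.0
        if p.latent_symptom_status == "persistent":
            shift += sm.persistent_shift_see * sm.noise_sd
        rows.append((p.id, "parent", "premorbid", max(pre, 0.0)))
        for rater in ("parent", "child"):
            post = sm.intercept + sm.slope * pre + shift + rng.normal(0.0, sm.noise_sd)
            if sm.round_scores:
                post = float(np.round(post))
            rows.append((p.id, rater, "1month", max(post, 0.0)))
    return pd.DataFrame(rows, columns=["participant_id", "rater", "timepoint", "total_score"])


# ---------------------------------------------------------------------------
# Connectome generation

def make_template(config: CohortConfig) -> np.ndarray:
    """Shared small-world base connectome (Watts-Strogatz ring, Beta weights)."""
    import networkx as nx

    rng = _rng(config, _TAG_TEMPLATE)
    g = nx.connected_watts_strogatz_graph(
        N_NODES, config.template_degree, config.template_rewire_p,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    w = np.zeros((N_NODES, N_NODES))
    a, b = config.template_beta
    wlo, whi = config.template_weight_range
    for u, v in sorted(g.edges()):
        wt = wlo + (whi - wlo) * rng.beta(a, b)
        w[u, v] = wt
        w[v, u] = wt
    return w


def generate_connectome(
    participant: Participant,
    days_post_injury: float,
    config: CohortConfig,
    visit: str = "scan",
    template: np.ndarray | None = None,
) -> ConnectivityMatrix:
    """One scan's 90x90 FA matrix: template + age trend + injected effects
    + site location/scale effects + edge noise, clipped to (0.01, 1]."""
    if participant.site not in config.site_effects and participant.site not in config.sites:
        raise KeyError(f"unknown site {participant.site!r}")
    if template is None:
        template = make_template(config)
    scan_id = f"{participant.id}_{visit}"
    rng = _scan_rng(config, scan_id)
    w = template.copy()
    mask = w > 0

    w[mask] += config.age_slope * (participant.age_at_injury - config.age_reference)

    for eff in config.effect_spec:
        if eff.matches(participant, days_post_injury):
            nodes = [i for r in eff.target_regions for i in nodes_of_region(r)]
            sel = np.zeros_like(mask)
            sel[nodes, :] = True
            sel[:, nodes] = True
            w[mask & sel] += eff.direction * eff.magnitude

    se = config.site_effects.get(participant.site, SiteEffect())
    w[mask] = se.scale * w[mask] + se.shift

    if config.noise_sd_edge > 0:
        noise = rng.normal(0.0, config.noise_sd_edge, size=w.shape)
        noise = (noise + noise.T) / np.sqrt(2.0)  # symmetric, sd preserved
        w[mask] += noise[mask]

    w[mask] = np.clip(w[mask], 0.01, 1.0)

    if config.isolation_rate > 0 and rng.random() < config.isolation_rate:
        node = int(rng.integers(0, N_NODES))
        w[node, :] = 0.0
        w[:, node] = 0.0

    return ConnectivityMatrix(scan_id=scan_id, weights=w, node_labels=list(NODE_LABELS))


def generate_scans(
    config: CohortConfig,
    participants: list[Participant],
    phenotype: pd.DataFrame,
) -> list[ConnectivityMatrix]:
    """All per-scan connectomes for a generated cohort, in phenotype order."""
    template = make_template(config)
    by_id = {p.id: p for p in participants}
    return [
        generate_connectome(by_id[r.participant_id], r.days_post_injury, config,
                            visit=r.visit, template=template)
        for r in phenotype.itertuples()
    ]


def write_cohort(
    config: CohortConfig,
    outdir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate and write phenotype.csv, symptoms.csv and matrix text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "matrices").mkdir(exist_ok=True)
    participants, phenotype, symptoms = generate_cohort(config)
    phenotype.to_csv(outdir / "phenotype.csv", index=False, float_format="%.6f")
    symptoms.to_csv(outdir / "symptoms.csv", index=False, float_format="%.6f")
    for scan in generate_scans(config, participants, phenotype):
        write_matrix(scan, outdir / "matrices" / f"{scan.scan_id}.txt")
    return phenotype, symptoms
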