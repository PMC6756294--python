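"""Synthetic longitudinal imaging + cognition + conversion cohorts.

Every pipeline stage is testable offline against known ground truth:

* ``make_phantom`` builds a nested-ellipsoid brain (CSF ventricles, WM
  core, GM shell) with periventricular lesion regions whose volume and
  diffusion profile grow with a latent per-subject severity;
* ``simulate_cognition`` couples per-domain cognitive slopes linearly to
  the baseline angle score and its annual change;
* ``simulate_conversion`` draws exponential conversion times whose hazard
  scales with the z-scored baseline angle, snaps observed onsets to the
  midpoint between bracketing visits and censors at the last attended
  visit;
* ``generate_cohort`` ties the three together, optionally running the real
  imaging pipeline (pooled histogram -> k-medians -> spectra -> reference
  -> angle) on the generated scans so the angle score is an emergent
  measurement rather than a copied latent variable.

Tissue eigenvalue defaults are generator conventions chosen so the four
tissue classes occupy distinct regions of the (p, q) plane; they are not
estimates of any acquired cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from dseg.cluster import assign_segments, build_pq_histogram, kmedians_fit
from dseg.pq import EigenvalueVolume, PQVolume, compute_pq
from dseg.spectra import compute_spectrum
from dseg.theta import select_reference, theta_series

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "make_phantom",
    "simulate_cognition",
    "simulate_conversion",
    "generate_cohort",
    "calibrate_baseline_hazard",
    "paper_like_config",
    "DOMAINS",
]

DOMAINS = ("EF", "IPS", "WkM", "EM", "GC")

_DEFAULT_TISSUE_MEANS = {
    "CSF": (3.0e-3, 3.0e-3, 3.0e-3),
    "WM": (1.7e-3, 0.4e-3, 0.3e-3),
    "GM": (1.1e-3, 0.9e-3, 0.8e-3),
    "WMH": (1.4e-3, 1.0e-3, 0.9e-3),
}


@dataclass
class SyntheticConfig:
    """Generator parameters; all effect sizes are free design choices."""

    n_subjects: int = 99
    n_healthy: int = 10
    visit_times_imaging: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    visit_times_cognition: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    grid_size: int = 32
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)
    tissue_means: dict = field(default_factory=lambda: dict(_DEFAULT_TISSUE_MEANS))
    tissue_sd: float = 0.08e-3
    wmh_growth: float = 0.6  # lesion-band width per unit severity
    wmh_profile_shift: float = 0.25e-3  # per unit severity, added to lesion eigenvalues
    # latent disease severity
    severity_baseline_mean: float = 0.5
    severity_baseline_sd: float = 0.3
    severity_rate_mean: float = 0.15
    severity_rate_sd: float = 0.08
    severity_rate_corr: float = 0.5  # corr(baseline severity, progression rate)
    # cognition coupling: slope_d = a0 + a1*theta_baseline + a2*theta_slope + noise
    cog_alpha0: dict = field(
        default_factory=lambda: {"EF": -0.03, "IPS": -0.03, "WkM": 0.0, "EM": 0.0, "GC": -0.03}
    )
    cog_alpha1: dict = field(
        default_factory=lambda: {"EF": -0.5, "IPS": -0.35, "WkM": 0.0, "EM": 0.0, "GC": -0.45}
    )
    cog_alpha2: dict = field(
        default_factory=lambda: {"EF": -2.0, "IPS": -1.2, "WkM": 0.0, "EM": 0.0, "GC": -1.6}
    )
    cog_slope_sd: float = 0.05
    cog_visit_sd: float = 0.15
    cog_baseline_coupling: float = -1.0
    cog_baseline_sd: float = 0.3
    # conversion model
    log_hr_per_sd: float = float(np.log(3.3))
    target_event_fraction: float = 0.18
    baseline_hazard: float | None = None  # calibrated when None
    dropout_rate: float = 0.04  # yearly probability of leaving after year 1
    # demographics
    age_mean: float = 68.4
    age_sd: float = 10.0
    male_fraction: float = 0.66
    iq_mean: float = 100.0
    iq_sd: float = 12.0
    # angle measurement
    theta_source: str = "imaging"  # or "latent"
    latent_theta0: float = 0.12
    latent_theta_per_severity: float = 0.3
    latent_theta_noise_sd: float = 0.015
    # pipeline settings used when theta_source == "imaging"
    n_bins: tuple[int, int] = (128, 128)
    k: int = 16
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("tissue_sd", "severity_baseline_sd", "severity_rate_sd", "cog_slope_sd",
                     "cog_visit_sd", "latent_theta_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for visits in (self.visit_times_imaging, self.visit_times_cognition):
            if np.any(np.diff(visits) <= 0):
                raise ValueError("visit times must be strictly increasing")
        if not 0 < self.target_event_fraction < 1:
            raise ValueError("target_event_fraction must lie in (0, 1)")
        if self.theta_source not in ("imaging", "latent"):
            raise ValueError("theta_source must be 'imaging' or 'latent'")

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["visit_times_imaging"] = list(self.visit_times_imaging)
        payload["visit_times_cognition"] = list(self.visit_times_cognition)
        payload["voxel_size"] = list(self.voxel_size)
        payload["n_bins"] = list(self.n_bins)
        payload["tissue_means"] = {k: list(v) for k, v in self.tissue_means.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        for key in ("visit_times_imaging", "visit_times_cognition", "voxel_size", "n_bins"):
            if key in payload:
                payload[key] = tuple(payload[key])
        if "tissue_means" in payload:
            payload["tissue_means"] = {k: tuple(v) for k, v in payload["tissue_means"].items()}
        return cls(**payload)


@dataclass
class SyntheticTruth:
    """Ground truth hidden from analysis stages."""

    subjects: pd.DataFrame  # severity0, rate, theta latent terms, true event time
    cognitive_slopes: pd.DataFrame  # true slope per subject x domain


@dataclass
class SyntheticCohort:
    cohort: pd.DataFrame  # one row per subject-visit (cognition grid)
    subjects: pd.DataFrame  # one row per subject (baseline + derived angle terms)
    truth: SyntheticTruth
    config: SyntheticConfig
    model: object = None  # DsegModel when theta_source == "imaging"
    reference: object = None
    spectra: list = field(default_factory=list)


@lru_cache(maxsize=8)
def _geometry(grid_size: int):
    """Tissue masks and the normalised ventricle-distance field for a grid."""
    if grid_size < 16:
        raise ValueError("grid too small: need grid_size >= 16 to hold all compartments")
    ax = np.linspace(-1.0, 1.0, grid_size)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    brain = (x / 0.92) ** 2 + (y / 0.85) ** 2 + (z / 0.80) ** 2 <= 1.0
    wm_core = (x / 0.62) ** 2 + (y / 0.58) ** 2 + (z / 0.55) ** 2 <= 1.0
    rho = np.minimum(
        np.sqrt(((x - 0.18) / 0.14) ** 2 + (y / 0.28) ** 2 + ((z - 0.05) / 0.18) ** 2),
        np.sqrt(((x + 0.18) / 0.14) ** 2 + (y / 0.28) ** 2 + ((z - 0.05) / 0.18) ** 2),
    )
    ventricles = (rho <= 1.0) & brain
    gm = brain & ~wm_core
    wm = wm_core & brain & ~ventricles
    return brain, gm, wm, ventricles, rho


def make_phantom(
    config: SyntheticConfig,
    subject: int,
    visit: float,
    severity: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EigenvalueVolume:
    """Nested-ellipsoid eigenvalue phantom for one subject-visit.

    The lesion compartment is the band of WM voxels within a normalised
    distance ``wmh_growth * severity`` of the ventricle surfaces, so its
    voxel count is non-decreasing in severity and exactly zero at severity
    0.  Determinism: when no generator is supplied one is derived from
    ``(rng_seed, subject, visit)``.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.rng_seed, 7919, int(subject), int(round(visit * 1000))])
        )
    brain, gm, wm, ventricles, rho = _geometry(config.grid_size)
    wmh = wm & (rho <= 1.0 + config.wmh_growth * max(float(severity), 0.0))
    wm_clean = wm & ~wmh

    lambdas = np.zeros(brain.shape + (3,), dtype=float)
    for tissue, tissue_mask in (("CSF", ventricles), ("GM", gm), ("WM", wm_clean), ("WMH", wmh)):
        n = int(tissue_mask.sum())
        if n == 0:
            continue
        mean = np.array(config.tissue_means[tissue], dtype=float)
        if tissue == "WMH":
            mean = mean + config.wmh_profile_shift * min(max(float(severity), 0.0), 2.0)
        draws = mean + rng.normal(0.0, config.tissue_sd, size=(n, 3))
        draws = np.clip(draws, 0.0, None)
        lambdas[tissue_mask] = -np.sort(-draws, axis=1)
    return EigenvalueVolume(
        lambdas=lambdas,
        mask=brain,
        voxel_size=config.voxel_size,
        provenance={"subject": int(subject), "visit": float(visit), "severity": float(severity)},
    )


def lesion_voxel_count(config: SyntheticConfig, severity: float) -> int:
    """Number of lesion voxels implied by a severity (construction oracle)."""
    _, _, wm, _, rho = _geometry(config.grid_size)
    return int(np.sum(wm & (rho <= 1.0 + config.wmh_growth * max(float(severity), 0.0))))


def calibrate_baseline_hazard(
    target_fraction: float,
    log_hr_per_sd: float,
    horizon: float = 5.0,
    z: np.ndarray | None = None,
) -> float:
    """Baseline hazard giving the target expected event fraction by the horizon.

    Expectation taken over the supplied z-scores (or a Gauss-Hermite
    approximation of a standard normal) for hazard ``h0 * exp(beta * z)``.
    """
    if z is None:
        nodes, weights = np.polynomial.hermite_e.hermegauss(61)
        w = weights / weights.sum()
        z, w = nodes, w
    else:
        z = np.asarray(z, float)
        w = np.full(len(z), 1.0 / len(z))

    def frac(log_h0: float) -> float:
        h = np.exp(log_h0 + log_hr_per_sd * z)
        return float(np.sum(w * (1.0 - np.exp(-horizon * h)))) - target_fraction

    return float(np.exp(brentq(frac, -20.0, 5.0, xtol=1e-12)))


def _draw_severity(config: SyntheticConfig, rng: np.random.Generator, n: int):
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = config.severity_rate_corr
    s0 = np.clip(config.severity_baseline_mean + config.severity_baseline_sd * z1, 0.0, None)
    rate = np.clip(
        config.severity_rate_mean
        + config.severity_rate_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2),
        0.0,
        None,
    )
    return s0, rate


def simulate_cognition(
    config: SyntheticConfig,
    subjects: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Visit-level cognitive composites coupled to the angle score.

    ``subjects`` must carry ``theta_baseline`` and ``theta_slope`` columns
    plus ``last_attended``.  Returns (long visit table, true slope table).
    """
    rows = []
    slope_rows = []
    for _, subj in subjects.iterrows():
        tb, ts = float(subj["theta_baseline"]), float(subj["theta_slope"])
        slopes = {}
        baselines = {}
        for d in DOMAINS:
            slopes[d] = (
                config.cog_alpha0[d]
                + config.cog_alpha1[d] * tb
                + config.cog_alpha2[d] * ts
                + rng.normal(0.0, config.cog_slope_sd)
            )
            baselines[d] = config.cog_baseline_coupling * tb + rng.normal(
                0.0, config.cog_baseline_sd
            )
        slope_rows.append({"subject_id": subj["subject_id"], **slopes})
        for t in config.visit_times_cognition:
            if t > subj["last_attended"] + 1e-9:
                break
            row = {"subject_id": subj["subject_id"], "visit_time": float(t)}
            for d in DOMAINS:
                row[d] = baselines[d] + slopes[d] * t + rng.normal(0.0, config.cog_visit_sd)
            rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(slope_rows).set_index("subject_id")


def simulate_conversion(
    config: SyntheticConfig,
    subjects: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Event times from an exponential hazard on z-scored baseline angle.

    Observed onsets are snapped to the midpoint between the attended visits
    bracketing the true event; non-events are censored at the last attended
    visit.
    """
    tb = subjects["theta_baseline"].to_numpy(float)
    sd = tb.std(ddof=1) if len(tb) > 1 else 0.0
    z = (tb - tb.mean()) / sd if sd > 0 else np.zeros_like(tb)
    h0 = config.baseline_hazard
    if h0 is None:
        h0 = calibrate_baseline_hazard(
            config.target_event_fraction,
            config.log_hr_per_sd,
            horizon=float(config.visit_times_cognition[-1]),
            z=z,
        )
    hazard = h0 * np.exp(config.log_hr_per_sd * z)
    event_true = rng.exponential(1.0 / hazard)

    visits = np.asarray(config.visit_times_cognition, float)
    out = []
    for i, (_, subj) in enumerate(subjects.iterrows()):
        last = float(subj["last_attended"])
        attended = visits[visits <= last + 1e-9]
        if event_true[i] <= last:
            nxt_idx = int(np.searchsorted(attended, event_true[i], side="left"))
            nxt_idx = max(nxt_idx, 1)
            onset = 0.5 * (attended[nxt_idx - 1] + attended[nxt_idx])
            out.append(
                {
                    "subject_id": subj["subject_id"],
                    "converted": True,
                    "event_observed": True,
                    "event_time": float(onset),
                    "event_time_true": float(event_true[i]),
                }
            )
        else:
            out.append(
                {
                    "subject_id": subj["subject_id"],
                    "converted": False,
                    "event_observed": False,
                    "event_time": float(max(attended[-1], visits[1])),
                    "event_time_true": float(event_true[i]),
                }
            )
    return pd.DataFrame(out)


def _theta_slope_ols(times: np.ndarray, thetas: np.ndarray) -> float:
    t = times - times.mean()
    if np.allclose(t, 0):
        return 0.0
    return float(np.sum(t * (thetas - thetas.mean())) / np.sum(t * t))


def _imaging_thetas(config: SyntheticConfig, severity: pd.DataFrame, rng_seed: int):
    """Run the real imaging pipeline on phantom scans.

    Returns per-scan angle table plus the fitted model, reference and
    spectra.  Healthy pool subjects are generated at severity 0 and pooled
    into the histogram alongside the patient scans, mirroring a joint
    segmentation of the healthy and disease samples.
    """
    scans = []  # (subject_id, visit, PQVolume over masked points)
    for subj_id, visit, sev in severity.itertuples(index=False):
        vol = make_phantom(config, int(subj_id.lstrip("SH")), visit, severity=sev)
        pts = compute_pq(vol).masked_points().astype(np.float32)
        scans.append((subj_id, visit, pts))
    healthy_ids = []
    for h in range(config.n_healthy):
        hid = f"H{h:03d}"
        healthy_ids.append(hid)
        vol = make_phantom(config, 100000 + h, 0.0, severity=0.0)
        pts = compute_pq(vol).masked_points().astype(np.float32)
        scans.append((hid, 0.0, pts))

    def as_pq(points: np.ndarray) -> PQVolume:
        shape = (len(points), 1, 1)
        return PQVolume(
            p=points[:, 0].astype(float).reshape(shape),
            q=points[:, 1].astype(float).reshape(shape),
            mask=np.ones(shape, dtype=bool),
        )

    hist = build_pq_histogram([pts for _, _, pts in scans], n_bins=config.n_bins)
    model = kmedians_fit(hist, k=config.k)
    spectra = []
    for subj_id, visit, pts in scans:
        labels = assign_segments(as_pq(pts), model)
        spectra.append(compute_spectrum(labels, subject_id=subj_id, visit_time=visit))
    healthy_spectra = [s for s in spectra if s.subject_id in set(healthy_ids)]
    reference = select_reference(healthy_spectra)
    scores = theta_series(spectra, reference)
    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in scores],
            "visit_time": [s.visit_time for s in scores],
            "theta": [s.theta for s in scores],
        }
    )
    return table, model, reference, spectra


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """End-to-end synthetic dataset with recorded ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 104729]))
    n = config.n_subjects
    ids = [f"S{i:04d}" for i in range(n)]
    s0, rate = _draw_severity(config, rng, n)
    age = config.age_mean + config.age_sd * rng.standard_normal(n)
    sex = (rng.random(n) < config.male_fraction).astype(int)
    iq = config.iq_mean + config.iq_sd * rng.standard_normal(n)

    # attendance: everyone attends baseline and year 1; yearly dropout after
    follow_up = np.asarray(config.visit_times_cognition[1:], float)
    last_attended = np.full(n, follow_up[-1])
    for i in range(n):
        for j, t in enumerate(follow_up[1:], start=1):
            if rng.random() < config.dropout_rate:
                last_attended[i] = follow_up[j - 1]
                break

    model = reference = None
    spectra: list = []
    imaging_visits = np.asarray(config.visit_times_imaging, float)
    if config.theta_source == "imaging":
        sev_rows = [
            (ids[i], float(t), float(s0[i] + rate[i] * t))
            for i in range(n)
            for t in imaging_visits
            if t <= last_attended[i] + 1e-9 or t == 0.0
        ]
        sev_df = pd.DataFrame(sev_rows, columns=["subject_id", "visit_time", "severity"])
        theta_table, model, reference, spectra = _imaging_thetas(config, sev_df, config.rng_seed)
        theta_table = theta_table[theta_table["subject_id"].str.startswith("S")]
    else:
        rows = []
        subj_noise = rng.normal(0.0, config.latent_theta_noise_sd, size=n)
        for i in range(n):
            for t in imaging_visits:
                if t > last_attended[i] + 1e-9 and t != 0.0:
                    continue
                sev = s0[i] + rate[i] * t
                theta = (
                    config.latent_theta0
                    + config.latent_theta_per_severity * sev
                    + subj_noise[i]
                    + rng.normal(0.0, 0.25 * config.latent_theta_noise_sd)
                )
                rows.append({"subject_id": ids[i], "visit_time": float(t), "theta": theta})
        theta_table = pd.DataFrame(rows)

    tb, ts = {}, {}
    for sid, grp in theta_table.groupby("subject_id"):
        grp = grp.sort_values("visit_time")
        tb[sid] = float(grp["theta"].iloc[0])
        ts[sid] = _theta_slope_ols(grp["visit_time"].to_numpy(), grp["theta"].to_numpy())

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "age_baseline": age,
            "sex": sex,
            "premorbid_iq": iq,
            "theta_baseline": [tb[i] for i in ids],
            "theta_slope": [ts[i] for i in ids],
            "last_attended": last_attended,
        }
    )
    conv = simulate_conversion(config, subjects, rng)
    subjects = subjects.merge(conv.drop(columns=["event_time_true"]), on="subject_id")
    cog, true_slopes = simulate_cognition(config, subjects, rng)

    cohort = cog.merge(
        subjects[
            [
                "subject_id",
                "age_baseline",
                "sex",
                "premorbid_iq",
                "converted",
                "event_time",
                "event_observed",
            ]
        ],
        on="subject_id",
    ).merge(theta_table, on=["subject_id", "visit_time"], how="left")

    truth = SyntheticTruth(
        subjects=pd.DataFrame(
            {
                "subject_id": ids,
                "severity_baseline": s0,
                "severity_rate": rate,
                "event_time_true": conv["event_time_true"].to_numpy(),
            }
        ).set_index("subject_id"),
        cognitive_slopes=true_slopes,
    )
    return SyntheticCohort(
        cohort=cohort,
        subjects=subjects,
        truth=truth,
        config=config,
        model=model,
        reference=reference,
        spectra=spectra,
    )


def paper_like_config(**overrides) -> SyntheticConfig:
    """Default cohort configuration: n=99, ~18% conversion, 3y imaging /
    5y cognition follow-up."""
    return SyntheticConfig(**overrides)
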