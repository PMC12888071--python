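"""Synthetic multi-method survey campaigns with known ground truth.

Emulates the study design the pipeline targets: ten 2-km^2 sampling
locations, each with a forest and an open survey area; continuous
40-day camera-trap and acoustic-recorder records scored in 5-day
occasions; three point-transect visits at least 5 days apart within
06:00-18:00; recorder battery dropout truncating the record tail.

Occupied sites emit detected events as an inhomogeneous Poisson process
whose hourly rate is a base rate (solved in closed form from the
target per-occasion detection probability) modulated by a 24-bin diel
activity profile: crepuscular call peaks for the acoustic method,
dawn-to-dusk activity for camera traps.  Only true detections are
generated — the occupancy framework downstream assumes no false
positives (a false-positive hook exists but defaults to zero).

Everything is deterministic under a seed, so pipeline tests and
parameter-recovery experiments need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detection_data import ValidationError

__all__ = [
    "SimulationScenario",
    "GroundTruth",
    "SimulatedCampaign",
    "default_diel_profiles",
    "rate_from_occasion_p",
    "simulate_campaign",
    "scenario_field_defaults",
]

CAMPAIGN_START = pd.Timestamp("2022-11-21 00:00")


def _normalize(profile: Sequence[float]) -> np.ndarray:
    w = np.asarray(profile, dtype=float)
    if w.shape != (24,):
        raise ValidationError("a diel profile must have 24 hourly weights")
    if (w < 0).any() or w.sum() <= 0:
        raise ValidationError("diel weights must be non-negative and not all zero")
    return w * (24.0 / w.sum())  # mean weight 1 over the day


def default_diel_profiles() -> dict[str, np.ndarray]:
    """Qualitative diel activity shapes per method.

    PAM: crepuscular loud-call peaks at 05-07 and 17-19 over a low
    around-the-clock floor.  CT: activity from 05:00 to 20:00.  PT:
    detections concentrated in the early morning (06-09) within the
    06:00-18:00 survey window.
    """
    pam = np.full(24, 0.4)
    pam[[5, 6, 17, 18]] = 4.0
    ct = np.zeros(24)
    ct[5:20] = 1.0
    pt = np.zeros(24)
    pt[6:9] = 1.0
    pt[9:18] = 0.25
    return {"PAM": _normalize(pam), "CT": _normalize(ct), "PT": _normalize(pt)}


def rate_from_occasion_p(
    p_target: float, occasion_hours: float, diel_profile: Sequence[float] | None = None
) -> float:
    """Base hourly event rate matching a per-occasion detection probability.

    Solves ``1 - exp(-lambda * W) = p_target`` for lambda, where W is
    the profile-weighted survey time of one occasion.  The profile is
    normalized to mean weight 1, so for occasions spanning whole days
    W equals ``occasion_hours`` and the inversion is exact in closed
    form regardless of the profile's shape.
    """
    if not 0.0 < p_target < 1.0:
        raise ValidationError(f"p_target must lie in (0, 1), got {p_target}")
    if occasion_hours <= 0:
        raise ValidationError("occasion_hours must be positive")
    if diel_profile is not None:
        _normalize(diel_profile)  # validate; normalization keeps W = occasion_hours
    return float(-np.log1p(-p_target) / occasion_hours)


@dataclass(frozen=True)
class PamDeployment:
    """One recorder placement with its dropout behaviour.

    ``active_days_range`` is the inclusive range from which the number
    of days actually recorded (before the batteries die) is drawn.
    """

    location_index: int
    habitat: str
    deploy_offset_days: int = 0
    deploy_days: int = 40
    active_days_range: tuple[int, int] = (24, 40)


#: the deployed-recorder layout of the emulated campaign: three 40-day
#: units (24-40 active days) and four 15-day units (5-11 active days),
#: five in forest and two in open areas.
FIELD_PAM_LAYOUT = (
    PamDeployment(0, "forest", 0, 40, (24, 40)),
    PamDeployment(1, "forest", 0, 40, (24, 40)),
    PamDeployment(0, "open", 0, 40, (24, 40)),
    PamDeployment(2, "forest", 25, 15, (5, 11)),
    PamDeployment(3, "forest", 25, 15, (5, 11)),
    PamDeployment(4, "forest", 25, 15, (5, 11)),
    PamDeployment(1, "open", 25, 15, (5, 11)),
)


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth design of one synthetic campaign."""

    n_locations: int = 10
    habitats: tuple[str, ...] = ("forest", "open")
    psi: float = 1.0
    p_targets: Mapping[str, float] = field(
        default_factory=lambda: {"PT": 0.33, "CT": 0.65, "PAM": 0.79}
    )
    campaign_days: int = 40
    occasion_days: int = 5
    pt_visits: int = 3
    min_visit_gap_days: int = 5
    visit_minutes: int = 200
    ct_omit: tuple[tuple[int, str], ...] = ()   # (location_index, habitat) without a camera
    pam_layout: tuple[PamDeployment, ...] | str = "all"
    diel_profiles: Mapping[str, np.ndarray] | None = None
    false_positive_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.psi <= 1.0:
            raise ValidationError("psi must lie in [0, 1]")
        for m, p in self.p_targets.items():
            if not 0.0 < p < 1.0:
                raise ValidationError(f"p target for {m} must lie in (0, 1)")
        span = (self.pt_visits - 1) * self.min_visit_gap_days + 1
        if span > self.campaign_days:
            raise ValidationError(
                f"campaign of {self.campaign_days} days cannot host "
                f"{self.pt_visits} visits {self.min_visit_gap_days} days apart"
            )

    @property
    def n_occasions(self) -> int:
        return self.campaign_days // self.occasion_days

    @property
    def occasion_hours(self) -> float:
        return self.occasion_days * 24.0

    def profiles(self) -> dict[str, np.ndarray]:
        base = default_diel_profiles()
        if self.diel_profiles:
            base.update({k: _normalize(v) for k, v in self.diel_profiles.items()})
        return base


def scenario_field_defaults() -> SimulationScenario:
    """The emulated study design: 10 locations x 2 habitats, 40 days,
    5-day occasions, 3 transect visits, one open area without a camera,
    seven recorders with battery dropout."""
    return SimulationScenario(
        ct_omit=((9, "open"),),
        pam_layout=FIELD_PAM_LAYOUT,
    )


@dataclass
class GroundTruth:
    """Simulation bookkeeping: what the campaign really contained."""

    z: dict[str, int]              # site_id -> occupancy state
    rate: dict[str, float]        # site_id -> base hourly event rate (sensors)
    p_occasion: dict[str, float]   # site_id -> implied per-occasion detection prob


@dataclass
class SimulatedCampaign:
    events: pd.DataFrame
    sites: pd.DataFrame
    coverage: pd.DataFrame         # sensor site_id, start, end (active span)
    truth: GroundTruth


def _sensor_events(
    rng: np.random.Generator,
    site_id: str,
    method: str,
    lam: float,
    profile: np.ndarray,
    start: pd.Timestamp,
    active_days: int,
) -> pd.DataFrame:
    n_hours = active_days * 24
    hod = np.arange(n_hours) % 24
    rates = lam * profile[hod]
    counts = rng.poisson(rates)
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=["site_id", "method", "timestamp", "detected", "visit_index"])
    hour_idx = np.repeat(np.arange(n_hours), counts)
    offsets = rng.random(total)
    ts = start + pd.to_timedelta((hour_idx + offsets) * 3600.0, unit="s")
    return pd.DataFrame(
        {
            "site_id": site_id,
            "method": method,
            "timestamp": ts.floor("min"),
            "detected": True,
            "visit_index": pd.array([pd.NA] * total, dtype="Int64"),
        }
    )


def _visit_days(rng: np.random.Generator, scenario: SimulationScenario) -> np.ndarray:
    """Visit days >= min_gap apart, uniform over the feasible day set."""
    n, g = scenario.pt_visits, scenario.min_visit_gap_days
    slack = scenario.campaign_days - 1 - (n - 1) * g
    u = np.sort(rng.random(n)) * slack
    return np.floor(u).astype(int) + np.arange(n) * g


def simulate_campaign(
    scenario: SimulationScenario, seed: int, start: pd.Timestamp = CAMPAIGN_START
) -> SimulatedCampaign:
    """Generate one synthetic multi-method campaign.

    Occupied sites (z ~ Bernoulli(psi)) emit detected sensor events as
    an inhomogeneous Poisson stream over each device's active span;
    recorder dropout truncates the tail of the record.  Point-transect
    visits are scheduled at least ``min_visit_gap_days`` apart, start
    between 06:00 and 18:00, and detect with the target visit-level
    probability; non-detection visits are recorded too.  Deterministic
    under the seed.
    """
    rng = np.random.default_rng(seed)
    profiles = scenario.profiles()
    occ_hours = scenario.occasion_hours

    sites_rows, cov_rows, event_frames = [], [], []
    z, rate, p_occ = {}, {}, {}

    locations = [f"L{i + 1:02d}" for i in range(scenario.n_locations)]

    def add_site(method: str, loc_i: int, habitat: str) -> str:
        sid = f"{locations[loc_i]}-{habitat}-{method}"
        sites_rows.append(
            {"site_id": sid, "location_id": locations[loc_i], "habitat": habitat,
             "method": method}
        )
        z[sid] = int(rng.random() < scenario.psi)
        return sid

    # --- point transects: one per location x habitat -----------------------
    p_pt = scenario.p_targets["PT"]
    pt_profile = profiles["PT"]
    day_hours = np.arange(24)
    visit_window = (day_hours >= 6) & (day_hours < 18)
    pt_hour_w = np.where(visit_window, pt_profile, 0.0)
    pt_hour_w = pt_hour_w / pt_hour_w.sum()
    pt_rows: dict[str, list] = {"site_id": [], "minutes": [], "detected": [], "visit": []}
    for li in range(scenario.n_locations):
        for hab in scenario.habitats:
            sid = add_site("PT", li, hab)
            rate[sid] = np.nan
            p_occ[sid] = p_pt if z[sid] else 0.0
            days = _visit_days(rng, scenario)
            for vi, d in enumerate(days, start=1):
                detected = bool(z[sid]) and bool(rng.random() < p_pt)
                hour = int(rng.choice(24, p=pt_hour_w))
                minute = int(rng.integers(0, 60))
                pt_rows["site_id"].append(sid)
                pt_rows["minutes"].append(int(d) * 1440 + hour * 60 + minute)
                pt_rows["detected"].append(detected)
                pt_rows["visit"].append(vi)
    if pt_rows["site_id"]:
        event_frames.append(
            pd.DataFrame(
                {
                    "site_id": pt_rows["site_id"],
                    "method": "PT",
                    "timestamp": start + pd.to_timedelta(pt_rows["minutes"], unit="m"),
                    "detected": pt_rows["detected"],
                    "visit_index": pd.array(pt_rows["visit"], dtype="Int64"),
                }
            )
        )

    # --- camera traps: full 40-day coverage --------------------------------
    lam_ct = rate_from_occasion_p(scenario.p_targets["CT"], occ_hours)
    for li in range(scenario.n_locations):
        for hab in scenario.habitats:
            if (li, hab) in scenario.ct_omit:
                continue
            sid = add_site("CT", li, hab)
            rate[sid] = lam_ct
            p_occ[sid] = scenario.p_targets["CT"] if z[sid] else 0.0
            cov_rows.append(
                {"site_id": sid, "start": start,
                 "end": start + pd.Timedelta(days=scenario.campaign_days)}
            )
            if z[sid]:
                event_frames.append(
                    _sensor_events(rng, sid, "CT", lam_ct, profiles["CT"], start,
                                   scenario.campaign_days)
                )

    # --- acoustic recorders: layout with battery dropout -------------------
    lam_pam = rate_from_occasion_p(scenario.p_targets["PAM"], occ_hours)
    if scenario.pam_layout == "all":
        layout = tuple(
            PamDeployment(li, hab, 0, scenario.campaign_days,
                          (scenario.campaign_days, scenario.campaign_days))
            for li in range(scenario.n_locations)
            for hab in scenario.habitats
        )
    else:
        layout = scenario.pam_layout
    for dep in layout:
        sid = add_site("PAM", dep.location_index, dep.habitat)
        rate[sid] = lam_pam
        p_occ[sid] = scenario.p_targets["PAM"] if z[sid] else 0.0
        lo, hi = dep.active_days_range
        active = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        active = min(active, dep.deploy_days)
        dev_start = start + pd.Timedelta(days=dep.deploy_offset_days)
        cov_rows.append(
            {"site_id": sid, "start": dev_start,
             "end": dev_start + pd.Timedelta(days=active)}
        )
        if z[sid]:
            event_frames.append(
                _sensor_events(rng, sid, "PAM", lam_pam, profiles["PAM"], dev_start, active)
            )

    events = (
        pd.concat([f for f in event_frames if len(f)], ignore_index=True)
        if any(len(f) for f in event_frames)
        else pd.DataFrame(columns=["site_id", "method", "timestamp", "detected", "visit_index"])
    )
    events = events.sort_values(["method", "site_id", "timestamp"], kind="mergesort")
    events = events.reset_index(drop=True)
    return SimulatedCampaign(
        events=events,
        sites=pd.DataFrame(sites_rows),
        coverage=pd.DataFrame(cov_rows),
        truth=GroundTruth(z=z, rate=rate, p_occasion=p_occ),
    )
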