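"""Raw survey events to occasion-level detection histories.

The entry point of the pipeline is a table of timestamped survey events
(camera-trap triggers, acoustic-recorder detections, point-transect visit
outcomes).  This module validates that table, collapses it into per-site
detection histories — one row per survey site, one column per survey
occasion, cells in {1, 0, NA} — fuses histories from co-located methods,
and computes naive (detection-uncorrected) summaries: detection rates by
method and habitat, latency to first detection, pairwise method overlap,
and diel activity profiles.

Conventions
-----------
* A sensor survey occasion is a block of ``occasion_days`` consecutive
  days anchored at each device's own deployment start; windows are
  half-open ``[t0 + k*D, t0 + (k+1)*D)``.
* A point-transect occasion is one visit; a transect is scored 1 if the
  species was detected at at least one of its sampling points.
* Fusion of co-located methods is a cell-wise OR with NA absorption:
  1 if any method detected, 0 if at least one method was active with no
  detection, NA only when no method was active.
* Timestamps are timezone-naive local clock time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

METHODS = ("PT", "CT", "PAM")
HABITATS = ("forest", "open")

#: canonical ordering used when labelling fused method combinations
_METHOD_RANK = {m: i for i, m in enumerate(METHODS)}

EVENT_COLUMNS = ("site_id", "method", "timestamp", "detected", "visit_index")


class ValidationError(ValueError):
    """Input values violate a domain invariant."""


class SchemaError(ValidationError):
    """Input table does not conform to the expected schema."""


# ---------------------------------------------------------------------------
# Event I/O
# ---------------------------------------------------------------------------

def read_events(
    path,
    schema: Mapping[str, str] | None = None,
    campaign: tuple | None = None,
) -> pd.DataFrame:
    """Read and validate a raw survey-event CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from canonical column names (``site_id``,
        ``method``, ``timestamp``, ``detected``, ``visit_index``) to the
        names used in the file.
    campaign
        Optional ``(start, end)`` datetimes; rows outside the window are
        dropped with a warning reporting how many were rejected.

    Returns
    -------
    pandas.DataFrame
        Columns ``site_id`` (str), ``method`` (one of PT/CT/PAM),
        ``timestamp`` (datetime64, minute resolution), ``detected``
        (bool), ``visit_index`` (nullable integer, PT only).
    """
    raw = pd.read_csv(path, dtype=str)
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in ("site_id", "method", "timestamp", "detected") if c not in raw.columns]
    if missing:
        raise SchemaError(f"events table is missing required column(s): {missing}")

    bad_method = ~raw["method"].isin(METHODS)
    if bad_method.any():
        offending = sorted(raw.loc[bad_method, "method"].unique())
        raise SchemaError(
            f"unknown method value(s) {offending}; allowed values are {list(METHODS)}"
        )

    ts = pd.to_datetime(raw["timestamp"], errors="coerce")
    if ts.isna().any():
        lines = (raw.index[ts.isna()] + 2).tolist()  # +2: header + 1-based
        raise ValidationError(f"unparseable timestamp(s) at CSV line(s) {lines}")

    detected = raw["detected"].astype(str).str.strip()
    ok = detected.isin({"0", "1", "True", "False", "true", "false"})
    if not ok.all():
        lines = (raw.index[~ok] + 2).tolist()
        raise ValidationError(f"detected flag must be 0/1 at CSV line(s) {lines}")
    detected = detected.isin({"1", "True", "true"})

    visit = pd.Series(pd.NA, index=raw.index, dtype="Int64")
    if "visit_index" in raw.columns:
        visit = pd.to_numeric(raw["visit_index"], errors="coerce").astype("Int64")

    events = pd.DataFrame(
        {
            "site_id": raw["site_id"].astype(str),
            "method": raw["method"].astype(str),
            "timestamp": ts.dt.floor("min"),
            "detected": detected.to_numpy(),
            "visit_index": visit,
        }
    )

    is_pt = events["method"] == "PT"
    if (is_pt & events["visit_index"].isna()).any():
        raise ValidationError("PT rows must carry a visit_index")
    if (~is_pt & events["visit_index"].notna()).any():
        raise ValidationError("visit_index is only meaningful for PT rows")

    if campaign is not None:
        start, end = pd.Timestamp(campaign[0]), pd.Timestamp(campaign[1])
        inside = (events["timestamp"] >= start) & (events["timestamp"] < end)
        n_bad = int((~inside).sum())
        if n_bad:
            warnings.warn(
                f"rejected {n_bad} event(s) outside the campaign window "
                f"[{start}, {end})",
                stacklevel=2,
            )
            events = events.loc[inside].reset_index(drop=True)
    return events


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table in the format accepted by :func:`read_events`."""
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    out["detected"] = out["detected"].astype(int)
    out.to_csv(path, index=False, columns=list(EVENT_COLUMNS))


def read_sites(path) -> pd.DataFrame:
    """Read the survey-site covariate table (site_id, location_id, habitat, method)."""
    sites = pd.read_csv(path, dtype=str)
    missing = [c for c in ("site_id", "location_id", "habitat", "method") if c not in sites.columns]
    if missing:
        raise SchemaError(f"sites table is missing required column(s): {missing}")
    bad_hab = ~sites["habitat"].isin(HABITATS)
    if bad_hab.any():
        raise SchemaError(
            f"unknown habitat value(s) {sorted(sites.loc[bad_hab, 'habitat'].unique())}; "
            f"allowed values are {list(HABITATS)}"
        )
    if sites["site_id"].duplicated().any():
        raise ValidationError("duplicate site_id in sites table")
    return sites


# ---------------------------------------------------------------------------
# Detection histories
# ---------------------------------------------------------------------------

@dataclass
class DetectionHistory:
    """Sites x occasions detection matrix with per-site covariates.

    ``matrix`` holds floats 1.0 / 0.0 / NaN (NaN encodes a missing
    occasion: device not active, visit not conducted).  ``covariates``
    is aligned 1:1 with the matrix rows and carries at least ``method``,
    ``habitat`` and ``location_id``.
    """

    matrix: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.matrix.index.equals(self.covariates.index):
            raise ValidationError("matrix and covariates must share the same site index")
        vals = self.matrix.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValidationError("detection matrix cells must be 1, 0 or NA")
        # all-NA rows are tolerated here (they arise transiently, e.g. as
        # fusion inputs from dropped-out devices); the model fit excludes
        # them with a warning

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per site (covariates + occ_1..occ_K)."""
        return pd.concat([self.covariates, self.matrix], axis=1)

    def to_csv(self, path) -> None:
        frame = self.to_frame().reset_index().rename(columns={"index": "site_id"})
        occ_cols = list(self.matrix.columns)
        for c in occ_cols:
            frame[c] = frame[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DetectionHistory":
        frame = pd.read_csv(path, dtype=str).set_index("site_id")
        occ_cols = [c for c in frame.columns if c.startswith("occ_")]
        cov_cols = [c for c in frame.columns if not c.startswith("occ_")]
        matrix = frame[occ_cols].replace("NA", np.nan).astype(float)
        return cls(matrix=matrix, covariates=frame[cov_cols])


def _occ_cols(n: int) -> list[str]:
    return [f"occ_{k + 1}" for k in range(n)]


def _site_covariates(sites: pd.DataFrame, site_ids: Sequence[str], method: str) -> pd.DataFrame:
    info = sites.set_index("site_id").reindex(site_ids)
    if info["habitat"].isna().any():
        unknown = info.index[info["habitat"].isna()].tolist()
        raise ValidationError(f"site(s) {unknown} missing from the sites table")
    return pd.DataFrame(
        {"method": method, "habitat": info["habitat"], "location_id": info["location_id"]},
        index=info.index,
    )


def build_sensor_history(
    events: pd.DataFrame,
    sites: pd.DataFrame,
    coverage: pd.DataFrame | None = None,
    occasion_days: int = 5,
    n_occasions: int = 8,
    min_coverage: float = 0.5,
) -> DetectionHistory:
    """Build a sensor (CT or PAM) detection history from an event stream.

    Each device's occasions are anchored at its own deployment start:
    occasion ``k`` covers the half-open window
    ``[start + k*occasion_days, start + (k+1)*occasion_days)``.

    A cell is 1 if at least one detected event falls in the window, 0 if
    the device was active with no detection, and NA when the device
    covered less than ``min_coverage`` of the window (battery dropout).

    Parameters
    ----------
    events
        Event table restricted to a single sensor method.
    sites
        Site covariate table.
    coverage
        Per-device active spans, columns ``site_id``, ``start``, ``end``.
        When omitted, each device's span is inferred from its first and
        last event (with a warning) — adequate only for dense streams.
    """
    methods = set(events["method"].unique())
    if not methods <= {"CT", "PAM"}:
        raise ValidationError(f"sensor history expects CT or PAM events, got {sorted(methods)}")
    if len(methods) > 1:
        raise ValidationError("build one history per method; received a mixed stream")
    if methods:
        method = methods.pop()
    else:
        if coverage is None or not len(coverage):
            raise ValidationError("no events and no coverage: nothing to build")
        cov_sites = sites.loc[sites["site_id"].isin(coverage["site_id"])]
        site_methods = set(cov_sites["method"]) & {"CT", "PAM"}
        if len(site_methods) != 1:
            raise ValidationError(
                "cannot infer the sensor method from an empty event stream; "
                "restrict the coverage table to one method"
            )
        method = site_methods.pop()

    if coverage is None:
        warnings.warn(
            "no coverage metadata supplied; inferring device spans from event "
            "timestamps (trailing silent occasions will be scored NA)",
            stacklevel=2,
        )
        coverage = (
            events.groupby("site_id")["timestamp"]
            .agg(start="min", end="max")
            .reset_index()
        )
    cov = coverage.copy()
    cov["start"] = pd.to_datetime(cov["start"])
    cov["end"] = pd.to_datetime(cov["end"])
    cov = cov.set_index("site_id")
    # a shared coverage table may list devices of the other sensor method
    method_sites = set(sites.loc[sites["method"] == method, "site_id"])
    cov = cov.loc[[s for s in cov.index if s in method_sites or not method_sites]]

    site_ids = list(cov.index)
    occ_len = pd.Timedelta(days=occasion_days)
    matrix = np.full((len(site_ids), n_occasions), np.nan)

    ev_by_site = {sid: grp for sid, grp in events.loc[events["detected"]].groupby("site_id")}

    for i, sid in enumerate(site_ids):
        dev_start, dev_end = cov.loc[sid, "start"], cov.loc[sid, "end"]
        if dev_end + occ_len * n_occasions < dev_start:
            raise ValidationError(f"device coverage for {sid} ends before it starts")
        ev_times = (
            ev_by_site[sid]["timestamp"].to_numpy()
            if sid in ev_by_site
            else np.array([], dtype="datetime64[ns]")
        )
        for k in range(n_occasions):
            w0 = dev_start + k * occ_len
            w1 = w0 + occ_len
            covered = max(
                pd.Timedelta(0), min(w1, dev_end) - max(w0, dev_start)
            ) / occ_len
            if covered < min_coverage:
                continue  # NA
            hit = np.any((ev_times >= np.datetime64(w0)) & (ev_times < np.datetime64(w1)))
            matrix[i, k] = 1.0 if hit else 0.0
        if np.isnan(matrix[i]).all():
            raise ValidationError(f"site {sid}: no occasion reaches the coverage threshold")

    return DetectionHistory(
        matrix=pd.DataFrame(matrix, index=pd.Index(site_ids, name="site_id"),
                            columns=_occ_cols(n_occasions)),
        covariates=_site_covariates(sites, site_ids, method),
    )


def build_transect_history(
    visits: pd.DataFrame,
    sites: pd.DataFrame,
    n_visits: int = 3,
    min_gap_days: float = 5.0,
) -> DetectionHistory:
    """Build a point-transect detection history: one column per visit.

    Each visit record is already transect-level (a transect counts as a
    detection when the species was seen or heard at at least one of its
    sampling points; detections made while walking between points are
    excluded upstream).  A visit that was not conducted is NA.  Visits
    closer than ``min_gap_days`` apart trigger a warning, not an error.
    """
    if not (visits["method"] == "PT").all():
        raise ValidationError("transect history expects PT visit records only")
    if visits["visit_index"].isna().any():
        raise ValidationError("every PT visit record needs a visit_index")
    vi = visits["visit_index"].astype(int)
    if (vi < 1).any() or (vi > n_visits).any():
        raise ValidationError(f"visit_index must lie in 1..{n_visits}")
    if visits.duplicated(subset=["site_id", "visit_index"]).any():
        raise ValidationError("duplicate (site_id, visit_index) visit records")

    for sid, grp in visits.groupby("site_id"):
        dates = grp.sort_values("visit_index")["timestamp"].dt.normalize()
        gaps = dates.diff().dropna().dt.days
        if (gaps < min_gap_days).any():
            warnings.warn(
                f"site {sid}: consecutive visits fewer than {min_gap_days} days apart",
                stacklevel=2,
            )

    site_ids = sorted(visits["site_id"].unique())
    matrix = pd.DataFrame(
        np.nan, index=pd.Index(site_ids, name="site_id"), columns=_occ_cols(n_visits)
    )
    for _, row in visits.iterrows():
        matrix.loc[row["site_id"], f"occ_{int(row['visit_index'])}"] = float(row["detected"])

    return DetectionHistory(
        matrix=matrix, covariates=_site_covariates(sites, site_ids, "PT")
    )


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def combo_label(methods: Iterable[str]) -> str:
    """Canonical label for a method combination (e.g. ``PT+CT+PAM``)."""
    parts = sorted({m for label in methods for m in str(label).split("+")},
                   key=lambda m: _METHOD_RANK.get(m, 99))
    return "+".join(parts)


def fuse_histories(histories: Sequence[DetectionHistory]) -> DetectionHistory:
    """Fuse co-located histories into a combined-method history.

    Sites are matched exactly on ``(location_id, habitat)``; the fused
    cell is the OR of the inputs with NA absorption (1 if any input is
    1; 0 if at least one input is 0 and none is 1; NA only if every
    input is NA).  Inputs with fewer occasions are NA-padded to the
    longest grid.  Fusing a single history returns it unchanged.
    """
    if not histories:
        raise ValidationError("fuse_histories needs at least one history")
    if len(histories) == 1:
        return histories[0]

    n_occ = max(h.n_occasions for h in histories)
    keyed: list[dict] = []
    for h in histories:
        d = {}
        for sid in h.matrix.index:
            key = (h.covariates.loc[sid, "location_id"], h.covariates.loc[sid, "habitat"])
            if key in d:
                raise ValidationError(
                    f"duplicate (location_id, habitat)={key} within one input history"
                )
            d[key] = sid
        keyed.append(d)

    shared = sorted(set.intersection(*(set(d) for d in keyed)))
    if not shared:
        raise ValidationError("no overlapping (location_id, habitat) sites to fuse")

    label = combo_label([h.covariates["method"].iloc[0] for h in histories])
    rows, covs, ids = [], [], []
    for loc, hab in shared:
        stacked = np.full((len(histories), n_occ), np.nan)
        for j, (h, d) in enumerate(zip(histories, keyed)):
            row = h.matrix.loc[d[(loc, hab)]].to_numpy(dtype=float)
            stacked[j, : row.size] = row
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            any_one = np.nanmax(stacked, axis=0) == 1.0
        any_obs = ~np.isnan(stacked).all(axis=0)
        fused = np.where(any_one, 1.0, np.where(any_obs, 0.0, np.nan))
        rows.append(fused)
        ids.append(f"{loc}-{hab}-{label}")
        covs.append({"method": label, "habitat": hab, "location_id": loc})

    index = pd.Index(ids, name="site_id")
    return DetectionHistory(
        matrix=pd.DataFrame(np.vstack(rows), index=index, columns=_occ_cols(n_occ)),
        covariates=pd.DataFrame(covs, index=index),
    )


def stack_histories(histories: Sequence[DetectionHistory]) -> DetectionHistory:
    """Stack histories row-wise into one design, NA-padding occasions.

    Used to assemble the single modelling table in which every method
    and method combination appears as its own rows (transect histories
    with 3 occasions are NA-padded to the sensor grid).  Fused rows
    reuse the same underlying observations as the single-method rows
    they combine; when both kinds share sampling locations a
    pseudo-replication warning is emitted.
    """
    if not histories:
        raise ValidationError("stack_histories needs at least one history")
    n_occ = max(h.n_occasions for h in histories)
    mats, covs = [], []
    for h in histories:
        m = h.matrix.reindex(columns=_occ_cols(n_occ))
        mats.append(m)
        covs.append(h.covariates)
    matrix = pd.concat(mats)
    covariates = pd.concat(covs)
    if matrix.index.duplicated().any():
        raise ValidationError("duplicate site_id across stacked histories")

    single = covariates.loc[~covariates["method"].str.contains(r"\+"), "location_id"]
    fused = covariates.loc[covariates["method"].str.contains(r"\+"), "location_id"]
    if len(fused) and len(set(single) & set(fused)):
        warnings.warn(
            "stacked design mixes fused and single-method rows from the same "
            "sampling locations: rows are not independent (pseudo-replication)",
            stacklevel=2,
        )
    return DetectionHistory(matrix=matrix, covariates=covariates)


# ---------------------------------------------------------------------------
# Naive summaries
# ---------------------------------------------------------------------------

@dataclass
class NaiveSummary:
    """Detection-uncorrected tallies: rates, latency, pairwise overlap."""

    rates: pd.DataFrame      # method, habitat, occasions_detected, occasions_total, rate
    latency: pd.DataFrame    # method, latency_mean, latency_min, latency_max, n_sites
    overlap: pd.DataFrame    # method_a, method_b, both, only_a, only_b, shared_cells


def naive_summary(histories: Sequence[DetectionHistory]) -> NaiveSummary:
    """Compute naive detection rates, first-detection latency and overlap.

    Rates are occasion-level: detected occasions / non-missing occasions
    per method x habitat (empty strata report 0/0 with rate NaN).
    Latency counts survey occasions until a site's first detection,
    over sites with at least one detection.  Overlap compares pairs of
    histories cell-wise on shared ``(location_id, habitat)`` sites and
    occasions where both are non-missing.
    """
    if not histories:
        raise ValidationError("naive_summary needs at least one history")

    rate_rows = []
    lat_rows = []
    for h in histories:
        method = h.covariates["method"].iloc[0]
        vals = h.matrix.to_numpy(dtype=float)
        for hab in HABITATS:
            mask = (h.covariates["habitat"] == hab).to_numpy()
            cells = vals[mask]
            total = int((~np.isnan(cells)).sum())
            det = int(np.nansum(cells)) if cells.size else 0
            rate_rows.append(
                {
                    "method": method,
                    "habitat": hab,
                    "occasions_detected": det,
                    "occasions_total": total,
                    "rate": det / total if total else np.nan,
                }
            )
        firsts = []
        for row in vals:
            hits = np.flatnonzero(row == 1.0)
            if hits.size:
                firsts.append(hits[0] + 1)  # occasions are 1-based
        lat_rows.append(
            {
                "method": method,
                "latency_mean": float(np.mean(firsts)) if firsts else np.nan,
                "latency_min": int(min(firsts)) if firsts else np.nan,
                "latency_max": int(max(firsts)) if firsts else np.nan,
                "n_sites": len(firsts),
            }
        )

    ov_rows = []
    for ha, hb in combinations(histories, 2):
        ma, mb = ha.covariates["method"].iloc[0], hb.covariates["method"].iloc[0]
        keys_a = {
            (ha.covariates.loc[s, "location_id"], ha.covariates.loc[s, "habitat"]): s
            for s in ha.matrix.index
        }
        keys_b = {
            (hb.covariates.loc[s, "location_id"], hb.covariates.loc[s, "habitat"]): s
            for s in hb.matrix.index
        }
        both = only_a = only_b = shared = 0
        n_occ = min(ha.n_occasions, hb.n_occasions)
        for key in set(keys_a) & set(keys_b):
            ra = ha.matrix.loc[keys_a[key]].to_numpy(dtype=float)[:n_occ]
            rb = hb.matrix.loc[keys_b[key]].to_numpy(dtype=float)[:n_occ]
            obs = ~np.isnan(ra) & ~np.isnan(rb)
            both += int(np.sum((ra == 1) & (rb == 1) & obs))
            only_a += int(np.sum((ra == 1) & (rb == 0) & obs))
            only_b += int(np.sum((ra == 0) & (rb == 1) & obs))
            shared += int(obs.sum())
        ov_rows.append(
            {
                "method_a": ma,
                "method_b": mb,
                "both": both,
                "only_a": only_a,
                "only_b": only_b,
                "shared_cells": shared,
            }
        )

    return NaiveSummary(
        rates=pd.DataFrame(rate_rows),
        latency=pd.DataFrame(lat_rows),
        overlap=pd.DataFrame(
            ov_rows,
            columns=["method_a", "method_b", "both", "only_a", "only_b", "shared_cells"],
        ),
    )


def hourly_profile(events: pd.DataFrame, sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Histogram of detected events by hour of day, per method (and habitat).

    Returns a 24-row frame (hour 0..23); column per method, or per
    (method, habitat) when a sites table is supplied.  Bin counts sum to
    the number of detected events.
    """
    det = events.loc[events["detected"]].copy()
    det["hour"] = det["timestamp"].dt.hour
    if sites is not None:
        det = det.merge(sites[["site_id", "habitat"]], on="site_id", how="left")
        grouped = det.groupby(["method", "habitat", "hour"]).size()
        wide = grouped.unstack(level=[0, 1], fill_value=0) if len(det) else pd.DataFrame()
    else:
        wide = det.groupby(["method", "hour"]).size().unstack(level=0, fill_value=0) \
            if len(det) else pd.DataFrame()
    out = wide.reindex(range(24), fill_value=0)
    out.index.name = "hour"
    return out
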