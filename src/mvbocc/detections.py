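"""Camera-trap event handling and occasion-level detection histories.

Raw inputs are an *event table* (one row per classified photograph event:
site, category, timestamp) and a *deployment table* (one row per camera site:
active dates plus site covariates).  Events are collapsed into a
site x species x occasion binary detection tensor using fixed-length
occasions (4 days by default), the representation the co-occurrence model
consumes.  Sites surveyed for too few occasions can be filtered, bursts of
photographs can be collapsed into independent events for the activity
analysis, and naive (detection-uncorrected) occurrence summaries computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: canonical category order; recreation categories are treated as "species"
CATEGORIES = ("grizzly", "black", "motorised", "non-motorised")
UNKNOWN_CATEGORY = "unknown"

EVENT_COLUMNS = ["site_id", "category", "timestamp"]
DEPLOYMENT_COLUMNS = ["site_id", "start", "end"]

__all__ = [
    "CATEGORIES",
    "DetectionHistory",
    "NaiveSummary",
    "load_events",
    "load_deployments",
    "build_histories",
    "filter_min_surveys",
    "independent_events",
    "naive_summary",
]


@dataclass
class DetectionHistory:
    """Occasion-level detection tensor.

    ``y`` has shape (n_sites, n_species, n_occasions) with values 1 (detected),
    0 (surveyed, not detected) and NaN (camera inactive for the entire
    occasion).  Occasion count is identical across sites; ragged deployment
    ends appear as NaN.  Missingness is a property of the camera, so it is
    shared across species at a site.
    """

    y: np.ndarray
    sites: tuple[str, ...]
    species: tuple[str, ...]
    occasion_days: int
    occasion_starts: pd.DatetimeIndex

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.sites = tuple(str(s) for s in self.sites)
        self.species = tuple(str(s) for s in self.species)
        if self.y.shape != (len(self.sites), len(self.species), len(self.occasion_starts)):
            raise ValueError(
                f"y shape {self.y.shape} does not match "
                f"({len(self.sites)}, {len(self.species)}, {len(self.occasion_starts)})"
            )
        vals = self.y[~np.isnan(self.y)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("detections must be 0, 1 or NaN")

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]

    def n_surveys(self) -> np.ndarray:
        """Non-missing occasion count per site."""
        return (~np.isnan(self.y[:, 0, :])).sum(axis=1)

    def detected(self) -> pd.DataFrame:
        """Boolean site x species table: any detection over the season."""
        return pd.DataFrame(
            np.nansum(self.y, axis=2) > 0, index=list(self.sites), columns=list(self.species)
        )

    def detection_counts(self) -> np.ndarray:
        """(n_sites, n_species) count of occasions with a detection."""
        return np.nansum(self.y, axis=2)

    def survey_counts(self) -> np.ndarray:
        """(n_sites, n_species) count of surveyed occasions."""
        return (~np.isnan(self.y)).sum(axis=2)

    def subset_sites(self, keep: Sequence[str]) -> "DetectionHistory":
        idx = [self.sites.index(s) for s in keep]
        return DetectionHistory(
            self.y[idx], tuple(keep), self.species, self.occasion_days, self.occasion_starts
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per site-species, one column per occasion."""
        rows = []
        for si, site in enumerate(self.sites):
            for pi, sp in enumerate(self.species):
                rows.append([site, sp] + list(self.y[si, pi]))
        cols = ["site_id", "species"] + [f"occ{t + 1}" for t in range(self.n_occasions)]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, occasion_days: int, occasion_starts: pd.DatetimeIndex
    ) -> "DetectionHistory":
        sites = list(dict.fromkeys(frame["site_id"].astype(str)))
        species = list(dict.fromkeys(frame["species"].astype(str)))
        occ_cols = [c for c in frame.columns if c.startswith("occ")]
        y = np.full((len(sites), len(species), len(occ_cols)), np.nan)
        for _, row in frame.iterrows():
            si = sites.index(str(row["site_id"]))
            pi = species.index(str(row["species"]))
            y[si, pi] = pd.to_numeric(row[occ_cols], errors="coerce").to_numpy(dtype=float)
        return cls(y, tuple(sites), tuple(species), occasion_days, occasion_starts)


def load_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path, comment="#")
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    ev = ev.copy()
    ev["site_id"] = ev["site_id"].astype(str)
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    return ev


def load_deployments(path) -> pd.DataFrame:
    dep = pd.read_csv(path, comment="#")
    missing = set(DEPLOYMENT_COLUMNS) - set(dep.columns)
    if missing:
        raise ValueError(f"deployments table missing columns {sorted(missing)}")
    dep = dep.copy()
    dep["site_id"] = dep["site_id"].astype(str)
    for col in ("start", "end"):
        dep[col] = pd.to_datetime(dep[col])
    return dep


def _validate_deployments(deployments: pd.DataFrame) -> pd.DataFrame:
    dep = deployments.copy()
    dep["site_id"] = dep["site_id"].astype(str)
    if dep["site_id"].duplicated().any():
        raise ValueError("duplicate site_id in deployments table")
    dep["start"] = pd.to_datetime(dep["start"])
    dep["end"] = pd.to_datetime(dep["end"])
    if (dep["end"] < dep["start"]).any():
        raise ValueError("deployment end precedes start")
    return dep


def build_histories(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    occasion_days: int = 4,
    species: Sequence[str] | None = None,
    study_start=None,
    study_end=None,
    anchor: str = "study",
) -> DetectionHistory:
    """Bin events into fixed-length presence-absence occasions.

    Occasion windows are anchored at the global study start by default so
    occasions are comparable across sites (``anchor="camera"`` instead anchors
    each site's windows at its own deployment start).  ``y[s,i,t]`` is 1 if
    at least one event of species ``i`` fell in occasion ``t`` at site ``s``,
    0 if the camera was active for at least part of the window with no event,
    and NaN if the camera was inactive for the whole window.  Events in the
    ``"unknown"`` category are excluded; events outside a site's deployment
    window are dropped with a warning; an event at an undeployed site is an
    error.
    """
    if occasion_days < 1:
        raise ValueError("occasion_days must be >= 1")
    if anchor not in ("study", "camera"):
        raise ValueError("anchor must be 'study' or 'camera'")
    dep = _validate_deployments(deployments)
    ev = events.copy()
    ev["site_id"] = ev["site_id"].astype(str)
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])

    unknown_sites = set(ev["site_id"]) - set(dep["site_id"])
    if unknown_sites:
        raise ValueError(f"events reference undeployed sites: {sorted(unknown_sites)}")
    ev = ev[ev["category"] != UNKNOWN_CATEGORY]
    if species is None:
        species = CATEGORIES
    species = tuple(species)
    bad = set(ev["category"]) - set(species)
    if bad:
        raise ValueError(f"unexpected event categories {sorted(bad)}; expected {species}")

    start = pd.Timestamp(study_start) if study_start is not None else dep["start"].min()
    # deployments are active through the end date, so the window closes at end + 1 day
    end = (pd.Timestamp(study_end) if study_end is not None else dep["end"].max()) + pd.Timedelta(days=1)
    width = pd.Timedelta(days=occasion_days)
    n_occ = int(np.ceil((end - start) / width))
    if n_occ < 1:
        raise ValueError("study window is empty")

    sites = tuple(dep["site_id"])
    site_idx = {s: k for k, s in enumerate(sites)}
    sp_idx = {s: k for k, s in enumerate(species)}
    dep_start = dep["start"].to_numpy()
    dep_end = (dep["end"] + pd.Timedelta(days=1)).to_numpy()  # active through end date

    if anchor == "study":
        anchors = np.full(len(sites), start.to_datetime64())
    else:
        anchors = dep_start

    y = np.full((len(sites), len(species), n_occ), np.nan)
    # a partially active window counts as surveyed (non-missing)
    width64 = width.to_numpy()
    for k in range(len(sites)):
        lo = anchors[k] + np.arange(n_occ) * width64
        hi = lo + width64
        active = (lo < dep_end[k]) & (hi > dep_start[k])
        y[k, :, active] = 0.0

    dropped = 0
    for site, cat, ts in ev[["site_id", "category", "timestamp"]].itertuples(index=False):
        k = site_idx[site]
        ts64 = np.datetime64(ts)
        if ts64 < dep_start[k] or ts64 >= dep_end[k]:
            dropped += 1
            continue
        t = int(np.floor((ts64 - anchors[k]) / width64))
        if 0 <= t < n_occ:
            y[k, sp_idx[cat], t] = 1.0
    if dropped:
        warnings.warn(f"dropped {dropped} event(s) outside their site's deployment window")

    starts = pd.DatetimeIndex([start + i * width for i in range(n_occ)])
    return DetectionHistory(y, sites, species, occasion_days, starts)


def filter_min_surveys(history: DetectionHistory, min_occasions: int = 4) -> DetectionHistory:
    """Drop sites surveyed for fewer than ``min_occasions`` non-missing
    occasions; site order is preserved.  Raises if nothing survives."""
    if min_occasions < 1:
        raise ValueError("min_occasions must be >= 1")
    n = history.n_surveys()
    keep = [s for s, m in zip(history.sites, n) if m >= min_occasions]
    if not keep:
        raise ValueError(f"all sites have fewer than {min_occasions} surveyed occasions")
    if len(keep) == history.n_sites:
        return history
    return history.subset_sites(keep)


def independent_events(events: pd.DataFrame, gap_minutes: float = 30.0) -> pd.DataFrame:
    """Collapse photo bursts into independent events.

    Within each (site, category), an event is retained only if it is at least
    ``gap_minutes`` after the previously retained event, so rapid-fire photo
    sets collapse onto the first frame's timestamp.
    """
    if gap_minutes <= 0:
        raise ValueError("gap_minutes must be positive")
    ev = events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"])
    ev = ev.sort_values(["site_id", "category", "timestamp"], kind="stable")
    gap = pd.Timedelta(minutes=gap_minutes)
    keep_rows = []
    for _, grp in ev.groupby(["site_id", "category"], sort=False):
        last = None
        for idx, ts in zip(grp.index, grp["timestamp"]):
            if last is None or ts - last >= gap:
                keep_rows.append(idx)
                last = ts
    return ev.loc[sorted(keep_rows)].reset_index(drop=True)


@dataclass
class NaiveSummary:
    """Detection-uncorrected occurrence summary."""

    occurrence: pd.Series  # per-species share of sites with >= 1 detection
    sites_detected: pd.Series  # per-species count of sites with >= 1 detection
    pairwise: pd.DataFrame  # species x species count of co-detection sites
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"sites_detected": self.sites_detected, "naive_occurrence": self.occurrence}
        )
        out.index.name = "species"
        return out


def naive_summary(history: DetectionHistory) -> NaiveSummary:
    """Per-species naive occurrence (share of sites with a detection) and
    pairwise co-detection site counts."""
    if history.n_sites < 1:
        raise ValueError("need at least one site")
    det = history.detected().to_numpy()
    counts = det.sum(axis=0)
    species = list(history.species)
    pairwise = pd.DataFrame(
        (det[:, :, None] & det[:, None, :]).sum(axis=0), index=species, columns=species
    )
    return NaiveSummary(
        occurrence=pd.Series(counts / history.n_sites, index=species),
        sites_detected=pd.Series(counts, index=species),
        pairwise=pairwise,
        n_sites=history.n_sites,
    )
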