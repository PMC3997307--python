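"""Data preparation: effort filtering, spatial pooling and encounter histories.

Implements the preparation rules applied to the ringing records before
modelling: capture effort per netting location, selection of high-effort
locations (>= 24 distinct capture days over the study period by default),
pooling of captures within a 0.17 decimal-degree box of a high-effort
location, the migratory/sedentary latitude split, assignment of captures to
annual Aug-Jul occasions, and construction of the encounter-history matrix
and the reduced m-array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ringing_io import CaptureRecord, RunConfig, occasion_index, occasion_label

logger = logging.getLogger("reedcmr")


@dataclass
class EncounterHistoryMatrix:
    """Individuals x occasions binary detection matrix.

    ``detections[i, t]`` is 1 when individual ``i`` was captured at least
    once in occasion ``t``.  Every row has at least one detection,
    ``first_capture[i]`` is the first occasion with a 1 and all earlier
    entries are 0.  Individuals first captured at the final occasion are
    excluded before construction: after conditioning on first capture they
    contribute nothing to the likelihood.
    """

    detections: np.ndarray  # (n, T) int8
    site_index: np.ndarray  # (n,) int site id per individual
    first_capture: np.ndarray  # (n,) int occasion index
    ring_ids: list[str] = field(default_factory=list)
    occasion_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=np.int8)
        self.site_index = np.asarray(self.site_index, dtype=np.int64)
        self.first_capture = np.asarray(self.first_capture, dtype=np.int64)
        n, T = self.detections.shape
        if n and not (self.detections.sum(axis=1) >= 1).all():
            raise ValueError("every individual must have >= 1 detection")
        for i in range(n):
            f = self.first_capture[i]
            if self.detections[i, f] != 1 or self.detections[i, :f].any():
                raise ValueError(f"first_capture inconsistent for individual {i}")
        if n and (self.first_capture == T - 1).any():
            raise ValueError("individuals first captured at the final occasion must be excluded")

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.detections.shape[1]

    @property
    def site_ids(self) -> np.ndarray:
        return np.unique(self.site_index)

    def for_site(self, site_id: int) -> "EncounterHistoryMatrix":
        mask = self.site_index == site_id
        return EncounterHistoryMatrix(
            self.detections[mask],
            self.site_index[mask],
            self.first_capture[mask],
            [r for r, m in zip(self.ring_ids, mask) if m] if self.ring_ids else [],
            self.occasion_labels,
        )

    def to_dataframe(self) -> pd.DataFrame:
        T = self.n_occasions
        df = pd.DataFrame(
            {
                "ring_id": self.ring_ids or [str(i) for i in range(self.n_individuals)],
                "site_id": self.site_index,
            }
        )
        for t in range(T):
            df[f"occ_{t + 1}"] = self.detections[:, t]
        return df

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "EncounterHistoryMatrix":
        df = pd.read_csv(path, dtype={"ring_id": str})
        occ_cols = [c for c in df.columns if c.startswith("occ_")]
        det = df[occ_cols].to_numpy(dtype=np.int8)
        return cls(
            det,
            df["site_id"].to_numpy(),
            det.argmax(axis=1),
            df["ring_id"].tolist(),
        )


@dataclass
class MArray:
    """Reduced m-array: releases and first-subsequent-reencounter counts.

    ``released[i]`` counts birds released at occasion ``i`` (first captures
    and re-releases; no losses on capture).  ``m[i, j]`` counts those whose
    first reencounter after ``i`` was at occasion ``j > i``;
    ``never[i] = released[i] - sum_j m[i, j]``.
    """

    released: np.ndarray  # (T-1,)
    m: np.ndarray  # (T-1, T) upper triangular, columns are reencounter occasions

    def __post_init__(self) -> None:
        self.released = np.asarray(self.released, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        if (self.m < 0).any() or (self.released < 0).any():
            raise ValueError("m-array counts must be >= 0")
        if (self.m.sum(axis=1) > self.released).any():
            raise ValueError("row sums of m exceed releases")

    @property
    def never(self) -> np.ndarray:
        return self.released - self.m.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        T = self.m.shape[1]
        df = pd.DataFrame(self.m, columns=[f"recap_{j + 1}" for j in range(T)])
        df.insert(0, "release_occ", np.arange(1, T))
        df.insert(1, "released", self.released)
        df["never_seen_again"] = self.never
        return df


# ---------------------------------------------------------------------------
# Effort and pooling
# ---------------------------------------------------------------------------

def records_to_frame(records: list[CaptureRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ring_id": [r.ring_id for r in records],
            "date": [r.capture_date for r in records],
            "lat": [r.lat for r in records],
            "lon": [r.lon for r in records],
        }
    )


def compute_effort(records: list[CaptureRecord]) -> pd.DataFrame:
    """Capture effort per netting location over the whole study window.

    A location is an exact (lat, lon) pair; its effort is the number of
    distinct calendar dates with at least one capture there.
    """
    if not records:
        raise ValueError("no records")
    df = records_to_frame(records)
    eff = (
        df.groupby(["lat", "lon"])["date"]
        .nunique()
        .reset_index()
        .rename(columns={"date": "effort_days"})
    )
    return eff


def filter_high_effort(effort: pd.DataFrame, min_days: int) -> pd.DataFrame:
    """Locations with effort >= ``min_days``, ordered by descending effort
    then coordinates.  An empty result halts the pipeline upstream."""
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    keep = effort[effort["effort_days"] >= min_days]
    keep = keep.sort_values(
        ["effort_days", "lat", "lon"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if keep.empty:
        logger.warning("no locations pass the %d-day effort threshold", min_days)
    return keep


def _distances(lat, lon, loc_lat, loc_lon, metric: str) -> np.ndarray:
    dlat = np.abs(lat[:, None] - loc_lat[None, :])
    dlon = np.abs(lon[:, None] - loc_lon[None, :])
    if metric == "chebyshev":
        return np.maximum(dlat, dlon)
    return np.hypot(dlat, dlon)


def pool_captures(
    records: list[CaptureRecord],
    high_locations: pd.DataFrame,
    radius: float,
    site_merge_map: dict[tuple[float, float], int] | None = None,
    metric: str = "chebyshev",
) -> pd.DataFrame:
    """Assign each record to its nearest high-effort location within
    ``radius`` and map the location to a pooled site.

    ``site_merge_map`` maps (lat, lon) of a high-effort location to a site
    id; it expresses the pooling of nearby locations sharing a vegetation
    unit into one site.  When absent, each high-effort location becomes its
    own site, numbered 1..K in the order of ``high_locations``.  Records
    outside every radius are dropped with a logged count.  Ties (equal
    distance) go to the lower site id.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    df = records_to_frame(records)
    loc_lat = high_locations["lat"].to_numpy(float)
    loc_lon = high_locations["lon"].to_numpy(float)
    if site_merge_map is None:
        site_of_loc = np.arange(1, len(loc_lat) + 1)
    else:
        site_of_loc = np.array(
            [site_merge_map[(la, lo)] for la, lo in zip(loc_lat, loc_lon)]
        )

    d = _distances(df["lat"].to_numpy(float), df["lon"].to_numpy(float),
                   loc_lat, loc_lon, metric)
    within = d <= radius
    any_within = within.any(axis=1)
    # nearest location; ties broken by lower site id (stable lexsort)
    dmask = np.where(within, d, np.inf)
    order = np.lexsort((site_of_loc[None, :].repeat(len(df), 0), dmask), axis=1)
    nearest = order[:, 0]
    df["site_id"] = np.where(any_within, site_of_loc[nearest], -1)
    dropped = int((~any_within).sum())
    if dropped:
        logger.info("dropped %d record(s) outside all pooling radii", dropped)
    out = df[any_within].reset_index(drop=True)
    assert len(out) + dropped == len(records)  # pooling never creates records
    return out


def classify_migratory(site_lat: float, threshold_lat: float = -26.0) -> bool:
    """Sites strictly south of the threshold latitude hold migratory
    populations; at or north of it, sedentary."""
    return site_lat < threshold_lat


# ---------------------------------------------------------------------------
# Histories and m-array
# ---------------------------------------------------------------------------

def build_histories(site_records: pd.DataFrame, config: RunConfig) -> EncounterHistoryMatrix:
    """Collapse site-assigned records into a per-individual detection matrix.

    The occasion of a record is the Aug-Jul year containing its date;
    repeat captures within an occasion become a single detection.
    Individuals first seen at the last occasion are excluded (logged).
    """
    T = config.n_occasions()
    occ = np.array([occasion_index(d, config) for d in site_records["date"]])
    bad = (occ < 0) | (occ >= T)
    if bad.any():
        first_bad = site_records.iloc[int(np.argmax(bad))]
        raise ValueError(
            f"record outside study window: ring {first_bad['ring_id']} "
            f"on {first_bad['date']}"
        )
    df = site_records.assign(occ=occ)

    rows, sites, firsts, rings = [], [], [], []
    n_last_only = 0
    # one row per bird; a bird belongs to the site of its retained captures
    for ring_id, grp in df.groupby("ring_id", sort=True):
        det = np.zeros(T, dtype=np.int8)
        det[np.unique(grp["occ"])] = 1
        f = int(det.argmax())
        if f == T - 1:
            n_last_only += 1
            continue
        # site of first capture (ties to lower site id)
        first_caps = grp[grp["occ"] == f]
        site = int(first_caps["site_id"].min())
        rows.append(det)
        sites.append(site)
        firsts.append(f)
        rings.append(str(ring_id))
    if n_last_only:
        logger.info(
            "excluded %d individual(s) first captured at the final occasion",
            n_last_only,
        )
    det = np.array(rows, dtype=np.int8) if rows else np.zeros((0, T), dtype=np.int8)
    return EncounterHistoryMatrix(
        det,
        np.array(sites, dtype=np.int64),
        np.array(firsts, dtype=np.int64),
        rings,
        [occasion_label(t, config) for t in range(T)],
    )


def build_marray(histories: EncounterHistoryMatrix) -> MArray:
    """Standard reduced m-array from encounter histories.

    Every capture is a release (no losses on capture), so releases at
    occasion i count all individuals detected at i < T.
    """
    det = histories.detections
    n, T = det.shape
    released = det[:, : T - 1].sum(axis=0)
    m = np.zeros((T - 1, T), dtype=np.int64)
    for i in range(n):
        caps = np.flatnonzero(det[i])
        for a, b in zip(caps[:-1], caps[1:]):
            m[a, b] += 1
    return MArray(released, m)
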