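"""Disk I/O, run configuration and logging for the ringing pipeline.

This module is the boundary between files and the typed pipeline: it reads
and writes capture records and the per-site metadata table, and holds the
run configuration (study window, pooling radius, effort threshold, MCMC
settings, prior bounds).

File dialect
------------
Capture records are comma-delimited text with a header naming the columns
``ring_id, date, lat, lon, age``.  Dates are ISO 8601 (``YYYY-MM-DD``),
coordinates are decimal degrees with southern latitudes negative, and
``age`` is one of ``adult``, ``juvenile``, ``unknown``.  Only adult records
enter the analysis; juvenile/unknown rows are dropped at read time with a
logged count.

The site table is comma-delimited with header
``site_id, center_lat, center_lon, vegetation_unit, rainfall_regime,
migratory, apcv, mat, mafd``; climate covariates may be missing (empty or
``?``), which is recorded as missing, never as zero.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import enum
import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("reedcmr")

RECORD_COLUMNS = ["ring_id", "date", "lat", "lon", "age"]
SITE_COLUMNS = [
    "site_id",
    "center_lat",
    "center_lon",
    "vegetation_unit",
    "rainfall_regime",
    "migratory",
    "apcv",
    "mat",
    "mafd",
]


class AgeClass(str, enum.Enum):
    ADULT = "adult"
    JUVENILE = "juvenile"
    UNKNOWN = "unknown"


class RecordError(ValueError):
    """Raised for malformed record or site files; message lists row numbers."""


@dataclass(frozen=True)
class CaptureRecord:
    """One capture event of one ringed bird."""

    ring_id: str
    capture_date: _dt.date
    lat: float
    lon: float
    age_class: AgeClass = AgeClass.ADULT

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class Site:
    """Per-site metadata: location, habitat stratum and climate covariates.

    Climate covariates (``apcv`` %, ``mat`` deg C, ``mafd`` days) may be
    ``None`` when unavailable; downstream seasonality scoring treats a site
    with any missing covariate as undefined rather than assuming zero.
    """

    site_id: int
    center_lat: float
    center_lon: float
    vegetation_unit: str = ""
    rainfall_regime: str = ""  # summer | winter | irregular
    migratory: bool | None = None
    apcv: float | None = None
    mat: float | None = None
    mafd: float | None = None

    @property
    def climate_complete(self) -> bool:
        return None not in (self.apcv, self.mat, self.mafd)


@dataclass
class McmcSettings:
    """Sampler settings.  Defaults are the scaled-down testing protocol;
    ``paper_scale()`` gives 3 x 100,000 / burn-in 50,000 / thin 20."""

    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcSettings":
        return cls(chains=3, iterations=100_000, burn_in=50_000, thinning=20, seed=seed)

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class PriorBounds:
    """Uniform prior supports: U(-5,5) for the mean logit survival and
    recapture, U(0,1) for residence, U(0,5) for random-effect SDs."""

    logit_mean_lo: float = -5.0
    logit_mean_hi: float = 5.0
    sd_lo: float = 0.0
    sd_hi: float = 5.0


@dataclass
class RunConfig:
    """Everything a reproducible run needs besides the data files."""

    study_start: _dt.date = _dt.date(1998, 8, 1)
    study_end: _dt.date = _dt.date(2010, 7, 31)
    occasion_boundary_month: int = 8  # occasions run Aug-Jul
    min_effort_days: int = 24
    pooling_radius: float = 0.17  # decimal degrees, Chebyshev box
    distance_metric: str = "chebyshev"  # or "euclidean"
    migratory_latitude: float = -26.0
    seasonality_breakpoints: tuple[float, float] = (50.0, 80.0)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    priors: PriorBounds = field(default_factory=PriorBounds)

    def __post_init__(self) -> None:
        if self.pooling_radius <= 0:
            raise ValueError("pooling_radius must be > 0")
        if self.min_effort_days < 1:
            raise ValueError("min_effort_days must be >= 1")
        if self.distance_metric not in ("chebyshev", "euclidean"):
            raise ValueError(f"unknown distance metric {self.distance_metric!r}")

    def n_occasions(self) -> int:
        """Number of Aug-Jul occasions fully or partly inside the window."""
        start = occasion_index(self.study_start, self)
        end = occasion_index(self.study_end, self)
        return end - start + 1

    # -- key:value (YAML) persistence ------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["seasonality_breakpoints"] = list(self.seasonality_breakpoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "study_start" in d:
            d["study_start"] = _dt.date.fromisoformat(d["study_start"])
        if "study_end" in d:
            d["study_end"] = _dt.date.fromisoformat(d["study_end"])
        if "seasonality_breakpoints" in d:
            d["seasonality_breakpoints"] = tuple(d["seasonality_breakpoints"])
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = McmcSettings(**d["mcmc"])
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = PriorBounds(**d["priors"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def occasion_index(date: _dt.date, config: RunConfig) -> int:
    """0-based Aug-Jul occasion index of a date relative to the study start.

    An occasion runs from the boundary month (default August) through the
    month before it in the following year.
    """
    m = config.occasion_boundary_month
    year = date.year if date.month >= m else date.year - 1
    start = config.study_start
    start_year = start.year if start.month >= m else start.year - 1
    return year - start_year


def occasion_label(k: int, config: RunConfig) -> str:
    start = config.study_start
    m = config.occasion_boundary_month
    start_year = start.year if start.month >= m else start.year - 1
    y = start_year + k
    return f"Aug {y}–Jul {y + 1}"


# ---------------------------------------------------------------------------
# Capture records
# ---------------------------------------------------------------------------

def read_records(
    path: str | Path,
    config: RunConfig | None = None,
    drop_non_adult: bool = True,
) -> list[CaptureRecord]:
    """Read capture records from a delimited text file.

    Rows that fail to parse (bad date, out-of-range coordinate, unknown age,
    date outside the study window) are collected and reported together with
    their 1-based data-row numbers; any such row aborts the run.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    config = config or RunConfig()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordError(f"missing required column(s): {', '.join(missing)}")

    records: list[CaptureRecord] = []
    errors: list[str] = []
    n_dropped_age = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            date = _dt.date.fromisoformat(str(row.date))
            lat = float(row.lat)
            lon = float(row.lon)
            age = AgeClass(str(row.age).strip().lower())
            if not config.study_start <= date <= config.study_end:
                raise ValueError(
                    f"date {date} outside study window "
                    f"{config.study_start}..{config.study_end}"
                )
            rec = CaptureRecord(str(row.ring_id), date, lat, lon, age)
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
            continue
        if drop_non_adult and rec.age_class is not AgeClass.ADULT:
            n_dropped_age += 1
            continue
        records.append(rec)
    if errors:
        raise RecordError(
            f"{len(errors)} malformed row(s) in {path.name}:\n" + "\n".join(errors)
        )
    if n_dropped_age:
        logger.info("dropped %d non-adult record(s) from %s", n_dropped_age, path.name)
    logger.info("read %d adult capture record(s) from %s", len(records), path.name)
    return records


def write_records(records: Iterable[CaptureRecord], path: str | Path) -> None:
    """Write records in the same dialect ``read_records`` expects."""
    rows = [
        {
            "ring_id": r.ring_id,
            "date": r.capture_date.isoformat(),
            "lat": repr(r.lat),
            "lon": repr(r.lon),
            "age": r.age_class.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Site table
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "?", "na", "nan", "none"}


def _opt_float(raw: str) -> float | None:
    raw = str(raw).strip()
    if raw.lower() in _MISSING_TOKENS:
        return None
    return float(raw)


def read_site_table(path: str | Path) -> dict[int, Site]:
    """Read the per-site metadata table; returns sites keyed by site_id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    sites: dict[int, Site] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        site_id = int(row.site_id)
        if site_id in sites:
            raise RecordError(f"duplicate site_id {site_id} at row {i}")
        migratory_raw = str(getattr(row, "migratory", "")).strip().lower()
        migratory = (
            None
            if migratory_raw in _MISSING_TOKENS
            else migratory_raw in ("true", "1", "yes")
        )
        sites[site_id] = Site(
            site_id=site_id,
            center_lat=float(row.center_lat),
            center_lon=float(row.center_lon),
            vegetation_unit=str(getattr(row, "vegetation_unit", "")),
            rainfall_regime=str(getattr(row, "rainfall_regime", "")).strip().lower(),
            migratory=migratory,
            apcv=_opt_float(getattr(row, "apcv", "")),
            mat=_opt_float(getattr(row, "mat", "")),
            mafd=_opt_float(getattr(row, "mafd", "")),
        )
    if not sites:
        logger.warning("site table %s is empty", path.name)
    return sites


def write_site_table(sites: dict[int, Site] | Sequence[Site], path: str | Path) -> None:
    if isinstance(sites, dict):
        sites = [sites[k] for k in sorted(sites)]
    rows = []
    for s in sites:
        rows.append(
            {
                "site_id": s.site_id,
                "center_lat": repr(s.center_lat),
                "center_lon": repr(s.center_lon),
                "vegetation_unit": s.vegetation_unit,
                "rainfall_regime": s.rainfall_regime,
                "migratory": "" if s.migratory is None else str(s.migratory).lower(),
                "apcv": "" if s.apcv is None else repr(s.apcv),
                "mat": "" if s.mat is None else repr(s.mat),
                "mafd": "" if s.mafd is None else repr(s.mafd),
            }
        )
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run directory / logging
# ---------------------------------------------------------------------------

def setup_logging(run_dir: str | Path | None = None, level: int = logging.INFO) -> None:
    """Log to stderr, and additionally to ``run.log`` in the run directory."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if run_dir is not None:
        Path(run_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(run_dir) / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def write_manifest(run_dir: str | Path, config: RunConfig, outputs: dict[str, str]) -> None:
    """Record the resolved configuration and output files of a run."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.save(run_dir / "config.yaml")
    manifest = {"config": "config.yaml", "outputs": outputs}
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
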