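"""Field tables: belt-transect segments, leaf counts, leaf areas, consumption.

The four tables come from a belt-transect survey of *Viola purpurea
quercetorum* (segments of at most 30 m along parallel transects, plants
counted within 1 m of each side of the line) plus lab rearing of *Speyeria
adiaste clemencei* larvae. Records are plain dataclasses validated on
construction; readers/writers speak CSV with a header row.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, FormatError, ValidationError

PathLike = Union[str, Path, IO[str]]

MAX_SEGMENT_LENGTH_M = 30.0
DEFAULT_BELT_WIDTH_M = 2.0

SEXES = ("female", "male", "unknown")


@dataclass(frozen=True)
class SegmentRecord:
    """One belt-transect segment with its violet count.

    ``length_m`` is the along-transect segment length (at most 30 m by
    survey protocol); ``belt_width_m`` is the full belt width (1 m either
    side of the line gives the default 2 m).
    """

    transect_id: str
    segment_id: str
    length_m: float
    violet_count: int
    belt_width_m: float = DEFAULT_BELT_WIDTH_M

    def __post_init__(self) -> None:
        if not (0.0 < self.length_m <= MAX_SEGMENT_LENGTH_M):
            raise ValidationError(
                f"segment length must be in (0, {MAX_SEGMENT_LENGTH_M}] m, "
                f"got {self.length_m}"
            )
        if self.belt_width_m <= 0.0:
            raise ValidationError(f"belt width must be positive, got {self.belt_width_m}")
        if self.violet_count < 0 or int(self.violet_count) != self.violet_count:
            raise ValidationError(
                f"violet_count must be a non-negative integer, got {self.violet_count}"
            )

    @property
    def area_m2(self) -> float:
        return self.length_m * self.belt_width_m

    @property
    def density_per_m2(self) -> float:
        return self.violet_count / self.area_m2


@dataclass(frozen=True)
class LeafCountRecord:
    """Number of leaves on one surveyed plant."""

    plant_id: str
    n_leaves: int

    def __post_init__(self) -> None:
        if self.n_leaves < 1 or int(self.n_leaves) != self.n_leaves:
            raise ValidationError(f"n_leaves must be a positive integer, got {self.n_leaves}")


@dataclass(frozen=True)
class LeafAreaRecord:
    """Area of one sampled leaf, in mm²."""

    leaf_id: str
    area_mm2: float

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0.0:
            raise ValidationError(f"area_mm2 must be positive, got {self.area_mm2}")


@dataclass(frozen=True)
class ConsumptionRecord:
    """Total leaf area one larva ate from first instar to pupation, in cm²."""

    larva_id: str
    sex: str
    total_area_cm2: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.total_area_cm2 <= 0.0:
            raise ValidationError(
                f"total_area_cm2 must be positive, got {self.total_area_cm2}"
            )


@dataclass(frozen=True)
class SiteConfig:
    """Site constants: total study area and the adult MRR estimate."""

    total_area_m2: float
    adult_estimate: float
    adult_ci_low: float
    adult_ci_high: float

    def __post_init__(self) -> None:
        if self.total_area_m2 <= 0.0:
            raise ValidationError("total_area_m2 must be positive")
        if not (0.0 < self.adult_ci_low <= self.adult_estimate <= self.adult_ci_high):
            raise ValidationError(
                "adult CI must satisfy 0 < low <= estimate <= high, got "
                f"[{self.adult_ci_low}, {self.adult_estimate}, {self.adult_ci_high}]"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    if path == "-":
        path = sys.stdin
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"could not parse CSV: {exc}") from exc
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    return frame


def _build(row_constructor, frame: pd.DataFrame):
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(row_constructor(row))
        except (ValidationError, TypeError) as exc:
            raise ValidationError(f"row {i + 1}: {exc}") from exc
    return records


def read_segments(path: PathLike) -> list[SegmentRecord]:
    """Read the belt-transect segment table.

    Expects columns ``transect_id, segment_id, length_m, violet_count``;
    ``belt_width_m`` is optional and defaults to 2 m.
    """
    frame = _read_table(path, ["transect_id", "segment_id", "length_m", "violet_count"])
    has_width = "belt_width_m" in frame.columns

    def make(row):
        width = float(row.belt_width_m) if has_width else DEFAULT_BELT_WIDTH_M
        return SegmentRecord(
            transect_id=str(row.transect_id),
            segment_id=str(row.segment_id),
            length_m=float(row.length_m),
            violet_count=int(row.violet_count),
            belt_width_m=width,
        )

    return _build(make, frame)


def read_leaf_counts(path: PathLike) -> list[LeafCountRecord]:
    frame = _read_table(path, ["plant_id", "n_leaves"])
    return _build(
        lambda row: LeafCountRecord(plant_id=str(row.plant_id), n_leaves=int(row.n_leaves)),
        frame,
    )


def read_leaf_areas(path: PathLike) -> list[LeafAreaRecord]:
    frame = _read_table(path, ["leaf_id", "area_mm2"])
    return _build(
        lambda row: LeafAreaRecord(leaf_id=str(row.leaf_id), area_mm2=float(row.area_mm2)),
        frame,
    )


def read_consumption(path: PathLike) -> list[ConsumptionRecord]:
    frame = _read_table(path, ["larva_id", "sex", "total_area_cm2"])
    return _build(
        lambda row: ConsumptionRecord(
            larva_id=str(row.larva_id),
            sex=str(row.sex),
            total_area_cm2=float(row.total_area_cm2),
        ),
        frame,
    )


def write_segments(records: Iterable[SegmentRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "transect_id": r.transect_id,
                "segment_id": r.segment_id,
                "length_m": r.length_m,
                "violet_count": r.violet_count,
                "belt_width_m": r.belt_width_m,
            }
            for r in records
        ]
    ).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def write_leaf_counts(records: Iterable[LeafCountRecord], path: PathLike) -> None:
    pd.DataFrame(
        [{"plant_id": r.plant_id, "n_leaves": r.n_leaves} for r in records]
    ).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def write_leaf_areas(records: Iterable[LeafAreaRecord], path: PathLike) -> None:
    pd.DataFrame(
        [{"leaf_id": r.leaf_id, "area_mm2": r.area_mm2} for r in records]
    ).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def write_consumption(records: Iterable[ConsumptionRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"larva_id": r.larva_id, "sex": r.sex, "total_area_cm2": r.total_area_cm2}
            for r in records
        ]
    ).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_site_config(path: PathLike) -> SiteConfig:
    """Read site constants from a YAML or JSON mapping."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    try:
        payload = yaml.safe_load(text)  # YAML superset also parses JSON
    except yaml.YAMLError as exc:
        raise FormatError(f"could not parse site config: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError("site config must be a mapping")
    try:
        return SiteConfig(
            total_area_m2=float(payload["total_area_m2"]),
            adult_estimate=float(payload["adult_estimate"]),
            adult_ci_low=float(payload["adult_ci_low"]),
            adult_ci_high=float(payload["adult_ci_high"]),
        )
    except KeyError as exc:
        raise FormatError(f"missing site config key: {exc}") from exc


# ---------------------------------------------------------------------------
# density arithmetic
# ---------------------------------------------------------------------------


def pooled_density(segments: Sequence[SegmentRecord]) -> float:
    """Site-level density: total violets divided by total sampled area (per m²)."""
    if not segments:
        raise EmptyInputError("pooled_density requires at least one segment")
    total_count = sum(s.violet_count for s in segments)
    total_area = sum(s.area_m2 for s in segments)
    return total_count / total_area


def mean_transect_density(segments: Sequence[SegmentRecord]) -> float:
    """Unweighted mean of per-transect densities (per m²).

    Each transect's density is its total count over its total area; the mean
    is taken over transects so long sparse transects do not dominate short
    dense ones.
    """
    if not segments:
        raise EmptyInputError("mean_transect_density requires at least one segment")
    counts: dict[str, float] = {}
    areas: dict[str, float] = {}
    for s in segments:
        counts[s.transect_id] = counts.get(s.transect_id, 0.0) + s.violet_count
        areas[s.transect_id] = areas.get(s.transect_id, 0.0) + s.area_m2
    densities = [counts[t] / areas[t] for t in counts]
    return float(np.mean(densities))


def segment_densities(segments: Sequence[SegmentRecord]) -> np.ndarray:
    """Per-segment densities (count/area, per m²) in input order.

    This vector, with its many exact zeros, is the input to the
    zero-inflated exponential fit.
    """
    return np.array([s.density_per_m2 for s in segments], dtype=float)
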