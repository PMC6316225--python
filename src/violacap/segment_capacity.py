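"""Distribution-aware capacity from the transect segments themselves.

The Monte Carlo treats every violet on site as reachable. A sharper
accounting asks which individual 30-m segments hold enough plants to feed
one larva to pupation, then scales that segment count up by the sampled
fraction of the site. The same average plant metrics also give a food
density (cm² of leaf per m² of ground) and the ground area one larva must
cover to find its ration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DomainError
from .field_data import SegmentRecord


@dataclass(frozen=True)
class SegmentCapacityResult:
    """Segments that can each support a pupa, extrapolated to the site."""

    threshold_plants: int
    n_supporting_segments: int
    sampled_area_m2: float
    total_area_m2: float
    extrapolated_pupae: int

    def to_dict(self) -> dict:
        return {
            "threshold_plants": self.threshold_plants,
            "n_supporting_segments": self.n_supporting_segments,
            "sampled_area_m2": self.sampled_area_m2,
            "total_area_m2": self.total_area_m2,
            "extrapolated_pupae": self.extrapolated_pupae,
        }


@dataclass(frozen=True)
class FoodDensity:
    """Leaf area per unit ground area at average plant metrics."""

    food_per_m2: float  # cm² leaf per m² ground
    mean_density: float
    mean_leaves: float
    mean_leaf_area_cm2: float


def plants_per_pupa_threshold(
    consumption_cm2: float, mean_leaves: float, mean_leaf_area_cm2: float
) -> int:
    """Smallest whole number of average plants that feeds one larva.

    ceil(consumption / (leaves per plant × leaf area per leaf)); the male
    mean consumption 196.7 cm² at 10.3 leaves of 1.99 cm² gives 10.
    """
    if consumption_cm2 <= 0.0 or mean_leaves <= 0.0 or mean_leaf_area_cm2 <= 0.0:
        raise DomainError("all inputs must be positive")
    return math.ceil(consumption_cm2 / (mean_leaves * mean_leaf_area_cm2))


def count_supporting_segments(
    segments: Sequence[SegmentRecord],
    threshold: int,
    full_length_only: bool = True,
) -> tuple[int, float]:
    """(number of segments with >= threshold plants, their summed area m²).

    ``full_length_only`` restricts the considered set to full 30-m
    segments, whose area (count × 60 m²) is the sampled-area denominator
    of the extrapolation.
    """
    if threshold < 0:
        raise DomainError("threshold must be non-negative")
    considered = [s for s in segments if (not full_length_only) or s.length_m == 30.0]
    count = sum(1 for s in considered if s.violet_count >= threshold)
    sampled_area = sum(s.area_m2 for s in considered)
    return count, sampled_area


def extrapolate_pupae(
    n_segments: int, sampled_area_m2: float, total_area_m2: float
) -> int:
    """Scale supporting-segment count to the whole site: floor(n × total/sampled)."""
    if sampled_area_m2 <= 0.0:
        raise DomainError("sampled_area_m2 must be positive")
    if total_area_m2 < sampled_area_m2:
        raise DomainError("total area must be at least the sampled area")
    if n_segments < 0:
        raise DomainError("n_segments must be non-negative")
    return math.floor(n_segments * total_area_m2 / sampled_area_m2)


def segment_capacity(
    segments: Sequence[SegmentRecord],
    threshold: int,
    total_area_m2: float,
    full_length_only: bool = True,
) -> SegmentCapacityResult:
    """Count supporting segments and extrapolate to the site in one step."""
    count, sampled = count_supporting_segments(segments, threshold, full_length_only)
    return SegmentCapacityResult(
        threshold_plants=threshold,
        n_supporting_segments=count,
        sampled_area_m2=sampled,
        total_area_m2=total_area_m2,
        extrapolated_pupae=extrapolate_pupae(count, sampled, total_area_m2),
    )


def food_per_area(
    mean_density: float, mean_leaves: float, mean_leaf_area_cm2: float
) -> float:
    """cm² of host leaf per m² of ground at uniform average density."""
    if mean_density < 0.0 or mean_leaves < 0.0 or mean_leaf_area_cm2 < 0.0:
        raise DomainError("inputs must be non-negative")
    return mean_density * mean_leaves * mean_leaf_area_cm2


def area_required_per_larva(consumption_cm2: float, food_per_m2: float) -> float:
    """Ground area (m²) a larva must strip at a given food density."""
    if consumption_cm2 <= 0.0:
        raise DomainError("consumption must be positive")
    if food_per_m2 <= 0.0:
        raise DomainError("food density must be positive")
    return consumption_cm2 / food_per_m2
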