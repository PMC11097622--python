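"""Variant-level characterization: selection direction, allele age, and
nearest human-specific regulatory element.

Modern human-specific (MHS) variants arose first in African populations, so
the direction of frequency change in Europeans relative to Africans carries a
qualitative selection signal: a higher European minor-allele frequency is
read as positive selection in Europe, a lower one as negative selection.
CADD deleteriousness and allele age (in generations, 25 years/generation)
are ingested annotation, carried through for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .colocalization import distance, overlaps
from .types import FeatureElement, FeatureTrack, GenomicInterval, Locus, Variant

logger = logging.getLogger(__name__)

POSITIVE = "positive_in_europe"
NEGATIVE = "negative_in_europe"
INDETERMINATE = "indeterminate"

#: Years per generation used to convert allele ages.
YEARS_PER_GENERATION = 25.0

#: Default search window for the nearest human-specific element, matching the
#: 500-kb vicinity convention used to link regulatory elements to genes.
DEFAULT_WINDOW_BP = 500_000


def classify_selection(
    freq_eur: Optional[float],
    freq_afr: Optional[float],
    delta_min: float = 0.001,
) -> str:
    """Qualitative selection direction from EUR vs AFR minor-allele frequencies.

    Returns ``positive_in_europe`` if the European frequency exceeds the
    African one by more than ``delta_min``, ``negative_in_europe`` for the
    reverse, ``indeterminate`` otherwise (including absent frequencies).
    """
    if delta_min < 0:
        raise ValueError("delta_min must be non-negative")
    if freq_eur is None or freq_afr is None:
        logger.warning("missing allele frequency; selection call is indeterminate")
        return INDETERMINATE
    if freq_eur - freq_afr > delta_min:
        return POSITIVE
    if freq_afr - freq_eur > delta_min:
        return NEGATIVE
    return INDETERMINATE


def age_years(age_generations: float, years_per_generation: float = YEARS_PER_GENERATION) -> float:
    """Convert an allele age in generations to years (no rounding)."""
    if age_generations < 0:
        raise ValueError("age_generations must be non-negative")
    return age_generations * years_per_generation


@dataclass
class VariantProfile:
    """One characterized variant: locus context, nearest element, selection."""

    variant: Variant
    containing_locus: Optional[Locus] = None
    nearest_element: Optional[FeatureElement] = None
    element_distance_bp: Optional[int] = None
    element_relation: str = "none"  # inside / adjacent / none
    selection_call: str = INDETERMINATE
    age_years: Optional[float] = None


_SOURCE_PRIORITY = {"familial": 0, "gwas": 1, "pleiotropic": 2, "candidate": 3}


def profile_variant(
    variant: Variant,
    loci: Sequence[Locus] = (),
    hs_tracks: Sequence[FeatureTrack] = (),
    max_window_bp: int = DEFAULT_WINDOW_BP,
    delta_min: float = 0.001,
) -> VariantProfile:
    """Build the full per-variant report row.

    The containing locus is the unique locus whose interval contains the
    variant; ties across source classes resolve familial > gwas; an
    unresolved tie raises. The nearest element is the minimum-distance
    human-specific element within ``max_window_bp`` across all tracks, ties
    broken by (distance, start, track class) for reproducible reports.
    """
    if max_window_bp <= 0:
        raise ValueError("max_window_bp must be positive")
    point = variant.position

    containing = [l for l in loci if overlaps(point, l.interval)]
    locus: Optional[Locus] = None
    if containing:
        containing.sort(key=lambda l: (_SOURCE_PRIORITY.get(l.source, 99), l.id))
        if (
            len(containing) > 1
            and _SOURCE_PRIORITY.get(containing[0].source, 99)
            == _SOURCE_PRIORITY.get(containing[1].source, 99)
        ):
            raise ValueError(
                f"{variant.rsid}: ambiguous containing locus "
                f"({containing[0].id} vs {containing[1].id})"
            )
        locus = containing[0]

    window = GenomicInterval(
        point.chrom, max(1, point.start - max_window_bp), point.end + max_window_bp
    )
    candidates: list[tuple[int, int, str, FeatureElement]] = []
    for track in hs_tracks:
        for element in track.query(window):
            if not element.human_specific:
                continue
            d = distance(point, element.interval)
            if d <= max_window_bp:
                candidates.append((d, element.interval.start, element.track_class, element))

    profile = VariantProfile(
        variant=variant,
        containing_locus=locus,
        selection_call=classify_selection(variant.freq_eur, variant.freq_afr, delta_min),
        age_years=(
            age_years(variant.age_generations)
            if variant.age_generations is not None
            else None
        ),
    )
    if candidates:
        candidates.sort(key=lambda t: t[:3])
        d, _, _, element = candidates[0]
        profile.nearest_element = element
        profile.element_distance_bp = d
        profile.element_relation = "inside" if d == 0 else "adjacent"
    return profile
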