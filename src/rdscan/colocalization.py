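"""Locus-level characterization against human-specific feature tracks.

A candidate locus is tested for positional overlap (>= 1 shared base, same
chromosome) with each feature track; a locus is flagged as carrying a
human-specific feature iff at least one overlapped element in a
human-specific track class is itself human-specific — primate-only units in
the same track do not qualify. Cortical-morphology membership is by
gene-symbol match against the 780-gene cortical list, not interval overlap.
Group proportions and a 2x2 chi-square comparison mirror the summary
statistics reported for familial vs GWAS candidate sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    DEFAULT_GLIAL_CELL_TYPES,
    HS_TRACK_CLASSES,
    FeatureElement,
    FeatureTrack,
    GenomicInterval,
    Locus,
)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff same chromosome and the inclusive intervals share >= 1 base."""
    return a.chrom == b.chrom and max(a.start, b.start) <= min(a.end, b.end)


def distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bp between two intervals on the same chromosome.

    0 if they overlap; otherwise (later start) - (earlier end), so abutting
    inclusive intervals (end=10, start=11) are at distance 1. Cross-chromosome
    comparison is undefined and raises.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"distance undefined across chromosomes: {a.chrom} vs {b.chrom}")
    if overlaps(a, b):
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def find_overlaps(query: GenomicInterval, track: FeatureTrack) -> set[FeatureElement]:
    """All track elements overlapping the query interval (set semantics)."""
    return track.query(query)


def find_overlaps_scan(query: GenomicInterval, track: FeatureTrack) -> set[FeatureElement]:
    """Brute-force reference scan; kept as the oracle for the indexed path."""
    return {e for e in track.elements if overlaps(query, e.interval)}


@dataclass
class LocusAnnotation:
    """Per-locus colocalization record across all tested tracks."""

    locus: Locus
    per_track_hits: dict[str, set[FeatureElement]] = field(default_factory=dict)
    has_hs_feature: bool = False
    glial_flag: bool = False
    cortical_trait: str = "none"  # area / thickness / both / none
    pleiotropic_hits: set[str] = field(default_factory=set)

    @property
    def is_cortical(self) -> bool:
        return self.cortical_trait != "none"

    def matched_elements(self) -> list[FeatureElement]:
        return [e for hits in self.per_track_hits.values() for e in hits]


def glial_regulation_flag(
    annotation: LocusAnnotation,
    glial_set: Iterable[str] = DEFAULT_GLIAL_CELL_TYPES,
) -> bool:
    """True iff any matched element regulates expression in a glial cell type."""
    glial = set(glial_set)
    return any(e.cell_type in glial for e in annotation.matched_elements())


def annotate_locus(
    locus: Locus,
    tracks: Sequence[FeatureTrack],
    cortical_genes: Optional[Mapping[str, str]] = None,
    pleiotropic_loci: Sequence[Locus] = (),
    glial_set: Iterable[str] = DEFAULT_GLIAL_CELL_TYPES,
) -> LocusAnnotation:
    """Record every colocalization of ``locus`` with the supplied tracks.

    ``cortical_genes`` maps upper-cased gene symbol -> trait ("area",
    "thickness" or "both"); a plain iterable of symbols is also accepted
    (trait defaults to "both"). Absent tracks simply yield no hits.
    """
    ann = LocusAnnotation(locus=locus)
    for track in tracks:
        hits = find_overlaps(locus.interval, track)
        ann.per_track_hits.setdefault(track.track_class, set()).update(hits)

    ann.has_hs_feature = any(
        e.human_specific
        for cls in HS_TRACK_CLASSES
        for e in ann.per_track_hits.get(cls, ())
    )

    if cortical_genes is not None and locus.gene_symbol:
        if isinstance(cortical_genes, Mapping):
            lookup = {g.upper(): t for g, t in cortical_genes.items()}
        else:
            lookup = {g.upper(): "both" for g in cortical_genes}
        ann.cortical_trait = lookup.get(locus.gene_symbol.upper(), "none")

    ann.pleiotropic_hits = {
        p.id for p in pleiotropic_loci if overlaps(locus.interval, p.interval)
    }
    ann.glial_flag = glial_regulation_flag(ann, glial_set)
    return ann


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (printed-table convention)."""
    factor = 10.0**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class GroupSummary:
    """Counts and percentages of feature-carrying loci within one source class."""

    group: str
    n_loci: int
    n_with_hs_feature: int
    pct_hs_feature: float
    n_cortical: int
    pct_cortical: float


def summarize_groups(
    annotations: Sequence[LocusAnnotation],
    group_by: str = "source",
) -> list[GroupSummary]:
    """Per-source-class summary of human-specific-feature and cortical rates."""
    if group_by != "source":
        raise ValueError("only grouping by locus source is supported")
    if not annotations:
        raise ValueError("no annotations: no percentage defined")
    groups: dict[str, list[LocusAnnotation]] = {}
    for ann in annotations:
        groups.setdefault(ann.locus.source, []).append(ann)
    out = []
    for label in sorted(groups):
        anns = groups[label]
        n = len(anns)
        if n == 0:
            raise ValueError(f"empty group {label!r}: no percentage defined")
        n_hs = sum(a.has_hs_feature for a in anns)
        n_cort = sum(a.is_cortical for a in anns)
        out.append(
            GroupSummary(
                group=label,
                n_loci=n,
                n_with_hs_feature=n_hs,
                pct_hs_feature=round_half_up(100.0 * n_hs / n, 1),
                n_cortical=n_cort,
                pct_cortical=round_half_up(100.0 * n_cort / n, 1),
            )
        )
    return out


def compare_groups(
    a_yes: int, a_no: int, b_yes: int, b_no: int, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x2 table [[a_yes, a_no], [b_yes, b_no]].

    Returns (statistic, df=1, p). ``correction`` applies Yates continuity
    correction. A zero margin leaves expected counts undefined and raises.
    """
    table = np.array([[a_yes, a_no], [b_yes, b_no]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    if table[0, 0] / table[0].sum() == table[1, 0] / table[1].sum():
        # identical proportions: statistic exactly 0 regardless of correction
        return 0.0, 1, 1.0
    result = stats.chi2_contingency(table, correction=correction)
    return float(result.statistic), 1, float(result.pvalue)
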