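"""Novel-locus discovery from sub-significant GWAS associations.

The cascade: keep associations with p strictly below a sub-significance
cutoff (default 1e-6), intersect them positionally with pleiotropic loci
replicated in cognitive traits, then characterize each hit locus against the
human-specific feature tracks. A candidate is considered to carry
human-specific features iff any of its PSIregion / hsCRE / HAR / MHS flags
is not "No"; glial qualifiers mark elements regulating expression in
neuroglial cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .colocalization import LocusAnnotation, annotate_locus, overlaps
from .types import (
    DEFAULT_GLIAL_CELL_TYPES,
    AssociationRecord,
    FeatureTrack,
    GenomicInterval,
    Locus,
)

#: Report columns, in order, and the track classes each column pools.
#: Cell-type (hence glial) information for the HAR and MHS columns comes
#: from the cis-regulatory-element companion tracks (CRE_HAR, CRE_MHS),
#: since plain HAR/MHS elements carry no cell type.
REPORT_TRACKS = ("PSIregion", "hsCRE", "HAR", "MHS")
REPORT_TRACK_CLASSES = {
    "PSIregion": ("PSIregion",),
    "hsCRE": ("hsCRE", "hsCRE_hsGene"),
    "HAR": ("HAR", "CRE_HAR"),
    "MHS": ("MHS", "CRE_MHS"),
}


def filter_subsignificant(
    associations: Sequence[AssociationRecord], p_max: float = 1e-6
) -> list[AssociationRecord]:
    """Associations with p strictly below ``p_max``, input order preserved."""
    return [a for a in associations if a.p_value < p_max]


def overlap_with_pleiotropic(
    retained: Sequence[AssociationRecord],
    pleiotropic: Sequence[Locus],
    cognitive_only: bool = True,
) -> dict[Locus, list[AssociationRecord]]:
    """Pleiotropic loci containing >= 1 retained association.

    Returns each distinct hit locus with its supporting associations, in
    locus-table order. With ``cognitive_only`` (the default) only loci
    replicated in cognitive traits are eligible.
    """
    eligible = [
        l for l in pleiotropic if (l.cognitive_replicated or not cognitive_only)
    ]
    hits: dict[Locus, list[AssociationRecord]] = {}
    for locus in eligible:
        support = [
            a
            for a in retained
            if overlaps(GenomicInterval.point(a.chrom, a.pos), locus.interval)
        ]
        if support:
            hits[locus] = support
    return hits


@dataclass
class DiscoveryRow:
    """One candidate locus with its flag vocabulary and supporting SNPs."""

    locus: Locus
    gene: str  # assigned gene symbol or "intergenic"
    flags: dict[str, str]  # track class -> "No" / subtype / "Yes, glia" / "Yes, not glia"
    cortical_trait: str  # area / thickness / "area, thickness" / "No"
    support: list[AssociationRecord] = field(default_factory=list)

    @property
    def has_hs_features(self) -> bool:
        return any(self.flags.get(t, "No") != "No" for t in REPORT_TRACKS)

    @property
    def has_glial_feature(self) -> bool:
        return any("Yes, glia" in self.flags.get(t, "") for t in REPORT_TRACKS)


@dataclass
class DiscoveryReport:
    rows: list[DiscoveryRow]
    n_candidate_loci: int = 0
    n_with_hs_features: int = 0
    n_protein_coding_with_glia: int = 0


def _flag_for(annotation: LocusAnnotation, column: str, glial: set[str]) -> str:
    """Table-style flag for one report column: No / subtype / Yes, (not) glia."""
    hits = [
        e
        for cls in REPORT_TRACK_CLASSES[column]
        for e in annotation.per_track_hits.get(cls, ())
        if e.human_specific
    ]
    if not hits:
        return "No"
    if column == "PSIregion":
        labels = sorted({e.label for e in hits if e.label}) or ["hsInsert"]
        return ", ".join(labels)
    if any(e.cell_type in glial for e in hits):
        return "Yes, glia"
    return "Yes, not glia"


def characterize_candidates(
    candidates: Mapping[Locus, Sequence[AssociationRecord]],
    tracks: Sequence[FeatureTrack] = (),
    cortical_genes: Optional[Mapping[str, str]] = None,
    protein_coding: Iterable[str] = (),
    glial_set: Iterable[str] = DEFAULT_GLIAL_CELL_TYPES,
) -> DiscoveryReport:
    """Annotate each candidate locus and build the discovery report."""
    glial = set(glial_set)
    rows: list[DiscoveryRow] = []
    for locus, support in candidates.items():
        ann = annotate_locus(locus, tracks, cortical_genes, glial_set=glial)
        flags = {t: _flag_for(ann, t, glial) for t in REPORT_TRACKS}
        trait = ann.cortical_trait
        cortical = (
            "No"
            if trait == "none"
            else ("area, thickness" if trait == "both" else trait)
        )
        rows.append(
            DiscoveryRow(
                locus=locus,
                gene=locus.gene_symbol or "intergenic",
                flags=flags,
                cortical_trait=cortical,
                support=list(support),
            )
        )
    report = DiscoveryReport(rows=rows, n_candidate_loci=len(rows))
    report.n_with_hs_features, report.n_protein_coding_with_glia = count_feature_flags(
        report, protein_coding
    )
    return report


def count_feature_flags(
    report: DiscoveryReport, protein_coding: Iterable[str] = ()
) -> tuple[int, int]:
    """Summary counts over a discovery report.

    Returns (number of loci whose PSIregion/hsCRE/HAR/MHS flags are not all
    "No", number of protein-coding loci with at least one glial flag).
    Protein-coding status is an input list, never inferred.
    """
    pc = {g.upper() for g in protein_coding}
    n_hs = sum(r.has_hs_features for r in report.rows)
    n_pc_glia = sum(
        r.has_glial_feature for r in report.rows if r.gene.upper() in pc
    )
    return n_hs, n_pc_glia


def discover(
    associations: Sequence[AssociationRecord],
    pleiotropic: Sequence[Locus],
    tracks: Sequence[FeatureTrack] = (),
    cortical_genes: Optional[Mapping[str, str]] = None,
    protein_coding: Iterable[str] = (),
    p_max: float = 1e-6,
    cognitive_only: bool = True,
) -> DiscoveryReport:
    """Full cascade: sub-significance filter -> pleiotropic overlap -> report.

    Associations from multiple studies are pooled; a locus hit by either
    study appears once, with all supporting SNPs attached.
    """
    retained = filter_subsignificant(associations, p_max)
    candidates = overlap_with_pleiotropic(retained, pleiotropic, cognitive_only)
    return characterize_candidates(
        candidates, tracks, cortical_genes, protein_coding
    )
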