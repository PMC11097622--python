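"""Core domain types and coordinate conventions.

All coordinates are stored 1-based inclusive, the convention used in the
curated candidate-locus and variant tables this package consumes. BED input
(0-based half-open) is converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Canonical chromosome names of the human nuclear + mitochondrial genome.
CANONICAL_CHROMS = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrM"]
)

#: Human-specific feature track classes tested for colocalization.
HS_TRACK_CLASSES = (
    "PSIregion",
    "hsGene",
    "hsCRE",
    "hsCRE_hsGene",
    "HAR",
    "CRE_HAR",
    "MHS",
    "CRE_MHS",
)

#: Track classes whose elements may carry a regulation direction / cell type.
CELL_TYPE_TRACKS = frozenset({"hsCRE", "hsCRE_hsGene", "CRE_HAR", "CRE_MHS", "hsGene"})

ALL_TRACK_CLASSES = HS_TRACK_CLASSES + ("corticalGene",)

#: Neuroglial cortical cell types (astrocytes, oligodendrocytes and their
#: precursors, microglia). Configurable wherever used.
DEFAULT_GLIAL_CELL_TYPES = frozenset(
    {"Astrocyte", "Oligodendrocyte", "OPC", "Microglia"}
)

LOCUS_SOURCES = ("familial", "gwas", "pleiotropic", "candidate")


class ChromosomeError(ValueError):
    """Raised for chromosome labels outside the canonical human set."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome label to canonical ``chrN``/``chrX``/``chrY``/``chrM``.

    Accepts bare numbers ("7"), "chr"-prefixed names, and the mitochondrial
    aliases "MT"/"chrMT"/"M". Raises :class:`ChromosomeError` otherwise.
    """
    if not name or not str(name).strip():
        raise ChromosomeError("empty chromosome label")
    label = str(name).strip()
    body = label[3:] if label.lower().startswith("chr") else label
    body = body.upper()
    if body == "MT":
        body = "M"
    candidate = f"chr{body}" if body in {"X", "Y", "M"} else f"chr{body}"
    if candidate not in CANONICAL_CHROMS:
        raise ChromosomeError(f"unrecognized chromosome label: {name!r}")
    return candidate


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 1-based inclusive on a canonical chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @classmethod
    def point(cls, chrom: str, pos: int) -> "GenomicInterval":
        """The 1-bp interval [pos, pos] — how point variants are tested."""
        return cls(chrom, pos, pos)

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_length(interval: GenomicInterval) -> int:
    """Length in bp under the inclusive convention: end - start + 1."""
    return len(interval)


@dataclass(frozen=True)
class Locus:
    """A named candidate region with its source class and replication flags."""

    id: str
    interval: GenomicInterval
    source: str
    gene_symbol: Optional[str] = None
    replicated_cohorts: int = 0
    cognitive_replicated: bool = False

    def __post_init__(self) -> None:
        if self.source not in LOCUS_SOURCES:
            raise ValueError(
                f"locus source must be one of {LOCUS_SOURCES}, got {self.source!r}"
            )
        if self.replicated_cohorts < 0:
            raise ValueError("replicated_cohorts must be non-negative")


@dataclass(frozen=True)
class FeatureElement:
    """An attribute-carrying interval from a feature track.

    ``human_specific`` separates genuinely human-specific elements from
    primate-only units within the same track (e.g. a primate-specific
    transcription unit inside a PSIregion track); only the former count
    toward the has-human-specific-feature rule.
    """

    interval: GenomicInterval
    track_class: str
    human_specific: bool = True
    direction: Optional[str] = None  # "up" / "down" / None
    cell_type: Optional[str] = None
    cortical_trait: Optional[str] = None  # "area" / "thickness" / "both"
    label: str = ""

    def __post_init__(self) -> None:
        if self.track_class not in ALL_TRACK_CLASSES:
            raise ValueError(f"unknown track class: {self.track_class!r}")
        if self.direction not in (None, "up", "down"):
            raise ValueError(f"direction must be up/down/None, got {self.direction!r}")
        if self.track_class not in CELL_TYPE_TRACKS:
            if self.direction is not None or self.cell_type is not None:
                raise ValueError(
                    f"direction/cell_type only valid for {sorted(CELL_TYPE_TRACKS)}"
                )
        if self.cortical_trait is not None and self.track_class != "corticalGene":
            raise ValueError("cortical_trait only valid for corticalGene elements")
        if self.cortical_trait not in (None, "area", "thickness", "both"):
            raise ValueError(f"bad cortical_trait: {self.cortical_trait!r}")


class FeatureTrack:
    """A queryable collection of :class:`FeatureElement`.

    Overlap queries are served by per-chromosome interval trees; the contract
    (checked by property tests) is that answers are identical to a full scan.
    """

    def __init__(self, name: str, elements: Iterable[FeatureElement]):
        self.name = name
        self.elements: list[FeatureElement] = list(elements)
        classes = {e.track_class for e in self.elements}
        if len(classes) > 1:
            raise ValueError(
                f"track {name!r} mixes element classes: {sorted(classes)}"
            )
        self.track_class = next(iter(classes)) if classes else name
        self._trees: dict[str, IntervalTree] = {}
        for e in self.elements:
            tree = self._trees.setdefault(e.interval.chrom, IntervalTree())
            # inclusive [start, end] -> half-open [start, end+1)
            tree.addi(e.interval.start, e.interval.end + 1, e)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[FeatureElement]:
        return iter(self.elements)

    def query(self, interval: GenomicInterval) -> set[FeatureElement]:
        """All elements overlapping ``interval`` by >= 1 base."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(interval.start, interval.end + 1)}


@dataclass(frozen=True)
class Variant:
    """A sequence variant with population frequencies and annotation columns.

    Frequencies are minor-allele frequencies per population as supplied
    (dbSNP convention); absent annotation is ``None``, never 0 — a printed
    0.0000 is a legitimate frequency.
    """

    rsid: str
    chrom: str
    pos: int
    ref_allele: str = ""
    alt_allele: str = ""
    gene_symbol: Optional[str] = None
    freq_eur: Optional[float] = None
    freq_afr: Optional[float] = None
    age_generations: Optional[float] = None
    cadd_phred: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        for f in (self.freq_eur, self.freq_afr):
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError(f"allele frequency out of [0,1]: {f}")
        if self.age_generations is not None and self.age_generations < 0:
            raise ValueError("age_generations must be non-negative")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")

    @property
    def position(self) -> GenomicInterval:
        return GenomicInterval.point(self.chrom, self.pos)


@dataclass(frozen=True)
class AssociationRecord:
    """A SNP association from GWAS summary statistics."""

    snp_id: str
    chrom: str
    pos: int
    p_value: float
    study: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
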