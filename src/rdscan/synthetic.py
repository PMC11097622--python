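"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the structure of the real inputs — attribute-carrying
feature tracks, candidate locus sets, variant tables with population
frequencies, GWAS summary-statistic lists, and developmental / cross-species
expression matrices — on a toy genome (three 10-Mb chromosomes by default)
small enough for brute-force oracles. Every entity's planted class is
recorded in a :class:`TruthManifest`, and every draw comes from a single
seeded generator, so outputs are fully deterministic under (seed, config).

It makes no attempt to match real annotation density, linkage structure, or
realistic allele-frequency spectra: it validates pipeline logic, not
population-genetic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io
from .types import (
    DEFAULT_GLIAL_CELL_TYPES,
    HS_TRACK_CLASSES,
    AssociationRecord,
    FeatureElement,
    FeatureTrack,
    GenomicInterval,
    Locus,
    Variant,
)

CELL_TYPES = (
    "Astrocyte",
    "Oligodendrocyte",
    "OPC",
    "Microglia",
    "L2-3_IT",
    "L3-5_RORB_1",
    "L4-5_RORB_1",
    "PVALB",
    "Endothelial",
)

EARLY_STAGES = ("12 pcw", "16 pcw", "21 pcw", "4 mos", "10 mos")
LATER_STAGES = ("1 yrs", "4 yrs", "13 yrs", "21 yrs", "40 yrs")

from .expression import SPECIES  # noqa: E402


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Locus counts default to the real candidate-set sizes (11 familial, 42
    GWAS); the pleiotropic set is scaled to the toy genome. All counts,
    lengths and planted effects are overridable.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    # feature tracks
    elements_per_track: int = 60
    element_len_range: tuple[int, int] = (500, 5_000)
    psi_human_specific_fraction: float = 0.8
    glial_cell_fraction: float = 0.5
    # loci
    n_loci: dict[str, int] = field(
        default_factory=lambda: {"familial": 11, "gwas": 42, "pleiotropic": 60}
    )
    locus_len_range: tuple[int, int] = (10_000, 50_000)
    planted_overlap_fraction: float = 0.5
    cognitive_replicated_fraction: float = 0.4
    # variants
    n_variants: int = 100
    selection_shift: float = 0.05
    neutral_fraction: float = 0.2
    # associations
    n_associations: int = 1_000
    n_planted_hits: int = 20
    n_planted_host_loci: int = 5
    # expression
    n_genes: int = 20
    n_uplift_genes: int = 8
    uplift_log2_ratio: float = 3.0
    expression_noise_sd: float = 0.1
    n_human_restricted_pairs: int = 12

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_overlap_fraction <= 1.0):
            raise ValueError("planted_overlap_fraction must be in [0,1]")
        lo, hi = self.element_len_range
        if lo < 1 or hi < lo:
            raise ValueError("bad element length range")
        if any(hi > size for size in self.chrom_sizes.values()):
            raise ValueError("element longer than a chromosome")
        for key, n in self.n_loci.items():
            if n < 0:
                raise ValueError(f"negative locus count for {key!r}")


@dataclass
class TruthManifest:
    """Planted class of every generated entity, keyed by entity id."""

    locus_class: dict[str, str] = field(default_factory=dict)  # overlapping / non_overlapping
    variant_direction: dict[str, str] = field(default_factory=dict)
    association_class: dict[str, str] = field(default_factory=dict)  # planted_hit:<locus> / background
    planted_host_loci: set[str] = field(default_factory=set)
    gene_class: dict[str, str] = field(default_factory=dict)  # uplift / flat
    human_restricted_pairs: set[tuple[str, str]] = field(default_factory=set)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# rdscan truth manifest\n")
            fh.write("entity_type\tid\tplanted_class\n")
            for d, etype in (
                (self.locus_class, "locus"),
                (self.variant_direction, "variant"),
                (self.association_class, "association"),
                (self.gene_class, "gene"),
            ):
                for key, cls in d.items():
                    fh.write(f"{etype}\t{key}\t{cls}\n")
            for gene, cell_type in sorted(self.human_restricted_pairs):
                fh.write(f"human_restricted_pair\t{gene}|{cell_type}\tplanted\n")


def _rand_interval(rng: np.random.Generator, config: SyntheticConfig) -> GenomicInterval:
    chroms = sorted(config.chrom_sizes)
    chrom = chroms[rng.integers(len(chroms))]
    size = config.chrom_sizes[chrom]
    lo, hi = config.element_len_range
    length = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(1, size - length + 2))
    return GenomicInterval(chrom, start, start + length - 1)


def gen_tracks(config: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> dict[str, FeatureTrack]:
    """One track per human-specific class, attributes from the documented
    vocabularies; PSIregion mixes human-specific inserts with primate-only
    transcription units."""
    rng = rng or np.random.default_rng(config.seed)
    from .types import CELL_TYPE_TRACKS

    tracks: dict[str, FeatureTrack] = {}
    for cls in HS_TRACK_CLASSES:
        elements = []
        for i in range(config.elements_per_track):
            iv = _rand_interval(rng, config)
            if cls == "PSIregion":
                hs = bool(rng.random() < config.psi_human_specific_fraction)
                elements.append(
                    FeatureElement(
                        iv,
                        cls,
                        human_specific=hs,
                        label="hsInsert" if hs else "primate_unit",
                    )
                )
            elif cls in CELL_TYPE_TRACKS:
                glial = rng.random() < config.glial_cell_fraction
                pool = (
                    sorted(DEFAULT_GLIAL_CELL_TYPES)
                    if glial
                    else [c for c in CELL_TYPES if c not in DEFAULT_GLIAL_CELL_TYPES]
                )
                elements.append(
                    FeatureElement(
                        iv,
                        cls,
                        human_specific=True,
                        direction="up" if rng.random() < 0.5 else "down",
                        cell_type=pool[rng.integers(len(pool))],
                        label=f"{cls}_{i}",
                    )
                )
            else:
                elements.append(FeatureElement(iv, cls, human_specific=True, label=f"{cls}_{i}"))
        tracks[cls] = FeatureTrack(cls, elements)
    return tracks


def _merged_element_spans(tracks: Sequence[FeatureTrack]) -> dict[str, list[tuple[int, int]]]:
    spans: dict[str, list[tuple[int, int]]] = {}
    for track in tracks:
        for e in track.elements:
            spans.setdefault(e.interval.chrom, []).append((e.interval.start, e.interval.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in spans.items():
        ivs.sort()
        out = [ivs[0]]
        for s, e in ivs[1:]:
            if s <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def _gaps(config: SyntheticConfig, merged: dict[str, list[tuple[int, int]]]) -> list[tuple[str, int, int]]:
    gaps = []
    for chrom, size in sorted(config.chrom_sizes.items()):
        cursor = 1
        for s, e in merged.get(chrom, []):
            if s > cursor:
                gaps.append((chrom, cursor, s - 1))
            cursor = max(cursor, e + 1)
        if cursor <= size:
            gaps.append((chrom, cursor, size))
    return gaps


def gen_loci(
    config: SyntheticConfig,
    tracks: dict[str, FeatureTrack],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Locus], TruthManifest]:
    """Locus sets with a planted human-specific-overlap fraction.

    Per source class, exactly ``round(f * n)`` loci are placed over a
    randomly chosen human-specific element (guaranteed overlap) and the rest
    inside element-free gaps (guaranteed non-overlap). Placement is direct,
    not rejection sampling, so recovery by the colocalization engine is
    exact by construction.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    manifest = TruthManifest()
    track_list = list(tracks.values())
    hs_elements = [
        e for t in track_list for e in t.elements if e.human_specific
    ]
    if not hs_elements and config.planted_overlap_fraction > 0:
        raise ValueError("no human-specific elements to plant overlaps on")
    merged = _merged_element_spans(track_list)
    gaps = _gaps(config, merged)

    loci: list[Locus] = []
    counter = 0
    lo, hi = config.locus_len_range
    for source in sorted(config.n_loci):
        n = config.n_loci[source]
        n_overlap = int(round(config.planted_overlap_fraction * n))
        for i in range(n):
            counter += 1
            length = int(rng.integers(lo, hi + 1))
            if i < n_overlap:
                e = hs_elements[rng.integers(len(hs_elements))]
                size = config.chrom_sizes[e.interval.chrom]
                # span the element's start so overlap is certain
                start = max(1, e.interval.start - length // 2)
                end = min(size, start + length - 1)
                planted = "overlapping"
                iv = GenomicInterval(e.interval.chrom, start, end)
            else:
                fitting = [g for g in gaps if g[2] - g[1] + 1 >= length + 2]
                if not fitting:
                    raise ValueError(
                        "insufficient element-free space; use a larger toy genome"
                    )
                chrom, gs, ge = fitting[rng.integers(len(fitting))]
                start = int(rng.integers(gs + 1, ge - length + 1))
                iv = GenomicInterval(chrom, start, start + length - 1)
                planted = "non_overlapping"
            locus_id = f"{source}_{counter:04d}"
            loci.append(
                Locus(
                    id=locus_id,
                    interval=iv,
                    source=source,
                    gene_symbol=f"GENE{counter:04d}",
                    replicated_cohorts=int(rng.integers(0, 4)),
                    cognitive_replicated=bool(
                        rng.random() < config.cognitive_replicated_fraction
                    ),
                )
            )
            manifest.locus_class[locus_id] = planted
    return loci, manifest


def gen_variants(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[Variant], TruthManifest]:
    """Variant table with planted EUR-vs-AFR frequency shifts of +/- delta."""
    rng = rng or np.random.default_rng(config.seed + 2)
    manifest = TruthManifest()
    delta = config.selection_shift
    chroms = sorted(config.chrom_sizes)
    variants = []
    for i in range(config.n_variants):
        u = rng.random()
        if u < config.neutral_fraction:
            direction = "indeterminate"
        elif u < config.neutral_fraction + (1 - config.neutral_fraction) / 2:
            direction = "positive_in_europe"
        else:
            direction = "negative_in_europe"
        base = float(rng.uniform(delta + 0.01, 1.0 - delta - 0.01))
        if direction == "positive_in_europe":
            eur, afr = base + delta, base
        elif direction == "negative_in_europe":
            eur, afr = base, base + delta
        else:
            eur = afr = base
        chrom = chroms[rng.integers(len(chroms))]
        rsid = f"rs{900000 + i}"
        alleles = "ACGT"
        ref = alleles[rng.integers(4)]
        alt = alleles[(alleles.index(ref) + 1 + rng.integers(3)) % 4]
        variants.append(
            Variant(
                rsid=rsid,
                chrom=chrom,
                pos=int(rng.integers(1, config.chrom_sizes[chrom] + 1)),
                ref_allele=ref,
                alt_allele=alt,
                freq_eur=round(eur, 4),
                freq_afr=round(afr, 4),
                age_generations=float(rng.integers(500, 50_000)),
                cadd_phred=round(float(rng.uniform(0, 20)), 1),
            )
        )
        manifest.variant_direction[rsid] = direction
    return variants, manifest


def gen_associations(
    config: SyntheticConfig,
    pleiotropic_loci: Sequence[Locus],
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[AssociationRecord]], TruthManifest]:
    """Two study association lists with planted sub-significant hits.

    ``n_planted_hits`` SNPs get p drawn log-uniform in [1e-12, 1e-7] and
    positions inside ``n_planted_host_loci`` randomly chosen
    cognitive-replicated pleiotropic loci; background SNPs get p >= 1e-5
    anywhere, so the sub-significance filter separates them exactly.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    manifest = TruthManifest()
    cognitive = [l for l in pleiotropic_loci if l.cognitive_replicated]
    n_hosts = min(config.n_planted_host_loci, len(cognitive))
    if config.n_planted_hits > 0 and n_hosts == 0:
        raise ValueError("no cognitive-replicated pleiotropic loci to host hits")
    hosts = (
        [cognitive[j] for j in rng.choice(len(cognitive), size=n_hosts, replace=False)]
        if n_hosts
        else []
    )
    chroms = sorted(config.chrom_sizes)
    records: list[AssociationRecord] = []
    for i in range(config.n_planted_hits):
        host = hosts[rng.integers(len(hosts))]
        pos = int(rng.integers(host.interval.start, host.interval.end + 1))
        p = float(10 ** rng.uniform(-12, -7))
        snp = f"rs{100000 + i}"
        records.append(AssociationRecord(snp, host.interval.chrom, pos, p))
        manifest.association_class[snp] = f"planted_hit:{host.id}"
        # cognitive loci may overlap one another, so a hit planted in one can
        # legitimately fall inside others too; the truth set is containment
        point = GenomicInterval.point(host.interval.chrom, pos)
        for locus in cognitive:
            if (
                locus.interval.chrom == point.chrom
                and locus.interval.start <= pos <= locus.interval.end
            ):
                manifest.planted_host_loci.add(locus.id)
    n_background = max(0, config.n_associations - config.n_planted_hits)
    for i in range(n_background):
        chrom = chroms[rng.integers(len(chroms))]
        snp = f"rs{200000 + i}"
        records.append(
            AssociationRecord(
                snp,
                chrom,
                int(rng.integers(1, config.chrom_sizes[chrom] + 1)),
                float(10 ** rng.uniform(-5, 0)),
            )
        )
        manifest.association_class[snp] = "background"
    # interleave into two study files, as the real inputs come from two GWASs
    studies = {"study1": [], "study2": []}
    for idx, rec in enumerate(records):
        name = "study1" if idx % 2 == 0 else "study2"
        studies[name].append(
            AssociationRecord(rec.snp_id, rec.chrom, rec.pos, rec.p_value, study=name)
        )
    return studies, manifest


def gen_expression(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
):
    """Stage profiles with planted early-uplift genes and a cross-species
    panel with planted human-restricted gene/cell-type pairs.

    Uplift genes have early-stage means ``2**uplift_log2_ratio`` times their
    later-stage means, with multiplicative Gaussian noise truncated at zero;
    flat genes share one mean across stages. Non-planted panel pairs are
    expressed in all four species, so only planted pairs are human-restricted.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    from .expression import CellTypePanel, PanelEntry, StageProfile

    manifest = TruthManifest()
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    profiles: dict[str, StageProfile] = {}
    for gi, gene in enumerate(genes):
        uplift = gi < config.n_uplift_genes
        later_mean = float(rng.uniform(0.5, 5.0))
        early_mean = later_mean * 2**config.uplift_log2_ratio if uplift else later_mean
        pairs = []
        for label in EARLY_STAGES:
            noise = rng.normal(0, config.expression_noise_sd * early_mean)
            pairs.append((label, max(0.0, early_mean + noise)))
        for label in LATER_STAGES:
            noise = rng.normal(0, config.expression_noise_sd * later_mean)
            pairs.append((label, max(0.0, later_mean + noise)))
        profiles[gene] = StageProfile.from_pairs(gene, pairs)
        manifest.gene_class[gene] = "uplift" if uplift else "flat"

    cell_types = list(CELL_TYPES)
    all_pairs = [(g, c) for g in genes for c in cell_types]
    idx = rng.choice(
        len(all_pairs),
        size=min(config.n_human_restricted_pairs, len(all_pairs)),
        replace=False,
    )
    restricted = {all_pairs[int(j)] for j in idx}
    entries = []
    for gene, cell_type in all_pairs:
        for species in SPECIES:
            if (gene, cell_type) in restricted:
                frac = float(rng.uniform(0.05, 0.9)) if species == "human" else float(
                    rng.uniform(0.0, 0.049)
                )
            else:
                frac = float(rng.uniform(0.05, 0.9))
            entries.append(
                PanelEntry(gene, species, cell_type, round(frac, 4), round(frac * 3, 3))
            )
    manifest.human_restricted_pairs = restricted
    return profiles, CellTypePanel(entries), manifest


def merge_manifests(*manifests: TruthManifest) -> TruthManifest:
    out = TruthManifest()
    for m in manifests:
        out.locus_class.update(m.locus_class)
        out.variant_direction.update(m.variant_direction)
        out.association_class.update(m.association_class)
        out.planted_host_loci |= m.planted_host_loci
        out.gene_class.update(m.gene_class)
        out.human_restricted_pairs |= m.human_restricted_pairs
    return out


def simulate(config: SyntheticConfig, outdir) -> TruthManifest:
    """Generate every input class and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracks = gen_tracks(config)
    loci, m_loci = gen_loci(config, tracks)
    variants, m_var = gen_variants(config)
    pleio = [l for l in loci if l.source == "pleiotropic"]
    studies, m_assoc = gen_associations(config, pleio)
    profiles, panel, m_expr = gen_expression(config)

    for cls, track in tracks.items():
        io.write_feature_track(track, outdir / f"{cls}.tsv", dialect="tsv1")
    io.write_loci(loci, outdir / "loci.tsv")
    io.write_variants(variants, outdir / "variants.tsv")
    for name, records in studies.items():
        io.write_associations(records, outdir / f"assoc_{name}.tsv")
    with open(outdir / "expression_stages.tsv", "w") as fh:
        fh.write("gene\tstage_label\tvalue\n")
        for gene, profile in profiles.items():
            for s in profile.samples:
                fh.write(f"{gene}\t{s.stage_label}\t{s.value:.6g}\n")
    with open(outdir / "expression_panel.tsv", "w") as fh:
        fh.write("gene\tspecies\tcell_type\tfraction\tmean_level\n")
        for e in panel.entries:
            fh.write(
                f"{e.gene}\t{e.species}\t{e.cell_type}\t{e.fraction_expressing}\t{e.mean_level}\n"
            )
    manifest = merge_manifests(m_loci, m_var, m_assoc, m_expr)
    manifest.write(outdir / "truth.tsv")
    return manifest
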