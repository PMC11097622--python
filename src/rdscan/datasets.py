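"""Curated worked-example tables from the reading-disorders literature.

Two published desk-scale tables are transcribed here so the pipeline's rules
can be exercised against real candidate data without any downloads:

* the 14 characterized variants — two familial SEMA3C variants tagged by a
  human-specific cis-regulatory element, plus twelve modern human-specific
  variants residing in replicated candidate loci — with their EUR/AFR
  minor-allele frequencies, allele ages, CADD scores and the coordinates of
  the nearest human-specific element (GRCh38, 1-based inclusive);
* the nine-locus novel-candidate annotation matrix from the sub-significant
  GWAS discovery cascade, with its published per-track flag vocabulary.

Both are inputs (published tables), not outputs of this package.
"""

from __future__ import annotations

from .discovery import DiscoveryReport, DiscoveryRow
from .types import FeatureElement, FeatureTrack, GenomicInterval, Locus, Variant

#: (rsid, chrom, pos, ref, alt, gene, freq_eur, freq_afr,
#:  element chrom:start-end, direction, cell_type, printed relation,
#:  age_generations, cadd, familial_sema3c)
_VARIANT_ROWS = [
    ("rs76737144", "7", 80908760, "A", "G", "SEMA3C", 0.0046, 0.1394,
     ("chr7", 80907172, 80907800), "up", "Oligodendrocyte", "adjacent", 37898, 0.0, False),
    ("rs144517871", "7", 80918075, "A", "C", "SEMA3C", 0.0137, 0.0024,
     ("chr7", 80918336, 80920558), "up", "Oligodendrocyte", "adjacent", 1338, 16.9, True),
    ("rs143835534", "7", 80918259, "T", "C", "SEMA3C", 0.0134, 0.0024,
     ("chr7", 80918336, 80920558), "up", "Oligodendrocyte", "adjacent", 1805, 2.0, True),
    ("rs73434215", "7", 111775190, "T", "C", "DOCK4", 0.0009, 0.1903,
     ("chr7", 111794184, 111795181), "down", "L3-5_RORB_1", "adjacent", 23661, 0.6, False),
    ("rs60412264", "21", 46447615, "A", "G", "DIP2A", 0.0765, 0.1985,
     ("chr21", 46442761, 46443421), "up", "Oligodendrocyte", "adjacent", 44209, 3.6, False),
    ("rs59308388", "21", 46447658, "C", "T", "DIP2A", 0.0764, 0.2024,
     ("chr21", 46442761, 46443421), "up", "Oligodendrocyte", "adjacent", 47345, 0.7, False),
    ("rs113032385", "2", 197838082, "C", "T", "PLCL1", 0.0002, 0.0458,
     ("chr2", 197836182, 197836472), None, None, "adjacent", 49349, 5.1, False),
    ("rs113638606", "4", 151746036, "T", "C", "GATB", 0.0003, 0.0426,
     ("chr4", 151762915, 151763509), "down", "Oligodendrocyte", "adjacent", 33783, 2.2, False),
    ("rs113801043", "4", 151753240, "A", "C", "GATB", 0.0003, 0.0431,
     ("chr4", 151762915, 151763509), "down", "Oligodendrocyte", "adjacent", 34173, 0.3, False),
    ("rs112761935", "6", 16940454, "A", "G", "STMND1", 0.0000, 0.0784,
     ("chr6", 16964157, 16965977), "down", "Astrocyte", "adjacent", 45548, 0.3, False),
    ("rs6910825", "6", 16993475, "C", "T", "STMND1", 0.0011, 0.0807,
     ("chr6", 16964157, 16965977), "down", "Astrocyte", "adjacent", 39367, 0.5, False),
    ("rs540764086", "12", 120619105, "G", "C", "CABP1", 0.0000, 0.0044,
     ("chr12", 120617778, 120620271), "down", "Astrocyte", "inside", 836, 1.8, False),
    ("rs77336065", "14", 99276804, "G", "T", "BCL11B", 0.0000, 0.0044,
     ("chr14", 99276678, 99278056), "down", "L4-5_RORB_1", "inside", 10089, 1.7, False),
    ("rs74474830", "17", 36592859, "T", "C", "DHRS11", 0.0351, 0.1592,
     ("chr17", 36590929, 36593324), "down", "Astrocyte", "inside", 20261, 1.4, False),
]


def characterized_variants() -> list[Variant]:
    """The 14 published characterized variants, in table order."""
    return [
        Variant(
            rsid=r[0], chrom=r[1], pos=r[2], ref_allele=r[3], alt_allele=r[4],
            gene_symbol=r[5], freq_eur=r[6], freq_afr=r[7],
            age_generations=float(r[12]), cadd_phred=r[13],
        )
        for r in _VARIANT_ROWS
    ]


def familial_sema3c_rsids() -> set[str]:
    """The two familial SEMA3C sequence variants; the rest are MHS variants."""
    return {r[0] for r in _VARIANT_ROWS if r[14]}


def printed_relations() -> dict[str, str]:
    """Published wording per variant: "inside" ("in ...") vs "adjacent"."""
    return {r[0]: r[11] for r in _VARIANT_ROWS}


def tagged_element_track() -> FeatureTrack:
    """The human-specific elements tagged by the 14 variants, as one track.

    All are human-specific cis-regulatory elements except the PLCL1 one,
    which is a human-specific insertion; that distinction does not affect
    nearest-element search, so all are carried as hsCRE-class elements here,
    the insertion flagged by its label.
    """
    elements = {}
    for r in _VARIANT_ROWS:
        chrom, start, end = r[8]
        key = (chrom, start, end)
        if key not in elements:
            label = "hsInsert" if r[0] == "rs113032385" else f"{chrom}:{start}-{end}"
            elements[key] = FeatureElement(
                interval=GenomicInterval(chrom, start, end),
                track_class="hsCRE",
                human_specific=True,
                direction=r[9],
                cell_type=r[10],
                label=label,
            )
    return FeatureTrack("hsCRE", elements.values())


#: (chrom, start, end, gene, PSIregion, hsCRE, HAR, MHS, corticalGene)
_NOVEL_LOCUS_ROWS = [
    ("1", 96195036, 96502355, "LINC01787", "hsInsert", "No", "No", "No", "No"),
    ("4", 3140934, 3240118, "HTT", "hsInsert", "Yes, not glia", "No", "Yes, glia", "No"),
    ("6", 19056096, 19098182, "intergenic", "No", "No", "Yes, not glia", "No", "No"),
    ("6", 97862415, 98102413, "MIR2113", "No", "No", "No", "Yes, not glia", "No"),
    ("6", 108540061, 108606639, "FOXO3", "hsInsert", "No", "Yes, glia", "No", "area, thickness"),
    ("7", 104953266, 105085688, "KMT2E", "hsInsert", "Yes, glia", "No", "Yes, glia", "No"),
    ("7", 105205928, 105421332, "SRPK2", "hsInsert", "Yes, not glia", "No", "No", "No"),
    ("14", 98140957, 98174050, "LINC02295", "No", "No", "No", "No", "No"),
    ("17", 45962818, 46018358, "MAPT", "No", "Yes, glia", "No", "No", "area, thickness"),
]

#: Protein-coding genes among the nine novel candidates (the others are
#: lincRNA, microRNA or intergenic).
NOVEL_PROTEIN_CODING = ("HTT", "FOXO3", "KMT2E", "SRPK2", "MAPT")


def novel_locus_report() -> DiscoveryReport:
    """The published nine-row novel-candidate annotation matrix, as a report.

    Flags are transcribed verbatim; summary counts are left to
    :func:`rdscan.discovery.count_feature_flags` so the counting rules are
    exercised, not copied.
    """
    rows = []
    for chrom, start, end, gene, psi, hscre, har, mhs, cortical in _NOVEL_LOCUS_ROWS:
        locus = Locus(
            id=gene if gene != "intergenic" else f"intergenic_{chrom}_{start}",
            interval=GenomicInterval(chrom, start, end),
            source="candidate",
            gene_symbol=None if gene == "intergenic" else gene,
        )
        rows.append(
            DiscoveryRow(
                locus=locus,
                gene=gene,
                flags={"PSIregion": psi, "hsCRE": hscre, "HAR": har, "MHS": mhs},
                cortical_trait=cortical,
            )
        )
    return DiscoveryReport(rows=rows, n_candidate_loci=len(rows))


#: Published locus-group counts: (n loci, n carrying human-specific
#: features, n cortical-morphology genes). Familial cortical membership is
#: the three genes ROBO1, SEMA3C and CEP63; the single familial exception is
#: DYX1C1, which overlaps only a primate-specific transcription unit. The
#: familial and GWAS counts are published directly; the pleiotropic counts
#: are back-computed from the published percentages over 431 loci.
GROUP_COUNTS = {
    "familial": {"n": 11, "hs": 10, "cortical": 3},
    "gwas": {"n": 42, "hs": 42, "cortical": 19},
    "pleiotropic": {"n": 431, "hs": 385, "cortical": 120},
}


def group_annotations_from_counts(groups=("familial", "gwas")):
    """Minimal annotation sets realizing the published per-group counts.

    Used to run the group-summary arithmetic (counting and half-up
    percentage rounding) over the published candidate-set compositions
    without the underlying supplementary interval data.
    """
    from .colocalization import LocusAnnotation

    annotations = []
    for group in groups:
        counts = GROUP_COUNTS[group]
        for i in range(counts["n"]):
            locus = Locus(
                id=f"{group}_{i:03d}",
                interval=GenomicInterval("chr1", 1 + i * 10, 5 + i * 10),
                source=group if group in ("familial", "gwas", "pleiotropic") else "candidate",
                gene_symbol=f"{group.upper()}{i:03d}",
            )
            annotations.append(
                LocusAnnotation(
                    locus=locus,
                    has_hs_feature=i < counts["hs"],
                    cortical_trait="both" if i < counts["cortical"] else "none",
                )
            )
    return annotations
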