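"""Overlap engine, locus annotation, group summaries, chi-square comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdscan.colocalization import (
    annotate_locus,
    compare_groups,
    distance,
    find_overlaps,
    find_overlaps_scan,
    glial_regulation_flag,
    overlaps,
    round_half_up,
    summarize_groups,
)
from rdscan.colocalization import LocusAnnotation
from rdscan.types import FeatureElement, FeatureTrack, GenomicInterval, Locus

intervals = st.tuples(
    st.sampled_from(["chr1", "chr2"]),
    st.integers(1, 10_000),
    st.integers(1, 10_000),
).map(lambda t: GenomicInterval(t[0], min(t[1], t[2]), max(t[1], t[2])))


class TestOverlaps:
    def test_point_inside_element(self):
        # the replicated variant printed as lying inside its element
        assert overlaps(
            GenomicInterval.point("chr17", 36592859),
            GenomicInterval("chr17", 36590929, 36593324),
        )

    def test_point_adjacent_element(self):
        assert not overlaps(
            GenomicInterval.point("chr7", 80908760),
            GenomicInterval("chr7", 80907172, 80907800),
        )

    def test_inclusive_boundaries(self):
        a = GenomicInterval("chr1", 1, 10)
        assert not overlaps(a, GenomicInterval("chr1", 11, 20))
        assert overlaps(a, GenomicInterval("chr1", 10, 20))

    def test_different_chromosomes_never_overlap(self):
        assert not overlaps(
            GenomicInterval("chr1", 1, 100), GenomicInterval("chr2", 1, 100)
        )

    @given(a=intervals, b=intervals)
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_and_consistent_with_distance(self, a, b):
        assert overlaps(a, b) == overlaps(b, a)
        if a.chrom == b.chrom:
            assert distance(a, b) == distance(b, a)
            assert (distance(a, b) == 0) == overlaps(a, b)


class TestDistance:
    def test_printed_variant_to_element_gap(self):
        # 27,498 bp from the variant position to its nearest element
        assert (
            distance(
                GenomicInterval.point("chr6", 16993475),
                GenomicInterval("chr6", 16964157, 16965977),
            )
            == 27_498
        )

    def test_zero_when_inside(self):
        assert (
            distance(
                GenomicInterval.point("chr12", 120619105),
                GenomicInterval("chr12", 120617778, 120620271),
            )
            == 0
        )

    def test_abutting_intervals(self):
        assert distance(GenomicInterval("chr1", 1, 10), GenomicInterval("chr1", 11, 20)) == 1

    def test_cross_chromosome_undefined(self):
        with pytest.raises(ValueError):
            distance(GenomicInterval("chr1", 1, 10), GenomicInterval("chr2", 1, 10))


class TestFindOverlaps:
    def test_empty_track(self):
        track = FeatureTrack("HAR", [])
        assert find_overlaps(GenomicInterval("chr1", 1, 100), track) == set()

    def test_region_query_against_candidate_elements(self):
        # three elements near one familial candidate gene; a window catches two
        elements = [
            FeatureElement(GenomicInterval("chr7", 80907172, 80907800), "hsCRE"),
            FeatureElement(GenomicInterval("chr7", 80918336, 80920558), "hsCRE"),
            FeatureElement(GenomicInterval("chr7", 80930000, 80931000), "hsCRE"),
        ]
        track = FeatureTrack("hsCRE", elements)
        hits = find_overlaps(GenomicInterval("chr7", 80900000, 80920000), track)
        assert {e.interval.start for e in hits} == {80907172, 80918336}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_index_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        chroms = ["chr1", "chr2", "chr3"]
        elements = []
        for _ in range(500):
            start = int(rng.integers(1, 100_000))
            end = start + int(rng.integers(0, 500))
            elements.append(
                FeatureElement(
                    GenomicInterval(chroms[rng.integers(3)], start, end), "HAR"
                )
            )
        track = FeatureTrack("HAR", elements)
        for _ in range(200):
            start = int(rng.integers(1, 100_000))
            end = start + int(rng.integers(0, 2_000))
            q = GenomicInterval(chroms[rng.integers(3)], start, end)
            assert find_overlaps(q, track) == find_overlaps_scan(q, track)


def _locus(chrom, start, end, source="gwas", gene=None, lid="L1"):
    return Locus(lid, GenomicInterval(chrom, start, end), source, gene_symbol=gene)


class TestAnnotateLocus:
    def test_primate_only_element_does_not_count(self):
        # the single familial exception: overlap with a primate-specific
        # transcription unit only
        track = FeatureTrack(
            "PSIregion",
            [
                FeatureElement(
                    GenomicInterval("chr15", 100, 200),
                    "PSIregion",
                    human_specific=False,
                    label="primate_unit",
                )
            ],
        )
        ann = annotate_locus(_locus("chr15", 50, 300, "familial", "DYX1C1"), [track])
        assert ann.per_track_hits["PSIregion"]
        assert not ann.has_hs_feature

    def test_hs_insert_and_glial_element(self):
        tracks = [
            FeatureTrack(
                "PSIregion",
                [FeatureElement(GenomicInterval("chr4", 3150000, 3151000), "PSIregion", label="hsInsert")],
            ),
            FeatureTrack(
                "hsCRE",
                [
                    FeatureElement(
                        GenomicInterval("chr4", 3160000, 3161000),
                        "hsCRE",
                        cell_type="L2-3_IT",
                        direction="up",
                    )
                ],
            ),
            FeatureTrack(
                "CRE_MHS",
                [
                    FeatureElement(
                        GenomicInterval("chr4", 3170000, 3171000),
                        "CRE_MHS",
                        cell_type="Astrocyte",
                        direction="down",
                    )
                ],
            ),
        ]
        ann = annotate_locus(_locus("chr4", 3140934, 3240118, gene="HTT"), tracks)
        assert ann.has_hs_feature and ann.glial_flag

    def test_no_overlapping_elements(self):
        track = FeatureTrack(
            "hsCRE", [FeatureElement(GenomicInterval("chr2", 1, 100), "hsCRE")]
        )
        ann = annotate_locus(_locus("chr14", 98140957, 98174050, gene="LINC02295"), [track])
        assert not ann.has_hs_feature and not ann.glial_flag

    def test_monotone_under_adding_tracks(self):
        base = FeatureTrack(
            "HAR", [FeatureElement(GenomicInterval("chr1", 10, 20), "HAR")]
        )
        extra = FeatureTrack("MHS", [])
        locus = _locus("chr1", 1, 100)
        assert annotate_locus(locus, [base]).has_hs_feature
        assert annotate_locus(locus, [base, extra]).has_hs_feature

    def test_cortical_membership_by_gene_symbol(self):
        ann = annotate_locus(
            _locus("chr6", 108540061, 108606639, gene="FOXO3"),
            [],
            cortical_genes={"FOXO3": "both"},
        )
        assert ann.cortical_trait == "both"
        ann2 = annotate_locus(
            _locus("chr6", 108540061, 108606639, gene="foxo3"),
            [],
            cortical_genes={"FOXO3": "area"},
        )
        assert ann2.cortical_trait == "area"  # case-insensitive

    def test_glial_flag_cases(self):
        glial_hit = LocusAnnotation(
            locus=_locus("chr6", 1, 10),
            per_track_hits={
                "CRE_HAR": {
                    FeatureElement(
                        GenomicInterval("chr6", 1, 5), "CRE_HAR", cell_type="Oligodendrocyte"
                    )
                }
            },
        )
        assert glial_regulation_flag(glial_hit)
        non_glial = LocusAnnotation(
            locus=_locus("chr7", 1, 10),
            per_track_hits={
                "hsCRE": {
                    FeatureElement(
                        GenomicInterval("chr7", 1, 5), "hsCRE", cell_type="L2-3_IT"
                    )
                }
            },
        )
        assert not glial_regulation_flag(non_glial)
        assert not glial_regulation_flag(LocusAnnotation(locus=_locus("chr1", 1, 10)))


class TestSummaries:
    def _ann(self, i, source, hs, cortical):
        return LocusAnnotation(
            locus=_locus("chr1", 1 + i, 10 + i, source, lid=f"{source}{i}"),
            has_hs_feature=hs,
            cortical_trait="both" if cortical else "none",
        )

    def test_published_group_percentages(self):
        anns = [self._ann(i, "familial", i != 0, i < 3) for i in range(11)]
        anns += [self._ann(i, "gwas", True, i < 19) for i in range(42)]
        summaries = {s.group: s for s in summarize_groups(anns)}
        assert summaries["familial"].pct_hs_feature == 90.9
        assert summaries["familial"].pct_cortical == 27.3
        assert summaries["gwas"].pct_hs_feature == 100.0
        assert summaries["gwas"].pct_cortical == 45.2

    def test_counts_conserved_and_bounded(self):
        anns = [self._ann(i, "gwas", i % 2 == 0, False) for i in range(10)]
        (s,) = summarize_groups(anns)
        assert s.n_loci == 10 and 0 <= s.n_with_hs_feature <= s.n_loci
        assert 0.0 <= s.pct_hs_feature <= 100.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            summarize_groups([])
        # an empty list produces no groups -> error, not silent output

    @pytest.mark.parametrize(
        "value, expected", [(90.85, 90.9), (90.94, 90.9), (27.25, 27.3), (100.0, 100.0)]
    )
    def test_half_up_rounding(self, value, expected):
        assert round_half_up(value, 1) == expected


class TestCompareGroups:
    def test_identical_proportions(self):
        stat, df, p = compare_groups(5, 5, 5, 5)
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_maximally_different(self):
        stat, _, p = compare_groups(10, 0, 0, 10, correction=False)
        assert stat == pytest.approx(20.0)
        assert p < 0.001

    def test_closed_form_oracle_on_published_counts(self):
        # 0/11 familial vs 19/42 GWAS pleiotropic colocalizations
        a, b, c, d = 0, 11, 19, 23
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _, p = compare_groups(a, b, c, d, correction=False)
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(7.757, abs=0.01)
        assert p < 0.01

    def test_group_order_invariance(self):
        assert compare_groups(3, 7, 8, 2) == compare_groups(8, 2, 3, 7)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            compare_groups(0, 0, 5, 5)
        with pytest.raises(ValueError):
            compare_groups(0, 5, 0, 5)

    @given(
        a=st.integers(1, 50), b=st.integers(1, 50),
        c=st.integers(1, 50), d=st.integers(1, 50),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_closed_form_on_random_tables(self, a, b, c, d):
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _, _ = compare_groups(a, b, c, d, correction=False)
        assert stat == pytest.approx(closed, rel=1e-9)
        assert stat >= 0.0
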