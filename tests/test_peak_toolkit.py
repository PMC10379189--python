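"""Overlap engine, condition partition, feature annotation and 20 kb association."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from chipcross.genome_model import GeneModel, GenomeAnnotation, GenomicInterval
from chipcross.peak_toolkit import (
    Feature,
    Peak,
    PeakError,
    PeakSet,
    annotate_peak,
    feature_distribution,
    genes_near_peaks,
    overlaps,
    partition_peaks,
    read_peaks,
)


def _peak(chrom, start, end, name="p", summit=None):
    return Peak(GenomicInterval(chrom, start, end, "."), name=name, summit_offset=summit)


# ---------------------------------------------------------------- I/O


class TestReadPeaks:
    def test_bed_passthrough(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t100\t200\tp1\n")
        pset = read_peaks(str(path), "A")
        (p,) = pset.peaks
        assert (p.interval.start, p.interval.end, p.name) == (100, 200, "p1")
        assert p.summit is None

    def test_narrowpeak_summit(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t500\t.\t8.5\t-1\t-1\t50\n")
        (p,) = read_peaks(str(path), "A").peaks
        assert p.summit == 150

    def test_narrowpeak_sentinel_minus_one(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t500\t.\t8.5\t-1\t-1\t-1\n")
        (p,) = read_peaks(str(path), "A").peaks
        assert p.summit is None

    def test_inverted_interval_reports_line(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t100\t200\tok\nchr1\t300\t250\tbad\n")
        with pytest.raises(PeakError, match=":2"):
            read_peaks(str(path), "A")

    def test_out_of_range_summit_rejected(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t0\t-1\t-1\t100\n")
        with pytest.raises(PeakError):
            read_peaks(str(path), "A")

    def test_peakset_sorted_and_deduplicated(self):
        pset = PeakSet("A", [_peak("chr1", 50, 60), _peak("chr1", 0, 10), _peak("chr1", 50, 60)])
        assert [(p.interval.start, p.interval.end) for p in pset] == [(0, 10), (50, 60)]


# ---------------------------------------------------------------- overlaps


class TestOverlaps:
    def test_single_base_overlap(self):
        assert overlaps(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 199, 250))

    def test_adjacent_half_open_do_not_overlap(self):
        assert not overlaps(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 300))

    def test_different_chromosomes(self):
        assert not overlaps(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10))

    def test_exhaustive_small_coordinates_match_set_oracle(self):
        """All interval pairs on a 12 bp axis agree with per-base intersection."""
        coords = range(13)
        for s1 in coords:
            for e1 in coords:
                if e1 <= s1:
                    continue
                for s2 in coords:
                    for e2 in coords:
                        if e2 <= s2:
                            continue
                        expected = len(set(range(s1, e1)) & set(range(s2, e2))) >= 1
                        got = overlaps(
                            GenomicInterval("c", s1, e1), GenomicInterval("c", s2, e2)
                        )
                        assert got == expected, (s1, e1, s2, e2)

    def test_min_overlap_thickness(self):
        a, b = GenomicInterval("c", 0, 10), GenomicInterval("c", 7, 20)
        assert overlaps(a, b, min_overlap=3)
        assert not overlaps(a, b, min_overlap=4)


# ---------------------------------------------------------------- partition

_interval_st = st.tuples(
    st.integers(min_value=0, max_value=500), st.integers(min_value=1, max_value=60)
).map(lambda t: (t[0], t[0] + t[1]))


def _quadratic_partition(a: PeakSet, b: PeakSet):
    """All-pairs >=1 bp overlap oracle."""
    def is_common(p, other):
        return any(overlaps(p.interval, q.interval) for q in other)

    common_a = {p.name for p in a if is_common(p, b)}
    common_b = {p.name for p in b if is_common(p, a)}
    return common_a, common_b


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    ivs_a=st.lists(_interval_st, min_size=0, max_size=40),
    ivs_b=st.lists(_interval_st, min_size=0, max_size=40),
)
def test_partition_matches_quadratic_oracle(ivs_a, ivs_b):
    a = PeakSet("A", [_peak("chr1", s, e, f"a{i}") for i, (s, e) in enumerate(ivs_a)])
    b = PeakSet("B", [_peak("chr1", s, e, f"b{i}") for i, (s, e) in enumerate(ivs_b)])
    part = partition_peaks(a, b)
    oracle_a, oracle_b = _quadratic_partition(a, b)
    assert {p.name for p in part.common_a} == oracle_a
    assert {p.name for p in part.common_b} == oracle_b
    assert len(part.common_a) + len(part.specific_a) == len(a)
    assert len(part.common_b) + len(part.specific_b) == len(b)


def test_partition_common_flags_agree_with_pyranges():
    """Independent cross-check of the overlap join against pyranges."""
    pd = pytest.importorskip("pandas")
    pr = pytest.importorskip("pyranges")
    import numpy as np

    rng = np.random.default_rng(5)
    def random_peaks(label, n):
        starts = rng.integers(0, 3000, size=n)
        return [
            _peak(f"chr{c}", int(s), int(s + l), f"{label}{i}")
            for i, (c, s, l) in enumerate(
                zip(rng.integers(1, 3, size=n), starts, rng.integers(1, 200, size=n))
            )
        ]

    a = PeakSet("A", random_peaks("a", 80))
    b = PeakSet("B", random_peaks("b", 60))
    part = partition_peaks(a, b)

    def frame(pset):
        return pd.DataFrame(
            {
                "Chromosome": [p.chrom for p in pset],
                "Start": [p.interval.start for p in pset],
                "End": [p.interval.end for p in pset],
                "Name": [p.name for p in pset],
            }
        )

    common_a = set(pr.PyRanges(frame(a)).overlap(pr.PyRanges(frame(b))).df["Name"])
    common_b = set(pr.PyRanges(frame(b)).overlap(pr.PyRanges(frame(a))).df["Name"])
    assert {p.name for p in part.common_a} == common_a
    assert {p.name for p in part.common_b} == common_b


class TestPartitionEdges:
    def test_worked_example(self):
        a = PeakSet("A", [_peak("chr1", 0, 10, "a0"), _peak("chr1", 50, 60, "a1")])
        b = PeakSet("B", [_peak("chr1", 5, 15, "b0"), _peak("chr1", 100, 110, "b1")])
        part = partition_peaks(a, b)
        assert [p.name for p in part.common_a] == ["a0"]
        assert [p.name for p in part.specific_a] == ["a1"]
        assert [p.name for p in part.common_b] == ["b0"]
        assert [p.name for p in part.specific_b] == ["b1"]

    def test_empty_other_set_makes_all_specific(self):
        a = PeakSet("A", [_peak("chr1", 0, 10), _peak("chr2", 5, 9)])
        part = partition_peaks(a, PeakSet("B", []))
        assert len(part.specific_a) == 2
        assert len(part.common_a) == len(part.common_b) == len(part.specific_b) == 0

    def test_identical_sets_all_common(self):
        peaks = [_peak("chr1", 0, 10, "x"), _peak("chr1", 50, 60, "y")]
        part = partition_peaks(PeakSet("A", peaks), PeakSet("B", list(peaks)))
        assert len(part.specific_a) == len(part.specific_b) == 0


# ---------------------------------------------------------------- annotation


class TestAnnotatePeak:
    def test_promoter_beats_intron(self, toy_annotation):
        # gB (chr1, -, 60000-75000): TSS at 74999, promoter [72999, 77000);
        # that window also lies inside gB itself -> Promoter must win
        ap = annotate_peak(_peak("chr1", 73_000, 73_100), toy_annotation)
        assert ap.feature == Feature.PROMOTER

    def test_exon_and_intron(self, toy_annotation):
        # gA exons [10000,14000) and [18000,22000); intron between
        assert annotate_peak(_peak("chr1", 13_000, 13_200), toy_annotation).feature == Feature.EXON
        assert (
            annotate_peak(_peak("chr1", 15_000, 15_200), toy_annotation).feature
            == Feature.INTRON
        )

    def test_downstream_window(self, toy_annotation):
        # past gA's TES (21999), beyond the promoter reach of anything else
        ap = annotate_peak(_peak("chr1", 24_000, 24_100), toy_annotation)
        assert ap.feature == Feature.DOWNSTREAM

    def test_distal_intergenic(self, toy_annotation):
        ap = annotate_peak(_peak("chr1", 40_000, 40_100), toy_annotation)
        assert ap.feature == Feature.DISTAL_INTERGENIC

    def test_summit_decides_when_present(self, toy_annotation):
        # the interval spans gA's promoter, but the summit sits in the intron
        p = _peak("chr1", 7_000, 16_000, summit=8_000)  # summit at 15000
        ap = annotate_peak(p, toy_annotation, use_summit=True)
        assert ap.feature == Feature.INTRON
        ap_full = annotate_peak(p, toy_annotation, use_summit=False)
        assert ap_full.feature == Feature.PROMOTER

    def test_midpoint_at_tss_gives_zero_distance(self, toy_annotation):
        ap = annotate_peak(_peak("chr1", 9_900, 10_100), toy_annotation)  # mid 10000 = gA TSS
        assert ap.nearest_gene_id == "gA" and ap.distance_bp == 0

    def test_signed_distance_is_strand_aware(self, toy_annotation):
        # 500 bp left of gA's TSS is upstream (negative) on the + strand
        ap = annotate_peak(_peak("chr1", 9_400, 9_600), toy_annotation)
        assert ap.distance_bp == -500
        # 500 bp right of gB's TSS (74999, - strand) is upstream as well
        ap2 = annotate_peak(_peak("chr1", 75_399, 75_601), toy_annotation)
        assert ap2.nearest_gene_id == "gB" and ap2.distance_bp == -501

    def test_gene_order_independent(self, toy_annotation):
        """Permuting gene insertion order never changes the annotation."""
        reordered = GenomeAnnotation(chrom_sizes=dict(toy_annotation.chrom_sizes))
        for g in reversed(list(toy_annotation)):
            reordered.add(g)
        for start in (9_500, 13_000, 15_000, 24_000, 40_000, 73_000):
            p = _peak("chr1", start, start + 100)
            a1, a2 = annotate_peak(p, toy_annotation), annotate_peak(p, reordered)
            assert (a1.feature, a1.nearest_gene_id, a1.distance_bp) == (
                a2.feature,
                a2.nearest_gene_id,
                a2.distance_bp,
            )

    def test_empty_annotation_rejected(self):
        with pytest.raises(PeakError):
            annotate_peak(_peak("chr1", 0, 10), GenomeAnnotation())


class TestFeatureDistribution:
    def test_fractions_sum_to_one(self, toy_annotation):
        annotated = [
            annotate_peak(_peak("chr1", s, s + 100), toy_annotation)
            for s in (9_500, 13_000, 15_000, 24_000, 40_000)
        ]
        counts, fractions = feature_distribution(annotated)
        assert sum(counts.values()) == 5
        assert abs(sum(fractions.values()) - 1.0) < 1e-12

    def test_hand_counted_tallies(self, toy_annotation):
        starts = [9_500] * 2 + [15_000] * 2
        annotated = [
            annotate_peak(_peak("chr1", s, s + 100), toy_annotation) for s in starts
        ]
        counts, fractions = feature_distribution(annotated)
        assert counts == {Feature.PROMOTER: 2, Feature.INTRON: 2}
        assert fractions == {Feature.PROMOTER: 0.5, Feature.INTRON: 0.5}

    def test_empty_collection_rejected(self):
        with pytest.raises(PeakError):
            feature_distribution([])


# ---------------------------------------------------------------- 20 kb association


class TestGenesNearPeaks:
    def test_overlap_is_gap_zero(self, toy_annotation):
        pset = PeakSet("A", [_peak("chr1", 10_100, 10_200)])
        assert genes_near_peaks(pset, toy_annotation) == ["gA"]

    def test_boundary_gap_inclusive(self):
        ann = GenomeAnnotation(chrom_sizes={"chr1": 100_000})
        ann.add(GeneModel("g", GenomicInterval("chr1", 20_100, 30_000, "+")))
        pset = PeakSet("A", [_peak("chr1", 0, 100)])
        assert genes_near_peaks(pset, ann, max_distance=20_000) == ["g"]
        ann2 = GenomeAnnotation(chrom_sizes={"chr1": 100_000})
        ann2.add(GeneModel("g", GenomicInterval("chr1", 20_101, 30_000, "+")))
        assert genes_near_peaks(pset, ann2, max_distance=20_000) == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        peak_ivs=st.lists(_interval_st, min_size=1, max_size=20),
        gene_ivs=st.lists(_interval_st, min_size=1, max_size=10, unique=True),
        max_d=st.integers(min_value=0, max_value=100),
    )
    def test_matches_all_pairs_gap_oracle(self, peak_ivs, gene_ivs, max_d):
        ann = GenomeAnnotation(chrom_sizes={"chr1": 10_000})
        for i, (s, e) in enumerate(gene_ivs):
            ann.add(GeneModel(f"g{i}", GenomicInterval("chr1", s, e, "+")))
        pset = PeakSet("A", [_peak("chr1", s, e, f"p{i}") for i, (s, e) in enumerate(peak_ivs)])
        expected = sorted(
            f"g{i}"
            for i, (gs, ge) in enumerate(gene_ivs)
            if any(max(gs - pe, ps - ge, 0) <= max_d for ps, pe in peak_ivs)
        )
        assert genes_near_peaks(pset, ann, max_d) == expected
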