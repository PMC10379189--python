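"""Peak I/O, the >=1 bp overlap engine, condition partition, and annotation.

The Venn-style partition follows per-peak accounting: every peak of each
condition is classified as *common* (overlaps, by at least 1 bp, at least one
peak of the other condition) or *condition-specific*.  No peak merging is
performed, so the per-condition counts sum beyond the size of the union —
matching how differential ChIP-seq peak tallies are usually reported.

Feature annotation assigns each peak one class by fixed precedence
Promoter > Exon > Intron > Downstream > DistalIntergenic, testing the summit
position when available and the full peak interval otherwise.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

from .genome_model import GeneModel, GenomeAnnotation, GenomicInterval, promoter_region

__all__ = [
    "Peak",
    "PeakSet",
    "PeakPartition",
    "Feature",
    "AnnotatedPeak",
    "PeakError",
    "read_peaks",
    "write_peaks",
    "overlaps",
    "partition_peaks",
    "annotate_peak",
    "annotate_peaks",
    "feature_distribution",
    "genes_near_peaks",
    "write_annotated_peaks",
]


class PeakError(ValueError):
    """Raised for malformed peak input."""


class Feature(str, Enum):
    """Genomic feature classes, in annotation precedence order."""

    PROMOTER = "Promoter"
    EXON = "Exon"
    INTRON = "Intron"
    DOWNSTREAM = "Downstream"
    DISTAL_INTERGENIC = "DistalIntergenic"


@dataclass(frozen=True)
class Peak:
    """One called peak: interval, name, optional score and summit offset.

    ``summit_offset`` is the offset of the point-source summit from the peak
    start (narrowPeak column 10); None when unknown.
    """

    interval: GenomicInterval
    name: str = "."
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise PeakError(
                f"peak {self.name}: summit offset {self.summit_offset} outside "
                f"[0, {len(self.interval)})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def summit(self) -> int | None:
        """Absolute summit position, if a summit offset is recorded."""
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset

    @property
    def anchor_point(self) -> int:
        """Summit when present, else interval midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint


@dataclass
class PeakSet:
    """An ordered, duplicate-free peak collection for one condition."""

    condition_label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.chrom, p.interval.start, p.interval.end)
        )
        seen: set[tuple[str, int, int]] = set()
        deduped: list[Peak] = []
        for p in self.peaks:
            key = (p.chrom, p.interval.start, p.interval.end)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(p)
        self.peaks = deduped

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


@dataclass
class PeakPartition:
    """Condition partition of two peak sets into common and specific parts."""

    common_a: PeakSet
    common_b: PeakSet
    specific_a: PeakSet
    specific_b: PeakSet

    def counts(self) -> dict[str, int]:
        return {
            "common_a": len(self.common_a),
            "common_b": len(self.common_b),
            "specific_a": len(self.specific_a),
            "specific_b": len(self.specific_b),
        }


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak with its feature class and nearest gene by TSS distance.

    ``distance_bp`` is the signed, strand-aware distance from the peak anchor
    (summit or midpoint) to the nearest gene's TSS: negative means upstream of
    the TSS in transcript orientation.
    """

    peak: Peak
    feature: Feature
    nearest_gene_id: str | None
    distance_bp: int | None


def read_peaks(path: str, condition_label: str) -> PeakSet:
    """Read a BED6 or ENCODE narrowPeak file.

    BED coordinates are taken as-is (already 0-based half-open).  For
    narrowPeak (10 columns) the last column is the summit offset; the ENCODE
    sentinel ``-1`` means "no summit called".
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise PeakError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PeakError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise PeakError(f"{path}:{lineno}: end {end} <= start {start}")
            name = cols[3] if len(cols) > 3 and cols[3] else f"peak_{lineno}"
            score: float | None = None
            if len(cols) > 4 and cols[4] not in (".", ""):
                score = float(cols[4])
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            summit_offset: int | None = None
            if len(cols) >= 10:
                so = int(cols[9])
                if so >= 0:
                    if so >= end - start:
                        raise PeakError(
                            f"{path}:{lineno}: summit offset {so} outside peak"
                        )
                    summit_offset = so
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    name=name,
                    score=score,
                    summit_offset=summit_offset,
                )
            )
    return PeakSet(condition_label=condition_label, peaks=peaks)


def write_peaks(pset: PeakSet, path: str, narrow: bool = False) -> None:
    """Write BED6, or narrowPeak when ``narrow`` (summit -1 if absent)."""
    with open(path, "w") as fh:
        for p in pset:
            iv = p.interval
            score = "0" if p.score is None else f"{p.score:g}"
            row = [iv.chrom, str(iv.start), str(iv.end), p.name, score, iv.strand]
            if narrow:
                so = -1 if p.summit_offset is None else p.summit_offset
                row += ["0", "-1", "-1", str(so)]
            fh.write("\t".join(row) + "\n")


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap: int = 1) -> bool:
    """True iff the two intervals share at least ``min_overlap`` bp.

    Strand is ignored; chromosomes must match.  Half-open arithmetic:
    the shared length is ``min(end_a, end_b) - max(start_a, start_b)``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_overlap


class _ChromIndex:
    """Sorted-start index of intervals on one chromosome with prefix max-end.

    Supports O(log n) "does [s, e) overlap anything here" queries:
    candidates are intervals starting before e; at least one of them
    reaches past s iff the running maximum of their ends exceeds s.
    """

    def __init__(self, intervals: Sequence[tuple[int, int]]):
        ivs = sorted(intervals)
        self.starts = [s for s, _ in ivs]
        self.ends = [e for _, e in ivs]
        self.prefix_max_end: list[int] = []
        running = -1
        for e in self.ends:
            running = max(running, e)
            self.prefix_max_end.append(running)

    def any_overlap(self, start: int, end: int, min_overlap: int = 1) -> bool:
        # intervals with start <= end - min_overlap can still share min_overlap bp
        idx = bisect.bisect_right(self.starts, end - min_overlap)
        if idx == 0:
            return False
        if min_overlap == 1:
            return self.prefix_max_end[idx - 1] >= start + min_overlap
        # the prefix-max shortcut can mix two intervals for thicker overlaps;
        # verify candidates explicitly (rarely used path)
        return any(
            min(end, self.ends[i]) - max(start, self.starts[i]) >= min_overlap
            for i in range(idx)
        )

    def any_within(self, start: int, end: int, max_gap: int) -> bool:
        """True iff some interval has edge-to-edge gap <= max_gap with [start, end)."""
        idx = bisect.bisect_right(self.starts, end + max_gap)
        if idx == 0:
            return False
        return self.prefix_max_end[idx - 1] >= start - max_gap


def _index_peaks(pset: PeakSet) -> dict[str, _ChromIndex]:
    return {
        chrom: _ChromIndex([(p.interval.start, p.interval.end) for p in plist])
        for chrom, plist in pset.by_chrom().items()
    }


def partition_peaks(
    set_a: PeakSet, set_b: PeakSet, min_overlap: int = 1
) -> PeakPartition:
    """Partition two condition peak sets into common and specific peaks.

    A peak of A is *common* iff it overlaps (>= ``min_overlap`` bp) at least
    one peak of B, else *A-specific*; symmetrically for B.  Implemented as a
    sorted sweep per chromosome, equivalent to the all-pairs test.
    """
    idx_b = _index_peaks(set_b)
    idx_a = _index_peaks(set_a)

    def split(pset: PeakSet, other_idx: dict[str, _ChromIndex]) -> tuple[list[Peak], list[Peak]]:
        common: list[Peak] = []
        specific: list[Peak] = []
        for p in pset:
            ci = other_idx.get(p.chrom)
            if ci is not None and ci.any_overlap(
                p.interval.start, p.interval.end, min_overlap
            ):
                common.append(p)
            else:
                specific.append(p)
        return common, specific

    common_a, specific_a = split(set_a, idx_b)
    common_b, specific_b = split(set_b, idx_a)
    la, lb = set_a.condition_label, set_b.condition_label
    return PeakPartition(
        common_a=PeakSet(f"{la}_common", common_a),
        common_b=PeakSet(f"{lb}_common", common_b),
        specific_a=PeakSet(f"{la}_specific", specific_a),
        specific_b=PeakSet(f"{lb}_specific", specific_b),
    )


def _signed_tss_distance(point: int, gene: GeneModel) -> int:
    """Distance from a point to the gene TSS, negative upstream of the TSS."""
    if gene.strand == "+":
        return point - gene.tss
    return gene.tss - point


def _nearest_gene(
    point: int, chrom: str, genes: Sequence[GeneModel]
) -> tuple[str | None, int | None]:
    best: tuple[int, str] | None = None
    best_gene: GeneModel | None = None
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(point - g.tss)
        key = (d, g.gene_id)
        if best is None or key < best:
            best = key
            best_gene = g
    if best_gene is None:
        return None, None
    return best_gene.gene_id, _signed_tss_distance(point, best_gene)


def annotate_peak(
    peak: Peak,
    annotation: GenomeAnnotation,
    promoter_up: int = 2000,
    promoter_down: int = 2000,
    downstream_window: int = 3000,
    use_summit: bool = True,
) -> AnnotatedPeak:
    """Assign a feature class and nearest gene to one peak.

    The overlap test uses the summit base when ``use_summit`` and a summit is
    recorded, else the full peak interval.  Precedence:
    Promoter > Exon > Intron > Downstream > DistalIntergenic.  The nearest
    gene minimises |anchor - TSS|, ties broken by gene_id.
    """
    if len(annotation) == 0:
        raise PeakError("cannot annotate against an empty annotation")

    if use_summit and peak.summit is not None:
        q_start, q_end = peak.summit, peak.summit + 1
    else:
        q_start, q_end = peak.interval.start, peak.interval.end

    def hits(start: int, end: int) -> bool:
        return min(q_end, end) - max(q_start, start) >= 1

    genes = [g for g in annotation if g.chrom == peak.chrom]

    feature = Feature.DISTAL_INTERGENIC
    in_promoter = in_exon = in_intron = in_downstream = False
    for g in genes:
        chrom_len = annotation.chrom_length(g.chrom)
        prom = promoter_region(g, promoter_up, promoter_down, chrom_len)
        if hits(prom.start, prom.end):
            in_promoter = True
            break
        if hits(g.interval.start, g.interval.end):
            if any(hits(s, e) for s, e in g.exon_intervals()):
                in_exon = True
            else:
                in_intron = True
            continue
        # downstream window past the TES in transcript orientation
        if g.strand == "+":
            ds, de = g.interval.end, g.interval.end + downstream_window
        else:
            ds, de = max(g.interval.start - downstream_window, 0), g.interval.start
        if de > ds and hits(ds, de):
            in_downstream = True

    if in_promoter:
        feature = Feature.PROMOTER
    elif in_exon:
        feature = Feature.EXON
    elif in_intron:
        feature = Feature.INTRON
    elif in_downstream:
        feature = Feature.DOWNSTREAM

    gene_id, distance = _nearest_gene(peak.anchor_point, peak.chrom, list(annotation))
    return AnnotatedPeak(
        peak=peak, feature=feature, nearest_gene_id=gene_id, distance_bp=distance
    )


def annotate_peaks(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    promoter_up: int = 2000,
    promoter_down: int = 2000,
    downstream_window: int = 3000,
    use_summit: bool = True,
) -> list[AnnotatedPeak]:
    return [
        annotate_peak(
            p, annotation, promoter_up, promoter_down, downstream_window, use_summit
        )
        for p in peaks
    ]


def feature_distribution(
    annotated: Iterable[AnnotatedPeak],
) -> tuple[dict[Feature, int], dict[Feature, float]]:
    """Counts and fractions of peaks per feature class (fractions sum to 1)."""
    annotated = list(annotated)
    if not annotated:
        raise PeakError("feature_distribution of an empty collection")
    counts: dict[Feature, int] = {}
    for ap in annotated:
        counts[ap.feature] = counts.get(ap.feature, 0) + 1
    total = len(annotated)
    fractions = {f: c / total for f, c in counts.items()}
    return counts, fractions


def genes_near_peaks(
    peaks: PeakSet, annotation: GenomeAnnotation, max_distance: int = 20000
) -> list[str]:
    """Gene ids whose edge-to-edge gap to any peak is <= ``max_distance``.

    Overlap counts as gap 0; the boundary is inclusive (a gap of exactly
    ``max_distance`` bp associates).  Output sorted for determinism.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    idx = _index_peaks(peaks)
    hit: list[str] = []
    for g in annotation:
        ci = idx.get(g.chrom)
        if ci is not None and ci.any_within(g.interval.start, g.interval.end, max_distance):
            hit.append(g.gene_id)
    return sorted(hit)


def write_annotated_peaks(annotated: Sequence[AnnotatedPeak], path: str) -> None:
    """TSV: chrom, start, end, name, feature, nearest_gene, distance_to_tss."""
    import pandas as pd

    rows = [
        {
            "chrom": ap.peak.chrom,
            "start": ap.peak.interval.start,
            "end": ap.peak.interval.end,
            "name": ap.peak.name,
            "feature": ap.feature.value,
            "nearest_gene": ap.nearest_gene_id or ".",
            "distance_to_tss": ap.distance_bp if ap.distance_bp is not None else ".",
        }
        for ap in annotated
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
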