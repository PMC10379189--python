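"""Gene annotation parsing and the promoter / TSS-region / gene-body region system.

All coordinates are 0-based half-open (BED convention) internally; GTF/GFF3
1-based closed coordinates are converted on read and write.  The transcription
start site (TSS) is the strand-aware 5' end of the gene, the transcription end
site (TES) the 3' end, both stored as single base positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GenomeAnnotation",
    "AnnotationError",
    "read_annotation",
    "write_annotation",
    "read_chrom_sizes",
    "promoter_region",
    "gene_body_region",
]

_STRANDS = frozenset({"+", "-", "."})


class AnnotationError(ValueError):
    """Raised for malformed annotation input or invalid region requests."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must be > start (empty intervals rejected).
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise AnnotationError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise AnnotationError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """One gene: identifier, span and strand-aware TSS/TES positions.

    ``tss`` and ``tes`` are base positions: for a ``+`` gene the TSS is
    ``interval.start`` and the TES ``interval.end - 1``; for a ``-`` gene the
    roles mirror.  Optional ``exons`` (list of half-open (start, end) pairs)
    support exon/intron feature annotation; when absent the full gene span is
    treated as a single exon.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.interval.strand!r}"
            )
        for s, e in self.exons:
            if not (self.interval.start <= s < e <= self.interval.end):
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{s}, {e}) outside gene span"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    def exon_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exons, or the full gene span when no exon structure is recorded."""
        if self.exons:
            return self.exons
        return ((self.interval.start, self.interval.end),)


@dataclass
class GenomeAnnotation:
    """A collection of genes keyed by gene_id plus chromosome lengths.

    Iteration order is deterministic: sorted by (chrom, start, gene_id).
    """

    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes.values():
            self._check_fits(g)

    def _check_fits(self, gene: GeneModel) -> None:
        size = self.chrom_sizes.get(gene.chrom)
        if size is not None and gene.interval.end > size:
            raise AnnotationError(
                f"gene {gene.gene_id} extends past end of {gene.chrom} ({size} bp)"
            )

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id {gene.gene_id!r}")
        self._check_fits(gene)
        self.genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(
            sorted(
                self.genes.values(),
                key=lambda g: (g.chrom, g.interval.start, g.gene_id),
            )
        )

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def chrom_length(self, chrom: str) -> int | None:
        return self.chrom_sizes.get(chrom)


def _parse_attributes(attr_field: str, gff3: bool) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if gff3:
        for part in attr_field.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, val = part.partition("=")
            attrs[key.strip()] = val.strip()
    else:
        for part in attr_field.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, val = part.partition(" ")
            attrs[key.strip()] = val.strip().strip('"')
    return attrs


def read_annotation(
    path: str,
    feature: str = "gene",
    chrom_sizes: Mapping[str, int] | None = None,
    exon_feature: str = "exon",
) -> GenomeAnnotation:
    """Read a GTF or GFF3 file into a :class:`GenomeAnnotation`.

    GTF 1-based closed coordinates become 0-based half-open
    (``start = GTF_start - 1``, ``end = GTF_end``).  Gene identifiers come
    from the ``gene_id`` attribute (GTF) or ``ID`` (GFF3).  Records of type
    ``exon_feature`` carrying a matching gene id are attached as exon
    structure.  Chromosome sizes default to the rightmost coordinate seen per
    chromosome when not supplied.
    """
    gff3 = path.endswith((".gff", ".gff3"))
    spans: dict[str, tuple[str, int, int, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order_check: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(cols)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr = cols
            if ftype not in (feature, exon_feature):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise AnnotationError(
                    f"{path}:{lineno}: invalid coordinates {start1}..{end1}"
                )
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(attr, gff3)
            gene_id = attrs.get("gene_id") or attrs.get("ID") or attrs.get("Parent")
            if not gene_id:
                raise AnnotationError(f"{path}:{lineno}: no gene identifier attribute")
            start, end = start1 - 1, end1
            if ftype == feature:
                if gene_id in order_check:
                    raise AnnotationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
                order_check.add(gene_id)
                spans[gene_id] = (chrom, start, end, strand)
            else:
                exons.setdefault(gene_id, []).append((start, end))

    ann = GenomeAnnotation(chrom_sizes=dict(chrom_sizes or {}))
    for gene_id, (chrom, start, end, strand) in spans.items():
        gene_exons = tuple(sorted(exons.get(gene_id, [])))
        ann.add(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(chrom, start, end, strand),
                exons=gene_exons,
            )
        )
    if not chrom_sizes:
        sizes: dict[str, int] = {}
        for g in ann.genes.values():
            sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.interval.end)
        ann.chrom_sizes = sizes
    return ann


def write_annotation(ann: GenomeAnnotation, path: str, source: str = "chipcross") -> None:
    """Write genes (and any exon structure) as GTF 2.2."""
    with open(path, "w") as fh:
        for g in ann:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{iv.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected two columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def promoter_region(
    gene: GeneModel,
    upstream: int = 2000,
    downstream: int = 2000,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware window around the TSS, clipped to chromosome bounds.

    The window covers ``tss - upstream .. tss + downstream`` inclusive in
    transcript orientation, i.e. ``upstream + downstream + 1`` bp before
    clipping; for a ``-``-strand gene "upstream" extends toward larger
    coordinates.
    """
    if upstream < 0 or downstream < 0:
        raise AnnotationError("promoter window extents must be >= 0")
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - upstream, tss + downstream + 1
    else:
        start, end = tss - downstream, tss + upstream + 1
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if end <= start:
        raise AnnotationError(
            f"promoter window of gene {gene.gene_id} lies entirely off-chromosome"
        )
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def gene_body_region(gene: GeneModel, tss_exclusion: int = 2000) -> GenomicInterval | None:
    """Gene interval minus the first ``tss_exclusion`` bp downstream of the TSS.

    Keeps the gene-body region disjoint from the TSS-proximal window by
    construction; returns None when the gene is shorter than the exclusion
    (``tss_exclusion = 0`` restores the full gene span).
    """
    iv = gene.interval
    if len(iv) <= tss_exclusion:
        return None
    if gene.strand == "+":
        # skip one extra base so the body starts strictly past tss + exclusion
        start, end = iv.start + tss_exclusion + 1, iv.end
    else:
        start, end = iv.start, iv.end - tss_exclusion - 1
    if end <= start:
        return None
    return GenomicInterval(iv.chrom, start, end, gene.strand)
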