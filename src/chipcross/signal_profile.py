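"""Binned coverage tracks and anchored (TSS/TES) metagene signal matrices.

A :class:`SignalTrack` holds per-chromosome coverage averaged into fixed-size
bins.  bedGraph records are length-weighted into the bins on read, so total
signal (value x covered length) is conserved.  Profile rows are strand
oriented: 5'->3' left to right, with the anchor at the centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import GenomeAnnotation, GenomicInterval

__all__ = [
    "SignalTrack",
    "ProfileMatrix",
    "SignalError",
    "read_bedgraph",
    "write_bedgraph",
    "anchored_profile",
    "region_mean_signal",
]


class SignalError(ValueError):
    """Raised for malformed coverage input or out-of-bounds regions."""


@dataclass
class SignalTrack:
    """Per-chromosome binned coverage for one condition.

    ``values[chrom]`` has length ``ceil(chrom_length / bin_size)``; each entry
    is the mean coverage over that bin.  All values are non-negative.
    """

    condition_label: str
    bin_size: int
    chrom_sizes: dict[str, int]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise SignalError("bin_size must be >= 1")
        for chrom, length in self.chrom_sizes.items():
            n_bins = -(-length // self.bin_size)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n_bins)
            elif len(self.values[chrom]) != n_bins:
                raise SignalError(
                    f"{chrom}: expected {n_bins} bins, got {len(self.values[chrom])}"
                )
            if np.any(self.values[chrom] < 0):
                raise SignalError(f"{chrom}: negative coverage values")

    def total_signal(self) -> float:
        """Sum over bins of value x bin length (bp-weighted, respecting the
        possibly short last bin)."""
        total = 0.0
        for chrom, arr in self.values.items():
            length = self.chrom_sizes[chrom]
            widths = np.full(len(arr), self.bin_size, dtype=float)
            if len(arr):
                widths[-1] = length - (len(arr) - 1) * self.bin_size
            total += float(np.dot(arr, widths))
        return total


@dataclass
class ProfileMatrix:
    """Per-gene signal vectors in a fixed window around TSS or TES.

    Rows are strand-oriented; ``mean_profile`` is the column mean.  Genes
    whose window ran past a chromosome edge are zero-padded there and listed
    in ``clipped_gene_ids``.
    """

    anchor: str
    flank: int
    n_bins: int
    gene_ids: list[str]
    rows: np.ndarray
    clipped_gene_ids: list[str] = field(default_factory=list)

    @property
    def mean_profile(self) -> np.ndarray:
        return self.rows.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        offsets = (np.arange(self.n_bins) - self.n_bins // 2) * (
            2 * self.flank // self.n_bins
        )
        return pd.DataFrame(self.rows, index=self.gene_ids, columns=offsets)

    def write_tsv(self, path: str) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def read_bedgraph(
    path: str,
    chrom_sizes: dict[str, int],
    bin_size: int = 50,
    condition_label: str = "",
) -> SignalTrack:
    """Read a bedGraph file into a binned :class:`SignalTrack`.

    Record values are length-weighted into the fixed bins: a record covering
    half a bin contributes half its value to that bin's mean.  Uncovered
    bases count as coverage 0.  Overlapping records are rejected — the signal
    they would assign is ambiguous.
    """
    track = SignalTrack(
        condition_label=condition_label, bin_size=bin_size, chrom_sizes=dict(chrom_sizes)
    )
    sums = {c: np.zeros(len(v)) for c, v in track.values.items()}
    last_end: dict[str, int] = {}
    intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise SignalError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if chrom not in chrom_sizes:
                raise SignalError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise SignalError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside {chrom}"
                )
            if value < 0:
                raise SignalError(f"{path}:{lineno}: negative coverage {value}")
            intervals[chrom].append((start, end))
            _accumulate(sums[chrom], start, end, value, bin_size)

    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise SignalError(
                    f"{path}: overlapping bedGraph records on {chrom} at {s2}"
                )

    for chrom, arr in sums.items():
        length = chrom_sizes[chrom]
        widths = np.full(len(arr), bin_size, dtype=float)
        if len(arr):
            widths[-1] = length - (len(arr) - 1) * bin_size
        track.values[chrom] = np.divide(
            arr, widths, out=np.zeros_like(arr), where=widths > 0
        )
    return track


def _accumulate(sums: np.ndarray, start: int, end: int, value: float, bin_size: int) -> None:
    """Add value x overlap-length of [start, end) into each bin's sum."""
    first, last = start // bin_size, (end - 1) // bin_size
    for b in range(first, last + 1):
        b_start, b_end = b * bin_size, (b + 1) * bin_size
        ov = min(end, b_end) - max(start, b_start)
        sums[b] += value * ov


def write_bedgraph(track: SignalTrack, path: str) -> None:
    """Write the binned track back out, merging equal-valued adjacent bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            length = track.chrom_sizes[chrom]
            i = 0
            while i < len(arr):
                j = i
                while j + 1 < len(arr) and arr[j + 1] == arr[i]:
                    j += 1
                if arr[i] != 0:
                    start = i * track.bin_size
                    end = min((j + 1) * track.bin_size, length)
                    fh.write(f"{chrom}\t{start}\t{end}\t{arr[i]:g}\n")
                i = j + 1


def region_mean_signal(track: SignalTrack, region: GenomicInterval) -> float:
    """Base-pair-weighted mean coverage over a region.

    Each track bin contributes its value weighted by its overlap with the
    region, so partial bins count partially.
    """
    if region.chrom not in track.values:
        raise SignalError(f"region on unknown chromosome {region.chrom!r}")
    length = track.chrom_sizes[region.chrom]
    if region.start < 0 or region.end > length:
        raise SignalError(
            f"region [{region.start}, {region.end}) outside {region.chrom} ({length} bp)"
        )
    return _window_mean(track, region.chrom, region.start, region.end, clip=False)


def _window_mean(
    track: SignalTrack, chrom: str, start: int, end: int, clip: bool
) -> float:
    """Mean coverage over [start, end); out-of-bounds bases count 0 if clip."""
    arr = track.values[chrom]
    bs = track.bin_size
    length = track.chrom_sizes[chrom]
    span = end - start
    s, e = (max(start, 0), min(end, length)) if clip else (start, end)
    if e <= s:
        return 0.0
    total = 0.0
    first, last = s // bs, (e - 1) // bs
    for b in range(first, last + 1):
        b_start, b_end = b * bs, (b + 1) * bs
        ov = min(e, b_end) - max(s, b_start)
        total += arr[b] * ov
    return total / span


def anchored_profile(
    track: SignalTrack,
    genes: GenomeAnnotation,
    anchor: str = "TSS",
    flank: int = 3000,
    bin_size: int | None = None,
) -> ProfileMatrix:
    """Per-gene signal matrix in a ±``flank`` bp window around TSS or TES.

    Each row has ``2 * flank / bin_size`` bins covering
    ``[anchor - flank, anchor + flank)`` in genome coordinates, reversed for
    ``-``-strand genes so every row reads 5'->3'.  Windows running past a
    chromosome edge are zero-padded and the gene flagged as clipped.
    """
    anchor = anchor.upper()
    if anchor not in ("TSS", "TES"):
        raise SignalError(f"anchor must be TSS or TES, got {anchor!r}")
    if len(genes) == 0:
        raise SignalError("anchored_profile needs at least one gene")
    bin_size = bin_size or track.bin_size
    if flank % bin_size != 0:
        raise SignalError(f"flank {flank} not a multiple of bin size {bin_size}")
    n_bins = 2 * flank // bin_size

    gene_ids: list[str] = []
    clipped: list[str] = []
    rows = np.zeros((len(genes), n_bins))
    for i, g in enumerate(genes):
        pos = g.tss if anchor == "TSS" else g.tes
        w_start = pos - flank
        length = track.chrom_sizes.get(g.chrom)
        if length is None:
            raise SignalError(f"gene {g.gene_id}: chromosome {g.chrom!r} not in track")
        if w_start < 0 or pos + flank > length:
            clipped.append(g.gene_id)
        for b in range(n_bins):
            rows[i, b] = _window_mean(
                track, g.chrom, w_start + b * bin_size, w_start + (b + 1) * bin_size, clip=True
            )
        if g.strand == "-":
            rows[i] = rows[i, ::-1]
        gene_ids.append(g.gene_id)

    return ProfileMatrix(
        anchor=anchor,
        flank=flank,
        n_bins=n_bins,
        gene_ids=gene_ids,
        rows=rows,
        clipped_gene_ids=clipped,
    )
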