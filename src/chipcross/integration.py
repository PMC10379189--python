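"""Gained/lost region-change calls and the ChIP-seq x RNA-seq intersections.

A gene *gains* histone-mark signal in a region (TSS window or gene body) when
at least one treatment-specific peak overlaps that region by >= 1 bp, and
*loses* signal when a control-specific peak does.  Differential expression is
called on a plain fold-change threshold (default 1.25-fold, boundary
inclusive).  The integration joins the 20-kb peak-associated gene set with
the up/down sets and splits the intersection into region x direction x sign
quadrants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .genome_model import GenomeAnnotation, gene_body_region, promoter_region
from .peak_toolkit import PeakPartition, PeakSet, overlaps

__all__ = [
    "RegionChangeCall",
    "ExpressionRecord",
    "DEGSet",
    "IntegrationResult",
    "classify_region_changes",
    "read_expression_table",
    "call_degs",
    "integrate",
    "write_calls",
    "write_degs",
]

REGIONS = ("TSS", "gene_body")
DIRECTIONS = ("gained", "lost")
SIGNS = ("up", "down")


@dataclass(frozen=True)
class RegionChangeCall:
    """One (gene, region, direction) call with its evidence peaks."""

    gene_id: str
    region: str  # "TSS" | "gene_body"
    direction: str  # "gained" | "lost"
    evidence_peaks: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not self.evidence_peaks:
            raise ValueError("a region-change call needs at least one evidence peak")


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene mean expression in treatment and control."""

    gene_id: str
    mean_treatment: float
    mean_control: float

    def __post_init__(self) -> None:
        if self.mean_treatment < 0 or self.mean_control < 0:
            raise ValueError(f"gene {self.gene_id}: negative expression mean")


@dataclass
class DEGSet:
    """Up/down differentially expressed gene sets at a fold threshold."""

    up: set[str]
    down: set[str]
    fold_threshold: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up and down")

    @property
    def all_degs(self) -> set[str]:
        return self.up | self.down


@dataclass
class IntegrationResult:
    """Intersection structure joining peak-associated genes with DEGs.

    ``common_genes``: peak-associated genes that are differentially
    expressed.  ``both_down``: common genes with a lost-signal call (either
    region) that are down-regulated.  ``quadrants``: for every
    (region, direction, sign) the common genes carrying that combination.
    """

    common_genes: set[str]
    both_down: set[str]
    quadrants: dict[tuple[str, str, str], set[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {
            "common_genes": len(self.common_genes),
            "both_down": len(self.both_down),
        }
        for key, genes in sorted(self.quadrants.items()):
            out["_".join(key)] = len(genes)
        return out

    def to_json(self, path: str) -> None:
        payload = {
            "common_genes": sorted(self.common_genes),
            "both_down": sorted(self.both_down),
            "quadrants": {
                "_".join(k): sorted(v) for k, v in sorted(self.quadrants.items())
            },
            "counts": self.counts(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def classify_region_changes(
    partition: PeakPartition,
    annotation: GenomeAnnotation,
    tss_up: int = 2000,
    tss_down: int = 2000,
    tss_exclusion: int | None = None,
) -> set[RegionChangeCall]:
    """Call per-gene gained/lost signal in the TSS window and gene body.

    ``partition`` must come from partition_peaks(treatment, control):
    treatment-specific peaks are *gained* evidence, control-specific peaks
    *lost* evidence.  A gene may carry several calls (both regions, or both
    directions when opposing evidence exists); nothing is collapsed.
    ``tss_exclusion`` defaults to ``tss_down`` so TSS and body regions are
    disjoint.
    """
    if tss_exclusion is None:
        tss_exclusion = tss_down
    calls: dict[tuple[str, str, str], list[str]] = {}

    def scan(specific: PeakSet, direction: str) -> None:
        by_chrom = specific.by_chrom()
        for g in annotation:
            peaks = by_chrom.get(g.chrom)
            if not peaks:
                continue
            chrom_len = annotation.chrom_length(g.chrom)
            tss_region = promoter_region(g, tss_up, tss_down, chrom_len)
            body = gene_body_region(g, tss_exclusion)
            for p in peaks:
                if overlaps(p.interval, tss_region):
                    calls.setdefault((g.gene_id, "TSS", direction), []).append(p.name)
                if body is not None and overlaps(p.interval, body):
                    calls.setdefault((g.gene_id, "gene_body", direction), []).append(p.name)

    scan(partition.specific_a, "gained")
    scan(partition.specific_b, "lost")
    return {
        RegionChangeCall(gene_id=g, region=r, direction=d, evidence_peaks=tuple(sorted(ev)))
        for (g, r, d), ev in calls.items()
    }


def read_expression_table(path: str) -> tuple[list[ExpressionRecord], dict[str, float]]:
    """Read a TSV with columns gene_id, mean_treatment, mean_control[, qvalue].

    Returns the records plus any per-gene q-values found.  Genes with both
    means zero are dropped (no usable signal).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "mean_treatment", "mean_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[ExpressionRecord] = []
    qvalues: dict[str, float] = {}
    for row in df.itertuples(index=False):
        t, c = float(row.mean_treatment), float(row.mean_control)
        if t == 0 and c == 0:
            continue
        records.append(ExpressionRecord(str(row.gene_id), t, c))
        if hasattr(row, "qvalue"):
            qvalues[str(row.gene_id)] = float(row.qvalue)
    return records, qvalues


def call_degs(
    records: Iterable[ExpressionRecord],
    fold_threshold: float = 1.25,
    pseudocount: float = 0.0,
    qvalues: Mapping[str, float] | None = None,
    q_cutoff: float | None = None,
) -> DEGSet:
    """Call up/down genes on a fold-change threshold (boundary inclusive).

    A gene is up when (treatment + pseudocount) / (control + pseudocount)
    >= ``fold_threshold`` and down when the ratio <= 1 / fold_threshold.
    With pseudocount 0 a zero control mean makes the gene up if the
    treatment mean is positive, else the gene is excluded.  An optional
    q-value filter keeps only genes with q < ``q_cutoff``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    up: set[str] = set()
    down: set[str] = set()
    for rec in records:
        if q_cutoff is not None:
            q = (qvalues or {}).get(rec.gene_id)
            if q is None or q >= q_cutoff:
                continue
        num = rec.mean_treatment + pseudocount
        den = rec.mean_control + pseudocount
        if den == 0:
            if num > 0:
                up.add(rec.gene_id)
            continue
        ratio = num / den
        if ratio >= fold_threshold:
            up.add(rec.gene_id)
        elif ratio <= 1.0 / fold_threshold:
            down.add(rec.gene_id)
    return DEGSet(up=up, down=down, fold_threshold=fold_threshold)


def integrate(
    changes: Iterable[RegionChangeCall],
    degs: DEGSet,
    diff_peak_genes: Iterable[str],
) -> IntegrationResult:
    """Join the 20-kb peak-associated gene set with the DEG sets.

    ``common_genes`` = peak-associated ∩ (up ∪ down); ``both_down`` = common
    genes with at least one lost call (either region) that are down;
    ``quadrants[(region, direction, sign)]`` = common genes with that
    region-change call and DEG sign.
    """
    changes = list(changes)
    diff_genes = set(diff_peak_genes)
    common = diff_genes & degs.all_degs

    lost_genes = {c.gene_id for c in changes if c.direction == "lost"}
    both_down = common & lost_genes & degs.down

    quadrants: dict[tuple[str, str, str], set[str]] = {
        (r, d, s): set() for r in REGIONS for d in DIRECTIONS for s in SIGNS
    }
    sign_of: dict[str, str] = {}
    for g in degs.up:
        sign_of[g] = "up"
    for g in degs.down:
        sign_of[g] = "down"
    for call in changes:
        g = call.gene_id
        if g not in common:
            continue
        sign = sign_of.get(g)
        if sign is None:
            continue
        quadrants[(call.region, call.direction, sign)].add(g)

    return IntegrationResult(common_genes=common, both_down=both_down, quadrants=quadrants)


def write_calls(changes: Iterable[RegionChangeCall], path: str) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "region": c.region,
            "direction": c.direction,
            "evidence_peaks": ",".join(c.evidence_peaks),
        }
        for c in sorted(changes, key=lambda c: (c.gene_id, c.region, c.direction))
    ]
    pd.DataFrame(rows, columns=["gene_id", "region", "direction", "evidence_peaks"]).to_csv(
        path, sep="\t", index=False
    )


def write_degs(degs: DEGSet, path: str) -> None:
    rows = [{"gene_id": g, "direction": "up"} for g in sorted(degs.up)]
    rows += [{"gene_id": g, "direction": "down"} for g in sorted(degs.down)]
    pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(path, sep="\t", index=False)
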