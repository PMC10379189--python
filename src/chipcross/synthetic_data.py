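"""Synthetic miniature ChIP-seq x RNA-seq experiment with known ground truth.

The generator lays out a small genome of non-overlapping genes separated by
wide intergenic gaps, then plants:

* *background peaks* — present in both conditions with guaranteed >=1 bp
  mutual overlap, so the condition partition classifies them as common;
* *condition-specific peaks* — placed inside the TSS window or gene body of
  designated genes: a treatment-specific peak is "gained" evidence, a
  control-specific peak "lost" evidence.  Intergenic gaps are wide enough
  that a specific peak sits within 20 kb of its own gene only;
* *expression changes* — planted up/down genes at fixed fold ratios beyond
  the 1.25-fold calling threshold, remaining genes at ratios inside
  [1/1.1, 1.1] so they can never cross it at zero noise;
* *a term map* — one term covering exactly the planted lost-and-down genes
  plus random decoy terms.

Down-regulated genes are assigned, direction-matched, to lost-signal genes
first (and up to gained-signal genes) in the fraction ``overlap_with_changes``
of the planted DEG count, capped by availability; the remainder fall on
unchanged genes.  All coordinates are integers and every random draw comes
from one seeded generator, so emitted files are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_model import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    gene_body_region,
    promoter_region,
    write_annotation,
)
from .peak_toolkit import Peak, PeakSet, overlaps, write_peaks

__all__ = ["SyntheticDesign", "TruthTable", "SyntheticBundle", "generate", "perturb"]

# geometry constants (bp): peak half-widths and placement offsets
_TSS_PEAK_HALF = 200
_BODY_PEAK_OFFSET = 2500  # transcript-coordinate start of body peaks, past the TSS exclusion
_BODY_PEAK_WIDTH = 400
_BG_PEAK_WIDTH = 600
_BG_OFFSET = 24000  # background peaks this far into a gap, clear of the 20 kb zone
_PEAK_HEIGHT = 10.0
_BASELINE = 1.0
_EXPR_BASELINE = 100.0


@dataclass
class SyntheticDesign:
    """Parameters of the planted experiment.

    Defaults encode the reference verification scenario: 50 genes with 5
    lost-at-TSS, 3 gained-at-TSS and 4 lost-in-body genes, 10 down- and 6
    up-regulated genes fully overlapping the signal changes, at zero
    expression noise.
    """

    n_chroms: int = 2
    chrom_length: int = 2_500_000
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (8000, 15000)
    min_intergenic_gap: int = 60000
    n_lost_tss: int = 5
    n_gained_tss: int = 3
    n_lost_body: int = 4
    n_gained_body: int = 0
    n_up: int = 6
    n_down: int = 10
    overlap_with_changes: float = 1.0
    background_peaks_per_condition: int = 30
    fold_up: float = 2.0
    fold_down: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        planted = self.n_lost_tss + self.n_gained_tss + self.n_lost_body + self.n_gained_body
        if planted > self.n_genes:
            raise ValueError("more planted region-change genes than genes")
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("more planted DEGs than genes")
        if not (0.0 <= self.overlap_with_changes <= 1.0):
            raise ValueError("overlap_with_changes must be in [0, 1]")
        if self.gene_length_range[0] < 3000:
            raise ValueError("genes must be >= 3000 bp so body peaks fit past the TSS window")
        if self.min_intergenic_gap < 24000:
            raise ValueError(
                "min_intergenic_gap must be >= 24000 so specific peaks stay "
                ">20 kb from neighbouring genes"
            )
        if self.fold_up < 1.25 or self.fold_down > 1 / 1.25:
            raise ValueError("planted folds must clear the 1.25-fold threshold")


@dataclass
class TruthTable:
    """Planted labels per gene plus the expected pipeline outputs."""

    region_changes: dict[str, list[tuple[str, str]]]  # gene -> [(region, direction)]
    deg_sign: dict[str, str]  # gene -> "up" | "down"
    diff_peak_genes: list[str]
    common_genes: list[str]
    both_down: list[str]
    quadrants: dict[str, list[str]]  # "TSS_lost_down" -> genes
    planted_term: str | None
    evidence: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    # peak name -> (gene, region, direction)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region_changes": {g: sorted(v) for g, v in sorted(self.region_changes.items())},
            "deg_sign": dict(sorted(self.deg_sign.items())),
            "diff_peak_genes": sorted(self.diff_peak_genes),
            "common_genes": sorted(self.common_genes),
            "both_down": sorted(self.both_down),
            "quadrants": {k: sorted(v) for k, v in sorted(self.quadrants.items())},
            "planted_term": self.planted_term,
            "evidence": {k: list(v) for k, v in sorted(self.evidence.items())},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            region_changes={g: [tuple(x) for x in v] for g, v in d["region_changes"].items()},
            deg_sign=d["deg_sign"],
            diff_peak_genes=d["diff_peak_genes"],
            common_genes=d["common_genes"],
            both_down=d["both_down"],
            quadrants=d["quadrants"],
            planted_term=d["planted_term"],
            evidence={k: tuple(v) for k, v in d.get("evidence", {}).items()},
        )


@dataclass
class SyntheticBundle:
    """Generated files plus in-memory state needed for perturbations."""

    outdir: Path
    design: SyntheticDesign
    annotation: GenomeAnnotation
    peaks_treatment: PeakSet
    peaks_control: PeakSet
    expression: dict[str, tuple[float, float]]  # gene -> (mean_treatment, mean_control)
    truth: TruthTable

    @property
    def paths(self) -> dict[str, Path]:
        d = self.outdir
        return {
            "annotation": d / "annotation.gtf",
            "chrom_sizes": d / "chrom.sizes",
            "peaks_treatment": d / "peaks_treatment.narrowPeak",
            "peaks_control": d / "peaks_control.narrowPeak",
            "track_treatment": d / "coverage_treatment.bedgraph",
            "track_control": d / "coverage_control.bedgraph",
            "expression": d / "expression.tsv",
            "terms": d / "terms.gmt",
            "truth": d / "truth.json",
        }

    def write(self) -> None:
        self.outdir.mkdir(parents=True, exist_ok=True)
        p = self.paths
        write_annotation(self.annotation, str(p["annotation"]))
        with open(p["chrom_sizes"], "w") as fh:
            for chrom, size in sorted(self.annotation.chrom_sizes.items()):
                fh.write(f"{chrom}\t{size}\n")
        write_peaks(self.peaks_treatment, str(p["peaks_treatment"]), narrow=True)
        write_peaks(self.peaks_control, str(p["peaks_control"]), narrow=True)
        _write_coverage(
            self.peaks_treatment, self.annotation.chrom_sizes, p["track_treatment"]
        )
        _write_coverage(
            self.peaks_control, self.annotation.chrom_sizes, p["track_control"]
        )
        with open(p["expression"], "w") as fh:
            fh.write("gene_id\tmean_treatment\tmean_control\n")
            for gene_id in sorted(self.expression):
                t, c = self.expression[gene_id]
                fh.write(f"{gene_id}\t{t:.6f}\t{c:.6f}\n")
        self.truth.to_json(p["truth"])


def _write_coverage(peaks: PeakSet, chrom_sizes: dict[str, int], path: Path) -> None:
    """Flat baseline coverage with elevated plateaus under the peaks."""
    by_chrom = peaks.by_chrom()
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            length = chrom_sizes[chrom]
            pos = 0
            for p in by_chrom.get(chrom, []):
                s, e = p.interval.start, p.interval.end
                if s > pos:
                    fh.write(f"{chrom}\t{pos}\t{s}\t{_BASELINE:g}\n")
                fh.write(f"{chrom}\t{s}\t{e}\t{_PEAK_HEIGHT:g}\n")
                pos = e
            if pos < length:
                fh.write(f"{chrom}\t{pos}\t{length}\t{_BASELINE:g}\n")


def _layout_genes(design: SyntheticDesign, rng: np.random.Generator) -> GenomeAnnotation:
    """Place non-overlapping genes with at least the minimum gap between them."""
    lo, hi = design.gene_length_range
    per_chrom = -(-design.n_genes // design.n_chroms)
    ann = GenomeAnnotation(
        chrom_sizes={f"chr{i + 1}": design.chrom_length for i in range(design.n_chroms)}
    )
    gene_idx = 0
    for ci in range(design.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = design.min_intergenic_gap
        for _ in range(per_chrom):
            if gene_idx >= design.n_genes:
                break
            length = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            start, end = pos, pos + length
            if end + design.min_intergenic_gap > design.chrom_length:
                raise ValueError(
                    f"infeasible packing: gene g{gene_idx + 1:03d} would run past "
                    f"{chrom} ({design.chrom_length} bp)"
                )
            third = length // 3
            exons = ((start, start + third), (end - third, end))
            ann.add(
                GeneModel(
                    gene_id=f"g{gene_idx + 1:03d}",
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                )
            )
            pos = end + design.min_intergenic_gap
            gene_idx += 1
    return ann


def _tss_peak_interval(gene: GeneModel) -> GenomicInterval:
    tss = gene.tss
    return GenomicInterval(gene.chrom, tss - _TSS_PEAK_HALF, tss + _TSS_PEAK_HALF, ".")


def _body_peak_interval(gene: GeneModel) -> GenomicInterval:
    iv = gene.interval
    if gene.strand == "+":
        s = iv.start + _BODY_PEAK_OFFSET
    else:
        s = iv.end - _BODY_PEAK_OFFSET - _BODY_PEAK_WIDTH
    return GenomicInterval(gene.chrom, s, s + _BODY_PEAK_WIDTH, ".")


def _assign_degs(
    design: SyntheticDesign,
    lost_genes: list[str],
    gained_genes: list[str],
    unchanged: list[str],
) -> tuple[list[str], list[str]]:
    """Direction-matched DEG assignment: down on lost genes, up on gained."""
    unchanged = list(unchanged)
    down_matched = min(round(design.overlap_with_changes * design.n_down), len(lost_genes), design.n_down)
    down = lost_genes[:down_matched]
    need = design.n_down - len(down)
    down += unchanged[:need]
    unchanged = unchanged[need:]

    up_matched = min(round(design.overlap_with_changes * design.n_up), len(gained_genes), design.n_up)
    up = [g for g in gained_genes if g not in down][:up_matched]
    need = design.n_up - len(up)
    up += unchanged[:need]
    return up, down


def generate(design: SyntheticDesign, outdir: str | Path) -> SyntheticBundle:
    """Generate the full file bundle and its truth table into ``outdir``."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    ann = _layout_genes(design, rng)
    gene_ids = [g.gene_id for g in ann]

    # planted region-change genes: disjoint categories off one permutation
    perm = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = perm[cursor : cursor + n]
        cursor += n
        return out

    lost_tss = take(design.n_lost_tss)
    gained_tss = take(design.n_gained_tss)
    lost_body = take(design.n_lost_body)
    gained_body = take(design.n_gained_body)
    changed = set(lost_tss + gained_tss + lost_body + gained_body)
    unchanged = [g for g in perm if g not in changed]

    # specific peaks; "gained" evidence lives in the treatment set,
    # "lost" evidence in the control set
    evidence: dict[str, tuple[str, str, str]] = {}
    region_changes: dict[str, list[tuple[str, str]]] = {}
    treatment_extra: list[Peak] = []
    control_extra: list[Peak] = []

    def plant(genes: list[str], region: str, direction: str) -> None:
        for gid in genes:
            gene = ann[gid]
            iv = _tss_peak_interval(gene) if region == "TSS" else _body_peak_interval(gene)
            name = f"sp_{gid}_{region}_{direction}"
            peak = Peak(interval=iv, name=name, score=100.0, summit_offset=len(iv) // 2)
            (treatment_extra if direction == "gained" else control_extra).append(peak)
            evidence[name] = (gid, region, direction)
            region_changes.setdefault(gid, []).append((region, direction))

    plant(lost_tss, "TSS", "lost")
    plant(gained_tss, "TSS", "gained")
    plant(lost_body, "gene_body", "lost")
    plant(gained_body, "gene_body", "gained")

    # background peaks shared by both conditions, one per intergenic gap,
    # jittered widths so the mutual overlap is deliberate, not incidental
    bg_treatment: list[Peak] = []
    bg_control: list[Peak] = []
    gaps: list[tuple[str, int]] = []  # (chrom, left-edge of gap)
    prev_end: dict[str, int] = {}
    for g in ann:
        left = prev_end.get(g.chrom, 0)
        gaps.append((g.chrom, left))
        prev_end[g.chrom] = g.interval.end
    if not gaps:
        gaps = [(c, 0) for c in ann.chrom_sizes]
    for i in range(design.background_peaks_per_condition):
        chrom, left = gaps[i % len(gaps)]
        lane = i // len(gaps)
        start = left + _BG_OFFSET + lane * (2 * _BG_PEAK_WIDTH)
        end = start + _BG_PEAK_WIDTH
        if end > ann.chrom_sizes[chrom]:
            raise ValueError("infeasible packing: background peak past chromosome end")
        bg_treatment.append(
            Peak(GenomicInterval(chrom, start, end, "."), name=f"bg{i:03d}_t", score=10.0)
        )
        bg_control.append(
            Peak(
                GenomicInterval(chrom, start + 50, end + 50, "."),
                name=f"bg{i:03d}_c",
                score=10.0,
            )
        )

    peaks_t = PeakSet("treatment", bg_treatment + treatment_extra)
    peaks_c = PeakSet("control", bg_control + control_extra)

    # expression: planted ratios on a common baseline, near-unity elsewhere
    up, down = _assign_degs(design, lost_tss + lost_body, gained_tss + gained_body, unchanged)
    expression: dict[str, tuple[float, float]] = {}
    for gid in gene_ids:
        if gid in up:
            ratio = design.fold_up
        elif gid in down:
            ratio = design.fold_down
        else:
            ratio = float(np.exp(rng.uniform(-np.log(1.1), np.log(1.1))))
        noise_t = float(np.exp(rng.normal(0.0, design.noise_sd))) if design.noise_sd else 1.0
        noise_c = float(np.exp(rng.normal(0.0, design.noise_sd))) if design.noise_sd else 1.0
        expression[gid] = (_EXPR_BASELINE * ratio * noise_t, _EXPR_BASELINE * noise_c)

    truth = _build_truth(region_changes, evidence, set(up), set(down))

    # term map: one term covering exactly the planted lost-and-down genes
    planted_set = sorted(truth.both_down)
    terms_lines: list[str] = []
    planted_term = None
    if planted_set:
        planted_term = "TERM_PLANTED"
        terms_lines.append(
            "\t".join(["TERM_PLANTED", "planted lost-and-down gene set", *planted_set])
        )
    for d in range(5):
        members = sorted(
            str(x) for x in rng.choice(gene_ids, size=min(8, len(gene_ids)), replace=False)
        )
        terms_lines.append("\t".join([f"DECOY{d:02d}", f"decoy term {d}", *members]))
    truth.planted_term = planted_term

    bundle = SyntheticBundle(
        outdir=Path(outdir),
        design=design,
        annotation=ann,
        peaks_treatment=peaks_t,
        peaks_control=peaks_c,
        expression=expression,
        truth=truth,
    )
    bundle.write()
    with open(bundle.paths["terms"], "w") as fh:
        fh.write("\n".join(terms_lines) + "\n")
    with open(bundle.outdir / "design.json", "w") as fh:
        json.dump(asdict(design), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle


def _build_truth(
    region_changes: dict[str, list[tuple[str, str]]],
    evidence: dict[str, tuple[str, str, str]],
    up: set[str],
    down: set[str],
) -> TruthTable:
    """Expected pipeline outputs implied by the planted structure."""
    diff_genes = sorted(region_changes)
    degs = up | down
    common = sorted(set(diff_genes) & degs)
    lost = {g for g, ch in region_changes.items() if any(d == "lost" for _, d in ch)}
    both_down = sorted(set(common) & lost & down)
    quadrants: dict[str, list[str]] = {
        f"{r}_{d}_{s}": []
        for r in ("TSS", "gene_body")
        for d in ("gained", "lost")
        for s in ("up", "down")
    }
    sign = {g: "up" for g in up} | {g: "down" for g in down}
    for g, ch in region_changes.items():
        if g not in sign or g not in set(common):
            continue
        for region, direction in ch:
            quadrants[f"{region}_{direction}_{sign[g]}"].append(g)
    deg_sign = dict(sign)
    return TruthTable(
        region_changes={g: sorted(set(v)) for g, v in region_changes.items()},
        deg_sign=deg_sign,
        diff_peak_genes=diff_genes,
        common_genes=common,
        both_down=both_down,
        quadrants={k: sorted(v) for k, v in quadrants.items()},
        planted_term=None,
        evidence=evidence,
    )


def perturb(
    bundle: SyntheticBundle,
    op: str,
    target: str,
    shift_bp: int = 30000,
    max_distance: int = 20000,
) -> SyntheticBundle:
    """Apply one controlled mutation and rewrite files + truth table.

    Operations: ``drop_peak`` (remove a named specific peak),
    ``shift_peak`` (move it ``shift_bp`` bp away from its gene, upstream of
    the gene start), ``flip_expression`` (swap a gene's condition means).
    """
    if op == "drop_peak":
        return _perturb_drop(bundle, target)
    if op == "shift_peak":
        return _perturb_shift(bundle, target, shift_bp, max_distance)
    if op == "flip_expression":
        return _perturb_flip(bundle, target)
    raise ValueError(f"unknown perturbation {op!r}")


def _find_peak(bundle: SyntheticBundle, name: str) -> tuple[PeakSet, Peak]:
    for pset in (bundle.peaks_treatment, bundle.peaks_control):
        for p in pset:
            if p.name == name:
                return pset, p
    raise ValueError(f"no peak named {name!r}")


def _refresh(bundle: SyntheticBundle) -> SyntheticBundle:
    """Recompute derived truth sets from current labels and rewrite files.

    ``diff_peak_genes`` is maintained explicitly by the peak perturbations;
    everything downstream of it is a pure set computation.
    """
    t = bundle.truth
    t.region_changes = {g: sorted(set(v)) for g, v in t.region_changes.items() if v}
    up = {g for g, s in t.deg_sign.items() if s == "up"}
    down = {g for g, s in t.deg_sign.items() if s == "down"}
    common = set(t.diff_peak_genes) & (up | down)
    lost = {g for g, ch in t.region_changes.items() if any(d == "lost" for _, d in ch)}
    quadrants: dict[str, list[str]] = {
        f"{r}_{d}_{s}": []
        for r in ("TSS", "gene_body")
        for d in ("gained", "lost")
        for s in ("up", "down")
    }
    sign = dict(t.deg_sign)
    for g, ch in t.region_changes.items():
        if g not in common or g not in sign:
            continue
        for region, direction in ch:
            quadrants[f"{region}_{direction}_{sign[g]}"].append(g)
    t.common_genes = sorted(common)
    t.both_down = sorted(common & lost & down)
    t.quadrants = {k: sorted(v) for k, v in quadrants.items()}
    bundle.write()
    return bundle


def _drop_label(truth: TruthTable, name: str) -> None:
    gid, region, direction = truth.evidence.pop(name)
    remaining = [
        n for n, (g, r, d) in truth.evidence.items() if (g, r, d) == (gid, region, direction)
    ]
    if not remaining:
        truth.region_changes[gid] = [
            rc for rc in truth.region_changes.get(gid, []) if rc != (region, direction)
        ]
        if not truth.region_changes[gid]:
            del truth.region_changes[gid]


def _perturb_drop(bundle: SyntheticBundle, name: str) -> SyntheticBundle:
    pset, peak = _find_peak(bundle, name)
    pset.peaks = [p for p in pset.peaks if p.name != name]
    if name in bundle.truth.evidence:
        gid = bundle.truth.evidence[name][0]
        _drop_label(bundle.truth, name)
        if gid not in bundle.truth.region_changes:
            bundle.truth.diff_peak_genes = [
                g for g in bundle.truth.diff_peak_genes if g != gid
            ]
    return _refresh(bundle)


def _perturb_shift(
    bundle: SyntheticBundle, name: str, shift_bp: int, max_distance: int
) -> SyntheticBundle:
    pset, peak = _find_peak(bundle, name)
    iv = peak.interval
    new_iv = GenomicInterval(iv.chrom, iv.start - shift_bp, iv.end - shift_bp, iv.strand)
    moved = Peak(new_iv, name=peak.name, score=peak.score, summit_offset=peak.summit_offset)
    pset.peaks = [moved if p.name == name else p for p in pset.peaks]
    pset.__post_init__()  # re-sort

    if name in bundle.truth.evidence:
        gid, _, direction = bundle.truth.evidence[name]
        _drop_label(bundle.truth, name)
        # re-derive labels for the moved peak against every gene
        still_diff: set[str] = set()
        for g in bundle.annotation:
            if g.chrom != new_iv.chrom:
                continue
            giv = g.interval
            gap = max(giv.start - new_iv.end, new_iv.start - giv.end, 0)
            if gap <= max_distance:
                still_diff.add(g.gene_id)
            tss_region = promoter_region(g, chrom_length=bundle.annotation.chrom_length(g.chrom))
            body = gene_body_region(g)
            if overlaps(new_iv, tss_region):
                bundle.truth.evidence[name] = (g.gene_id, "TSS", direction)
                bundle.truth.region_changes.setdefault(g.gene_id, []).append(("TSS", direction))
            elif body is not None and overlaps(new_iv, body):
                bundle.truth.evidence[name] = (g.gene_id, "gene_body", direction)
                bundle.truth.region_changes.setdefault(g.gene_id, []).append(
                    ("gene_body", direction)
                )
        diff = {
            g for g in bundle.truth.diff_peak_genes if g in bundle.truth.region_changes
        } | still_diff
        bundle.truth.diff_peak_genes = sorted(diff)
    return _refresh(bundle)


def _perturb_flip(bundle: SyntheticBundle, gene_id: str) -> SyntheticBundle:
    if gene_id not in bundle.expression:
        raise ValueError(f"no expression record for gene {gene_id!r}")
    t, c = bundle.expression[gene_id]
    bundle.expression[gene_id] = (c, t)
    ratio = c / t if t else float("inf")
    sign = "up" if ratio >= 1.25 else ("down" if ratio <= 0.8 else None)
    bundle.truth.deg_sign.pop(gene_id, None)
    if sign:
        bundle.truth.deg_sign[gene_id] = sign
    return _refresh(bundle)
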