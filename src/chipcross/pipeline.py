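"""End-to-end orchestration: read -> partition -> annotate -> profile ->
classify -> DEG -> integrate -> enrich, with a run manifest.

Every stage writes its output under ``outdir`` so stages can be re-run or
inspected individually; ``run_all`` is deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import __version__
from .enrichment import enrich, read_term_map, write_enrichment
from .genome_model import read_annotation, read_chrom_sizes
from .integration import (
    IntegrationResult,
    call_degs,
    classify_region_changes,
    integrate,
    read_expression_table,
    write_calls,
    write_degs,
)
from .peak_toolkit import (
    PeakSet,
    annotate_peaks,
    feature_distribution,
    genes_near_peaks,
    partition_peaks,
    read_peaks,
    write_annotated_peaks,
    write_peaks,
)
from .signal_profile import anchored_profile, read_bedgraph

__all__ = ["RunConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters of one integration run.

    Parameter defaults follow the analysis this pipeline reproduces: a
    ±2 kb TSS window, a 3 kb downstream annotation window, 20 kb peak-gene
    association, a 1.25-fold expression threshold and a 0.05 FDR cutoff.
    """

    annotation: str = ""
    peaks_treatment: str = ""
    peaks_control: str = ""
    track_treatment: str | None = None
    track_control: str | None = None
    expression: str = ""
    terms: str | None = None
    chrom_sizes: str | None = None
    outdir: str = "chipcross_out"

    promoter_up: int = 2000
    promoter_down: int = 2000
    downstream_window: int = 3000
    max_distance: int = 20000
    fold_threshold: float = 1.25
    pseudocount: float = 0.0
    alpha: float = 0.05
    bin_size: int = 50
    tss_exclusion: int = 2000
    flank: int = 3000
    use_summit: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.promoter_up < 0 or self.promoter_down < 0:
            raise ValueError("promoter window extents must be >= 0")
        if self.downstream_window < 0 or self.max_distance < 0:
            raise ValueError("windows and distances must be >= 0")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.bin_size < 1 or self.flank % self.bin_size:
            raise ValueError("flank must be a positive multiple of bin_size")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _log(msg: str, logfile) -> None:
    print(f"[chipcross] {msg}", file=sys.stderr)
    if logfile is not None:
        logfile.write(msg + "\n")


def run_all(config: RunConfig) -> IntegrationResult:
    """Run the full integration analysis and write all stage outputs.

    Returns the :class:`~chipcross.integration.IntegrationResult`; every
    intermediate table lands in ``config.outdir`` along with a manifest
    recording inputs, parameters and library versions.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logfile = open(outdir / "run.log", "w")
    manifest: dict = {
        "parameters": asdict(config),
        "versions": _versions(),
        "outputs": [],
    }
    stage = "setup"

    def emit(name: str) -> Path:
        path = outdir / name
        manifest["outputs"].append(name)
        return path

    try:
        stage = "read_annotation"
        _log(f"{stage}: {config.annotation}", logfile)
        sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
        ann = read_annotation(config.annotation, chrom_sizes=sizes)
        _log(f"  {len(ann)} genes on {len(ann.chrom_sizes)} chromosomes", logfile)

        stage = "read_peaks"
        peaks_t = read_peaks(config.peaks_treatment, "treatment")
        peaks_c = read_peaks(config.peaks_control, "control")
        _log(f"{stage}: {len(peaks_t)} treatment, {len(peaks_c)} control peaks", logfile)

        stage = "partition"
        part = partition_peaks(peaks_t, peaks_c)
        for label, pset in (
            ("common_treatment", part.common_a),
            ("common_control", part.common_b),
            ("specific_treatment", part.specific_a),
            ("specific_control", part.specific_b),
        ):
            write_peaks(pset, str(emit(f"peaks_{label}.bed")))
        with open(emit("partition_counts.json"), "w") as fh:
            json.dump(part.counts(), fh, indent=2, sort_keys=True)
        _log(f"{stage}: {part.counts()}", logfile)

        stage = "annotate"
        differential = PeakSet(
            "differential", list(part.specific_a) + list(part.specific_b)
        )
        annotated = annotate_peaks(
            differential,
            ann,
            config.promoter_up,
            config.promoter_down,
            config.downstream_window,
            config.use_summit,
        )
        write_annotated_peaks(annotated, str(emit("annotated_differential_peaks.tsv")))
        if annotated:
            counts, fractions = feature_distribution(annotated)
            with open(emit("feature_distribution.json"), "w") as fh:
                json.dump(
                    {
                        "counts": {f.value: c for f, c in sorted(counts.items())},
                        "fractions": {f.value: x for f, x in sorted(fractions.items())},
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )

        stage = "profile"
        if config.track_treatment and config.track_control:
            for label, path in (
                ("treatment", config.track_treatment),
                ("control", config.track_control),
            ):
                track = read_bedgraph(
                    path, ann.chrom_sizes, config.bin_size, condition_label=label
                )
                for anchor in ("TSS", "TES"):
                    pm = anchored_profile(track, ann, anchor, config.flank)
                    pm.write_tsv(str(emit(f"profile_{anchor}_{label}.tsv")))
                prom = anchored_profile(
                    track, ann, "TSS", config.promoter_up - config.promoter_up % config.bin_size
                )
                with open(emit(f"promoter_mean_profile_{label}.tsv"), "w") as fh:
                    fh.write("bin_offset\tmean_signal\n")
                    for off, v in zip(prom.to_frame().columns, prom.mean_profile):
                        fh.write(f"{off}\t{v:.6g}\n")
            _log("profile: TSS/TES matrices and promoter mean profiles written", logfile)
        else:
            _log("profile: no coverage tracks supplied, skipping", logfile)

        stage = "classify"
        changes = classify_region_changes(
            part, ann, config.promoter_up, config.promoter_down, config.tss_exclusion
        )
        write_calls(changes, str(emit("region_change_calls.tsv")))
        _log(f"{stage}: {len(changes)} region-change calls", logfile)

        stage = "degs"
        records, qvalues = read_expression_table(config.expression)
        degs = call_degs(
            records, config.fold_threshold, config.pseudocount, qvalues=qvalues
        )
        write_degs(degs, str(emit("degs.tsv")))
        _log(f"{stage}: {len(degs.up)} up, {len(degs.down)} down", logfile)

        stage = "integrate"
        diff_genes = genes_near_peaks(differential, ann, config.max_distance)
        result = integrate(changes, degs, diff_genes)
        with open(emit("diff_peak_genes.txt"), "w") as fh:
            fh.write("\n".join(diff_genes) + ("\n" if diff_genes else ""))
        result.to_json(str(emit("integration.json")))
        _log(f"{stage}: {result.counts()}", logfile)

        stage = "enrich"
        if config.terms and result.both_down:
            terms = read_term_map(config.terms)
            background = {g.gene_id for g in ann}
            results = enrich(result.both_down, background, terms, config.alpha)
            write_enrichment(results, str(emit("enrichment_both_down.tsv")))
            _log(
                f"{stage}: {sum(r.significant for r in results)} significant terms",
                logfile,
            )
        else:
            _log(f"{stage}: skipped (no term map or empty both-down set)", logfile)

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return result
    except StageError:
        raise
    except BaseException as exc:  # noqa: BLE001 — re-raised with stage context
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise StageError(stage, exc) from exc
    finally:
        logfile.close()


def _versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    return {
        "chipcross": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
    }
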