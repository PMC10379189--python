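"""Shared fixtures: a hand-built toy annotation and a generated bundle."""

from __future__ import annotations

import pytest

from chipcross.genome_model import GeneModel, GenomeAnnotation, GenomicInterval
from chipcross.synthetic_data import SyntheticDesign, generate


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Three genes on two chromosomes, both strands, with exon structure."""
    ann = GenomeAnnotation(chrom_sizes={"chr1": 100_000, "chr2": 60_000})
    ann.add(
        GeneModel(
            "gA",
            GenomicInterval("chr1", 10_000, 22_000, "+"),
            exons=((10_000, 14_000), (18_000, 22_000)),
        )
    )
    ann.add(
        GeneModel(
            "gB",
            GenomicInterval("chr1", 60_000, 75_000, "-"),
            exons=((60_000, 65_000), (70_000, 75_000)),
        )
    )
    ann.add(GeneModel("gC", GenomicInterval("chr2", 30_000, 40_000, "+")))
    return ann


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The reference synthetic experiment (zero noise), generated once."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate(SyntheticDesign(seed=7), outdir)


@pytest.fixture(scope="session")
def pipeline_result(default_bundle, tmp_path_factory):
    """run_all over the reference bundle, shared across tests."""
    from chipcross.pipeline import RunConfig, run_all

    p = default_bundle.paths
    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        annotation=str(p["annotation"]),
        peaks_treatment=str(p["peaks_treatment"]),
        peaks_control=str(p["peaks_control"]),
        track_treatment=str(p["track_treatment"]),
        track_control=str(p["track_control"]),
        expression=str(p["expression"]),
        terms=str(p["terms"]),
        chrom_sizes=str(p["chrom_sizes"]),
        outdir=str(outdir),
    )
    return cfg, run_all(cfg)
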