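"""End-to-end pipeline: repeat densities -> compartment calls -> Hi-C statistics.

The pipeline composes the two analysis arms the package exists for:

1. density -> log-ratio -> compartment calling -> overlap scoring against a
   reference (Hi-C-annotated or planted) compartment set;
2. contact matrix -> O/E -> correlation -> eigenvector -> saddle strength and
   segregation index.

Inputs come either from files (repeat annotation, chrom.sizes, reference BED,
dense matrices or a cooler-style container) or from the built-in simulators.
All randomness flows from one top-level seed, expanded per stage with
``numpy.random.SeedSequence`` and logged in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compartments import (
    NormalizationConstants,
    call_repeat_compartments,
    log_ratio_track,
    overlap_score,
)
from .errors import InputError
from .genome import GenomeTable, read_chrom_sizes
from .hic import (
    compartment_eigenvector,
    correlation_matrix,
    observed_over_expected,
    saddle_strength,
    segregation_index,
)
from .io import read_bed, read_cooler, read_dense_matrix, write_bed, write_bedgraph
from .repeats import bin_coverage, parse_repeatmasker
from .simulate import (
    SyntheticGenomeSpec,
    SyntheticHiCSpec,
    simulate_contact_matrices,
    simulate_repeat_genome,
)

logger = logging.getLogger("repeatcomp")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs; file paths or simulation specs."""

    out_dir: str = "repeatcomp_out"
    seed: int = 0
    repeat_bin_size: int = 10_000
    calling_bin_size: int = 100_000
    min_compartment_size: int = 500_000
    constants: NormalizationConstants = field(default_factory=NormalizationConstants)
    exclude_chroms: tuple[str, ...] = ("chrX", "chrY")
    n_quantiles: int = 50
    corner_fraction: float = 0.2
    min_separation_bins: int = 2
    # file inputs (all optional when simulating)
    annotation_path: str | None = None
    chrom_sizes_path: str | None = None
    reference_compartments_path: str | None = None
    matrix_paths: dict[str, str] | None = None  # chrom -> dense matrix text
    cooler_path: str | None = None
    # simulation
    simulate: bool = False
    genome_spec: SyntheticGenomeSpec = field(default_factory=SyntheticGenomeSpec)
    hic_spec: SyntheticHiCSpec = field(default_factory=SyntheticHiCSpec)

    def __post_init__(self) -> None:
        if self.calling_bin_size % self.repeat_bin_size:
            raise InputError("calling bin size must be a multiple of the repeat bin size")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "constants" in raw:
            raw["constants"] = NormalizationConstants(**raw["constants"])
        if "genome_spec" in raw:
            raw["genome_spec"] = SyntheticGenomeSpec(**raw["genome_spec"])
        if "hic_spec" in raw:
            raw["hic_spec"] = SyntheticHiCSpec(**raw["hic_spec"])
        if "exclude_chroms" in raw:
            raw["exclude_chroms"] = tuple(raw["exclude_chroms"])
        return cls(**raw)


def _load_inputs(config: PipelineConfig, seeds):
    if config.simulate:
        annotation, reference, genome = simulate_repeat_genome(
            config.genome_spec, seeds["genome"]
        )
        matrices = simulate_contact_matrices(
            reference, genome, config.hic_spec, seeds["hic"]
        )
        return annotation, genome, reference, matrices
    if not (config.annotation_path and config.chrom_sizes_path):
        raise InputError("stage inputs: annotation_path and chrom_sizes_path are required")
    genome = read_chrom_sizes(config.chrom_sizes_path)
    annotation = parse_repeatmasker(config.annotation_path, genome)
    reference = (
        read_bed(config.reference_compartments_path)
        if config.reference_compartments_path
        else None
    )
    matrices = {}
    if config.cooler_path:
        for chrom in genome.names:
            matrices[chrom] = read_cooler(config.cooler_path, chrom)
    elif config.matrix_paths:
        bin_size = config.calling_bin_size
        for chrom, p in config.matrix_paths.items():
            matrices[chrom] = read_dense_matrix(p, chrom, bin_size)
    return annotation, genome, reference, matrices


def run_pipeline(config: PipelineConfig) -> dict:
    """Run both analysis arms and write a machine-readable JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(3)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(("genome", "hic", "shuffle"), children)
    }

    logger.info("stage: load/simulate inputs")
    try:
        annotation, genome, reference, matrices = _load_inputs(config, seeds)
    except Exception as exc:
        raise InputError(f"stage 'inputs' failed: {exc}") from exc

    logger.info("stage: repeat densities and compartment calling")
    b1 = bin_coverage(annotation, genome, config.calling_bin_size, "B1", prefix=True)
    l1 = bin_coverage(annotation, genome, config.calling_bin_size, "L1", prefix=True)
    ratio = log_ratio_track(b1, l1, config.constants)
    called = call_repeat_compartments(ratio, config.min_compartment_size)
    write_bed(called, out / "called_compartments.bed", genome)
    write_bedgraph(ratio, out / "log2_b1_l1.bedgraph")

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_called_compartments": int(len(called)),
        "called_label_counts": called["label"].value_counts().to_dict(),
        "median_compartment_size_bp": float((called["end"] - called["start"]).median())
        if len(called)
        else None,
    }

    if reference is not None:
        score = overlap_score(called, reference)
        report["overlap_consistent_fraction"] = score.consistent_fraction

    if matrices:
        logger.info("stage: Hi-C eigenvector, saddle, segregation")
        strengths = {}
        for chrom, m in matrices.items():
            oe = observed_over_expected(m)
            corr = correlation_matrix(oe)
            anchor = b1.values[chrom]
            # anchor is at calling resolution; matrices may differ
            if len(anchor) != m.n_bins:
                factor = m.bin_size // config.calling_bin_size
                anchor = anchor[: m.n_bins * factor].reshape(m.n_bins, factor).mean(axis=1)
            ev = compartment_eigenvector(corr, anchor, chrom=chrom, bin_size=m.bin_size)
            sad = saddle_strength(
                oe,
                ev,
                n_quantiles=config.n_quantiles,
                corner_fraction=config.corner_fraction,
                min_separation_bins=config.min_separation_bins,
            )
            strengths[chrom] = sad.strength
            write_bedgraph(ev.to_binned_track(genome), out / f"eigenvector_{chrom}.bedgraph")
        report["compartment_strength"] = strengths
        report["compartment_strength_mean"] = float(np.mean(list(strengths.values())))

        oes = {c: observed_over_expected(m) for c, m in matrices.items()}
        seg_ref = reference if reference is not None else called
        seg = segregation_index(
            oes, seg_ref, config.min_separation_bins, config.exclude_chroms
        )
        seg.per_chrom.to_csv(out / "segregation_index.tsv", sep="\t", index=False)
        report["segregation_index"] = dict(
            zip(seg.per_chrom["chrom"], seg.per_chrom["index"].astype(float))
        )
        report["segregation_index_mean"] = seg.summary_index

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
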