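"""End-to-end orchestration of the two workflows (intra and inter).

Stages: digest and annotate the genome, classify and filter read pairs,
accumulate intra- and inter-chromosomal contact matrices, then normalize —
intra maps get low-norm filtering, genomic-distance normalization and SCN;
inter maps get low-norm filtering and SCN.  Every stage logs its counts and
all outputs carry JSON metadata sidecars recording the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import biases, coloc, events as ev, normalize as norm, restriction

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class PipelineConfig:
    fasta: str = ""
    pairs: str = ""
    outdir: str = "scn3c_out"
    re1_motif: str = "AAGCTT"
    re2_motif: str = "CCGG"
    cut_offset: int = 1
    condition: str = "A"
    mapq_min: int = 30
    min_gap: int = 20
    low_norm_threshold: float = 30.0
    scn_tol: float = 1e-3
    scn_max_iter: int = 200
    distance_fit_degree: int = 8
    bin_size: int = 1
    features_bed: str = ""
    feature_name: str = "feature"

    def validate(self) -> None:
        if not self.fasta or not self.pairs:
            raise ConfigError("fasta and pairs paths are required")
        if self.condition not in ev.CONDITION_WINDOWS:
            raise ConfigError(f"condition must be one of {set(ev.CONDITION_WINDOWS)}")
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")
        for path, label in ((self.fasta, "fasta"), (self.pairs, "pairs")):
            if not Path(path).exists():
                raise ConfigError(f"{label} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the artifact directory.

    Raises DataError when a stage leaves nothing to continue with (for
    example, zero events surviving the filters) and propagates
    ConvergenceError from SCN.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2) + "\n"
    )

    logger.info("digesting genome from %s", config.fasta)
    genome = restriction.read_fasta(config.fasta)
    frags = restriction.build_fragment_table(
        genome,
        config.re1_motif,
        config.re2_motif,
        cut_offset=config.cut_offset,
        min_gap=config.min_gap,
    )
    logger.info("fragment table: %d fragments", len(frags))
    frags.to_tsv(outdir / "fragments.tsv")

    kept, summary = ev.filter_events(
        ev.read_pairs_tsv(config.pairs), frags,
        condition=config.condition, mapq_min=config.mapq_min,
    )
    summary.to_json(outdir / "event_summary.json")
    logger.info(
        "events: %d input, %d kept (%s)", summary.n_input, summary.n_kept,
        ", ".join(f"{k}={v}" for k, v in summary.removed.items() if v),
    )
    if not kept:
        raise DataError("no events survived the read-level filters")
    ev.events_to_frame(kept).to_csv(outdir / "events.tsv", sep="\t", index=False)

    results: dict[str, float | int] = {"n_events_kept": summary.n_kept}
    for scope in ("intra", "inter"):
        matrix = ev.build_contact_matrix(kept, frags, scope=scope)
        if config.bin_size > 1:
            matrix = norm.bin_matrix(
                matrix, config.bin_size, chroms=frags.col("chrom")
            )
        matrix.to_coo_tsv(outdir / f"raw_{scope}.tsv")
        try:
            filtered = norm.filter_low_norm(matrix, config.low_norm_threshold)
        except norm.DegenerateMatrixError as exc:
            raise DataError(f"{scope}: {exc}") from exc
        logger.info(
            "%s: %d fragments retained after low-norm filter", scope, filtered.n
        )
        if scope == "intra" and config.bin_size == 1:
            expectation = biases.distance_expectation(
                filtered, frags, degree=config.distance_fit_degree
            )
            filtered = norm.distance_normalize(filtered, expectation, frags)
        balanced, sweeps = norm.scn(
            filtered, tol=config.scn_tol, max_iter=config.scn_max_iter
        )
        logger.info("%s: SCN converged in %d sweeps", scope, sweeps)
        balanced.to_dense_tsv(outdir / f"scn_{scope}.tsv")
        balanced.write_metadata(outdir / f"scn_{scope}.meta.json")
        results[f"scn_sweeps_{scope}"] = sweeps
        results[f"n_retained_{scope}"] = balanced.n

        if config.features_bed and config.bin_size == 1:
            feats = coloc.features_from_bed(
                frags, config.features_bed, name=config.feature_name
            )
            roc = coloc.colocalization_roc(balanced, feats)
            roc.curve_to_tsv(outdir / f"roc_{scope}_{feats.name}.tsv")
            roc.to_json(outdir / f"roc_{scope}_{feats.name}.json")
            results[f"roc_auc_{scope}"] = roc.auc

    (outdir / "pipeline_summary.json").write_text(json.dumps(results, indent=2) + "\n")
    return outdir
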