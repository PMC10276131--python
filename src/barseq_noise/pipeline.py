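"""End-to-end pipeline: simulate -> (sequence/demux) -> fit -> decompose.

Each stage writes its inputs and outputs to disk under the run's output
directory, stamped with the configuration hash and seed, so a rerun with
the same configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import demux as dx
from . import fitness_inference as fi
from . import noise_decomposition as nd
from . import synthetic_data as sd
from .config import RunConfig, validate_config
from .index_design import build_scheme, write_sample_sheet
from .io import config_hash, write_run_metadata
from .demux import BarcodeCountTable

__all__ = ["PipelineResult", "run_pipeline", "simulate_study"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    outdir: Path
    pool: list
    competition: "sd.CompetitionResult"
    counts: BarcodeCountTable
    sample_sheet: pd.DataFrame
    fitness: pd.DataFrame
    decomposition: "nd.VarianceDecomposition"
    contrast: tuple[pd.DataFrame, float]
    misassignment_report: dict | None = None


def _pool_for_batch(pool, engineered: bool):
    """Drop engineered identical-mutation sets for batches lacking them."""
    if engineered:
        return pool
    kept = [l for l in pool if l.genotype_label not in ("IRA1non", "IRA1mis")]
    total = sum(l.initial_frequency for l in kept)
    return [
        sd.LineageSpec(l.barcode_id, l.genotype_label, l.base_fitness,
                       l.env_sensitivity, l.initial_frequency / total)
        for l in kept
    ]


def simulate_study(config: RunConfig) -> tuple[list, sd.CompetitionResult]:
    """Simulate every batch of the study design; returns (pool, result).

    Batches may have different replicate counts; the engineered
    identical-mutation sets are present only in the configured batches.
    Replicate identifiers are unique across the whole study.
    """
    pool = sd.make_pool(seed=config.seed, **config["pool"])
    engineered_batches = set(config.data.get("engineered_batches") or [])
    rpb = config.replicates_per_batch()
    batch_model = config.batch_model()

    freq_parts, s_parts = [], []
    rep_offset = 0
    for b, k in enumerate(rpb, start=1):
        batch_pool = _pool_for_batch(pool, b in engineered_batches)
        res = sd.simulate_competition(
            batch_pool, config.design(n_batches=1, n_replicates=k),
            batch_model, seed=config.seed + 1000 * b,
        )
        freq = res.frequencies.copy()
        s_eff = res.s_eff.copy()
        relabel = {f"rep_{i:02d}": f"rep_{rep_offset + i:02d}" for i in range(1, k + 1)}
        for df in (freq, s_eff):
            df["batch_id"] = f"batch_{b}"
            df["replicate_id"] = df["replicate_id"].map(relabel)
        rep_offset += k
        freq_parts.append(freq)
        s_parts.append(s_eff)

    result = sd.CompetitionResult(
        pd.concat(freq_parts, ignore_index=True),
        pd.concat(s_parts, ignore_index=True),
        {"seed": config.seed, "n_batches": len(rpb), "n_replicates_total": rep_offset,
         "has_reference": any(l.genotype_label == "reference" for l in pool)},
    )
    return pool, result


def _counts_from_frequencies(result: sd.CompetitionResult, depth: int, seed: int):
    """Direct multinomial read-count sampling (no read-level simulation)."""
    rows = []
    sheet = []
    rng_seed = seed
    groups = result.frequencies.groupby(["batch_id", "replicate_id", "timepoint"], sort=True)
    for (batch, rep, tp), grp in groups:
        rng_seed += 1
        counts = sd.sample_read_counts(
            pd.Series(grp["frequency"].to_numpy(), index=grp["barcode_id"]),
            depth, seed=rng_seed,
        )
        sample_id = f"{rep}_t{tp:g}"
        rows.append(pd.DataFrame({"sample_id": sample_id,
                                  "barcode_id": counts.index, "count": counts.to_numpy()}))
        sheet.append({"sample_id": sample_id, "f_idx": "", "n_idx": "", "r_idx": "",
                      "s_idx": "", "experiment_id": rep, "timepoint": tp,
                      "replicate_id": rep, "batch_id": batch})
    table = BarcodeCountTable(pd.concat(rows, ignore_index=True))
    return table, pd.DataFrame(sheet)


def _counts_from_reads(config: RunConfig, result: sd.CompetitionResult):
    """Read-level path: indexed reads, misassignment, nested demultiplexing."""
    groups = result.frequencies.groupby(["batch_id", "replicate_id", "timepoint"], sort=True)
    keys = list(groups.groups)
    sch_cfg = config["scheme"]
    if sch_cfg["kind"] == "unique_dual":
        scheme = build_scheme("unique_dual", len(keys))
    else:
        scheme = build_scheme(sch_cfg["kind"], len(keys),
                              sch_cfg.get("n_f_pairs"), sch_cfg.get("n_r_pairs"))
    sample_ids = [f"{rep}_t{tp:g}" for (_, rep, tp) in keys]
    assignment = {sid: scheme.samples[s] for sid, s in zip(sample_ids, list(scheme.samples))}
    scheme.samples = dict(assignment)  # rename samples to pipeline sample ids

    freqs = {}
    sheet = []
    for sid, ((batch, rep, tp), grp) in zip(sample_ids, groups):
        freqs[sid] = pd.Series(grp["frequency"].to_numpy(), index=grp["barcode_id"])
        f, n, r, s = assignment[sid]
        sheet.append({"sample_id": sid, "f_idx": f, "n_idx": n, "r_idx": r, "s_idx": s,
                      "experiment_id": rep, "timepoint": tp,
                      "replicate_id": rep, "batch_id": batch})
    design = config.design()
    reads = sd.simulate_sequencing(freqs, design, scheme, assignment, seed=config.seed + 7)
    mis = config["misassignment"]
    reads = sd.apply_misassignment(
        reads, float(mis["p_template_switch"]), float(mis["p_hop"]),
        config.geometry(), seed=config.seed + 11,
    )
    table, report, _ = dx.demux_reads(reads.reads(), scheme)
    return table, pd.DataFrame(sheet), report, reads, scheme


def fit_study(
    counts: BarcodeCountTable,
    sample_sheet: pd.DataFrame,
    reference_barcodes,
    mode: str = "reference",
    pseudocount: float = 0.5,
    min_coverage: float = 10.0,
) -> pd.DataFrame:
    """Infer fitness per replicate experiment from a study count table."""
    wide = counts.wide()
    parts = []
    for rep, grp in sample_sheet.groupby("replicate_id", sort=True):
        grp = grp.sort_values("timepoint")
        cols = grp["sample_id"].tolist()
        tps = [float(t) for t in grp["timepoint"]]
        present = [c for c in cols if c in wide.columns]
        if len(present) < 2:
            logger.warning("replicate %s has < 2 timepoints with counts; skipped", rep)
            continue
        mat = wide[present]
        mat.columns = tps[: len(present)]
        # barcodes never observed in this experiment are not part of its pool
        mat = mat.loc[mat.sum(axis=1) > 0]
        if mode == "reference":
            est = fi.infer_fitness_reference(mat, reference_barcodes,
                                             pseudocount=pseudocount,
                                             min_coverage=min_coverage)
        else:
            est, _ = fi.infer_fitness_meanfit(mat, pseudocount=pseudocount,
                                              min_coverage=min_coverage)
        batch = grp["batch_id"].iloc[0]
        parts.append(fi.estimates_to_frame(est, replicate_id=rep, batch_id=batch))
    if not parts:
        raise ValueError("no replicate produced a fitness estimate")
    return pd.concat(parts, ignore_index=True)


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute simulate -> demux -> fit -> noise, writing artifacts to disk."""
    problems = [p for p in validate_config(config) if not p.startswith("warning")]
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    outdir = Path(outdir if outdir is not None else config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    stage_times = {}

    def _stage(name):
        stage_times[name] = time.perf_counter()
        logger.info("stage %s started", name)

    try:
        _stage("simulate")
        pool, result = simulate_study(config)
        result.frequencies.to_csv(outdir / "true_frequencies.tsv", sep="\t", index=False)
        result.s_eff.to_csv(outdir / "true_s_eff.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    report = None
    try:
        _stage("demux")
        if config["read_level"]:
            counts, sheet, mis_report, reads, scheme = _counts_from_reads(config, result)
            report = mis_report.to_dict()
            with open(outdir / "misassignment_report.json", "w") as fh:
                json.dump(report, fh, indent=2)
            from .io import write_truth_tsv

            write_truth_tsv(reads, outdir / "reads_truth.tsv")
            with open(outdir / "scheme.json", "w") as fh:
                fh.write(scheme.to_json())
        else:
            counts, sheet = _counts_from_frequencies(
                result, config["design"]["reads_per_sample"], config.seed + 500_000
            )
        counts.to_tsv(outdir / "counts.tsv")
        write_sample_sheet(outdir / "sample_sheet.csv", sheet.to_dict("records"))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'demux' failed: {exc}") from exc

    try:
        _stage("fit")
        refs = [l.barcode_id for l in pool if l.genotype_label == "reference"]
        inf = config["inference"]
        fitness = fit_study(counts, sheet, refs, mode=inf["mode"],
                            pseudocount=inf["pseudocount"],
                            min_coverage=inf.get("min_coverage", 10.0))
        fi.write_fitness_tsv(fitness, outdir / "fitness.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    try:
        _stage("noise")
        genotype_map = pd.Series({l.barcode_id: l.genotype_label for l in pool})
        noise_cfg = config["noise"]
        decomp = nd.variance_decomposition(
            fitness, genotype_map,
            within_groups=noise_cfg.get("within_groups"),
            across_groups=noise_cfg.get("across_groups"),
        )
        decomp.within_experiment.to_csv(outdir / "sd_within_experiment.tsv", sep="\t", index=False)
        decomp.across_replicate.to_csv(outdir / "sd_across_replicate.tsv", sep="\t", index=False)
        decomp.across_batch.to_csv(outdir / "sd_across_batch.tsv", sep="\t", index=False)
        contrast_df, contrast_sd = nd.genotype_contrast(
            fitness, genotype_map, *noise_cfg.get("contrast", ["IRA1", "GPB2"])
        )
        summary = {
            "config_hash": config_hash(cfg_dict),
            "seed": config.seed,
            "decomposition_counts": decomp.counts(),
            "decomposition_boxstats": decomp.summary(),
            "genotype_contrast_sd": contrast_sd,
        }
        with open(outdir / "noise_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'noise' failed: {exc}") from exc

    write_run_metadata(outdir / "run_metadata.json", cfg_dict, config.seed,
                       extra={"stages": sorted(stage_times)})
    return PipelineResult(outdir, pool, result, counts, sheet, fitness,
                          decomp, (contrast_df, contrast_sd), report)
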