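"""Run configuration: one serializable document drives the whole pipeline."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

from .synthetic_data import AmpliconGeometry, BatchEffectModel, CompetitionDesign

__all__ = ["RunConfig", "PRESETS", "validate_config"]


_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "pool": {
        "n_lineages": 500,
        "n_reference": 40,
        "include_engineered": False,
    },
    "design": {
        "timepoints": [0.0, 1.0, 2.0, 3.0, 4.0],
        "bottleneck_size": 1_000_000,
        "reads_per_sample": 100_000,
        "n_batches": 1,
        "n_replicates": 3,
    },
    # replicate counts per batch; overrides design.n_batches/n_replicates
    "replicates_per_batch": None,
    # batches (1-based) whose pool includes the engineered identical-mutation sets
    "engineered_batches": [1],
    "batch_model": {"sigma_batch": 0.0, "sigma_rep": 0.0},
    "geometry": {},
    "misassignment": {"p_template_switch": 0.0, "p_hop": 0.0},
    "scheme": {"kind": "nested_unique_dual", "n_f_pairs": 12, "n_r_pairs": 8},
    "inference": {"mode": "reference", "pseudocount": 0.5, "min_coverage": 10.0},
    "noise": {
        "within_groups": None,
        "across_groups": None,
        "contrast": ["IRA1", "GPB2"],
    },
    # read-level simulation (FASTQ-style reads, misassignment, demux) instead
    # of direct multinomial count sampling
    "read_level": False,
    "output_dir": "barseq_noise_run",
}

#: End-to-end scenario presets.
PRESETS: dict[str, dict] = {
    # four replicates performed together: replicate effects only
    "one-big-batch": {
        "replicates_per_batch": [4],
        "pool": {"include_engineered": True},
        "batch_model": {"sigma_batch": 0.0, "sigma_rep": 0.03},
        "noise": {
            "within_groups": ["GPB2", "IRA1non", "IRA1mis"],
            "across_groups": ["IRA1", "GPB2"],
        },
    },
    # 28 replicate experiments in 9 batches; engineered identical-mutation
    # sets present only in the first (4-replicate) batch
    "nine-batches": {
        "replicates_per_batch": [4, 4, 3, 3, 3, 3, 3, 3, 2],
        "pool": {"include_engineered": True},
        "engineered_batches": [1],
        "batch_model": {"sigma_batch": 0.10, "sigma_rep": 0.03},
        "noise": {
            "within_groups": ["GPB2", "IRA1non", "IRA1mis"],
            "across_groups": ["IRA1", "GPB2"],
        },
    },
    # small lane demonstrating index misassignment mechanisms: every index
    # used exactly once, so each mechanism leaves its own signature
    "misassignment-demo": {
        "pool": {"n_lineages": 60, "n_reference": 10},
        "design": {
            "reads_per_sample": 5_000,
            "n_replicates": 2,
            "timepoints": [0.0, 1.0, 2.0, 3.0],
        },
        "misassignment": {"p_template_switch": 0.10, "p_hop": 0.02},
        "scheme": {"kind": "unique_dual"},
        "read_level": True,
    },
}


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """Validated, fully serializable pipeline configuration."""

    data: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict | None = None, preset: str | None = None) -> "RunConfig":
        merged = _DEFAULTS
        if preset is not None:
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
            merged = _deep_update(merged, PRESETS[preset])
        if d:
            merged = _deep_update(merged, d)
        return cls(merged)

    @classmethod
    def from_yaml(cls, path, preset: str | None = None) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {}, preset=preset)

    def to_dict(self) -> dict:
        return copy.deepcopy(self.data)

    def __getitem__(self, key):
        return self.data[key]

    # -- typed accessors -------------------------------------------------

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def replicates_per_batch(self) -> list[int]:
        rpb = self.data.get("replicates_per_batch")
        if rpb:
            return [int(x) for x in rpb]
        d = self.data["design"]
        return [int(d.get("n_replicates", 3))] * int(d.get("n_batches", 1))

    def design(self, n_batches: int = 1, n_replicates: int | None = None) -> CompetitionDesign:
        d = dict(self.data["design"])
        d["timepoints"] = tuple(float(t) for t in d["timepoints"])
        d["n_batches"] = n_batches
        if n_replicates is not None:
            d["n_replicates"] = n_replicates
        return CompetitionDesign(**d)

    def batch_model(self) -> BatchEffectModel:
        return BatchEffectModel(**self.data["batch_model"])

    def geometry(self) -> AmpliconGeometry:
        return AmpliconGeometry(**self.data["geometry"])


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff every stage precondition is met."""
    problems: list[str] = []
    d = config.data

    tp = d["design"].get("timepoints", [])
    if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
        problems.append("design.timepoints must be strictly increasing with >= 2 points")
    elif len(tp) < 3 and d["inference"].get("mode") in ("reference", "mean_fitness"):
        problems.append(
            "warning: fewer than 3 timepoints — slope-based fitness inference "
            "(fitness_inference) recommends >= 3"
        )

    mis = d["misassignment"]
    p = float(mis.get("p_template_switch", 0)) + float(mis.get("p_hop", 0))
    if not 0 <= p <= 1:
        problems.append("misassignment: p_template_switch + p_hop must lie in [0, 1]")

    try:
        config.batch_model()
    except (TypeError, ValueError) as exc:
        problems.append(f"batch_model: {exc}")
    try:
        config.geometry()
    except (TypeError, ValueError) as exc:
        problems.append(f"geometry: {exc}")
    try:
        rpb = config.replicates_per_batch()
        if any(k < 1 for k in rpb):
            problems.append("replicates_per_batch entries must be >= 1")
    except (TypeError, ValueError) as exc:
        problems.append(f"replicates_per_batch: {exc}")

    if d.get("read_level"):
        from .index_design import capacity

        sch = d["scheme"]
        n_samples = sum(config.replicates_per_batch()) * len(tp)
        if sch["kind"] != "unique_dual":
            cap = capacity(sch["kind"], int(sch["n_f_pairs"]), int(sch["n_r_pairs"]))
            if cap < n_samples:
                problems.append(
                    f"scheme capacity {cap} < {n_samples} samples required for "
                    "read-level simulation"
                )

    if d["inference"].get("mode") not in ("reference", "mean_fitness"):
        problems.append("inference.mode must be 'reference' or 'mean_fitness'")
    return problems
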