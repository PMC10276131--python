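"""Reproducibility and variance decomposition of fitness measurements.

Fitness variation is split into three descriptive categories:

* **within experiment** — SD of fitness across lineages carrying the same
  genotype competing in the same vessel (sampling noise only: identical
  genotypes cannot differ in true fitness within one environment);
* **across replicates** — SD of one barcode's fitness across replicate
  experiments within a batch (adds replicate-level environmental noise);
* **across batches** — SD of one barcode's fitness across all replicate
  experiments regardless of batch (adds batch-level environmental noise).

All SDs are sample standard deviations (n-1 denominator) over groups with
at least two members; smaller groups are skipped and logged.  The module
also provides technical-replicate R², the genotype contrast that cancels
shared environmental shifts, a condition-effect estimator with a
batch-confounding diagnostic, and boxplot summary statistics (type-7
quartile hinges, 1.5xIQR whiskers, notch half-width 1.58*IQR/sqrt(n)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BoxStats",
    "summarize_box",
    "ReplicateComparison",
    "replicate_r2",
    "VarianceDecomposition",
    "variance_decomposition",
    "genotype_contrast",
    "ConditionEffect",
    "estimate_condition_effect",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Boxplot statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxStats:
    median: float
    lower_hinge: float
    upper_hinge: float
    iqr: float
    whisker_low: float
    whisker_high: float
    notch_halfwidth: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "median", "lower_hinge", "upper_hinge", "iqr",
            "whisker_low", "whisker_high", "notch_halfwidth", "n",
        )}


def summarize_box(values: Sequence[float]) -> BoxStats:
    """Boxplot summary: type-7 quartile hinges, 1.5xIQR whiskers, notches.

    Whiskers extend to the most extreme data value within 1.5xIQR of the
    hinges; the notch half-width is 1.58*IQR/sqrt(n), a rough 95%
    confidence interval around the median.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear (type 7) interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    within = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxStats(
        median=float(med),
        lower_hinge=float(q1),
        upper_hinge=float(q3),
        iqr=float(iqr),
        whisker_low=float(within.min()),
        whisker_high=float(within.max()),
        notch_halfwidth=float(1.58 * iqr / math.sqrt(x.size)),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Technical-replicate reproducibility
# ---------------------------------------------------------------------------


@dataclass
class ReplicateComparison:
    pair_id: str
    n_barcodes: int
    r_squared: float
    coverage_class_a: str
    coverage_class_b: str
    transform: str


def _counts_series(table) -> pd.Series:
    """Counts per barcode from a Series or a single-sample BarcodeCountTable."""
    if isinstance(table, pd.Series):
        return table
    df = table.df
    samples = df["sample_id"].unique()
    if len(samples) != 1:
        raise ValueError("replicate_r2 expects single-sample count tables")
    return df.set_index("barcode_id")["count"]


def _coverage_of(counts: pd.Series) -> str:
    mean = counts.sum() / max(1, counts.index.nunique())
    return "low" if mean < 20 else ("moderate" if mean <= 600 else "high")


def replicate_r2(
    table_a,
    table_b,
    pseudocount: float = 0.5,
    transform: str = "log10",
    pair_id: str = "pair",
) -> ReplicateComparison:
    """Reproducibility (R²) of barcode frequencies between technical replicates.

    Barcodes observed in either member are retained (a barcode that dropped
    to zero in one split enters through the pseudocount rather than being
    discarded, which would bias R² upward).  R² is the squared Pearson
    correlation of log10 pseudo-frequencies (``transform="raw"`` uses the
    frequencies directly).
    """
    a = _counts_series(table_a)
    b = _counts_series(table_b)
    barcodes = a.index.union(b.index)
    if len(barcodes) < 3:
        raise ValueError("need at least 3 shared barcodes to compute R²")
    av = a.reindex(barcodes, fill_value=0).to_numpy(dtype=float)
    bv = b.reindex(barcodes, fill_value=0).to_numpy(dtype=float)
    fa = (av + pseudocount) / (av.sum() + pseudocount * len(barcodes))
    fb = (bv + pseudocount) / (bv.sum() + pseudocount * len(barcodes))
    if transform == "log10":
        fa, fb = np.log10(fa), np.log10(fb)
    elif transform != "raw":
        raise ValueError("transform must be 'log10' or 'raw'")
    r, _ = stats.pearsonr(fa, fb)
    return ReplicateComparison(
        pair_id=pair_id,
        n_barcodes=len(barcodes),
        r_squared=float(r**2),
        coverage_class_a=_coverage_of(a),
        coverage_class_b=_coverage_of(b),
        transform=transform,
    )


# ---------------------------------------------------------------------------
# Variance decomposition
# ---------------------------------------------------------------------------


@dataclass
class VarianceDecomposition:
    """SD observations per category plus boxplot summaries.

    ``within_experiment``: one row per (replicate experiment, genotype
    group); ``across_replicate``: one row per (barcode, batch);
    ``across_batch``: one row per barcode.
    """

    within_experiment: pd.DataFrame
    across_replicate: pd.DataFrame
    across_batch: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "within_experiment": len(self.within_experiment),
            "across_replicate": len(self.across_replicate),
            "across_batch": len(self.across_batch),
        }

    def summary(self) -> dict[str, dict]:
        out = {}
        for name, df in (
            ("within_experiment", self.within_experiment),
            ("across_replicate", self.across_replicate),
            ("across_batch", self.across_batch),
        ):
            if len(df):
                out[name] = summarize_box(df["sd"].to_numpy()).to_dict()
        return out


def _genotype_series(genotype_map, barcodes) -> pd.Series:
    if isinstance(genotype_map, Mapping):
        genotype_map = pd.Series(genotype_map)
    return genotype_map.reindex(barcodes)


def variance_decomposition(
    fitness: pd.DataFrame,
    genotype_map,
    within_groups: Sequence[str] | None = None,
    across_groups: Sequence[str] | None = None,
) -> VarianceDecomposition:
    """Decompose fitness variation into the three descriptive SD categories.

    ``fitness`` requires columns barcode_id, replicate_id, batch_id, s_hat
    (one row per barcode per replicate experiment).  ``genotype_map`` maps
    barcode_id -> genotype label.  ``within_groups`` restricts the
    within-experiment category to the named genotype groups (e.g. the
    engineered identical-mutation sets); ``across_groups`` restricts the
    barcodes entering the across-replicate and across-batch categories.
    Groups with fewer than two members are skipped and logged.
    """
    required = {"barcode_id", "replicate_id", "batch_id", "s_hat"}
    if not required <= set(fitness.columns):
        raise ValueError(f"fitness table requires columns {sorted(required)}")
    df = fitness.copy()
    df["genotype"] = _genotype_series(genotype_map, df["barcode_id"]).to_numpy()
    skipped: list[str] = []

    sub = df if within_groups is None else df[df["genotype"].isin(within_groups)]
    within_rows = []
    for (rep, geno), grp in sub.groupby(["replicate_id", "genotype"], sort=True):
        if len(grp) < 2:
            skipped.append(f"within_experiment: ({rep}, {geno}) has {len(grp)} lineage(s)")
            continue
        within_rows.append(
            {"replicate_id": rep, "genotype_group": geno,
             "sd": float(grp["s_hat"].std(ddof=1)), "n_lineages": len(grp)}
        )

    sub = df if across_groups is None else df[df["genotype"].isin(across_groups)]
    rep_rows = []
    for (bc, batch), grp in sub.groupby(["barcode_id", "batch_id"], sort=True):
        if len(grp) < 2:
            skipped.append(f"across_replicate: ({bc}, {batch}) has {len(grp)} replicate(s)")
            continue
        rep_rows.append(
            {"barcode_id": bc, "batch_id": batch,
             "sd": float(grp["s_hat"].std(ddof=1)), "n_replicates": len(grp)}
        )

    batch_rows = []
    for bc, grp in sub.groupby("barcode_id", sort=True):
        if len(grp) < 2:
            skipped.append(f"across_batch: {bc} has {len(grp)} measurement(s)")
            continue
        batch_rows.append(
            {"barcode_id": bc, "sd": float(grp["s_hat"].std(ddof=1)),
             "n_replicates_total": len(grp)}
        )

    for msg in skipped:
        logger.info("variance_decomposition skipped %s", msg)
    cols_w = ["replicate_id", "genotype_group", "sd", "n_lineages"]
    cols_r = ["barcode_id", "batch_id", "sd", "n_replicates"]
    cols_b = ["barcode_id", "sd", "n_replicates_total"]
    return VarianceDecomposition(
        within_experiment=pd.DataFrame(within_rows, columns=cols_w),
        across_replicate=pd.DataFrame(rep_rows, columns=cols_r),
        across_batch=pd.DataFrame(batch_rows, columns=cols_b),
        skipped=skipped,
    )


def genotype_contrast(
    fitness: pd.DataFrame,
    genotype_map,
    genotype_a: str,
    genotype_b: str,
) -> tuple[pd.DataFrame, float]:
    """Per-replicate mean fitness difference between two genotype groups.

    Because batch- and replicate-level environmental shifts move both
    groups together (when their sensitivities match), the contrast cancels
    the shared deviate: its SD across replicates isolates the residual,
    non-shared noise.  Replicates missing either genotype are excluded and
    logged.  Returns (per-replicate differences, SD of the differences).
    """
    df = fitness.copy()
    df["genotype"] = _genotype_series(genotype_map, df["barcode_id"]).to_numpy()
    rows = []
    for rep, grp in df.groupby("replicate_id", sort=True):
        a = grp.loc[grp["genotype"] == genotype_a, "s_hat"]
        b = grp.loc[grp["genotype"] == genotype_b, "s_hat"]
        if a.empty or b.empty:
            logger.info("genotype_contrast: replicate %s lacks %s or %s; excluded",
                        rep, genotype_a, genotype_b)
            continue
        rows.append({"replicate_id": rep, "difference": float(a.mean() - b.mean())})
    out = pd.DataFrame(rows, columns=["replicate_id", "difference"])
    sd = float(out["difference"].std(ddof=1)) if len(out) > 1 else float("nan")
    return out, sd


# ---------------------------------------------------------------------------
# Condition effects and batch confounding
# ---------------------------------------------------------------------------


@dataclass
class ConditionEffect:
    """Difference of condition means with its naive standard error.

    ``naive_se`` treats every replicate as independent (σ/√n per
    condition); ``between_batch_sd`` is the SD of per-batch condition-mean
    differences, which exposes batch-level variation the naive SE ignores.
    ``confounded`` is raised when no batch contains both conditions, in
    which case the condition effect and the batch effect cannot be
    separated at all.
    """

    condition_a: str
    condition_b: str
    estimate: float
    naive_se: float
    n_a: int
    n_b: int
    between_batch_sd: float
    confounded: bool


def estimate_condition_effect(
    measurements: pd.DataFrame,
    condition_col: str = "condition",
    batch_col: str = "batch_id",
    value_col: str = "s_hat",
) -> ConditionEffect:
    """Estimate the effect of a condition with a batch-confounding diagnostic."""
    conds = sorted(measurements[condition_col].unique())
    if len(conds) != 2:
        raise ValueError(f"exactly two conditions required, got {conds}")
    a, b = conds
    xa = measurements.loc[measurements[condition_col] == a, value_col].to_numpy(float)
    xb = measurements.loc[measurements[condition_col] == b, value_col].to_numpy(float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("standard error undefined with fewer than 2 replicates per condition")
    estimate = float(xa.mean() - xb.mean())
    naive_se = float(math.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb)))

    per_batch = measurements.groupby([batch_col, condition_col])[value_col].mean().unstack(
        condition_col
    )
    both = per_batch.dropna()
    confounded = both.empty
    if len(both) > 1:
        between_batch_sd = float((both[a] - both[b]).std(ddof=1))
    else:
        # fall back to SD of per-batch means pooled over conditions
        batch_means = measurements.groupby(batch_col)[value_col].mean()
        between_batch_sd = float(batch_means.std(ddof=1)) if len(batch_means) > 1 else float("nan")
    return ConditionEffect(a, b, estimate, naive_se, len(xa), len(xb), between_batch_sd, confounded)
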