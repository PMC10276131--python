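"""Log-linear fitness inference from barcode count trajectories.

A lineage's fitness ``s`` is the log-linear rate of change of its
frequency relative to a benchmark, per unit competition time.  Two
benchmarking modes are provided:

``reference``
    Fitness relative to a set of spiked-in neutral reference lineages.
    The references are pooled by summing their counts (maximising the
    effective depth of the benchmark, which otherwise loses coverage as
    adaptive lineages expand) and ``s_i`` is the ordinary least-squares
    slope of ``ln f_i(t) - ln f_ref(t)``.

``mean_fitness``
    Fitness relative to the population mean fitness
    ``x̄(t) = Σ_i f_i(t) s_i``, obtained by fixed-point iteration: starting
    from raw log-frequency slopes, each pass recomputes x̄(t), integrates
    it over time, and re-fits slopes of ``ln f_i(t) + X(t)`` where
    ``X(t) = ∫ x̄ dt``.  At the fixed point the estimates are
    self-consistent with the mean fitness they imply.

Both modes operate on pseudocounted frequencies
``f_i = (c_i + a) / (C + a·B)`` (default ``a = 0.5``) so lineages with
zero-count timepoints are retained rather than dropped; affected
estimates are flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "FitnessEstimate",
    "MeanFitnessSeries",
    "pseudo_frequencies",
    "infer_fitness_reference",
    "infer_fitness_meanfit",
    "fitness_fold_change",
    "estimates_to_frame",
    "write_fitness_tsv",
    "read_fitness_tsv",
]

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_COVERAGE = 10.0


@dataclass
class FitnessEstimate:
    barcode_id: str
    s_hat: float
    std_error: float
    mode: str
    n_timepoints_used: int
    flags: tuple[str, ...] = ()


@dataclass
class MeanFitnessSeries:
    """Population mean fitness per timepoint plus convergence metadata."""

    timepoints: tuple[float, ...]
    mean_fitness: tuple[float, ...]
    iterations: int
    final_change: float
    converged: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "timepoints": list(self.timepoints),
                "mean_fitness": list(self.mean_fitness),
                "iterations": self.iterations,
                "final_change": self.final_change,
                "converged": self.converged,
            },
            indent=2,
        )


def _as_matrix(counts: pd.DataFrame, timepoints: Sequence[float] | None):
    """Counts as (barcodes x timepoints) float array with sorted time axis."""
    if timepoints is None:
        timepoints = list(counts.columns)
    t = np.asarray(timepoints, dtype=float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing (>= 2 points)")
    mat = counts.loc[:, list(timepoints)].to_numpy(dtype=float)
    return mat, t


def pseudo_frequencies(counts: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-timepoint frequencies (count + a) / (total + a * n_barcodes)."""
    c = counts.to_numpy(dtype=float)
    totals = c.sum(axis=0)
    f = (c + pseudocount) / (totals + pseudocount * c.shape[0])
    return pd.DataFrame(f, index=counts.index, columns=counts.columns)


def _ols_slopes(
    t: np.ndarray, Y: np.ndarray, var_y: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise OLS slope of Y against t with a calibrated standard error.

    The standard error is the larger of (a) the residual-based OLS
    estimate, which captures trajectory-level noise such as drift between
    transfers, and (b) a counting-noise (delta-method) propagation of the
    per-point variances ``var_y`` when provided — with few timepoints the
    residual variance estimate itself is very noisy (2-3 degrees of
    freedom), and the counting term keeps the error bar honest.  With
    exactly two timepoints only the counting term is available.
    """
    xc = t - t.mean()
    sxx = float(np.sum(xc**2))
    ybar = Y.mean(axis=1, keepdims=True)
    slope = (Y - ybar) @ xc / sxx
    fitted = ybar + slope[:, None] * xc[None, :]
    rss = ((Y - fitted) ** 2).sum(axis=1)
    dof = len(t) - 2
    if dof > 0:
        se = np.sqrt(np.maximum(rss, 0.0) / dof / sxx)
    else:
        se = np.zeros_like(slope)
    if var_y is not None:
        w = xc / sxx
        se_count = np.sqrt((w[None, :] ** 2 * var_y).sum(axis=1))
        se = np.maximum(se, se_count)
    return slope, se


def _base_flags(counts_mat: np.ndarray, min_coverage: float) -> list[tuple[str, ...]]:
    flags = []
    for row in counts_mat:
        fl = []
        if row.mean() < min_coverage:
            fl.append("low_coverage")
        if (row == 0).any():
            fl.append("zero_count_timepoint")
        flags.append(tuple(fl))
    return flags


def infer_fitness_reference(
    counts: pd.DataFrame,
    reference_barcodes: Sequence[str],
    timepoints: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[FitnessEstimate]:
    """Fitness relative to the pooled spiked-in reference lineages.

    ``counts`` is a barcode x timepoint matrix of deduplicated counts.
    The reference aggregate must have a nonzero raw count at every
    timepoint; otherwise the mean-fitness mode is the appropriate
    benchmark and an error says so.
    """
    refs = [b for b in reference_barcodes if b in counts.index]
    if not refs:
        raise ValueError("reference barcode set is empty or absent from the table")
    mat, t = _as_matrix(counts, timepoints)
    ref_counts = counts.loc[refs].to_numpy(dtype=float).sum(axis=0)
    if np.any(ref_counts == 0):
        raise ValueError(
            "reference lineages have zero aggregate count at some timepoint; "
            "use the mean_fitness benchmarking mode instead"
        )
    totals = mat.sum(axis=0)
    n_bc = mat.shape[0]
    f = (mat + pseudocount) / (totals + pseudocount * n_bc)
    f_ref = (ref_counts + pseudocount) / (totals + pseudocount * n_bc)
    y = np.log(f) - np.log(f_ref)[None, :]
    # Poisson-scale counting variance of y: 1/c_i + 1/c_ref per timepoint
    var_y = 1.0 / (mat + pseudocount) + (1.0 / (ref_counts + pseudocount))[None, :]
    slope, se = _ols_slopes(t, y, var_y)
    flags = _base_flags(mat, min_coverage)
    if len(t) == 2:
        flags = [fl + ("no_residual_df",) for fl in flags]
    return [
        FitnessEstimate(bc, float(slope[i]), float(se[i]), "reference", len(t), flags[i])
        for i, bc in enumerate(counts.index)
    ]


def infer_fitness_meanfit(
    counts: pd.DataFrame,
    timepoints: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    tol: float = 1e-6,
    max_iter: int = 100,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[list[FitnessEstimate], MeanFitnessSeries]:
    """Fitness relative to the self-consistent population mean fitness."""
    mat, t = _as_matrix(counts, timepoints)
    totals = mat.sum(axis=0)
    n_bc = mat.shape[0]
    f = (mat + pseudocount) / (totals + pseudocount * n_bc)
    logf = np.log(f)

    # The model is identified only up to an additive constant (shifting all
    # s_i and x̄ together changes nothing observable), so the scale is
    # anchored by pinning the population mean fitness at the first
    # timepoint to zero.
    def _anchor(v: np.ndarray) -> np.ndarray:
        return v - float(f[:, 0] @ v)

    s = _anchor(_ols_slopes(t, logf)[0])
    change = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        xbar = (f * s[:, None]).sum(axis=0)
        X = cumulative_trapezoid(xbar, t, initial=0.0)
        new_s = _anchor(_ols_slopes(t, logf + X[None, :])[0])
        change = float(np.max(np.abs(new_s - s)))
        s = new_s
        if change < tol:
            break
    converged = change < tol
    xbar = (f * s[:, None]).sum(axis=0)
    var_y = 1.0 / (mat + pseudocount)
    _, se = _ols_slopes(
        t, logf + cumulative_trapezoid(xbar, t, initial=0.0)[None, :], var_y
    )

    flags = _base_flags(mat, min_coverage)
    if len(t) == 2:
        flags = [fl + ("no_residual_df",) for fl in flags]
    if not converged:
        flags = [fl + ("not_converged",) for fl in flags]
    estimates = [
        FitnessEstimate(bc, float(s[i]), float(se[i]), "mean_fitness", len(t), flags[i])
        for i, bc in enumerate(counts.index)
    ]
    series = MeanFitnessSeries(
        tuple(float(x) for x in t),
        tuple(float(x) for x in xbar),
        iterations,
        change,
        converged,
    )
    return estimates, series


def fitness_fold_change(
    counts: pd.DataFrame,
    t_first: float,
    t_last: float,
    reference_barcodes: Sequence[str],
    timepoints: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[FitnessEstimate]:
    """Two-timepoint fold-change estimator of fitness relative to the reference.

    ``s_fc = [ln(f_i/f_ref)(t_last) - ln(f_i/f_ref)(t_first)] / (t_last - t_first)``.
    Ignores intermediate timepoints; a flag marks endpoints that were zero
    in the raw counts (estimable only through the pseudocount).
    """
    if t_last == t_first:
        raise ValueError("t_last must differ from t_first")
    if t_last < t_first:
        raise ValueError("t_last must exceed t_first")
    cols = list(counts.columns) if timepoints is None else list(timepoints)
    if t_first not in cols or t_last not in cols:
        raise ValueError("both endpoints must be observed timepoints")
    refs = [b for b in reference_barcodes if b in counts.index]
    if not refs:
        raise ValueError("reference barcode set is empty or absent from the table")
    sub = counts.loc[:, [t_first, t_last]]
    mat = sub.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    n_bc = mat.shape[0]
    f = (mat + pseudocount) / (totals + pseudocount * n_bc)
    ref_counts = sub.loc[refs].to_numpy(dtype=float).sum(axis=0)
    f_ref = (ref_counts + pseudocount) / (totals + pseudocount * n_bc)
    y = np.log(f) - np.log(f_ref)[None, :]
    s = (y[:, 1] - y[:, 0]) / (t_last - t_first)
    var_y = 1.0 / (mat + pseudocount) + (1.0 / (ref_counts + pseudocount))[None, :]
    se = np.sqrt(var_y.sum(axis=1)) / (t_last - t_first)
    out = []
    for i, bc in enumerate(counts.index):
        fl = []
        if (mat[i] == 0).any():
            fl.append("zero_count_endpoint")
        out.append(FitnessEstimate(bc, float(s[i]), float(se[i]), "fold_change", 2, tuple(fl)))
    return out


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def estimates_to_frame(
    estimates: Sequence[FitnessEstimate],
    replicate_id: str | None = None,
    batch_id: str | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "barcode_id": [e.barcode_id for e in estimates],
            "s_hat": [e.s_hat for e in estimates],
            "std_error": [e.std_error for e in estimates],
            "mode": [e.mode for e in estimates],
            "n_timepoints_used": [e.n_timepoints_used for e in estimates],
            "flags": [";".join(e.flags) for e in estimates],
        }
    )
    if replicate_id is not None:
        df.insert(1, "replicate_id", replicate_id)
    if batch_id is not None:
        df.insert(2, "batch_id", batch_id)
    return df


def write_fitness_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fitness_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"barcode_id": str}, keep_default_na=False)
    if "flags" in df.columns:
        df["flags"] = df["flags"].astype(str)
    return df
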