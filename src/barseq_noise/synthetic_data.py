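"""Generative simulator for DNA-barcoded pooled fitness competitions.

The simulator produces everything the downstream analysis consumes —
barcode frequency trajectories, technical-replicate splits, UMI-tagged
indexed reads — together with complete ground-truth labels, so that every
analysis step (demultiplexing, swap classification, fitness inference,
variance decomposition) can be checked against what actually happened.

Model
-----
A pool of barcoded lineages competes through serial transfers.  Lineage
``i`` has a baseline fitness ``s_i`` (log-frequency change per transfer
interval) and an environmental sensitivity ``g_i``.  Experiments are
organised into batches (sets of replicates performed together); a batch
draws a shared environmental deviate ``delta_b ~ N(0, sigma_batch)`` and
each replicate adds its own ``eps_r ~ N(0, sigma_rep)``, giving the
effective fitness

    s_eff(i, b, r) = s_i + g_i * (delta_b + eps_r)

Per transfer interval the population updates deterministically,
``f_i <- f_i * exp(s_eff_i) / sum_j f_j * exp(s_eff_j)``, followed by a
multinomial bottleneck of ``bottleneck_size`` cells (``bottleneck_size=0``
selects an exact, noise-free recursion).  Because reference lineages are
pinned at ``s = 0`` and ``g = 0``, shared deviates move all mutants up or
down together — the signature of a batch effect.

Sequencing is modeled as molecule sampling (multinomial draw of PCR
template molecules, each tagged with a random UMI) followed by read
sampling over molecules (PCR duplicates share a UMI).  Index
misassignment is applied read-wise: template switching forms a chimera
with a random partner read, with the breakpoint uniform over the amplicon
(two flanks between the Illumina and inline indices plus the homologous
middle region between the inline indices); index hopping replaces a single
Illumina index with a random draw from the index pool.

Amplicon convention: each inline index sits on the same end of the
molecule as its paired Illumina index, i.e. the molecule reads
``[N][F][left flank | middle | right flank][R][S]``.  A breakpoint in the
middle region therefore exchanges the whole ``(R, S)`` half; a breakpoint
in a flank exchanges only the outer Illumina index on that side, which is
exactly why flank template switches present as single Illumina swaps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LineageSpec",
    "BatchEffectModel",
    "CompetitionDesign",
    "AmpliconGeometry",
    "ReadSet",
    "CompetitionResult",
    "make_pool",
    "simulate_competition",
    "split_sample",
    "sample_read_counts",
    "simulate_sequencing",
    "apply_misassignment",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

TRUTH_COLUMNS = ("origin_sample", "event", "partner_sample", "breakpoint_region", "hidden")
READ_COLUMNS = ("f_idx", "n_idx", "r_idx", "s_idx", "barcode_id", "umi")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineageSpec:
    """One barcoded lineage in the competition pool.

    ``base_fitness`` is the log-linear frequency change per transfer
    interval (s); ``env_sensitivity`` scales the shared environmental
    deviates (0 for reference lineages, which define the fitness origin).
    """

    barcode_id: str
    genotype_label: str
    base_fitness: float
    env_sensitivity: float
    initial_frequency: float


@dataclass(frozen=True)
class BatchEffectModel:
    """Shared environmental fitness shifts at the batch and replicate level."""

    sigma_batch: float = 0.0
    sigma_rep: float = 0.0

    def __post_init__(self):
        if self.sigma_batch < 0 or self.sigma_rep < 0:
            raise ValueError("batch/replicate effect SDs must be >= 0")


@dataclass(frozen=True)
class CompetitionDesign:
    """Sampling design of a pooled competition experiment.

    ``bottleneck_size = 0`` is a sentinel selecting the deterministic
    (infinite population) recursion.  ``pcr_molecules_per_sample = None``
    derives the molecule count from ``reads_per_sample / duplication_rate``.
    """

    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    bottleneck_size: int = 1_000_000
    reads_per_sample: int = 100_000
    n_replicates: int = 3
    n_batches: int = 1
    pcr_molecules_per_sample: int | None = None
    duplication_rate: float = 1.5
    umi_length: int = 8
    generations_per_interval: float = 1.0

    def __post_init__(self):
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 2 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing (>= 2 points)")
        if self.bottleneck_size < 0:
            raise ValueError("bottleneck_size must be >= 0 (0 = deterministic)")
        for name in ("reads_per_sample", "n_replicates", "n_batches", "umi_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.pcr_molecules_per_sample is not None and self.pcr_molecules_per_sample < 1:
            raise ValueError("pcr_molecules_per_sample must be positive")
        if self.duplication_rate <= 0:
            raise ValueError("duplication_rate must be positive")

    @property
    def n_molecules(self) -> int:
        if self.pcr_molecules_per_sample is not None:
            return self.pcr_molecules_per_sample
        return max(1, round(self.reads_per_sample / self.duplication_rate))


@dataclass(frozen=True)
class AmpliconGeometry:
    """Lengths (bp) of the amplicon segments between the index positions.

    The barcode occupies ``barcode_length`` bases of the homologous middle
    region starting at ``barcode_offset`` (default: centered).
    """

    left_flank_len: int = 40
    middle_len: int = 167
    right_flank_len: int = 40
    barcode_length: int = 26
    barcode_offset: int | None = None

    def __post_init__(self):
        if min(self.left_flank_len, self.middle_len, self.right_flank_len) <= 0:
            raise ValueError("all segment lengths must be > 0")
        off = self.barcode_start
        if off < 0 or off + self.barcode_length > self.middle_len:
            raise ValueError("barcode must lie fully inside the middle region")

    @property
    def barcode_start(self) -> int:
        if self.barcode_offset is not None:
            return self.barcode_offset
        return (self.middle_len - self.barcode_length) // 2

    @property
    def total_len(self) -> int:
        return self.left_flank_len + self.middle_len + self.right_flank_len


@dataclass
class ReadSet:
    """Indexed reads plus a truth sidecar.

    ``df`` holds both the analysis-facing columns (:data:`READ_COLUMNS`
    plus ``sample_id`` is *not* included — assignment is the demultiplexer's
    job) and the truth columns (:data:`TRUTH_COLUMNS`).  Use :meth:`reads`
    for the analysis-facing view and :meth:`truth` for the sidecar; the
    truth never leaks into demultiplexer input.
    """

    df: pd.DataFrame
    scheme: object = None  # IndexScheme; duck-typed to avoid circular import
    assignment: dict[str, tuple[str, str, str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def reads(self) -> pd.DataFrame:
        return self.df[list(READ_COLUMNS)].copy()

    def truth(self) -> pd.DataFrame:
        return self.df[list(TRUTH_COLUMNS)].copy()


@dataclass
class CompetitionResult:
    """True trajectories and effective-fitness truth of one simulation.

    ``frequencies``: long table (batch_id, replicate_id, timepoint,
    barcode_id, frequency).  ``s_eff``: one row per (barcode, batch,
    replicate) with the realised effective fitness.
    """

    frequencies: pd.DataFrame
    s_eff: pd.DataFrame
    metadata: dict

    def wide(self, batch_id: str, replicate_id: str) -> pd.DataFrame:
        """Barcode x timepoint frequency matrix for one replicate."""
        sub = self.frequencies[
            (self.frequencies.batch_id == batch_id)
            & (self.frequencies.replicate_id == replicate_id)
        ]
        return sub.pivot(index="barcode_id", columns="timepoint", values="frequency")


# ---------------------------------------------------------------------------
# Pool construction
# ---------------------------------------------------------------------------


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        arr = _BASES[rng.integers(0, 4, size=(n - len(out), length))]
        for bc in arr.view(f"S{length}").ravel():
            s = bc.decode()
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def make_pool(
    n_lineages: int = 500,
    n_reference: int = 40,
    n_ira1: int = 21,
    n_gpb2: int = 13,
    n_ira1non: int = 6,
    n_ira1mis: int = 8,
    include_engineered: bool = False,
    reference_initial_fraction: float = 0.10,
    s_ira1: float = 0.69,
    s_gpb2: float = 0.35,
    sigma_within_gene: float = 0.01,
    sigma_background: float = 0.05,
    barcode_length: int = 26,
    seed: int = 0,
) -> list[LineageSpec]:
    """Build a default competition pool.

    The pool emulates a barcoded yeast competition: a block of neutral
    reference lineages spiked in at a substantial combined frequency, a
    class of strongly adaptive mutants (IRA1-like, fitness roughly x2 the
    reference per interval, i.e. s ~= 0.69), an intermediate class
    (GPB2-like, s ~= 0.35), optional engineered sets carrying identical
    mutations under distinct barcodes (IRA1non*/IRA1mis*), and weakly
    selected background lineages filling the pool to ``n_lineages``.

    Lineages within the IRA1 and GPB2 classes carry different mutations of
    similar effect (per-lineage spread ``sigma_within_gene``); lineages of
    an engineered set carry the *same* mutation and therefore share one
    true fitness value — variation among them within one experiment is
    pure measurement noise.
    """
    rng = np.random.default_rng(seed)
    groups: list[tuple[str, int]] = [("reference", n_reference), ("IRA1", n_ira1), ("GPB2", n_gpb2)]
    if include_engineered:
        groups += [("IRA1non", n_ira1non), ("IRA1mis", n_ira1mis)]
    n_named = sum(n for _, n in groups)
    if n_named > n_lineages:
        raise ValueError("named groups exceed n_lineages")
    groups.append(("other", n_lineages - n_named))

    barcodes = _random_barcodes(n_lineages, barcode_length, rng)
    n_other = n_lineages - n_named
    mutant_freq = (1.0 - reference_initial_fraction) / max(1, n_lineages - n_reference)
    ref_freq = reference_initial_fraction / max(1, n_reference)

    # one shared true fitness per engineered identical-mutation set
    set_fitness = {
        "IRA1non": float(rng.normal(s_ira1, sigma_within_gene)),
        "IRA1mis": float(rng.normal(s_ira1, sigma_within_gene)),
    }
    pool: list[LineageSpec] = []
    k = 0
    for label, n in groups:
        for _ in range(n):
            if label == "reference":
                s, g, f0 = 0.0, 0.0, ref_freq
            elif label in ("IRA1non", "IRA1mis"):
                s, g, f0 = set_fitness[label], 1.0, mutant_freq
            elif label == "IRA1":
                s, g, f0 = rng.normal(s_ira1, sigma_within_gene), 1.0, mutant_freq
            elif label == "GPB2":
                s, g, f0 = rng.normal(s_gpb2, sigma_within_gene), 1.0, mutant_freq
            else:
                s, g, f0 = rng.normal(0.0, sigma_background), 1.0, mutant_freq
            pool.append(LineageSpec(barcodes[k], label, float(s), g, f0))
            k += 1
    total = sum(l.initial_frequency for l in pool)
    pool = [
        LineageSpec(l.barcode_id, l.genotype_label, l.base_fitness, l.env_sensitivity,
                    l.initial_frequency / total)
        for l in pool
    ]
    return pool


def _check_pool(pool: Sequence[LineageSpec]) -> None:
    if not pool:
        raise ValueError("empty pool")
    ids = [l.barcode_id for l in pool]
    if len(set(ids)) != len(ids):
        raise ValueError("barcode_ids must be unique within a pool")
    total = sum(l.initial_frequency for l in pool)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"initial frequencies must sum to 1 (got {total})")
    for l in pool:
        if l.genotype_label == "reference" and (l.base_fitness != 0.0 or l.env_sensitivity != 0.0):
            raise ValueError("reference lineages must have s = 0 and env_sensitivity = 0")
        if not (0 < l.initial_frequency <= 1):
            raise ValueError("initial frequencies must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Competition dynamics
# ---------------------------------------------------------------------------


def _propagate(
    f0: np.ndarray,
    s_eff: np.ndarray,
    timepoints: np.ndarray,
    bottleneck: int,
    gen_per_interval: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Frequencies at the recorded timepoints (rows) for one replicate."""
    out = np.empty((len(timepoints), len(f0)))
    f = f0.copy()
    t = timepoints[0]
    growth = np.exp(s_eff * gen_per_interval)
    for k, tk in enumerate(timepoints):
        remaining = tk - t
        while remaining > 1e-12:
            dt = min(1.0, remaining)
            f = f * growth**dt
            f /= f.sum()
            # one bottleneck per completed transfer interval
            if bottleneck > 0 and dt >= 1.0 - 1e-12:
                counts = rng.multinomial(bottleneck, f)
                f = counts / bottleneck
            remaining -= dt
        t = tk
        out[k] = f
    return out


def simulate_competition(
    pool: Sequence[LineageSpec],
    design: CompetitionDesign,
    batch_model: BatchEffectModel | None = None,
    seed: int = 0,
) -> CompetitionResult:
    """Simulate true frequency trajectories for every (batch, replicate).

    Identical ``(pool, design, batch_model, seed)`` reproduce identical
    output.  A pool without reference lineages is allowed but flagged in
    the result metadata.
    """
    _check_pool(pool)
    batch_model = batch_model or BatchEffectModel()
    rng = np.random.default_rng(seed)

    barcodes = np.array([l.barcode_id for l in pool])
    s = np.array([l.base_fitness for l in pool])
    g = np.array([l.env_sensitivity for l in pool])
    f0 = np.array([l.initial_frequency for l in pool])
    tp = np.asarray(design.timepoints, dtype=float)

    freq_rows = []
    s_rows = []
    rep_counter = 0
    for b in range(design.n_batches):
        batch_id = f"batch_{b + 1}"
        delta_b = rng.normal(0.0, batch_model.sigma_batch) if batch_model.sigma_batch else 0.0
        for _ in range(design.n_replicates):
            rep_counter += 1
            replicate_id = f"rep_{rep_counter:02d}"
            eps_r = rng.normal(0.0, batch_model.sigma_rep) if batch_model.sigma_rep else 0.0
            s_eff = s + g * (delta_b + eps_r)
            traj = _propagate(
                f0, s_eff, tp, design.bottleneck_size, design.generations_per_interval, rng
            )
            for k, tk in enumerate(tp):
                freq_rows.append(
                    pd.DataFrame(
                        {
                            "batch_id": batch_id,
                            "replicate_id": replicate_id,
                            "timepoint": tk,
                            "barcode_id": barcodes,
                            "frequency": traj[k],
                        }
                    )
                )
            s_rows.append(
                pd.DataFrame(
                    {
                        "barcode_id": barcodes,
                        "batch_id": batch_id,
                        "replicate_id": replicate_id,
                        "s_eff": s_eff,
                        "delta_batch": delta_b,
                        "eps_replicate": eps_r,
                    }
                )
            )

    frequencies = pd.concat(freq_rows, ignore_index=True)
    s_eff_table = pd.concat(s_rows, ignore_index=True)
    has_reference = any(l.genotype_label == "reference" for l in pool)
    meta = {
        "seed": seed,
        "n_lineages": len(pool),
        "has_reference": has_reference,
        "deterministic": design.bottleneck_size == 0,
    }
    return CompetitionResult(frequencies, s_eff_table, meta)


# ---------------------------------------------------------------------------
# Technical replicate splitting
# ---------------------------------------------------------------------------


def split_sample(counts, n_splits: int = 2, seed: int = 0):
    """Split integer counts symmetrically into ``n_splits`` technical replicates.

    Each barcode's count is distributed multinomially with equal weight per
    split (symmetric binomial thinning), so per-barcode totals across the
    splits equal the input exactly.  Accepts a mapping or an integer array;
    returns a list of objects of the same kind.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    rng = np.random.default_rng(seed)
    is_mapping = isinstance(counts, Mapping)
    keys = list(counts.keys()) if is_mapping else None
    vec = np.asarray(list(counts.values()) if is_mapping else counts)
    if np.any(vec < 0) or not np.issubdtype(vec.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    p = np.full(n_splits, 1.0 / n_splits)
    parts = np.zeros((n_splits, len(vec)), dtype=np.int64)
    for i, n in enumerate(vec):
        if n > 0:
            parts[:, i] = rng.multinomial(int(n), p)
    if is_mapping:
        return [dict(zip(keys, parts[j])) for j in range(n_splits)]
    return [parts[j] for j in range(n_splits)]


# ---------------------------------------------------------------------------
# Sequencing
# ---------------------------------------------------------------------------


def sample_read_counts(
    frequencies: Mapping[str, float] | pd.Series, depth: int, seed: int = 0
) -> pd.Series:
    """Multinomial read counts over barcodes at a given depth (no UMI model)."""
    ser = pd.Series(frequencies, dtype=float)
    p = ser.to_numpy()
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    return pd.Series(rng.multinomial(depth, p), index=ser.index, name="count")


def _random_umis(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    digits = rng.integers(0, 4, size=(n, length))
    return _BASES[digits].view(f"S{length}").ravel().astype(str)


def simulate_sequencing(
    sample_frequencies: Mapping[str, Mapping[str, float] | pd.Series],
    design: CompetitionDesign,
    scheme,
    assignment: Mapping[str, tuple[str, str, str, str]] | None = None,
    seed: int = 0,
) -> ReadSet:
    """Draw UMI-tagged indexed reads for every sample.

    Per sample: ``design.n_molecules`` template molecules are drawn
    multinomially from the barcode frequencies and tagged with random UMIs
    (collisions allowed — their count is recorded in no output, UMI space
    is 4^umi_length); then ``design.reads_per_sample`` reads are drawn
    multinomially over the molecules, so PCR duplicates share a UMI.
    Every read carries its sample's index tuple and a truth label.
    """
    assignment = dict(assignment) if assignment is not None else dict(scheme.samples)
    missing = set(sample_frequencies) - set(assignment)
    if missing:
        raise ValueError(f"samples missing from index assignment: {sorted(missing)}")
    rng = np.random.default_rng(seed)

    frames = []
    for sample_id in sample_frequencies:
        ser = pd.Series(sample_frequencies[sample_id], dtype=float)
        p = ser.to_numpy()
        p = p / p.sum()
        barcodes = ser.index.to_numpy()

        n_mol = design.n_molecules
        mol_counts = rng.multinomial(n_mol, p)
        mol_barcodes = np.repeat(barcodes, mol_counts)
        umis = _random_umis(n_mol, design.umi_length, rng)

        reads_per_mol = rng.multinomial(design.reads_per_sample, np.full(n_mol, 1.0 / n_mol))
        read_idx = np.repeat(np.arange(n_mol), reads_per_mol)

        f, n, r, s = assignment[sample_id]
        frames.append(
            pd.DataFrame(
                {
                    "f_idx": f,
                    "n_idx": n,
                    "r_idx": r,
                    "s_idx": s,
                    "barcode_id": mol_barcodes[read_idx],
                    "umi": umis[read_idx],
                    "origin_sample": sample_id,
                    "event": "none",
                    "partner_sample": None,
                    "breakpoint_region": None,
                    "hidden": False,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return ReadSet(df, scheme=scheme, assignment=assignment)


# ---------------------------------------------------------------------------
# Index misassignment
# ---------------------------------------------------------------------------


def apply_misassignment(
    readset: ReadSet,
    p_template_switch: float,
    p_hop: float,
    geometry: AmpliconGeometry | None = None,
    seed: int = 0,
) -> ReadSet:
    """Apply template switching and index hopping to a pooled read set.

    Each read independently: with probability ``p_template_switch`` it
    becomes a chimera with a partner read drawn uniformly from the whole
    pooled set (hence frequency-weighted), with the breakpoint uniform
    over the amplicon; with probability ``p_hop`` one Illumina index
    (N or S, equal odds) is replaced by a uniform draw from the scheme's
    corresponding pool.  Truth columns record the event, partner sample,
    breakpoint region, and whether the event is hidden (the resulting
    tuple still equals the origin sample's own tuple).
    """
    geometry = geometry or AmpliconGeometry()
    if p_template_switch < 0 or p_hop < 0 or p_template_switch + p_hop > 1:
        raise ValueError("require 0 <= p_template_switch + p_hop <= 1")
    n = len(readset)
    if n == 0:
        if p_template_switch + p_hop > 0:
            raise ValueError("cannot apply misassignment to an empty read set")
        return ReadSet(readset.df.copy(), readset.scheme, dict(readset.assignment))

    rng = np.random.default_rng(seed)
    df = readset.df.copy()
    orig = {c: readset.df[c].to_numpy() for c in ("f_idx", "n_idx", "r_idx", "s_idx", "barcode_id")}

    u = rng.random(n)
    ts = u < p_template_switch
    hop = (u >= p_template_switch) & (u < p_template_switch + p_hop)

    event = np.full(n, "none", dtype=object)
    partner_sample = np.full(n, None, dtype=object)
    region = np.full(n, None, dtype=object)

    # --- template switching -------------------------------------------
    idx_ts = np.flatnonzero(ts)
    if idx_ts.size:
        partners = rng.integers(0, n, size=idx_ts.size)
        pos = rng.uniform(0.0, geometry.total_len, size=idx_ts.size)
        left = pos < geometry.left_flank_len
        middle = (~left) & (pos < geometry.left_flank_len + geometry.middle_len)
        right = ~(left | middle)

        event[idx_ts] = "template_switch"
        partner_sample[idx_ts] = readset.df["origin_sample"].to_numpy()[partners]
        region[idx_ts[left]] = "left_flank"
        region[idx_ts[middle]] = "middle"
        region[idx_ts[right]] = "right_flank"

        # left flank: outer Illumina index (N) from the partner
        df.loc[df.index[idx_ts[left]], "n_idx"] = orig["n_idx"][partners[left]]
        # right flank: outer Illumina index (S) from the partner
        df.loc[df.index[idx_ts[right]], "s_idx"] = orig["s_idx"][partners[right]]
        # middle: the whole (R, S) half comes from the partner; the barcode
        # follows whichever side of the breakpoint it lies on
        mid_rows = df.index[idx_ts[middle]]
        df.loc[mid_rows, "r_idx"] = orig["r_idx"][partners[middle]]
        df.loc[mid_rows, "s_idx"] = orig["s_idx"][partners[middle]]
        pos_in_middle = pos[middle] - geometry.left_flank_len
        from_partner = pos_in_middle < geometry.barcode_start
        df.loc[mid_rows[from_partner], "barcode_id"] = orig["barcode_id"][
            partners[middle][from_partner]
        ]

    # --- index hopping --------------------------------------------------
    idx_hop = np.flatnonzero(hop)
    if idx_hop.size:
        event[idx_hop] = "index_hop"
        which_s = rng.integers(0, 2, size=idx_hop.size).astype(bool)
        n_pool = np.asarray(readset.scheme.illumina_n, dtype=object)
        s_pool = np.asarray(readset.scheme.illumina_s, dtype=object)
        new_n = n_pool[rng.integers(0, len(n_pool), size=idx_hop.size)]
        new_s = s_pool[rng.integers(0, len(s_pool), size=idx_hop.size)]
        df.loc[df.index[idx_hop[~which_s]], "n_idx"] = new_n[~which_s]
        df.loc[df.index[idx_hop[which_s]], "s_idx"] = new_s[which_s]

    # --- truth bookkeeping ----------------------------------------------
    df["event"] = event
    df["partner_sample"] = partner_sample
    df["breakpoint_region"] = region

    origin_tuples = np.array(
        [readset.assignment[s] for s in df["origin_sample"]], dtype=object
    )
    new_tuples = df[["f_idx", "n_idx", "r_idx", "s_idx"]].to_numpy(dtype=object)
    same = (origin_tuples == new_tuples).all(axis=1)
    df["hidden"] = same & (df["event"] != "none")
    return ReadSet(df, readset.scheme, dict(readset.assignment))


# ---------------------------------------------------------------------------
# Index-identifier pseudo-sequences (for FASTQ emission)
# ---------------------------------------------------------------------------


def index_sequence(identifier: str, length: int = 8) -> str:
    """Deterministic pseudo-sequence for an index identifier."""
    digest = hashlib.sha256(identifier.encode()).digest()
    return "".join("ACGT"[b % 4] for b in digest[:length])
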