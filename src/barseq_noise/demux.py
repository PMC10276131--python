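"""Demultiplexing: swap classification, UMI deduplication, count tables.

Every observed index tuple ``(F, N, R, S)`` is classified into exactly one
category, in strict precedence order:

1. ``unmatched`` — any index absent from the scheme's pools;
2. ``correct`` — the tuple equals a sample's tuple;
3. ``template_switch`` — the (F, N) half belongs to one sample and the
   (R, S) half to another, but the combination is no sample: a chimeric
   read whose two ends each match a correct index combination;
4. ``single_illumina_swap`` / ``single_inline_swap`` — the tuple differs
   from some sample's tuple in exactly one position (Illumina index N/S,
   or inline index F/R respectively);
5. ``double_swap`` — differs from some sample in exactly two positions;
6. ``unmatched`` otherwise.

On a nested unique-dual scheme these categories are disjoint by
construction; the precedence order resolves overlaps on other schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

__all__ = [
    "SWAP_CLASSES",
    "Classifier",
    "classify_read",
    "classify_reads",
    "BarcodeCountTable",
    "MisassignmentReport",
    "misassignment_report",
    "umi_deduplicate",
    "demux_reads",
    "collapse_to_combinatorial",
    "coverage_class",
]

SWAP_CLASSES = (
    "correct",
    "template_switch",
    "single_illumina_swap",
    "single_inline_swap",
    "double_swap",
    "unmatched",
)

_ILLUMINA_POSITIONS = (1, 3)  # N and S within the (F, N, R, S) tuple


class Classifier:
    """Precomputed lookup tables for classifying index tuples under a scheme."""

    def __init__(self, scheme):
        self.scheme = scheme
        self.pools = scheme.pools()
        self.samples = scheme.sample_tuples
        self.left = scheme.left_halves()
        self.right = scheme.right_halves()
        # projections of sample tuples with 1 and 2 positions removed
        self._drop1: list[set] = [set() for _ in range(4)]
        self._drop2: dict[tuple[int, int], set] = {
            pair: set() for pair in combinations(range(4), 2)
        }
        for t in self.samples:
            for p in range(4):
                self._drop1[p].add(t[:p] + t[p + 1 :])
            for pair in self._drop2:
                kept = tuple(t[q] for q in range(4) if q not in pair)
                self._drop2[pair].add(kept)

    def classify(self, tup: tuple[str, str, str, str]) -> tuple[str, str | None]:
        """Return (swap_class, inferred origin sample or None)."""
        f, n, r, s = tup
        pf, pn, pr, ps = self.pools
        if f not in pf or n not in pn or r not in pr or s not in ps:
            return "unmatched", None
        if tup in self.samples:
            return "correct", self.samples[tup]
        if (f, n) in self.left and (r, s) in self.right:
            return "template_switch", None
        one_mismatch = [p for p in range(4) if tup[:p] + tup[p + 1 :] in self._drop1[p]]
        if one_mismatch:
            if any(p in _ILLUMINA_POSITIONS for p in one_mismatch):
                return "single_illumina_swap", None
            return "single_inline_swap", None
        for pair, kept_set in self._drop2.items():
            kept = tuple(tup[q] for q in range(4) if q not in pair)
            if kept in kept_set:
                return "double_swap", None
        return "unmatched", None


def classify_read(tup, scheme) -> str:
    """Swap class of a single observed (F, N, R, S) tuple."""
    return Classifier(scheme).classify(tuple(tup))[0]


def classify_reads(reads: pd.DataFrame, scheme) -> pd.DataFrame:
    """Classify every read; returns a copy with swap_class and sample_id columns."""
    clf = Classifier(scheme)
    tuples = list(
        zip(reads["f_idx"], reads["n_idx"], reads["r_idx"], reads["s_idx"])
    )
    classes, origins = [], []
    cache: dict[tuple, tuple[str, str | None]] = {}
    for t in tuples:
        got = cache.get(t)
        if got is None:
            got = clf.classify(t)
            cache[t] = got
        classes.append(got[0])
        origins.append(got[1])
    out = reads.copy()
    out["swap_class"] = classes
    out["sample_id"] = origins
    return out


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


@dataclass
class BarcodeCountTable:
    """Deduplicated counts per (sample, barcode).

    ``df`` has columns sample_id, barcode_id, count.  ``all_barcodes``
    optionally fixes the barcode universe used as the denominator of
    per-sample mean coverage (otherwise the distinct barcodes in the
    table are used).
    """

    df: pd.DataFrame
    all_barcodes: list[str] | None = None

    def __post_init__(self):
        required = {"sample_id", "barcode_id", "count"}
        if not required <= set(self.df.columns):
            raise ValueError(f"count table requires columns {sorted(required)}")
        if (self.df["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_barcodes(self) -> int:
        if self.all_barcodes is not None:
            return len(self.all_barcodes)
        return self.df["barcode_id"].nunique()

    def sample_totals(self) -> pd.Series:
        return self.df.groupby("sample_id")["count"].sum()

    def mean_coverage(self) -> pd.Series:
        """Mean reads per barcode, per sample."""
        return self.sample_totals() / self.n_barcodes

    def total(self) -> int:
        return int(self.df["count"].sum())

    def wide(self) -> pd.DataFrame:
        """barcode x sample count matrix (absent entries are 0)."""
        return (
            self.df.pivot_table(
                index="barcode_id", columns="sample_id", values="count", fill_value=0,
                aggfunc="sum",
            )
            .astype(int)
        )

    def to_tsv(self, path) -> None:
        self.df[["sample_id", "barcode_id", "count"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BarcodeCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "barcode_id": str})
        return cls(df)


def umi_deduplicate(reads: pd.DataFrame) -> BarcodeCountTable:
    """Collapse PCR duplicates: count distinct UMIs per (sample, barcode).

    UMI comparison is exact string match; no edit-distance collapsing.
    """
    for col in ("sample_id", "barcode_id", "umi"):
        if col not in reads.columns:
            raise ValueError(f"reads table missing required column {col!r}")
    if reads["umi"].isna().any():
        raise ValueError("reads with missing UMIs cannot be deduplicated")
    counts = (
        reads.groupby(["sample_id", "barcode_id"], sort=True)["umi"]
        .nunique()
        .rename("count")
        .reset_index()
    )
    return BarcodeCountTable(counts)


# ---------------------------------------------------------------------------
# Misassignment report
# ---------------------------------------------------------------------------


@dataclass
class MisassignmentReport:
    """Fractions of mapped reads per swap category.

    ``breakdown`` maps each misassigned class to
    (fraction of misassigned reads, fraction of total mapped reads).
    Unmatched reads are excluded from the mapped denominator and reported
    separately via ``unmatched`` / ``unmatched_fraction_of_all``.
    """

    total_mapped: int
    correct_fraction: float
    misassigned_fraction: float
    breakdown: dict[str, tuple[float, float]] = field(default_factory=dict)
    unmatched: int = 0

    @property
    def unmatched_fraction_of_all(self) -> float:
        denom = self.total_mapped + self.unmatched
        return self.unmatched / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "total_mapped": self.total_mapped,
            "correct_fraction": self.correct_fraction,
            "misassigned_fraction": self.misassigned_fraction,
            "breakdown": {
                k: {"of_misassigned": a, "of_total_mapped": b}
                for k, (a, b) in self.breakdown.items()
            },
            "unmatched": self.unmatched,
            "unmatched_fraction_of_all": self.unmatched_fraction_of_all,
        }


def misassignment_report(classified: pd.DataFrame | pd.Series) -> MisassignmentReport:
    """Summarize swap classes into per-category fractions of mapped reads."""
    classes = classified["swap_class"] if isinstance(classified, pd.DataFrame) else classified
    n_unmatched = int((classes == "unmatched").sum())
    mapped = classes[classes != "unmatched"]
    total = len(mapped)
    if total == 0:
        raise ValueError("no mapped reads: cannot compute a misassignment report")
    n_correct = int((mapped == "correct").sum())
    n_mis = total - n_correct
    breakdown: dict[str, tuple[float, float]] = {}
    if n_mis:
        for cls in SWAP_CLASSES[1:-1]:  # misassigned categories only
            k = int((mapped == cls).sum())
            if k:
                breakdown[cls] = (k / n_mis, k / total)
    return MisassignmentReport(
        total_mapped=total,
        correct_fraction=n_correct / total,
        misassigned_fraction=n_mis / total,
        breakdown=breakdown,
        unmatched=n_unmatched,
    )


# ---------------------------------------------------------------------------
# Demultiplexing pipelines
# ---------------------------------------------------------------------------


def demux_reads(reads: pd.DataFrame, scheme) -> tuple[BarcodeCountTable, MisassignmentReport, pd.DataFrame]:
    """Full nested/UDI demultiplexing: classify, keep correct reads, dedup.

    Returns (count table, misassignment report, classified reads).
    """
    classified = classify_reads(reads, scheme)
    report = misassignment_report(classified)
    correct = classified[classified["swap_class"] == "correct"]
    table = umi_deduplicate(correct)
    return table, report, classified


def collapse_to_combinatorial(reads: pd.DataFrame, scheme) -> BarcodeCountTable:
    """Demultiplex by Illumina indices (N, S) alone, ignoring inline indices.

    This reproduces what a combinatorial-indexing analysis would see: every
    swap that only a nested/UDI check could catch is silently accepted and
    credited to the sample owning that (N, S) combination.
    """
    ns_map: dict[tuple[str, str], str] = {}
    for sample_id, (f, n, r, s) in scheme.samples.items():
        if (n, s) in ns_map and ns_map[(n, s)] != sample_id:
            raise ValueError(
                f"(N, S) = {(n, s)} maps to multiple samples under this scheme; "
                "collapse to combinatorial indexing is ambiguous"
            )
        ns_map[(n, s)] = sample_id
    keys = list(zip(reads["n_idx"], reads["s_idx"]))
    assigned = pd.Series([ns_map.get(k) for k in keys], index=reads.index)
    kept = reads[assigned.notna()].copy()
    kept["sample_id"] = assigned[assigned.notna()]
    return umi_deduplicate(kept)


def coverage_class(table: BarcodeCountTable) -> pd.Series:
    """Per-sample coverage class from mean reads per barcode.

    low: < 20; moderate: 20–600 inclusive; high: > 600.
    """
    if table.df.empty:
        raise ValueError("empty count table")
    mean = table.mean_coverage()

    def _cls(x: float) -> str:
        if x < 20:
            return "low"
        if x <= 600:
            return "moderate"
        return "high"

    return mean.map(_cls).rename("coverage_class")
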