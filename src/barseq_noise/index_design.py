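"""Multiplexing index schemes for pooled amplicon sequencing.

Three ways of labeling samples on a shared sequencing lane are supported:

``combinatorial``
    Every (forward, reverse) index combination labels a sample.  Cheap in
    primers, but a single swapped index turns a read from one sample into a
    perfectly valid read of another sample, so misassignment is invisible.

``unique_dual``
    Each sample gets indices used by no other sample, so any single-index
    swap produces an invalid combination and can be discarded.  Costs two
    dedicated primers per sample.

``nested_unique_dual``
    Inline indices (read as part of the amplicon) are paired one-to-one
    with Illumina adapter indices on the same end of the molecule: every
    forward inline index F is used with exactly one i7 index N, and every
    reverse inline index R with exactly one i5 index S.  The F/N pairs are
    then combined combinatorially with the R/S pairs.  This detects the
    same swaps unique dual indexing does while the primer count grows with
    the *sum*, not the product, of the pool sizes.

Samples are identified by 4-tuples of opaque index identifiers
``(f_idx, n_idx, r_idx, s_idx)``; the oligo sequences themselves are not
modeled here.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "SCHEME_KINDS",
    "IndexScheme",
    "SchemeError",
    "build_scheme",
    "capacity",
    "primer_count",
    "validate_scheme",
    "read_sample_sheet",
    "write_sample_sheet",
]

SCHEME_KINDS = ("combinatorial", "unique_dual", "nested_unique_dual")

#: Column order of the sample-sheet CSV dialect.
SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "f_idx",
    "n_idx",
    "r_idx",
    "s_idx",
    "experiment_id",
    "timepoint",
    "replicate_id",
    "batch_id",
)


class SchemeError(ValueError):
    """Raised for invalid scheme construction requests or failed validation."""


@dataclass
class IndexScheme:
    """An index scheme: index pools plus the sample -> index-tuple map.

    Parameters
    ----------
    kind:
        One of :data:`SCHEME_KINDS`.
    inline_f, inline_r:
        Pools of inline (in-read) index identifiers, forward and reverse.
    illumina_n, illumina_s:
        Pools of Illumina adapter index identifiers (i7-like "N" and
        i5-like "S").
    samples:
        Mapping ``sample_id -> (f_idx, n_idx, r_idx, s_idx)``.
    f_pairing, r_pairing:
        For the nested kind, the enforced one-to-one pairings ``F -> N``
        and ``R -> S``.  Empty for other kinds.
    """

    kind: str
    inline_f: list[str]
    inline_r: list[str]
    illumina_n: list[str]
    illumina_s: list[str]
    samples: dict[str, tuple[str, str, str, str]] = field(default_factory=dict)
    f_pairing: dict[str, str] = field(default_factory=dict)
    r_pairing: dict[str, str] = field(default_factory=dict)

    # -- convenience views used heavily by the demultiplexer ------------

    @property
    def sample_tuples(self) -> dict[tuple[str, str, str, str], str]:
        """Reverse map: index tuple -> sample_id."""
        return {t: s for s, t in self.samples.items()}

    def left_halves(self) -> set[tuple[str, str]]:
        """All (F, N) halves that belong to some sample."""
        return {(f, n) for f, n, _, _ in self.samples.values()}

    def right_halves(self) -> set[tuple[str, str]]:
        """All (R, S) halves that belong to some sample."""
        return {(r, s) for _, _, r, s in self.samples.values()}

    def pools(self) -> tuple[set[str], set[str], set[str], set[str]]:
        return (
            set(self.inline_f),
            set(self.illumina_n),
            set(self.inline_r),
            set(self.illumina_s),
        )

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "inline_f": self.inline_f,
            "inline_r": self.inline_r,
            "illumina_n": self.illumina_n,
            "illumina_s": self.illumina_s,
            "samples": {s: list(t) for s, t in self.samples.items()},
            "f_pairing": self.f_pairing,
            "r_pairing": self.r_pairing,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "IndexScheme":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            inline_f=list(d["inline_f"]),
            inline_r=list(d["inline_r"]),
            illumina_n=list(d["illumina_n"]),
            illumina_s=list(d["illumina_s"]),
            samples={s: tuple(t) for s, t in d["samples"].items()},
            f_pairing=dict(d.get("f_pairing", {})),
            r_pairing=dict(d.get("r_pairing", {})),
        )


def capacity(kind: str, n_f: int, n_r: int) -> int:
    """Maximum number of samples a scheme of ``kind`` can label.

    ``n_f`` and ``n_r`` are the numbers of forward-side and reverse-side
    combinations available: inline/Illumina pair counts for the nested
    kind, index pool sizes for the combinatorial kind, and disjoint
    index-pair counts for unique dual indexing.
    """
    if n_f < 1 or n_r < 1:
        raise SchemeError("pool sizes must be >= 1")
    if kind in ("combinatorial", "nested_unique_dual"):
        return n_f * n_r
    if kind == "unique_dual":
        # each sample consumes one forward pair and one reverse pair
        return min(n_f, n_r)
    raise SchemeError(f"unknown scheme kind: {kind!r}")


def build_scheme(
    kind: str,
    n_samples: int,
    n_f_pairs: int | None = None,
    n_r_pairs: int | None = None,
) -> IndexScheme:
    """Construct a valid index scheme labeling ``n_samples`` samples.

    For the nested and combinatorial kinds, ``n_f_pairs`` x ``n_r_pairs``
    gives the capacity (defaults 12 x 8, the layout that labels 96 samples
    with 40 primers).  Samples are assigned tuples in F-major order, so
    requesting fewer samples than the capacity uses an initial prefix of
    the combinations.  For unique dual indexing each sample receives
    indices of its own on every position.
    """
    if kind not in SCHEME_KINDS:
        raise SchemeError(f"unknown scheme kind: {kind!r}")
    if n_samples < 1:
        raise SchemeError("n_samples must be >= 1")

    if kind == "unique_dual":
        names = [f"sample_{i + 1}" for i in range(n_samples)]
        scheme = IndexScheme(
            kind=kind,
            inline_f=[f"F{i + 1:03d}" for i in range(n_samples)],
            inline_r=[f"R{i + 1:03d}" for i in range(n_samples)],
            illumina_n=[f"N{i + 1:03d}" for i in range(n_samples)],
            illumina_s=[f"S{i + 1:03d}" for i in range(n_samples)],
        )
        for i, name in enumerate(names):
            scheme.samples[name] = (
                scheme.inline_f[i],
                scheme.illumina_n[i],
                scheme.inline_r[i],
                scheme.illumina_s[i],
            )
        validate_scheme(scheme)
        return scheme

    n_f = 12 if n_f_pairs is None else n_f_pairs
    n_r = 8 if n_r_pairs is None else n_r_pairs
    cap = capacity(kind, n_f, n_r)
    if cap < n_samples:
        raise SchemeError(
            f"{kind} scheme with {n_f} x {n_r} index pairs labels at most "
            f"{cap} samples; {n_samples} requested. Increase n_f_pairs or "
            "n_r_pairs."
        )

    inline_f = [f"F{i + 1:03d}" for i in range(n_f)]
    inline_r = [f"R{i + 1:03d}" for i in range(n_r)]
    illumina_n = [f"N{i + 1:03d}" for i in range(n_f)]
    illumina_s = [f"S{i + 1:03d}" for i in range(n_r)]
    scheme = IndexScheme(
        kind=kind,
        inline_f=inline_f,
        inline_r=inline_r,
        illumina_n=illumina_n,
        illumina_s=illumina_s,
    )
    if kind == "nested_unique_dual":
        scheme.f_pairing = dict(zip(inline_f, illumina_n))
        scheme.r_pairing = dict(zip(inline_r, illumina_s))

    k = 0
    for i in range(n_f):  # F-major assignment order
        for j in range(n_r):
            if k >= n_samples:
                break
            scheme.samples[f"sample_{k + 1}"] = (
                inline_f[i],
                illumina_n[i],
                inline_r[j],
                illumina_s[j],
            )
            k += 1
    validate_scheme(scheme)
    return scheme


def primer_count(scheme: IndexScheme) -> int:
    """Number of distinct physical primer oligos the scheme requires.

    One oligo per distinct index identifier per side; Illumina i7 and i5
    primers are counted individually.  Unique dual indexing therefore
    costs ``2 * n_samples`` while the nested scheme costs the sum of the
    four pool sizes.
    """
    if scheme.kind == "unique_dual":
        return 2 * len(scheme.samples)
    if scheme.kind == "nested_unique_dual":
        return (
            len(scheme.inline_f)
            + len(scheme.inline_r)
            + len(scheme.illumina_n)
            + len(scheme.illumina_s)
        )
    # combinatorial: count the distinct indices actually used
    used: set[tuple[str, str]] = set()
    for f, n, r, s in scheme.samples.values():
        used |= {("f", f), ("n", n), ("r", r), ("s", s)}
    return len(used)


def validate_scheme(scheme: IndexScheme) -> None:
    """Check the invariants of ``scheme.kind``; raise SchemeError on failure."""
    if scheme.kind not in SCHEME_KINDS:
        raise SchemeError(f"unknown scheme kind: {scheme.kind!r}")
    if not scheme.samples:
        raise SchemeError("scheme has no samples")

    pools = scheme.pools()
    tuples = list(scheme.samples.values())
    if len(set(tuples)) != len(tuples):
        raise SchemeError("sample index tuples are not distinct")
    for sample_id, t in scheme.samples.items():
        for idx, pool, side in zip(t, pools, ("F", "N", "R", "S")):
            if idx not in pool:
                raise SchemeError(
                    f"sample {sample_id}: {side} index {idx!r} not in the "
                    "declared pool"
                )

    if scheme.kind == "nested_unique_dual":
        f_seen: dict[str, str] = {}
        r_seen: dict[str, str] = {}
        n_owner: dict[str, str] = {}
        s_owner: dict[str, str] = {}
        for f, n, r, s in tuples:
            if f_seen.setdefault(f, n) != n or n_owner.setdefault(n, f) != f:
                raise SchemeError(
                    f"nested invariant violated: inline index {f} / Illumina "
                    f"index {n} are not exclusively paired"
                )
            if r_seen.setdefault(r, s) != s or s_owner.setdefault(s, r) != r:
                raise SchemeError(
                    f"nested invariant violated: inline index {r} / Illumina "
                    f"index {s} are not exclusively paired"
                )
        for f, n in scheme.f_pairing.items():
            if f in f_seen and f_seen[f] != n:
                raise SchemeError("declared F/N pairing contradicts samples")
        for r, s in scheme.r_pairing.items():
            if r in r_seen and r_seen[r] != s:
                raise SchemeError("declared R/S pairing contradicts samples")

    if scheme.kind == "unique_dual":
        seen: set[str] = set()
        for t in tuples:
            for idx in t:
                if idx in seen:
                    raise SchemeError(
                        f"unique_dual invariant violated: index {idx} reused"
                    )
                seen.add(idx)


# ---------------------------------------------------------------------------
# Sample sheet I/O
# ---------------------------------------------------------------------------


def write_sample_sheet(path, rows: Iterable[Mapping[str, object]]) -> None:
    """Write a sample sheet CSV (columns :data:`SAMPLE_SHEET_COLUMNS`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=SAMPLE_SHEET_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in SAMPLE_SHEET_COLUMNS})


def read_sample_sheet(path) -> list[dict[str, str]]:
    """Read a sample sheet CSV; requires the header of the dialect."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(SAMPLE_SHEET_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemeError(
                f"sample sheet missing required columns: {sorted(missing)}"
            )
        return [dict(row) for row in reader]
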