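"""File formats: paired FASTQ in the synthetic dialect, reads tables, metadata.

FASTQ dialect
-------------
R1 carries, at fixed offsets, the forward inline index pseudo-sequence,
the UMI, and the barcode; R2 carries the reverse inline index
pseudo-sequence.  The Illumina indices travel in the header comment in the
conventional ``1:N:0:<i7>+<i5>`` slot, as they are read in separate index
reads on a real instrument.  Index identifiers are mapped to deterministic
pseudo-sequences per scheme; quality strings are uniform placeholders
(base-call error models are out of scope).
"""

from __future__ import annotations

import gzip
import hashlib
import json
from typing import TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import READ_COLUMNS, TRUTH_COLUMNS, ReadSet

__all__ = [
    "scheme_sequences",
    "write_fastq_pair",
    "read_fastq_pair",
    "write_reads_tsv",
    "read_reads_tsv",
    "write_truth_tsv",
    "write_run_metadata",
    "config_hash",
]

INDEX_SEQ_LEN = 10
_QUAL = 40


def _pseudo_seq(identifier: str, salt: int = 0) -> str:
    digest = hashlib.sha256(f"{identifier}#{salt}".encode()).digest()
    return "".join("ACGT"[b % 4] for b in digest[:INDEX_SEQ_LEN])


def scheme_sequences(scheme) -> dict[str, dict[str, str]]:
    """Deterministic identifier -> pseudo-sequence maps, one per index side.

    Collisions within a pool are resolved by salted re-hashing, so the map
    is always invertible for a given scheme.
    """
    out: dict[str, dict[str, str]] = {}
    for side, pool in (
        ("f", scheme.inline_f),
        ("n", scheme.illumina_n),
        ("r", scheme.inline_r),
        ("s", scheme.illumina_s),
    ):
        seen: dict[str, str] = {}
        mapping: dict[str, str] = {}
        for ident in pool:
            salt = 0
            seq = _pseudo_seq(ident, salt)
            while seq in seen and seen[seq] != ident:
                salt += 1
                seq = _pseudo_seq(ident, salt)
            seen[seq] = ident
            mapping[ident] = seq
        out[side] = mapping
    return out


def _open_text(path, mode: str) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pair(readset: ReadSet, r1_path, r2_path) -> None:
    """Emit the read set as a gzipped paired FASTQ in the synthetic dialect."""
    seqs = scheme_sequences(readset.scheme)
    df = readset.df
    with _open_text(r1_path, "w") as h1, _open_text(r2_path, "w") as h2:
        recs1, recs2 = [], []
        for i, row in enumerate(df.itertuples(index=False)):
            comment = f"{i} 1:N:0:{seqs['n'][row.n_idx]}+{seqs['s'][row.s_idx]}"
            r1 = seqs["f"][row.f_idx] + row.umi + row.barcode_id
            r2 = seqs["r"][row.r_idx]
            rec1 = SeqRecord(Seq(r1), id=f"read_{i}", description=comment)
            rec2 = SeqRecord(Seq(r2), id=f"read_{i}", description=comment)
            rec1.letter_annotations["phred_quality"] = [_QUAL] * len(r1)
            rec2.letter_annotations["phred_quality"] = [_QUAL] * len(r2)
            recs1.append(rec1)
            recs2.append(rec2)
        SeqIO.write(recs1, h1, "fastq")
        SeqIO.write(recs2, h2, "fastq")


def read_fastq_pair(r1_path, r2_path, scheme, umi_length: int = 8) -> pd.DataFrame:
    """Parse the synthetic paired FASTQ dialect back into a reads table.

    Returns the analysis-facing columns only (no truth).  Index
    pseudo-sequences are decoded with the scheme's deterministic maps;
    reads with undecodable index sequences get the raw sequence as the
    identifier (they will classify as unmatched downstream).
    """
    seqs = scheme_sequences(scheme)
    decode = {side: {v: k for k, v in m.items()} for side, m in seqs.items()}
    rows = []
    with _open_text(r1_path, "r") as h1, _open_text(r2_path, "r") as h2:
        for rec1, rec2 in zip(SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq")):
            comment = rec1.description.split()[-1]
            n_seq, s_seq = comment.split(":")[-1].split("+")
            s1 = str(rec1.seq)
            f_seq = s1[:INDEX_SEQ_LEN]
            umi = s1[INDEX_SEQ_LEN : INDEX_SEQ_LEN + umi_length]
            barcode = s1[INDEX_SEQ_LEN + umi_length :]
            r_seq = str(rec2.seq)[:INDEX_SEQ_LEN]
            rows.append(
                {
                    "f_idx": decode["f"].get(f_seq, f_seq),
                    "n_idx": decode["n"].get(n_seq, n_seq),
                    "r_idx": decode["r"].get(r_seq, r_seq),
                    "s_idx": decode["s"].get(s_seq, s_seq),
                    "barcode_id": barcode,
                    "umi": umi,
                }
            )
    return pd.DataFrame(rows, columns=list(READ_COLUMNS))


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    """Plain TSV reads table (f_idx, n_idx, r_idx, s_idx, barcode_id, umi)."""
    reads[list(READ_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads table missing columns: {sorted(missing)}")
    return df[list(READ_COLUMNS)]


def write_truth_tsv(readset: ReadSet, path) -> None:
    """Truth sidecar: simulation labels, kept separate from analysis inputs."""
    readset.df[list(TRUTH_COLUMNS)].to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_run_metadata(path, config: dict, seed: int, extra: dict | None = None) -> None:
    payload = {"seed": seed, "config_hash": config_hash(config), "config": config}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
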