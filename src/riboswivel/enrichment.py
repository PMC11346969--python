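"""Sequencing-enrichment analysis for in-vitro selection (RISE) libraries.

Variable regions are extracted from reads by exact-match search for the
fixed up- and downstream flanks (each of length N+2 for an N-nt variable
region, no mismatches allowed); any base with a phred score below 30
(error probability above 0.001) in the extracted span rejects the read.
Per-pool variant abundance is count / total accepted; enrichment is
output abundance over input abundance, and winners are ranked by
enrichment (ties broken by output abundance, then sequence).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd

__all__ = [
    "ReadRecord",
    "ExtractionSpec",
    "read_fastq",
    "extract_variable_region",
    "extract_pool",
    "count_variants",
    "compute_enrichment",
    "enrichment_from_fastq",
]

REJECTION_REASONS = ("no_flank", "low_quality", "bad_length")


@dataclass
class ReadRecord:
    id: str
    sequence: str
    phred: np.ndarray

    def __post_init__(self):
        self.phred = np.asarray(self.phred, dtype=int)
        if len(self.sequence) != len(self.phred):
            raise ValueError(f"read {self.id}: sequence and quality lengths differ")


@dataclass
class ExtractionSpec:
    """Flanks bracketing the variable region (exact match only)."""

    upstream: str
    downstream: str
    n: int

    def __post_init__(self):
        if not self.upstream or not self.downstream:
            raise ValueError("flank sequences must be non-empty")
        if self.n < 1:
            raise ValueError("variable-region length must be >= 1")


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path) -> list[ReadRecord]:
    """Read a (possibly gzipped) FASTQ file; phred offset 33."""
    from Bio import SeqIO

    out = []
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            out.append(ReadRecord(rec.id, str(rec.seq),
                                  np.array(rec.letter_annotations["phred_quality"])))
    return out


def extract_variable_region(
    read: ReadRecord,
    spec: ExtractionSpec,
    min_phred: int = 30,
    quality_scope: str = "region",
) -> tuple[str | None, str]:
    """Extract the variable region of one read, or a rejection reason.

    Returns ``(variant, "accepted")`` or ``(None, reason)`` with reason
    one of ``no_flank``, ``low_quality``, ``bad_length``.  The phred
    filter covers the flanks plus the variable region
    (``quality_scope="region"``, default) or the whole read
    (``quality_scope="read"``).  N bases carry phred 0 and are always
    rejected inside the filtered span.
    """
    seq = read.sequence
    up = seq.find(spec.upstream)
    if up < 0:
        return None, "no_flank"
    start = up + len(spec.upstream)
    down = seq.find(spec.downstream, start)
    if down < 0:
        return None, "no_flank"
    phred = read.phred.copy()
    if "N" in seq:
        phred[np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")] = 0
    if quality_scope == "read":
        lo, hi = 0, len(seq)
    else:
        lo, hi = up, down + len(spec.downstream)
    if np.any(phred[lo:hi] < min_phred):
        return None, "low_quality"
    variant = seq[start:down]
    if len(variant) != spec.n:
        return None, "bad_length"
    return variant, "accepted"


def extract_pool(
    reads: list[ReadRecord],
    spec: ExtractionSpec,
    min_phred: int = 30,
    quality_scope: str = "region",
) -> tuple[list[str], Counter]:
    """Extract all reads of a pool; returns (accepted variants, reason tally).

    The tally includes "accepted", and the reasons partition the pool:
    accepted + no_flank + low_quality + bad_length == len(reads).
    """
    accepted: list[str] = []
    tally: Counter = Counter({r: 0 for r in ("accepted",) + REJECTION_REASONS})
    for read in reads:
        variant, reason = extract_variable_region(read, spec, min_phred, quality_scope)
        tally[reason] += 1
        if variant is not None:
            accepted.append(variant)
    return accepted, tally


def count_variants(sequences: list[str]) -> pd.DataFrame:
    """Counts and abundances per distinct sequence for one pool."""
    if not sequences:
        raise ValueError("no accepted sequences in the pool")
    counts = Counter(sequences)
    total = sum(counts.values())
    df = pd.DataFrame(
        {"sequence": list(counts), "count": list(counts.values())}
    ).sort_values("sequence", ignore_index=True)
    df["abundance"] = df["count"] / total
    return df


def compute_enrichment(input_table: pd.DataFrame, output_table: pd.DataFrame) -> pd.DataFrame:
    """Per-variant enrichment (output abundance / input abundance) with ranks.

    Variants absent from the input pool get undefined (NaN) enrichment
    and are flagged; ranking is by enrichment descending, ties broken by
    output abundance, then lexicographically.
    """
    if input_table.empty or output_table.empty:
        raise ValueError("both pools must be non-empty")
    merged = pd.merge(
        input_table.rename(columns={"count": "input_count", "abundance": "input_abundance"}),
        output_table.rename(columns={"count": "output_count", "abundance": "output_abundance"}),
        on="sequence", how="outer",
    )
    for col in ("input_count", "output_count"):
        merged[col] = merged[col].fillna(0).astype(int)
    for col in ("input_abundance", "output_abundance"):
        merged[col] = merged[col].fillna(0.0)
    merged["absent_from_input"] = merged["input_count"] == 0
    merged["enrichment"] = np.where(
        merged["input_count"] > 0,
        merged["output_abundance"] / merged["input_abundance"].replace(0.0, np.nan),
        np.nan,
    )
    merged = merged.sort_values(
        by=["enrichment", "output_abundance", "sequence"],
        ascending=[False, False, True],
        na_position="last",
        ignore_index=True,
    )
    merged["rank"] = np.arange(1, len(merged) + 1)
    return merged


def enrichment_from_fastq(
    input_path,
    output_path,
    spec: ExtractionSpec,
    min_phred: int = 30,
    quality_scope: str = "region",
):
    """Full pipeline: FASTQ pools -> ranked enrichment table + tallies."""
    in_var, in_tally = extract_pool(read_fastq(input_path), spec, min_phred, quality_scope)
    out_var, out_tally = extract_pool(read_fastq(output_path), spec, min_phred, quality_scope)
    table = compute_enrichment(count_variants(in_var), count_variants(out_var))
    return table, {"input": in_tally, "output": out_tally}
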