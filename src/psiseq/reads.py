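"""FASTQ preprocessing: adapter trimming, 4N stripping, filtering, collapsing.

Small RNA reads are sequenced through the insert into the 3' adapter, so
trimming removes the longest read suffix that matches a prefix of the
adapter (one mismatch tolerated for overlaps of at least ten bases).
NextFlex libraries additionally carry four random nucleotides on both ends
of the insert, stripped after adapter removal. Filtering applies a length
window and, where configured, a quality rule retaining reads with at least
a given fraction of bases at or above a Phred threshold (the mouse preset
uses Q20 over 90% of the read, 14-44 nt). Collapsing replaces the read
stream with unique sequences and their multiplicities.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simdata import NEB_ADAPTER3

# length windows per analysis arm
LENGTH_PRESETS: dict[str, tuple[int, int]] = {
    "rrna": (15, 30),
    "te": (18, 30),
    "mirna": (20, 25),
    "mn2": (18, 42),
    "mouse": (14, 44),
}

MIN_OVERLAP = 6          # shortest adapter prefix accepted at the read end
MISMATCH_MIN_OVERLAP = 10  # one mismatch allowed only at/above this overlap


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int
    sample: str = ""


@dataclass
class FilterPolicy:
    """Trimming and filtering parameters for one library dialect/preset."""

    adapter3: str = NEB_ADAPTER3
    dialect: str = "NEB"  # NEB | NextFlex
    min_len: int = 14
    max_len: int = 44
    min_q: int | None = None  # None disables the quality rule
    q_frac: float = 0.9
    drop_unmatched: bool = False

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if not 0.0 <= self.q_frac <= 1.0:
            raise ValueError("q_frac outside [0, 1]")

    @classmethod
    def preset(cls, name: str, **kw) -> "FilterPolicy":
        lo, hi = LENGTH_PRESETS[name]
        if name == "mouse":
            kw.setdefault("min_q", 20)
        return cls(min_len=lo, max_len=hi, **kw)


def find_adapter(seq: str, adapter: str) -> int:
    """Start of the adapter match in ``seq`` or -1 if none.

    The match is the longest suffix of the read equal to a prefix of the
    adapter: a full internal occurrence, or a terminal overlap of at least
    MIN_OVERLAP bases (<=1 mismatch once the overlap reaches
    MISMATCH_MIN_OVERLAP). The leftmost (longest) match wins.
    """
    # fast path: exact occurrence of the adapter head
    head = adapter[: min(12, len(adapter))]
    i = seq.find(head)
    if i >= 0:
        return i
    L = len(seq)
    for i in range(max(0, L - len(adapter)), L - MIN_OVERLAP + 1):
        overlap = min(len(adapter), L - i)
        budget = 1 if overlap >= MISMATCH_MIN_OVERLAP else 0
        mm = 0
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mm += 1
                if mm > budget:
                    break
        else:
            return i
    return -1


def trim_adapter(seq: str, qual: str | None, policy: FilterPolicy
                 ) -> tuple[str, str | None] | None:
    """Remove the 3' adapter (and NextFlex 4N ends); None means discard."""
    i = find_adapter(seq, policy.adapter3)
    if i < 0:
        if policy.drop_unmatched:
            return None
    else:
        seq = seq[:i]
        qual = qual[:i] if qual is not None else None
    if policy.dialect == "NextFlex":
        if len(seq) <= 8:
            return None
        seq = seq[4:-4]
        qual = qual[4:-4] if qual is not None else None
    if not seq:
        return None
    return seq, qual


def passes_quality(qual: str, min_q: int, q_frac: float) -> bool:
    thr = chr(min_q + 33)
    good = sum(1 for c in qual if c >= thr)
    return good >= q_frac * len(qual)


def filter_read(seq: str, qual: str | None, policy: FilterPolicy) -> str | None:
    """Reason the read fails the filter, or None if it is kept."""
    if not policy.min_len <= len(seq) <= policy.max_len:
        return "length"
    if policy.min_q is not None and qual is not None:
        if not passes_quality(qual, policy.min_q, policy.q_frac):
            return "quality"
    return None


def collapse(seqs) -> list[CollapsedRead]:
    """One record per distinct sequence; total counts are conserved."""
    c = Counter(seqs)
    return [CollapsedRead(s, n) for s, n in sorted(c.items())]


def _open(path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def preprocess_fastq(path, policy: FilterPolicy) -> tuple[Counter, dict[str, int]]:
    """Stream one FASTQ through trim -> filter -> collapse.

    Returns the sequence Counter and per-reason discard statistics; kept +
    discarded always equals the input read count.
    """
    counts: Counter = Counter()
    stats = {"input": 0, "kept": 0, "adapter_discard": 0,
             "length": 0, "quality": 0}
    with _open(path) as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            stats["input"] += 1
            trimmed = trim_adapter(seq, qual, policy)
            if trimmed is None:
                stats["adapter_discard"] += 1
                continue
            tseq, tqual = trimmed
            reason = filter_read(tseq, tqual, policy)
            if reason is not None:
                stats[reason] += 1
                continue
            counts[tseq] += 1
            stats["kept"] += 1
    return counts, stats


def write_collapsed_fasta(counts: Counter, path) -> Path:
    """Collapsed FASTA with ``>seq{i}_x{count}`` headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))):
            fh.write(f">seq{i}_x{n}\n{seq}\n")
    return path


def counts_table(samples: dict[str, Counter]) -> pd.DataFrame:
    """Sequence x sample count matrix from per-sample collapsed counters."""
    df = pd.DataFrame(samples).fillna(0).astype(int)
    df.index.name = "sequence"
    return df.sort_index()
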