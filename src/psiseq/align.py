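"""Loci-scale read placement with mismatch and deletion tolerance.

References here are individual small RNA loci (tRNAs, rRNA, miRNA
precursors, TE arrays), not genomes, so an exact k-mer index plus a banded
verification is sufficient and exhaustively correct: provided the seed
length k is at most (L - max_mismatch) / (max_mismatch + max_deletion + 1)
for a read of length L, the pigeonhole principle guarantees that every
valid placement contains an exact k-mer, so the indexed search returns the
same placements as a brute-force scan (``brute_force_map`` is kept as the
test oracle).

Deletions consume reference bases only; they are what the CMC/Mn²⁺
chemistry produces at Ψ, together with substitutions. Insertions are not
modeled. Leading and trailing deletions are canonicalised away (a deletion
before the first or after the last read base is indistinguishable from a
shifted or shorter placement).

Internally all coordinates are 0-based half-open; SAM output is 1-based
per the standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .simdata import ReferenceSet, revcomp


@dataclass(frozen=True)
class EditOp:
    """A substitution or reference deletion at one reference position."""

    ref_pos: int
    kind: str  # "mismatch" | "deletion"
    read_base: str | None  # None for deletions


@dataclass
class AlignmentRecord:
    seq: str
    ref: str
    start: int
    strand: str  # "+" | "-"
    ops: tuple[EditOp, ...] = ()
    n_hits: int = 1

    @property
    def n_mismatch(self) -> int:
        return sum(1 for o in self.ops if o.kind == "mismatch")

    @property
    def n_deletion(self) -> int:
        return sum(1 for o in self.ops if o.kind == "deletion")

    @property
    def end(self) -> int:
        """Reference end (half-open); deletions consume reference."""
        return self.start + len(self.seq) + self.n_deletion

    def aligned_seq(self) -> str:
        """Read sequence in reference orientation."""
        return self.seq if self.strand == "+" else revcomp(self.seq)


@dataclass
class MapPolicy:
    max_mismatch: int = 1
    max_deletion: int = 0
    multimap: str = "all"  # all | unique_only | best_random
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatch <= 3:
            raise ValueError("max_mismatch must be within 0-3")
        if not 0 <= self.max_deletion <= 2:
            raise ValueError("max_deletion must be within 0-2")
        if self.multimap not in ("all", "unique_only", "best_random"):
            raise ValueError(f"unknown multimap policy {self.multimap!r}")


class KmerIndex:
    """Exact k-mer -> (ref, pos) map over the forward strand of every ref."""

    def __init__(self, sequences: dict[str, str], k: int):
        if k <= 0:
            raise ValueError("k must be positive")
        self.k = k
        self.sequences = dict(sequences)
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[i : i + k], []).append((name, i))

    @classmethod
    def from_reference(cls, ref: ReferenceSet, k: int = 10) -> "KmerIndex":
        return cls(ref.sequences, k)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.kmers.get(kmer, [])


def _verify(read: str, ref_seq: str, start: int, max_mm: int, max_del: int
            ) -> tuple[int, int, tuple[EditOp, ...]] | None:
    """Align ``read`` to the reference at ``start``; read fully consumed,
    substitutions and reference deletions only. Returns (mm, dels, ops) of
    the edit-minimal alignment, or None if no alignment fits the policy.
    """
    L = len(read)
    if start < 0 or start + L > len(ref_seq):
        return None
    # DP over (read position i, deletions used d): minimal mismatch count
    INF = 99
    mm = [[INF] * (max_del + 1) for _ in range(L + 1)]
    mm[0][0] = 0
    for i in range(L + 1):
        for d in range(max_del + 1):
            cur = mm[i][d]
            if cur == INF:
                continue
            if i < L:
                j = start + i + d
                if j < len(ref_seq):
                    cost = cur + (read[i] != ref_seq[j])
                    if cost < mm[i + 1][d]:
                        mm[i + 1][d] = cost
            # deletion of reference base (never leading or trailing)
            if 0 < i < L and d < max_del:
                if start + i + d < len(ref_seq) and cur + 0 < INF:
                    if cur < mm[i][d + 1]:
                        mm[i][d + 1] = cur
    best = None
    for d in range(max_del + 1):
        if start + L + d > len(ref_seq):
            continue
        if mm[L][d] <= max_mm:
            edits = mm[L][d] + d
            if best is None or edits < best[0]:
                best = (edits, mm[L][d], d)
    if best is None:
        return None
    _, bmm, bdel = best
    # traceback: walk forward greedily re-deriving the optimal path
    ops: list[EditOp] = []
    i, d = L, bdel
    path: list[tuple[str, int, int]] = []
    while i > 0 or d > 0:
        if d > 0 and 0 < i and mm[i][d - 1] == mm[i][d]:
            d -= 1
            path.append(("D", i, d))
        else:
            j = start + i - 1 + d
            cost = read[i - 1] != ref_seq[j]
            if mm[i - 1][d] + cost == mm[i][d]:
                i -= 1
                path.append(("M", i, d))
            else:  # pragma: no cover - DP invariant
                raise AssertionError("traceback failed")
    for kind, i, d in reversed(path):
        j = start + i + d
        if kind == "D":
            ops.append(EditOp(j, "deletion", None))
        elif read[i] != ref_seq[j]:
            ops.append(EditOp(j, "mismatch", read[i]))
    ops.sort(key=lambda o: (o.ref_pos, o.kind))
    return bmm, bdel, tuple(ops)


def _search_strand(read: str, index: KmerIndex, policy: MapPolicy,
                   orig_seq: str, strand: str) -> list[AlignmentRecord]:
    k = index.k
    L = len(read)
    if L < k:
        return []
    candidates: set[tuple[str, int]] = set()
    for off in range(L - k + 1):
        for ref_name, pos in index.lookup(read[off : off + k]):
            for delta in range(policy.max_deletion + 1):
                candidates.add((ref_name, pos - off - delta))
    hits = []
    for ref_name, start in sorted(candidates):
        res = _verify(read, index.sequences[ref_name], start,
                      policy.max_mismatch, policy.max_deletion)
        if res is not None:
            mmn, deln, ops = res
            hits.append(AlignmentRecord(orig_seq, ref_name, start, strand, ops))
    return hits


def map_read(seq: str, index: KmerIndex, policy: MapPolicy,
             rng: np.random.Generator | None = None) -> list[AlignmentRecord]:
    """All placements within policy, minimal edit count first.

    ``n_hits`` on every returned record is the number of placements tied at
    the minimal edit count; the multimap policy is applied to that tier
    (``unique_only`` discards ambiguous reads, ``best_random`` draws one
    placement with the supplied RNG).
    """
    hits = _search_strand(seq, index, policy, seq, "+")
    if policy.both_strands:
        hits += _search_strand(revcomp(seq), index, policy, seq, "-")
    if not hits:
        return []
    hits.sort(key=lambda h: (len(h.ops), h.ref, h.start, h.strand))
    best_edits = len(hits[0].ops)
    n_best = sum(1 for h in hits if len(h.ops) == best_edits)
    for h in hits:
        h.n_hits = n_best
    if policy.multimap == "unique_only":
        return [] if n_best > 1 else hits[:1]
    if policy.multimap == "best_random":
        if rng is None:
            rng = np.random.default_rng(0)
        return [hits[int(rng.integers(n_best))]]
    return hits


def map_reads(seqs, index: KmerIndex, policy: MapPolicy,
              rng: np.random.Generator | None = None
              ) -> dict[str, list[AlignmentRecord]]:
    """Map many (collapsed) sequences; unmapped sequences are absent."""
    out: dict[str, list[AlignmentRecord]] = {}
    for s in seqs:
        recs = map_read(s, index, policy, rng)
        if recs:
            out[s] = recs
    return out


def brute_force_map(seq: str, sequences: dict[str, str], policy: MapPolicy
                    ) -> list[AlignmentRecord]:
    """Exhaustive O(n*m) scan; the independent oracle for ``map_read``."""
    hits = []
    for strand in ("+", "-") if policy.both_strands else ("+",):
        read = seq if strand == "+" else revcomp(seq)
        for ref_name, ref_seq in sequences.items():
            for start in range(len(ref_seq) - len(read) + 1):
                res = _verify(read, ref_seq, start,
                              policy.max_mismatch, policy.max_deletion)
                if res is not None:
                    hits.append(AlignmentRecord(seq, ref_name, start, strand, res[2]))
    hits.sort(key=lambda h: (len(h.ops), h.ref, h.start, h.strand))
    if hits:
        best = len(hits[0].ops)
        n_best = sum(1 for h in hits if len(h.ops) == best)
        for h in hits:
            h.n_hits = n_best
    return hits


# ---------------------------------------------------------------------------
# SAM round trip
# ---------------------------------------------------------------------------


def _cigar(rec: AlignmentRecord) -> list[tuple[int, int]]:
    """CIGAR as pysam (op, length) tuples; 0=M, 2=D."""
    dels = sorted(o.ref_pos for o in rec.ops if o.kind == "deletion")
    cig: list[tuple[int, int]] = []
    ref_cursor = rec.start
    read_left = len(rec.seq)
    for dpos in dels:
        m = dpos - ref_cursor
        if m > 0:
            cig.append((0, m))
            read_left -= m
        if cig and cig[-1][0] == 2:
            cig[-1] = (2, cig[-1][1] + 1)
        else:
            cig.append((2, 1))
        ref_cursor = dpos + 1
    if read_left > 0:
        cig.append((0, read_left))
    return cig


def write_sam(records, sequences: dict[str, str], path) -> None:
    names = list(sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(sequences[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, rec in enumerate(records):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.query_sequence = rec.aligned_seq()
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = names.index(rec.ref)
            a.reference_start = rec.start
            a.mapping_quality = 255
            a.cigar = _cigar(rec)
            a.set_tag("NM", len(rec.ops))
            out.write(a)


def read_sam(path, sequences: dict[str, str]) -> list[AlignmentRecord]:
    """Ingest externally produced SAM; edit ops are rebuilt from CIGAR plus
    a comparison against the supplied reference sequences."""
    records = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            ref_seq = sequences[a.reference_name]
            ops: list[EditOp] = []
            read = a.query_sequence
            i = 0
            j = a.reference_start
            for op, ln in a.cigartuples:
                if op == 0:  # M
                    for t in range(ln):
                        if read[i + t] != ref_seq[j + t]:
                            ops.append(EditOp(j + t, "mismatch", read[i + t]))
                    i += ln
                    j += ln
                elif op == 2:  # D
                    for t in range(ln):
                        ops.append(EditOp(j + t, "deletion", None))
                    j += ln
                else:
                    raise ValueError(f"unsupported CIGAR op {op}")
            strand = "-" if a.is_reverse else "+"
            seq = read if strand == "+" else revcomp(read)
            records.append(AlignmentRecord(seq, a.reference_name,
                                           a.reference_start, strand,
                                           tuple(ops)))
    return records
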