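"""Feature-level classification and aggregation of small RNA reads.

tRNA fragments (tRFs) are classified by how they anchor on the parent
tRNA: a fragment starting at position 1 is a 5'-tRF, one ending at the 3'
terminus (the post-transcriptional CCA tail) is a 3'-tRF, anything else is
internal. On a standard 76-nt tRNA the T-loop pseudouridine Ψ-55 sits 22
nt upstream of the 3' end, so a 3'-CCA tRF covers Ψ-55 exactly when it is
at least 22 nt long; ``spans_psi55`` is nevertheless computed from the
alignment span, never from the length shortcut, and the equivalence of
the two is a tested invariant.

TE-derived siRNAs are aggregated per family in two size classes (20-22
and 23-25 nt); a read hitting several copies of one family counts once
for that family (a 1/n fractional mode across families is available).
piRNA-sized reads are partitioned, in priority order, into transposon /
structural RNA / neither, and intersected with piRNA cluster intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import AlignmentRecord
from .simdata import Feature, find_unuar

SIZE_CLASSES = {"20-22": (20, 22), "23-25": (23, 25)}
PIRNA_SIZE_WINDOW = (26, 32)
STRUCTURAL_CLASSES = ("tRNA", "snoRNA", "snRNA", "rRNA")


@dataclass(frozen=True)
class TRFRecord:
    sequence: str
    parent: str
    isotype: str
    cls: str  # five_prime | three_prime | internal
    has_cca: bool
    spans_psi55: bool
    has_unuar: bool
    length: int


def classify_trf(alignment: AlignmentRecord, trna: Feature,
                 psi55_pos: int | None = None) -> TRFRecord:
    """Classify one tRF from its placement on the parent tRNA.

    ``psi55_pos`` is the 0-based index of the canonical position-55
    uridine on this tRNA (defaults to 54 for the 76-nt standard model);
    ``spans_psi55`` is true when the alignment span covers it.
    """
    if trna.cls != "tRNA":
        raise ValueError(f"feature {trna.name} is not a tRNA")
    if psi55_pos is None:
        psi55_pos = trna.start + 54
    start, end = alignment.start, alignment.end
    if start == trna.start:
        cls = "five_prime"
    elif end == trna.end:
        cls = "three_prime"
    else:
        cls = "internal"
    seq = alignment.aligned_seq()
    has_cca = cls == "three_prime" and seq.endswith("CCA")
    isotype = trna.name.split("-", 1)[1] if "-" in trna.name else trna.name
    return TRFRecord(
        sequence=alignment.seq,
        parent=trna.name,
        isotype=isotype,
        cls=cls,
        has_cca=has_cca,
        spans_psi55=start <= psi55_pos < end,
        has_unuar=bool(find_unuar(seq)),
        length=len(alignment.seq),
    )


def minimal_psi55_trf_length(index, policy, trna: Feature, trna_seq: str,
                             lengths=range(18, 31)) -> int:
    """Shortest 3'-CCA tRF whose *alignment* covers position 55.

    Each candidate suffix is actually mapped and classified; the result is
    derived from the alignment span, not from arithmetic on the lengths.
    """
    from .align import map_read

    spanning = []
    for L in lengths:
        read = trna_seq[-L:]
        for rec in map_read(read, index, policy):
            if rec.ref == trna.ref:
                trf = classify_trf(rec, trna)
                if trf.cls == "three_prime" and trf.spans_psi55:
                    spanning.append(L)
                break
    if not spanning:
        raise ValueError("no 3'-tRF covers position 55 in the given range")
    return min(spanning)


def _size_class(length: int) -> str | None:
    for name, (lo, hi) in SIZE_CLASSES.items():
        if lo <= length <= hi:
            return name
    return None


def aggregate_te_families(alignments, te_features: list[Feature],
                          fractional: bool = False) -> pd.DataFrame:
    """TE family x size class count table.

    ``alignments`` yields (sequence, records, count) triples, one per
    collapsed read, where ``records`` are that read's placements. A read
    overlapping several copies of one family counts once per family; with
    ``fractional=True`` a read hitting n distinct families contributes 1/n
    to each instead of 1.
    """
    trees: dict[str, IntervalTree] = {}
    for f in te_features:
        trees.setdefault(f.ref, IntervalTree()).addi(f.start, f.end, f.family)
    table: dict[tuple[str, str], float] = {}
    for seq, records, count in alignments:
        sc = _size_class(len(seq))
        if sc is None:
            continue
        fams = set()
        for rec in records:
            tree = trees.get(rec.ref)
            if tree is None:
                continue
            for iv in tree.overlap(rec.start, rec.end):
                fams.add(iv.data)
        w = count / len(fams) if (fractional and fams) else count
        for fam in fams:
            table[(fam, sc)] = table.get((fam, sc), 0.0) + w
    rows = [(fam, sc, n) for (fam, sc), n in sorted(table.items())]
    return pd.DataFrame(rows, columns=["family", "size_class", "count"])


def family_log2fc(treated: pd.DataFrame, control: pd.DataFrame,
                  pseudocount: float = 0.5) -> pd.DataFrame:
    """Paired log2 fold change on family x size-class aggregates."""
    key = ["family", "size_class"]
    merged = treated.merge(control, on=key, how="outer",
                           suffixes=("_t", "_c")).fillna(0.0)
    merged["log2fc"] = np.log2((merged["count_t"] + pseudocount)
                               / (merged["count_c"] + pseudocount))
    return merged[key + ["count_t", "count_c", "log2fc"]]


def ago_preference(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Preferred AGO per (family, size class) by argmax IP/input enrichment.

    ``enrichment`` has columns family, size_class, ago, enrichment. Ties
    are broken lexicographically by AGO name and flagged; a group with a
    single AGO is flagged 'uncontested'; all-missing groups yield 'none'.
    """
    rows = []
    for (fam, sc), grp in enrichment.groupby(["family", "size_class"]):
        grp = grp.dropna(subset=["enrichment"])
        if grp.empty:
            rows.append((fam, sc, "none", np.nan, "missing"))
            continue
        best = grp["enrichment"].max()
        winners = sorted(grp.loc[grp["enrichment"] == best, "ago"])
        flag = "tie" if len(winners) > 1 else (
            "uncontested" if grp["ago"].nunique() == 1 else "")
        rows.append((fam, sc, winners[0], best, flag))
    return pd.DataFrame(rows, columns=["family", "size_class", "ago",
                                       "enrichment", "flag"])


def categorize_repeats(alignments, repeat_features: list[Feature],
                       structural_features: list[Feature],
                       clusters: list[Feature]) -> pd.DataFrame:
    """Partition non-tRF reads into transposon / structural / neither.

    The priority order is fixed: a read overlapping both a repeat and a
    structural RNA is a transposon read. Cluster membership requires at
    least 1 bp of overlap with a piRNA cluster interval.
    """
    def build(feats):
        trees: dict[str, IntervalTree] = {}
        for f in feats:
            trees.setdefault(f.ref, IntervalTree()).addi(f.start, f.end, f.name)
        return trees

    rep = build(repeat_features)
    struct = build(structural_features)
    clu = build(clusters)
    rows = []
    for seq, records, count in alignments:
        cat = "neither"
        cluster = "none"
        for rec in records:
            if rec.ref in rep and rep[rec.ref].overlap(rec.start, rec.end):
                cat = "transposon"
                break
        if cat == "neither":
            for rec in records:
                if rec.ref in struct and struct[rec.ref].overlap(rec.start, rec.end):
                    cat = "structural"
                    break
        for rec in records:
            if rec.ref in clu:
                hits = clu[rec.ref].overlap(rec.start, rec.end)
                if hits:
                    cluster = sorted(iv.data for iv in hits)[0]
                    break
        rows.append((seq, count, cat, cluster))
    return pd.DataFrame(rows, columns=["sequence", "count", "category",
                                       "cluster"])


def terminal_nt_bias(sequences: list[str], background: list[str],
                     structural: set[str] | None = None,
                     pseudocount: float = 0.01) -> pd.DataFrame:
    """5'/3' terminal base composition of a set against a background.

    Both sets must already exclude structural-RNA-derived sequences; if a
    ``structural`` set is supplied, any overlap raises. Frequencies are
    reported in RNA space (U for T) with log2 enrichment per base.
    """
    if not sequences or not background:
        raise ValueError("empty sequence set")
    if structural:
        bad = (set(sequences) | set(background)) & structural
        if bad:
            raise ValueError(
                f"{len(bad)} structural-RNA sequences present; filter first")

    def freqs(seqs, pos):
        c = pd.Series([s[pos] for s in seqs]).value_counts(normalize=True)
        return {b: float(c.get(b, 0.0)) for b in "ACGT"}

    rows = []
    for end, pos in (("5p", 0), ("3p", -1)):
        fa = freqs(sequences, pos)
        fb = freqs(background, pos)
        for base in "ACGT":
            shown = "U" if base == "T" else base
            with np.errstate(divide="ignore"):
                enr = float(np.log2(np.float64(fa[base] + pseudocount)
                                    / np.float64(fb[base] + pseudocount)))
            rows.append((end, shown, fa[base], fb[base], enr))
    return pd.DataFrame(rows, columns=["end", "base", "freq", "freq_background",
                                       "log2_enrichment"])


def size_distribution(lengths) -> tuple[pd.Series, int | None, bool]:
    """Integer length histogram, its mode, and a tie flag.

    Ties resolve to the smallest length and are flagged; an empty subset
    yields an empty histogram and no mode.
    """
    lengths = list(lengths)
    if not lengths:
        return pd.Series(dtype=int), None, False
    hist = pd.Series(lengths).value_counts().sort_index()
    top = hist.max()
    modes = hist.index[hist == top]
    return hist, int(modes.min()), len(modes) > 1
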