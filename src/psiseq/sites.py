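"""Position-level Ψ evidence: coverage tracks, metaplots, mismatch calling.

Two kinds of positional evidence are computed. For the IP and CMC RT-stop
arms, per-base coverage is normalized to the total coverage across the
locus and paired log2 fold-change tracks (treated/control) are averaged
around known Ψ sites in a metaplot; depletion (CMC) or enrichment (IP)
centred at offset 0 indicates Ψ. For the CMC/Mn²⁺ arm, a pileup of
mismatches and deletions per reference position feeds the site caller:
a position is called when the treated library has at least ``min_reads``
covering reads and the combined mismatch+deletion ratio is at least
``min_fc``-fold higher than in the mock library (defaults 5 reads and
1.5-fold). The mock ratio carries a (mm+0.5)/(total+1) pseudocount so a
clean mock never divides by zero.

Alignment input is weighted: each record is paired with its collapsed
read count so pileups over unique sequences reproduce per-read pileups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .simdata import Feature


@dataclass
class CoverageTrack:
    ref: str
    depth: np.ndarray
    sample: str = ""
    normalized: bool = False


@dataclass
class MismatchProfile:
    ref: str
    total: np.ndarray
    mismatch: np.ndarray
    deletion: np.ndarray
    sample: str = ""


@dataclass(frozen=True)
class PsiCall:
    ref: str
    pos: int
    evidence: str  # coverage_depletion | ip_enrichment | mismatch
    statistic: float
    passed: bool


def _weighted(alignments) -> list[tuple[AlignmentRecord, float]]:
    out = []
    for item in alignments:
        if isinstance(item, tuple):
            out.append(item)
        else:
            out.append((item, 1.0))
    return out


def locus_coverage(alignments, ref: str, ref_len: int,
                   normalize: bool = False, sample: str = "") -> CoverageTrack:
    """Per-base depth on one reference; optionally normalized to sum 1.

    ``alignments`` is an iterable of AlignmentRecord or (record, weight)
    pairs; weights carry collapsed-read counts. Deleted reference bases
    remain covered by the read span.
    """
    import warnings

    depth = np.zeros(ref_len + 1)
    for rec, w in _weighted(alignments):
        if rec.ref != ref:
            continue
        depth[rec.start] += w
        depth[min(rec.end, ref_len)] -= w
    depth = np.cumsum(depth[:-1])
    if normalize:
        tot = depth.sum()
        if tot == 0:
            warnings.warn(f"zero coverage on {ref}; normalized track is all zero")
        else:
            depth = depth / tot
    return CoverageTrack(ref, depth, sample, normalize)


def paired_log2fc_track(track_a: CoverageTrack, track_b: CoverageTrack,
                        pseudocount: float = 1e-6) -> np.ndarray:
    """log2((a_i + c)/(b_i + c)) per base of one locus."""
    if len(track_a.depth) != len(track_b.depth):
        raise ValueError("coverage tracks differ in length")
    return np.log2((track_a.depth + pseudocount) / (track_b.depth + pseudocount))


def smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the available bases."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    return (pd.Series(values).rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def site_metaplot(tracks, sites: list[int], halfwidth: int = 25,
                  smooth_window: int = 6) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean profile of one or more tracks around a site list.

    Returns (offsets, profile, n_truncated). The site sits at offset 0;
    windows running off the locus edge contribute their in-bounds part
    only (and are counted in ``n_truncated``). Smoothing is a centered
    moving average applied to the averaged profile.
    """
    if not sites:
        raise ValueError("empty site list")
    if isinstance(tracks, np.ndarray):
        tracks = [tracks]
    width = 2 * halfwidth + 1
    acc = []
    n_trunc = 0
    for tr in tracks:
        tr = np.asarray(tr, dtype=float)
        for s in sites:
            row = np.full(width, np.nan)
            lo = max(0, s - halfwidth)
            hi = min(len(tr), s + halfwidth + 1)
            if lo > s - halfwidth or hi < s + halfwidth + 1:
                n_trunc += 1
            row[lo - (s - halfwidth): hi - (s - halfwidth)] = tr[lo:hi]
            acc.append(row)
    profile = np.nanmean(np.vstack(acc), axis=0)
    profile = smooth(profile, smooth_window)
    offsets = np.arange(-halfwidth, halfwidth + 1)
    return offsets, profile, n_trunc


def mismatch_profile(alignments, ref: str, ref_len: int,
                     sample: str = "") -> MismatchProfile:
    """Pileup of covering/mismatching/deleted reads per reference position."""
    total = np.zeros(ref_len + 1)
    mism = np.zeros(ref_len)
    dele = np.zeros(ref_len)
    for rec, w in _weighted(alignments):
        if rec.ref != ref:
            continue
        total[rec.start] += w
        total[min(rec.end, ref_len)] -= w
        for op in rec.ops:
            if op.kind == "mismatch":
                mism[op.ref_pos] += w
            elif op.kind == "deletion":
                dele[op.ref_pos] += w
    return MismatchProfile(ref, np.cumsum(total[:-1]), mism, dele, sample)


def call_mismatch_sites(treated: MismatchProfile, mock: MismatchProfile,
                        min_reads: int = 5, min_fc: float = 1.5
                        ) -> list[PsiCall]:
    """Ψ sites from the Mn²⁺ mismatch/deletion pileup.

    Mismatch and deletion events are pooled for the ratio; positions with
    fewer than ``min_reads`` treated reads are not evaluated, and the
    boundary is inclusive (a fold change of exactly ``min_fc`` is called).
    """
    if treated.ref != mock.ref:
        raise ValueError("profiles are on different references")
    calls = []
    n = len(treated.total)
    ev_t = treated.mismatch + treated.deletion
    ev_m = mock.mismatch + mock.deletion
    for pos in range(n):
        tot_t = treated.total[pos]
        if tot_t < min_reads:
            continue
        ratio_t = ev_t[pos] / tot_t
        ratio_m = (ev_m[pos] + 0.5) / (mock.total[pos] + 1.0)
        fc = ratio_t / ratio_m
        passed = bool(fc >= min_fc * (1.0 - 1e-9))  # 'at least' is inclusive
        calls.append(PsiCall(treated.ref, pos, "mismatch", fc, passed))
    return calls


def collapse_adjacent_calls(calls: list[PsiCall]) -> list[PsiCall]:
    """Merge runs of adjacent passed calls, keeping the best-supported one.

    A deletion cannot be localized within a homopolymer run (removing any
    base of TT... yields the same read), so the pileup can split one site's
    deletion evidence across neighbouring positions. Adjacent passed calls
    are therefore collapsed to the position with the highest statistic;
    mismatch evidence, which localizes exactly, dominates that choice.
    """
    passed = sorted((c for c in calls if c.passed), key=lambda c: (c.ref, c.pos))
    failed = [c for c in calls if not c.passed]
    out: list[PsiCall] = []
    group: list[PsiCall] = []
    for c in passed:
        if group and c.ref == group[-1].ref and c.pos == group[-1].pos + 1:
            group.append(c)
        else:
            if group:
                out.append(max(group, key=lambda g: g.statistic))
            group = [c]
    if group:
        out.append(max(group, key=lambda g: g.statistic))
    return sorted(out + failed, key=lambda c: (c.ref, c.pos))


def mismatch_site_table(treated: MismatchProfile, mock: MismatchProfile,
                        min_reads: int = 5, min_fc: float = 1.5) -> pd.DataFrame:
    """Per-position caller output as a table (evaluated positions only)."""
    rows = []
    ev_t = treated.mismatch + treated.deletion
    ev_m = mock.mismatch + mock.deletion
    for pos in range(len(treated.total)):
        tot_t = treated.total[pos]
        if tot_t < min_reads:
            continue
        ratio_t = ev_t[pos] / tot_t
        ratio_m = (ev_m[pos] + 0.5) / (mock.total[pos] + 1.0)
        fc = ratio_t / ratio_m
        rows.append((treated.ref, pos, tot_t, ev_t[pos], ratio_t, ratio_m,
                     fc, bool(fc >= min_fc * (1.0 - 1e-9))))
    return pd.DataFrame(rows, columns=["ref", "pos0", "treated_total",
                                       "treated_events", "ratio_treated",
                                       "ratio_mock", "fold_change", "called"])


def feature_max_calls(table: pd.DataFrame, features: list[Feature]
                      ) -> pd.DataFrame:
    """Per-feature maximum fold change (the per-miRNA reading of the
    published criterion, alongside the per-position one)."""
    rows = []
    for f in features:
        sub = table[(table["ref"] == f.ref) & (table["pos0"] >= f.start)
                    & (table["pos0"] < f.end)]
        if len(sub):
            best = sub.loc[sub["fold_change"].idxmax()]
            rows.append((f.name, best["pos0"], best["fold_change"],
                         bool(best["called"])))
    return pd.DataFrame(rows, columns=["feature", "pos0", "fold_change",
                                       "called"])


def terminal_position_summary(calls: pd.DataFrame, mature: list[Feature]
                              ) -> pd.DataFrame:
    """Distance of each called site to the nearer miRNA end.

    Calls are mapped to min(distance to 5' end, distance to 3' end) with
    the end label; a deletion call at offset 0 from either end is
    classified terminal, anything else internal. Calls outside every
    mature annotation are bucketed as 'unannotated'.
    """
    rows = []
    called = calls[calls["called"]] if "called" in calls else calls
    for r in called.itertuples():
        hit = None
        for f in mature:
            if f.ref == r.ref and f.start <= r.pos0 < f.end:
                hit = f
                break
        if hit is None:
            rows.append((r.ref, r.pos0, "unannotated", -1, "unannotated"))
            continue
        d5 = r.pos0 - hit.start
        d3 = (hit.end - 1) - r.pos0
        if d5 <= d3:
            end, dist = "5p", d5
        else:
            end, dist = "3p", d3
        kind = "terminal" if dist == 0 else "internal"
        rows.append((r.ref, r.pos0, end, dist, kind))
    return pd.DataFrame(rows, columns=["ref", "pos0", "end", "distance",
                                       "class"])
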