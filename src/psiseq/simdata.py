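"""Synthetic small RNA libraries with known pseudouridine (Ψ) ground truth.

This module builds a loci-scale reference (rRNA, tRNAs, miRNA precursors,
TE families, piRNA clusters, structural RNAs), plants Ψ sites according to
enzyme specificity (PUS7 at UNUAR motifs, PUS10 at tRNA position 55, DKC1
at rRNA/miRNA sites), and emits FASTQ libraries under the three assay
chemistries used to detect Ψ in short sequences:

* Ψ-IP         — antibody capture; Ψ-containing reads are bound with
                 probability ``eps_psi``, background with ``eps_bg``.
* CMC RT-stop  — a CMC adduct on Ψ blocks reverse transcription; because
                 only one adapter is ligated before treatment, a blocked
                 cDNA never amplifies, so the read is dropped (not
                 truncated) with probability 1-(1-alpha)^k for k Ψ sites.
* CMC/Mn²⁺     — readthrough past the adduct with Mn²⁺ converts the stop
                 into a mismatch (rate ``m``) or deletion (rate ``d``) at
                 the Ψ position.

The internal alphabet is DNA (T for U); FASTA/FASTQ conventions and the
aligner operate on A/C/G/T. Reports may render U where a motif is shown.
Every stochastic choice flows from one RNG stream per sample derived from
(master seed, sample name), so individual libraries are reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

DNA = "ACGT"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# 3' adapters of the two library kits (DNA-space)
NEB_ADAPTER3 = "AGATCGGAAGAGCACACGTC"
NEXTFLEX_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

PHRED_HI = chr(35 + 33)  # Q35, the default base quality
PHRED_LO = chr(20 + 33)  # Q20, assigned where a sequencing error is injected

ENZYMES = ("PUS7", "PUS10", "DKC1", "OTHER")
# genotype -> enzyme class abolished by the knockout
GENOTYPE_KO = {"WT": None, "pus7": "PUS7", "pus10": "PUS10", "dkc1": "DKC1"}

# canonical tRNA numbering: position 55 of a 76-nt tRNA is 0-based index 54
TRNA_LEN = 76
PSI55_INDEX = 54


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """Annotated interval on a reference (0-based, half-open)."""

    name: str
    ref: str
    start: int
    end: int
    strand: str = "+"
    cls: str = ""
    family: str = ""


@dataclass
class ReferenceSet:
    """Reference sequences plus feature annotation."""

    sequences: dict[str, str]
    annotations: list[Feature]

    def features(self, cls: str | None = None) -> list[Feature]:
        if cls is None:
            return list(self.annotations)
        return [f for f in self.annotations if f.cls == cls]

    def validate(self) -> None:
        for f in self.annotations:
            seq = self.sequences.get(f.ref)
            if seq is None:
                raise ValueError(f"feature {f.name} on unknown reference {f.ref}")
            if not (0 <= f.start < f.end <= len(seq)):
                raise ValueError(f"feature {f.name} outside reference {f.ref}")
            if f.cls == "tRNA" and seq[f.start : f.end][-3:] != "CCA":
                raise ValueError(f"tRNA {f.name} does not end in CCA")


@dataclass(frozen=True)
class PsiTruth:
    """A planted Ψ site: reference, 0-based position, responsible enzyme."""

    ref: str
    pos: int
    enzyme: str


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Capture, blocking and readthrough rates default to the values used
    throughout the package's validation simulations: antibody capture
    eps_psi=0.8 / eps_bg=0.05, CMC adduct x RT-stop probability 0.8,
    Mn²⁺ mismatch/deletion rates 0.3/0.1, and an Illumina-like 1e-3
    background per-base error rate.
    """

    seed: int = 0
    genotype: str = "WT"
    depth: int = 200_000
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    ip_capture: tuple[float, float] = (0.05, 0.8)  # (eps_bg, eps_psi)
    cmc_alpha: float = 0.8
    mn_rates: tuple[float, float] = (0.3, 0.1)  # (mismatch m, deletion d)
    base_error: float = 1e-3
    dialect: str = "NEB"  # NEB | NextFlex
    size_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "miRNA": (20, 22),
            "tRF": (18, 30),
            "TE_siRNA_short": (20, 22),
            "TE_siRNA_long": (23, 25),
            "piRNA": (26, 31),
            "rRNA_frag": (18, 30),
        }
    )
    # reference composition
    n_trna: int = 8
    n_mirna: int = 24
    n_mirna_psi: int = 10
    n_rrna_psi: int = 20
    n_te_families: int = 6
    te_copies: int = 3
    n_pirna_clusters: int = 2
    # restrict which enzyme classes are active (before the genotype switch)
    active_enzymes: tuple[str, ...] = ENZYMES
    log_events: bool = False

    def validate(self) -> None:
        if self.depth <= 0:
            raise ConfigError("depth must be > 0")
        eps_bg, eps_psi = self.ip_capture
        m, d = self.mn_rates
        for name, p in [
            ("eps_bg", eps_bg),
            ("eps_psi", eps_psi),
            ("cmc_alpha", self.cmc_alpha),
            ("m", m),
            ("d", d),
            ("base_error", self.base_error),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {name}={p} outside [0, 1]")
        if m + d > 1.0:
            raise ConfigError("mismatch + deletion rates exceed 1")
        if self.genotype not in GENOTYPE_KO:
            raise ConfigError(f"unknown genotype {self.genotype!r}")
        if self.dialect not in ("NEB", "NextFlex"):
            raise ConfigError(f"unknown dialect {self.dialect!r}")
        for cls, (lo, hi) in self.size_ranges.items():
            if not (0 < lo <= hi):
                raise ConfigError(f"invalid size range for {cls}: ({lo}, {hi})")

    @property
    def adapter3(self) -> str:
        return NEB_ADAPTER3 if self.dialect == "NEB" else NEXTFLEX_ADAPTER3


def sample_rng(seed: int, name: str) -> np.random.Generator:
    """One RNG stream per sample, derived from (master seed, sample name)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [DNA[i] for i in rng.integers(0, 4, n)]


_UNUAR_RE = None


def find_unuar(seq: str) -> list[int]:
    """0-based indices of the modified (third) U of every UNUAR motif.

    The motif is U-N-U-A-R with R a purine; in DNA space T-N-T-A-[AG].
    The returned index points at the second T, the base carrying Ψ.
    """
    global _UNUAR_RE
    import re

    if _UNUAR_RE is None:
        _UNUAR_RE = re.compile("(?=T.TA[AG])")
    return [m.start() + 2 for m in _UNUAR_RE.finditer(seq)]


def _scrub_unuar(seq: list[str], keep: set[int], rng: np.random.Generator) -> None:
    """Destroy accidental UNUAR motifs except those whose Ψ index is in keep."""
    while True:
        hits = [i for i in find_unuar("".join(seq)) if i not in keep]
        if not hits:
            return
        for i in hits:
            # break the motif at its A (position +1 from the modified U)
            seq[i + 1] = rng.choice(["C", "G", "T"])


def build_reference(config: SimConfig) -> tuple[ReferenceSet, list[PsiTruth]]:
    """Construct the reference loci and the planted Ψ truth table.

    Returns at least one rRNA locus with DKC1-class sites, eight 76-nt
    tRNAs ending in CCA with Ψ-55 (a subset additionally carrying a UNUAR
    motif), miRNA precursors (a subset with Ψ in the mature arm), several
    TE families with multiple copies, and piRNA-cluster intervals. The
    genotype switch removes the corresponding enzyme class from the truth.
    """
    config.validate()
    rng = sample_rng(config.seed, "reference")
    sequences: dict[str, str] = {}
    annotations: list[Feature] = []
    truth: list[PsiTruth] = []

    # --- rRNA locus with DKC1 sites ----------------------------------
    rrna_len = 1500
    rrna = _random_seq(rng, rrna_len)
    spacing = rrna_len // (config.n_rrna_psi + 1)
    rrna_psi = [spacing * (i + 1) for i in range(config.n_rrna_psi)]
    for p in rrna_psi:
        rrna[p] = "T"
    _scrub_unuar(rrna, set(), rng)
    sequences["rRNA"] = "".join(rrna)
    annotations.append(Feature("rRNA25S", "rRNA", 0, rrna_len, "+", "rRNA"))
    truth += [PsiTruth("rRNA", p, "DKC1") for p in rrna_psi]

    # --- tRNAs: 76 nt, CCA tail, Ψ-55; half carry a UNUAR motif -------
    amino = ["Ala", "Gly", "Glu", "Asp", "Val", "Leu", "Lys", "Arg",
             "Ser", "Thr", "Pro", "His"]
    n_unuar = config.n_trna // 2
    for i in range(config.n_trna):
        name = f"tRNA-{amino[i % len(amino)]}{i}"
        seq = _random_seq(rng, TRNA_LEN)
        seq[PSI55_INDEX] = "T"
        seq[73:76] = list("CCA")
        keep: set[int] = set()
        if i < n_unuar:
            # UNUAR motif at indices 30..34, Ψ on the T at index 32
            seq[30] = "T"
            seq[31] = rng.choice(list(DNA))
            seq[32] = "T"
            seq[33] = "A"
            seq[34] = rng.choice(["A", "G"])
            keep.add(32)
        _scrub_unuar(seq, keep, rng)
        seq[54] = "T"  # scrubbing never touches it, but keep the invariant explicit
        sequences[name] = "".join(seq)
        annotations.append(Feature(name, name, 0, TRNA_LEN, "+", "tRNA"))
        truth.append(PsiTruth(name, PSI55_INDEX, "PUS10"))
        if i < n_unuar:
            truth.append(PsiTruth(name, 32, "PUS7"))

    # --- miRNA precursors, mature arm 21 nt at [30, 51) ---------------
    mat_start, mat_end = 30, 51
    for i in range(config.n_mirna):
        ref = f"MIR{i}"
        seq = _random_seq(rng, 120)
        if i < config.n_mirna_psi:
            seq[40] = "T"
        _scrub_unuar(seq, set(), rng)
        sequences[ref] = "".join(seq)
        annotations.append(Feature(f"{ref}_pre", ref, 0, 120, "+", "miRNA_precursor"))
        annotations.append(Feature(f"miR{i}", ref, mat_start, mat_end, "+", "miRNA_mature"))
        if i < config.n_mirna_psi:
            truth.append(PsiTruth(ref, 40, "DKC1"))

    # --- TE families on one chromosome, Ψ in half the families --------
    te_len, gap = 300, 50
    chrom: list[str] = []
    pos = 0
    n_psi_fams = config.n_te_families // 2
    for fi in range(config.n_te_families):
        fam = f"ATTE{fi}"
        consensus = _random_seq(rng, te_len)
        psi_offsets: list[int] = []
        if fi < n_psi_fams:
            psi_offsets = sorted(rng.choice(np.arange(20, te_len - 20), 4, replace=False).tolist())
            for off in psi_offsets:
                consensus[off] = "T"
        for ci in range(config.te_copies):
            copy = list(consensus)
            n_mut = rng.binomial(te_len, 0.02)
            for j in rng.choice(te_len, n_mut, replace=False):
                if j in psi_offsets:
                    continue
                copy[j] = rng.choice([b for b in DNA if b != copy[j]])
            _scrub_unuar(copy, set(psi_offsets), rng)
            chrom += _random_seq(rng, gap)
            pos = len(chrom)
            chrom += copy
            annotations.append(
                Feature(f"{fam}|copy{ci}", "chrTE", pos, pos + te_len, "+", "TE", fam)
            )
            truth += [PsiTruth("chrTE", pos + off, "OTHER") for off in psi_offsets]
            pos = len(chrom)
    chrom += _random_seq(rng, gap)
    sequences["chrTE"] = "".join(chrom)

    # --- piRNA clusters ----------------------------------------------
    pi_len = 2000
    pi = _random_seq(rng, pi_len)
    cluster_iv = [(100, 900), (1100, 1900)][: config.n_pirna_clusters]
    psi_pi = sorted(np.asarray(
        rng.choice(np.arange(cluster_iv[0][0] + 10, cluster_iv[0][1] - 10), 10, replace=False)
    ).tolist())
    for p in psi_pi:
        pi[p] = "T"
    _scrub_unuar(pi, set(psi_pi), rng)
    sequences["chrPI"] = "".join(pi)
    for ci, (s, e) in enumerate(cluster_iv):
        annotations.append(Feature(f"piCluster{ci}", "chrPI", s, e, "+", "piRNA_cluster"))
    truth += [PsiTruth("chrPI", p, "OTHER") for p in psi_pi]

    # --- structural RNAs (snoRNA/snRNA) used by exclusion filters -----
    for i in range(2):
        for cls in ("snoRNA", "snRNA"):
            ref = f"{cls}{i}"
            seq = _random_seq(rng, 100)
            _scrub_unuar(seq, set(), rng)
            sequences[ref] = "".join(seq)
            annotations.append(Feature(ref, ref, 0, 100, "+", cls))

    active = set(config.active_enzymes)
    ko = GENOTYPE_KO[config.genotype]
    if ko is not None:
        active.discard(ko)
    truth = [t for t in truth if t.enzyme in active]

    refset = ReferenceSet(sequences, annotations)
    refset.validate()
    for t in truth:
        assert sequences[t.ref][t.pos] == "T", "Ψ must sit on a uridine"
    return refset, truth


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------

POOL_COLUMNS = [
    "species", "sequence", "ref", "start", "end", "cls", "family",
    "psi_offsets", "n_psi", "true_abundance",
]


def _psi_offsets(truth_by_ref: dict[str, list[int]], ref: str, start: int, end: int) -> list[int]:
    return [p - start for p in truth_by_ref.get(ref, []) if start <= p < end]


def simulate_pool(ref: ReferenceSet, truth: list[PsiTruth], config: SimConfig) -> pd.DataFrame:
    """Draw the species pool: one row per distinct small RNA sequence.

    Species are subsequences of annotated features with class-appropriate
    lengths (miRNA 20-22 via the 21-nt mature arm, 3'-CCA tRFs 18-30,
    TE siRNA 20-22 and 23-25, piRNA-like 26-31, rRNA fragments 18-30) and
    log-normal abundances normalised to the configured depth.
    """
    rng = sample_rng(config.seed, "pool")
    truth_by_ref: dict[str, list[int]] = {}
    for t in truth:
        truth_by_ref.setdefault(t.ref, []).append(t.pos)

    rows: list[dict] = []

    def add(ref_name: str, start: int, end: int, cls: str, family: str = "") -> None:
        seq = ref.sequences[ref_name][start:end]
        offs = _psi_offsets(truth_by_ref, ref_name, start, end)
        rows.append(
            dict(species="", sequence=seq, ref=ref_name, start=start, end=end,
                 cls=cls, family=family,
                 psi_offsets=",".join(map(str, offs)), n_psi=len(offs))
        )

    # miRNA: the mature sequence of every locus
    for f in ref.features("miRNA_mature"):
        add(f.ref, f.start, f.end, "miRNA")

    # tRFs: per tRNA a 3'-CCA fragment at every length in the configured
    # range, plus fragments spanning the UNUAR motif but not position 55
    lo, hi = config.size_ranges["tRF"]
    for f in ref.features("tRNA"):
        for L in range(lo, hi + 1):
            add(f.ref, f.end - L, f.end, "tRF_3p")
        motif = find_unuar(ref.sequences[f.ref])
        internal = [i for i in motif if i != PSI55_INDEX]
        if internal:
            m = internal[0]
            for L in (18, 20, 22):
                start = max(0, m - L // 2)
                if start + L <= PSI55_INDEX:  # must not span Ψ-55
                    add(f.ref, start, start + L, "tRF_internal")
        else:
            add(f.ref, 10, 30, "tRF_internal")

    # rRNA fragments
    lo, hi = config.size_ranges["rRNA_frag"]
    rlen = len(ref.sequences["rRNA"])
    for _ in range(40):
        L = int(rng.integers(lo, hi + 1))
        s = int(rng.integers(0, rlen - L))
        add("rRNA", s, s + L, "rRNA_frag")

    # TE siRNA in the two size classes
    te_feats = ref.features("TE")
    for key in ("TE_siRNA_short", "TE_siRNA_long"):
        lo, hi = config.size_ranges[key]
        fams = sorted({f.family for f in te_feats})
        for fam in fams:
            copies = [f for f in te_feats if f.family == fam]
            for _ in range(6):
                f = copies[int(rng.integers(len(copies)))]
                L = int(rng.integers(lo, hi + 1))
                s = int(rng.integers(f.start, f.end - L))
                add(f.ref, s, s + L, "TE_siRNA", fam)

    # piRNA-like species from the clusters
    lo, hi = config.size_ranges["piRNA"]
    for f in ref.features("piRNA_cluster"):
        for _ in range(15):
            L = int(rng.integers(lo, hi + 1))
            s = int(rng.integers(f.start, f.end - L))
            add(f.ref, s, s + L, "piRNA")

    # structural fragments (snoRNA/snRNA)
    for f in ref.features("snoRNA") + ref.features("snRNA"):
        for _ in range(2):
            L = int(rng.integers(18, 26))
            s = int(rng.integers(f.start, f.end - L))
            add(f.ref, s, s + L, f.cls + "_frag")

    pool = pd.DataFrame(rows)
    # collapse duplicated sequences (two windows can coincide)
    pool = pool.drop_duplicates(subset=["ref", "start", "end"]).reset_index(drop=True)
    pool["species"] = [f"sp{i:04d}" for i in range(len(pool))]
    ab = rng.lognormal(config.abundance_mu, config.abundance_sigma, len(pool))
    pool["true_abundance"] = ab / ab.sum() * config.depth
    return pool[POOL_COLUMNS]


def tiling_pool(ref: ReferenceSet, truth: list[PsiTruth], config: SimConfig,
                ref_name: str = "rRNA", length: int = 24, step: int = 3
                ) -> pd.DataFrame:
    """Species pool of fragments tiling one locus at a fixed step.

    Used for position-level evaluations (mismatch pileups, metaplots),
    where every reference base — in particular every planted Ψ site —
    must be covered by several distinct fragments. Abundances are
    log-normal as in ``simulate_pool``.
    """
    rng = sample_rng(config.seed, f"tiling_{ref_name}")
    seq = ref.sequences[ref_name]
    truth_by_ref: dict[str, list[int]] = {}
    for t in truth:
        truth_by_ref.setdefault(t.ref, []).append(t.pos)
    rows = []
    for s in range(0, len(seq) - length + 1, step):
        offs = _psi_offsets(truth_by_ref, ref_name, s, s + length)
        rows.append(dict(species=f"tile{s:05d}", sequence=seq[s : s + length],
                         ref=ref_name, start=s, end=s + length, cls="tile",
                         family="", psi_offsets=",".join(map(str, offs)),
                         n_psi=len(offs)))
    pool = pd.DataFrame(rows)
    ab = rng.lognormal(config.abundance_mu, config.abundance_sigma, len(pool))
    pool["true_abundance"] = ab / ab.sum() * config.depth
    return pool[POOL_COLUMNS]


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------


@dataclass
class SimOutput:
    """Paths and truth tables for one simulated library pair."""

    fastq: dict[str, Path]
    counts: pd.DataFrame  # species x sample emitted-read counts
    events: pd.DataFrame | None  # per-read event log (when enabled)
    pool: pd.DataFrame


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> tuple[str, str]:
    """Inject background sequencing errors; errored bases get Q20."""
    L = len(seq)
    k = rng.binomial(L, rate) if rate > 0 else 0
    if not k:
        return seq, PHRED_HI * L
    s = list(seq)
    qual = [PHRED_HI] * L
    for j in rng.choice(L, min(k, L), replace=False):
        s[j] = DNA[(DNA.index(s[j]) + int(rng.integers(1, 4))) % 4]
        qual[j] = PHRED_LO
    return "".join(s), "".join(qual)


def _emit(fh, name: str, insert: str, qual: str, config: SimConfig,
          rng: np.random.Generator) -> None:
    adapter = config.adapter3
    if config.dialect == "NextFlex":
        n5 = "".join(_random_seq(rng, 4))
        n3 = "".join(_random_seq(rng, 4))
        seq = n5 + insert + n3 + adapter
        q = PHRED_HI * 4 + qual + PHRED_HI * 4 + PHRED_HI * len(adapter)
    else:
        seq = insert + adapter
        q = qual + PHRED_HI * len(adapter)
    fh.write(f"@{name}\n{seq}\n+\n{q}\n")


def _draw_counts(pool: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    probs = pool["true_abundance"].to_numpy()
    return rng.multinomial(config.depth, probs / probs.sum())


def _write_library(path: Path, pool: pd.DataFrame, counts: np.ndarray,
                   config: SimConfig, rng: np.random.Generator,
                   mn_mode: bool = False,
                   events: list | None = None, lib: str = "") -> None:
    m, d = config.mn_rates
    with open(path, "w") as fh:
        serial = 0
        for row, n in zip(pool.itertuples(), counts):
            if n == 0:
                continue
            offs = [int(x) for x in row.psi_offsets.split(",")] if row.psi_offsets else []
            if mn_mode and offs:
                for _ in range(int(n)):
                    seq = row.sequence
                    evs = []
                    # apply Ψ events right-to-left so deletions keep offsets valid
                    for off in sorted(offs, reverse=True):
                        u = rng.random()
                        if u < m:
                            base = seq[off]
                            alt = DNA[(DNA.index(base) + int(rng.integers(1, 4))) % 4]
                            seq = seq[:off] + alt + seq[off + 1:]
                            evs.append(f"mm@{off}>{alt}")
                        elif u < m + d:
                            seq = seq[:off] + seq[off + 1:]
                            evs.append(f"del@{off}")
                    seq, qual = _apply_errors(seq, rng, config.base_error)
                    name = f"{lib}.{serial}"
                    _emit(fh, name, seq, qual, config, rng)
                    if events is not None:
                        events.append((name, row.species, ";".join(evs) or "."))
                    serial += 1
            else:
                for _ in range(int(n)):
                    seq, qual = _apply_errors(row.sequence, rng, config.base_error)
                    name = f"{lib}.{serial}"
                    _emit(fh, name, seq, qual, config, rng)
                    if events is not None:
                        events.append((name, row.species, "."))
                    serial += 1


def simulate_ip(pool: pd.DataFrame, config: SimConfig, outdir: Path,
                pair: str = "pair1") -> SimOutput:
    """Antibody-capture arm: split one pool draw into bound and unbound.

    Each read of a Ψ-spanning species is captured with probability
    eps_psi, background reads with eps_bg; bound + unbound counts conserve
    the pool draw exactly.
    """
    config.validate()
    eps_bg, eps_psi = config.ip_capture
    if eps_psi < eps_bg:
        warnings.warn("eps_psi < eps_bg inverts the expected IP enrichment")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = sample_rng(config.seed, f"ip_{pair}")
    n = _draw_counts(pool, config, rng)
    eps = np.where(pool["n_psi"].to_numpy() > 0, eps_psi, eps_bg)
    bound = rng.binomial(n, eps)
    unbound = n - bound
    events: list | None = [] if config.log_events else None
    paths = {}
    for role, cnt in (("bound", bound), ("unbound", unbound)):
        lib = f"ip_{pair}_{role}"
        p = outdir / f"{lib}.fastq"
        _write_library(p, pool, cnt, config, sample_rng(config.seed, lib),
                       events=events, lib=lib)
        paths[role] = p
    counts = pd.DataFrame(
        {"species": pool["species"], "bound": bound, "unbound": unbound}
    )
    ev = pd.DataFrame(events, columns=["read", "species", "events"]) if events is not None else None
    return SimOutput(paths, counts, ev, pool)


def simulate_cmc(pool: pd.DataFrame, config: SimConfig, outdir: Path,
                 mode: str = "stop", pair: str = "pair1") -> SimOutput:
    """CMC arm: RT-stop depletion (``stop``) or Mn²⁺ readthrough (``mn2plus``).

    stop:    a read spanning k Ψ sites survives with probability (1-alpha)^k;
             dropped reads are logged but never written (the blocked cDNA
             lacks the second adapter and cannot amplify).
    mn2plus: each Ψ position in a read mutates with probability m or is
             deleted with probability d, independently per site.
    """
    config.validate()
    if mode not in ("stop", "mn2plus"):
        raise ValueError(f"unknown CMC mode {mode!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = sample_rng(config.seed, f"cmc_{mode}_{pair}")
    n_treated = _draw_counts(pool, config, rng)
    n_mock = _draw_counts(pool, config, rng)
    events: list | None = [] if config.log_events else None

    if mode == "stop":
        survive = (1.0 - config.cmc_alpha) ** pool["n_psi"].to_numpy()
        kept = rng.binomial(n_treated, survive)
        if events is not None:
            for row, nt, nk in zip(pool.itertuples(), n_treated, kept):
                for j in range(int(nt - nk)):
                    events.append((f"dropped_{row.species}.{j}", row.species, "rt_stop"))
        treated_counts, mn = kept, False
    else:
        treated_counts, mn = n_treated, True

    paths = {}
    for role, cnt, is_mn in (("treated", treated_counts, mn), ("mock", n_mock, False)):
        lib = f"cmc{mode}_{pair}_{role}"
        p = outdir / f"{lib}.fastq"
        _write_library(p, pool, cnt, config, sample_rng(config.seed, lib),
                       mn_mode=is_mn, events=events, lib=lib)
        paths[role] = p
    counts = pd.DataFrame(
        {"species": pool["species"], "treated": treated_counts, "mock": n_mock}
    )
    ev = pd.DataFrame(events, columns=["read", "species", "events"]) if events is not None else None
    return SimOutput(paths, counts, ev, pool)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------


def write_reference_fasta(ref: ReferenceSet, path: Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in ref.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    return path


def write_annotation_bed(ref: ReferenceSet, path: Path) -> Path:
    """BED6; the name field is ``name|family|class`` (family may be empty)."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in ref.annotations:
            name = f"{f.name}|{f.family}|{f.cls}"
            fh.write(f"{f.ref}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")
    return path


def write_psi_truth(truth: Iterable[PsiTruth], path: Path) -> Path:
    path = Path(path)
    pd.DataFrame([(t.ref, t.pos, t.enzyme) for t in truth],
                 columns=["ref", "pos0", "enzyme"]).to_csv(path, sep="\t", index=False)
    return path


def read_psi_truth(path: Path) -> list[PsiTruth]:
    df = pd.read_csv(path, sep="\t")
    return [PsiTruth(r.ref, int(r.pos0), r.enzyme) for r in df.itertuples()]
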