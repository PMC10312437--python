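"""End-to-end orchestration: simulate -> preprocess -> align -> count ->
enrich -> sites -> classify -> report.

The pipeline is driven by a single YAML config (see ``validate_config``)
and is deterministic under a fixed seed: every sample owns an RNG stream
derived from (seed, sample name), and every output table carries the
config hash in a header comment. The stage helpers are plain functions so
they can be reused programmatically; the CLI wraps them thinly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import align as al
from . import features as ft
from . import reads as rd
from . import simdata as sd
from . import sites as st
from . import stats as stt

log = logging.getLogger("psiseq")

ARMS = ("ip", "stop", "mn2plus")
FEATURE_LEVELS = ("sequence", "mirna", "trf_isotype", "te_family_sizeclass",
                  "pirna_cluster")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "psiseq_out",
    "simulate": {"n_pairs": 3, "arms": ["ip", "stop"], "genotype": "WT"},
    "preprocess": {"preset": "te", "dialect": "NEB"},
    "align": {"k": 10, "max_mismatch": 1, "max_deletion": 1, "multimap": "all"},
    "enrich": {"alpha": 0.01, "mean_filter": 10, "level": "sequence",
               "cluster_min": 100},
    "sites": {"min_reads": 5, "min_fc": 1.5,
              "metaplot": {"halfwidth": 25, "smooth": 6}},
}


def config_hash(config: dict) -> str:
    """Hash of the analytic parameters (output location excluded)."""
    payload = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha1(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def validate_config(config: dict) -> list[str]:
    """Schema and cross-field checks; returns a list of errors (never raises)."""
    errors = []
    if "simulate" not in config and "reference" not in config:
        errors.append("config needs either a 'simulate' block or a 'reference' FASTA")
    pre = config.get("preprocess", {})
    preset = pre.get("preset")
    if preset is not None and preset not in rd.LENGTH_PRESETS:
        errors.append(f"unknown length preset {preset!r}")
    if pre.get("dialect", "NEB") not in ("NEB", "NextFlex"):
        errors.append(f"unknown dialect {pre.get('dialect')!r}")
    arms = config.get("simulate", {}).get("arms", [])
    for arm in arms:
        if arm not in ARMS:
            errors.append(f"unknown assay arm {arm!r}")
    amax = config.get("align", {}).get("max_deletion", 0)
    if "mn2plus" in arms and amax < 1:
        errors.append("mn2plus arm requires align.max_deletion >= 1 "
                      "(deletions are part of the Mn2+ signal)")
    lvl = config.get("enrich", {}).get("level", "sequence")
    if lvl not in FEATURE_LEVELS:
        errors.append(f"unknown feature level {lvl!r}")
    try:
        al.MapPolicy(config.get("align", {}).get("max_mismatch", 1),
                     config.get("align", {}).get("max_deletion", 0),
                     config.get("align", {}).get("multimap", "all"))
    except ValueError as e:
        errors.append(str(e))
    return errors


# ---------------------------------------------------------------------------
# simulation stage
# ---------------------------------------------------------------------------


@dataclass
class Experiment:
    """Everything one simulated experiment produced."""

    ref: sd.ReferenceSet
    truth: list[sd.PsiTruth]
    pool: pd.DataFrame
    fastq: dict[str, Path]          # sample -> path
    sample_sheet: pd.DataFrame
    config: sd.SimConfig
    outdir: Path


def simulate_experiment(simcfg: sd.SimConfig, outdir, arms=("ip", "stop"),
                        n_pairs: int = 3) -> Experiment:
    """Build reference + pool and write FASTQ for every arm and pair.

    Pairs model technical replicates on the same RNA pool: the pool is
    drawn once and each pair is an independent library draw, matching the
    paired (treatment, control) design of the assays.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, truth = sd.build_reference(simcfg)
    pool = sd.simulate_pool(ref, truth, simcfg)
    fastq: dict[str, Path] = {}
    rows = []
    for arm in arms:
        for i in range(1, n_pairs + 1):
            pair = f"p{i}"
            if arm == "ip":
                out = sd.simulate_ip(pool, simcfg, outdir, pair=pair)
                roles = {"bound": "treatment", "unbound": "control"}
                prefix = "ip"
            else:
                out = sd.simulate_cmc(pool, simcfg, outdir, mode=arm, pair=pair)
                roles = {"treated": "treatment", "mock": "control"}
                prefix = f"cmc{arm}"
            for frac, role in roles.items():
                sample = f"{prefix}_{pair}_{frac}"
                fastq[sample] = out.fastq[frac]
                rows.append(dict(sample=sample, arm=arm, role=role,
                                 pair=f"{arm}_{pair}", techrep=1, biorep=i,
                                 genotype=simcfg.genotype, tissue="synthetic"))
    sheet = pd.DataFrame(rows)
    sd.write_reference_fasta(ref, outdir / "reference.fasta")
    sd.write_annotation_bed(ref, outdir / "annotation.bed")
    sd.write_psi_truth(truth, outdir / "psi_truth.tsv")
    pool.to_csv(outdir / "pool.tsv", sep="\t", index=False)
    return Experiment(ref, truth, pool, fastq, sheet, simcfg, outdir)


# ---------------------------------------------------------------------------
# preprocess + align + count
# ---------------------------------------------------------------------------


@dataclass
class Quantification:
    counts: pd.DataFrame                        # sequence x sample
    records: dict[str, list[al.AlignmentRecord]]  # mapped sequences only
    stats: pd.DataFrame


def quantify(exp: Experiment, policy: rd.FilterPolicy,
             map_policy: al.MapPolicy, k: int = 10,
             samples: list[str] | None = None) -> Quantification:
    """Trim/filter/collapse every library, then map the unique sequences."""
    counters = {}
    stat_rows = []
    for sample, path in exp.fastq.items():
        if samples is not None and sample not in samples:
            continue
        t0 = time.perf_counter()
        counts, stats = rd.preprocess_fastq(path, policy)
        counters[sample] = counts
        stats["sample"] = sample
        stats["seconds"] = round(time.perf_counter() - t0, 2)
        stat_rows.append(stats)
        log.info("preprocess %s: %s", sample, stats)
    matrix = rd.counts_table(counters)
    index = al.KmerIndex.from_reference(exp.ref, k=k)
    rng = sd.sample_rng(exp.config.seed, "map")
    records = al.map_reads(matrix.index, index, map_policy, rng)
    matrix = matrix.loc[matrix.index.isin(records)]
    return Quantification(matrix, records, pd.DataFrame(stat_rows))


def feature_counts(quant: Quantification, ref: sd.ReferenceSet,
                   level: str) -> pd.DataFrame:
    """Aggregate the sequence x sample matrix to the requested level."""
    if level == "sequence":
        return quant.counts
    if level not in FEATURE_LEVELS:
        raise ValueError(f"unknown feature level {level!r}")
    feats_by_cls = {
        "mirna": ref.features("miRNA_mature"),
        "trf_isotype": ref.features("tRNA"),
        "pirna_cluster": ref.features("piRNA_cluster"),
        "te_family_sizeclass": ref.features("TE"),
    }[level]
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for f in feats_by_cls:
        trees.setdefault(f.ref, IntervalTree()).addi(f.start, f.end, f)
    agg: dict[str, np.ndarray] = {}
    n_samples = quant.counts.shape[1]
    for seq, recs in quant.records.items():
        if seq not in quant.counts.index:
            continue
        keys = set()
        for rec in recs:
            tree = trees.get(rec.ref)
            if tree is None:
                continue
            for iv in tree.overlap(rec.start, rec.end):
                f = iv.data
                if level == "mirna":
                    if rec.start >= f.start and rec.end <= f.end:
                        keys.add(f.name)
                elif level == "trf_isotype":
                    keys.add(f.name.split("-", 1)[1] if "-" in f.name else f.name)
                elif level == "te_family_sizeclass":
                    sc = ft._size_class(len(seq))
                    if sc is not None:
                        keys.add(f"{f.family}|{sc}")
                else:
                    keys.add(f.name)
        row = quant.counts.loc[seq].to_numpy()
        for key in keys:
            agg[key] = agg.get(key, np.zeros(n_samples)) + row
    out = pd.DataFrame(agg, index=quant.counts.columns).T.astype(int)
    out.index.name = level
    return out.sort_index()


def depleted_trf_length_mode(seed: int, outdir, depth: int = 100_000,
                             n_pairs: int = 3, cmc_alpha: float = 0.9,
                             alpha: float = 0.01) -> dict:
    """Modal length of 3'-CCA tRFs significantly depleted by CMC treatment.

    Simulates tRNAs whose only Ψ is the canonical position-55 site
    (active_enzymes restricted to PUS10), with 3'-tRF lengths spanning
    18-30 nt plus the generator's unmodified background classes, which
    anchor the median-of-ratios normalization. Runs preprocess, align and
    the paired NB test, then takes the length histogram of significantly
    depleted (padj < alpha, negative log2FC) 3'-CCA tRFs. Because only
    fragments of at least 22 nt reach back to Ψ-55, the histogram starts
    at 22 and its mode (ties resolve to the smallest length) is 22.
    """
    simcfg = sd.SimConfig(seed=seed, depth=depth, cmc_alpha=cmc_alpha,
                          active_enzymes=("PUS10",))
    exp = simulate_experiment(simcfg, outdir, arms=("stop",), n_pairs=n_pairs)
    policy = rd.FilterPolicy.preset("te", adapter3=simcfg.adapter3)
    quant = quantify(exp, policy, al.MapPolicy(1, 0, "all"), k=10)
    res = stt.nb_wald_test(quant.counts, exp.sample_sheet, mean_filter=10.0)
    depleted = res[(res["padj"] < alpha) & (res["log2fc"] < 0)]
    trnas = {f.ref: f for f in exp.ref.features("tRNA")}
    lengths = []
    for seq in depleted.index:
        for rec in quant.records.get(seq, []):
            feat = trnas.get(rec.ref)
            if feat is None:
                continue
            trf = ft.classify_trf(rec, feat)
            if trf.cls == "three_prime" and trf.has_cca:
                lengths.append(trf.length)
            break
    hist, mode, tie = ft.size_distribution(lengths)
    return {"mode": mode, "tie": tie, "histogram": hist,
            "n_depleted_trfs": len(lengths), "n_tested": len(res),
            "depth": depth}


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------


def _write_table(df: pd.DataFrame, path: Path, chash: str, seed: int,
                 index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# psiseq config={chash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_all(config: dict) -> dict:
    """Run every configured stage; returns a dict of result objects.

    Writes per-arm enrichment tables, Ψ-feature calls with the three-assay
    overlap, Mn²⁺ site calls, metaplot matrices, and (simulation input
    being ground-truthed) a truth-vs-call confusion table.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    chash = config_hash(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    simblock = config["simulate"]
    sim_kwargs = {k: v for k, v in simblock.items()
                  if k not in ("n_pairs", "arms")}
    if "dialect" not in sim_kwargs:
        sim_kwargs["dialect"] = config["preprocess"].get("dialect", "NEB")
    simcfg = sd.SimConfig(seed=seed, **sim_kwargs)
    arms = tuple(simblock.get("arms", ("ip", "stop")))
    t0 = time.perf_counter()
    exp = simulate_experiment(simcfg, outdir / "fastq", arms=arms,
                              n_pairs=int(simblock.get("n_pairs", 3)))
    log.info("simulate: %.1fs", time.perf_counter() - t0)

    policy = rd.FilterPolicy.preset(config["preprocess"]["preset"],
                                    dialect=config["preprocess"].get("dialect", "NEB"),
                                    adapter3=simcfg.adapter3)
    acfg = config["align"]
    map_policy = al.MapPolicy(acfg["max_mismatch"], acfg["max_deletion"],
                              acfg["multimap"])
    quant = quantify(exp, policy, map_policy, k=acfg["k"])
    _write_table(quant.stats.set_index("sample"), outdir / "preprocess_stats.tsv",
                 chash, seed)

    ecfg = config["enrich"]
    level = ecfg["level"]
    fmatrix = feature_counts(quant, exp.ref, level)
    results = {"experiment": exp, "quant": quant, "counts": fmatrix}
    sheet = exp.sample_sheet
    _write_table(fmatrix, outdir / f"counts_{level}.tsv", chash, seed)
    sheet.to_csv(outdir / "samples.csv", index=False)

    enrich: dict[str, pd.DataFrame] = {}
    for arm in arms:
        if arm == "mn2plus":
            continue
        info = sheet[sheet["arm"] == arm]
        cols = [s for s in info["sample"] if s in fmatrix.columns]
        res = stt.nb_wald_test(fmatrix[cols], info[info["sample"].isin(cols)],
                               mean_filter=float(ecfg["mean_filter"]))
        enrich[arm] = res
        _write_table(res, outdir / f"enrichment_{arm}_{level}.tsv", chash, seed)
    results["enrichment"] = enrich

    mn_sites = pd.DataFrame()
    mn_features: set[str] = set()
    if "mn2plus" in arms:
        scfg = config["sites"]
        info = sheet[sheet["arm"] == "mn2plus"]
        treated = info.loc[info["role"] == "treatment", "sample"].tolist()
        mock = info.loc[info["role"] == "control", "sample"].tolist()
        tables = []
        for ref_name, seq in exp.ref.sequences.items():
            def profile(cols):
                weighted = []
                for s, recs in quant.records.items():
                    w = float(quant.counts.loc[s, [c for c in cols
                                                   if c in quant.counts.columns]].sum())
                    if w > 0:
                        for rec in recs:
                            weighted.append((rec, w))
                return st.mismatch_profile(weighted, ref_name, len(seq))

            tab = st.mismatch_site_table(profile(treated), profile(mock),
                                         min_reads=scfg["min_reads"],
                                         min_fc=scfg["min_fc"])
            tables.append(tab)
        mn_sites = pd.concat(tables, ignore_index=True) if tables else mn_sites
        _write_table(mn_sites, outdir / "mn2plus_sites.tsv", chash, seed,
                     index=False)
        if len(mn_sites):
            called = mn_sites[mn_sites["called"]]
            for s, recs in quant.records.items():
                for rec in recs:
                    hit = called[(called["ref"] == rec.ref)
                                 & (called["pos0"] >= rec.start)
                                 & (called["pos0"] < rec.end)]
                    if len(hit):
                        mn_features.add(s)
                        break
    results["mn_sites"] = mn_sites

    if "ip" in enrich and "stop" in enrich:
        calls, overlap = stt.call_psi_features(
            enrich["ip"], enrich["stop"], alpha=float(ecfg["alpha"]),
            mn_features=mn_features if level == "sequence" else None)
        _write_table(calls, outdir / f"psi_calls_{level}.tsv", chash, seed)
        _write_table(pd.DataFrame([overlap]), outdir / "assay_overlap.tsv",
                     chash, seed, index=False)
        results["psi_calls"] = calls
        results["overlap"] = overlap
        if level == "sequence":
            truth_seqs = set(exp.pool.loc[exp.pool["n_psi"] > 0, "sequence"])
            pred = set(calls.index[calls["call"] != "none"])
            universe = set(calls.index)
            tp = len(pred & truth_seqs)
            fp = len(pred - truth_seqs)
            fn = len((universe & truth_seqs) - pred)
            tn = len(universe) - tp - fp - fn
            conf = pd.DataFrame([{"tp": tp, "fp": fp, "fn": fn, "tn": tn}])
            _write_table(conf, outdir / "confusion.tsv", chash, seed,
                         index=False)
            results["confusion"] = conf

    # metaplot of the CMC depletion signal around planted rRNA sites
    if "stop" in arms:
        mcfg = config["sites"]["metaplot"]
        info = sheet[sheet["arm"] == "stop"]
        rsites = [t.pos for t in exp.truth if t.ref == "rRNA"]
        if rsites:
            tracks = []
            for i in sorted(info["biorep"].unique()):
                pairrows = info[info["biorep"] == i]
                tr = pairrows.loc[pairrows["role"] == "treatment", "sample"].iloc[0]
                ct = pairrows.loc[pairrows["role"] == "control", "sample"].iloc[0]

                def cov(sample):
                    weighted = [(rec, float(quant.counts.loc[s, sample]))
                                for s, recs in quant.records.items()
                                if sample in quant.counts.columns
                                and quant.counts.loc[s, sample] > 0
                                for rec in recs]
                    return st.locus_coverage(weighted, "rRNA",
                                             len(exp.ref.sequences["rRNA"]),
                                             normalize=True)

                tracks.append(st.paired_log2fc_track(cov(tr), cov(ct)))
            offs, prof, _ = st.site_metaplot(tracks, rsites,
                                             halfwidth=mcfg["halfwidth"],
                                             smooth_window=mcfg["smooth"])
            meta = pd.DataFrame({"offset": offs, "log2fc": prof})
            _write_table(meta, outdir / "metaplot_rrna.tsv", chash, seed,
                         index=False)
            results["metaplot"] = meta

    return results
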