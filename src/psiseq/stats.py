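"""Paired differential-enrichment engine for small RNA count matrices.

Each assay arm produces paired libraries (IP/unbound, CMC+/mock) over a
feature level (sequence, miRNA, tRF isotype, TE family x size class,
piRNA cluster). Enrichment is tested with a negative-binomial generalized
linear model with a pair covariate:

    K_ij ~ NB(mu_ij, alpha_i),  log mu_ij = log s_j + x_j' beta_i

where s_j are median-of-ratios size factors, the design contains an
intercept, pair indicators, and the treatment indicator whose Wald test
gives the per-feature p-value, corrected across features by
Benjamini-Hochberg. Dispersions alpha_i are method-of-moments estimates
(Pearson-style, degrees-of-freedom corrected) shrunk 50/50 in log space
toward a lowess mean-dispersion trend fitted across features -- a
deliberate simplification of full empirical-Bayes dispersion machinery.

Features are pre-filtered on mean raw counts (strictly >10 by default;
piRNA clusters instead require a mean of at least 100 raw reads) and
excluded features never enter the BH denominator. A simpler per-pair
log-ratio t-test is provided as a cross-check mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

LFC_PSEUDOCOUNT = 0.5  # normalized counts, reporting only (not the GLM)
_MIN_ALPHA = 1e-8

SAMPLE_COLUMNS = ["sample", "arm", "role", "pair", "techrep", "biorep",
                  "genotype", "tissue"]


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    log2fc: float
    se: float
    pvalue: float
    padj: float
    base_mean: float


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over features (nonzero in every sample) of
    count_ij / geometric-mean_i, rescaled to geometric mean one so that
    identical libraries get factor 1. Falls back to total-count ratios
    (with a warning) when no feature is nonzero everywhere.
    """
    counts = matrix.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if allpos.any():
        logc = np.log(counts[allpos])
        logratio = logc - logc.mean(axis=1, keepdims=True)
        logsf = np.median(logratio, axis=0)
    else:
        warnings.warn("no feature nonzero in all samples; "
                      "falling back to total-count size factors")
        tot = counts.sum(axis=0)
        logsf = np.log(np.maximum(tot, 1.0))
    logsf = logsf - logsf.mean()
    return pd.Series(np.exp(logsf), index=matrix.columns, name="size_factor")


def mean_count_filter(matrix: pd.DataFrame, threshold: float = 10.0,
                      samples: list[str] | None = None,
                      at_least: bool = False) -> pd.DataFrame:
    """Keep features whose mean raw count exceeds ``threshold``.

    The default is a strict '>' on the mean over all samples. With
    ``at_least=True`` the rule is '>=', and ``samples`` restricts the mean
    to a subset of libraries -- the piRNA-cluster mode (mean of at least
    100 raw reads per IP-arm sample).
    """
    sub = matrix[samples] if samples is not None else matrix
    m = sub.mean(axis=1)
    keep = m >= threshold if at_least else m > threshold
    return matrix.loc[keep]


def _design(info: pd.DataFrame, treatment_role: str) -> tuple[np.ndarray, int]:
    """Design matrix [1 | pair dummies | condition]; returns it and the
    column index of the condition coefficient."""
    pairs = pd.get_dummies(info["pair"], drop_first=True, dtype=float)
    cond = (info["role"] == treatment_role).astype(float)
    X = np.column_stack([np.ones(len(info)), pairs.to_numpy(), cond.to_numpy()])
    return X, X.shape[1] - 1


def _mom_dispersion(y: np.ndarray, X: np.ndarray, offset: np.ndarray) -> float:
    """Pearson method-of-moments NB dispersion after a Poisson fit."""
    n, p = X.shape
    if n <= p:
        return _MIN_ALPHA
    try:
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        mu = np.maximum(fit.fittedvalues, 1e-8)
    except Exception:
        return _MIN_ALPHA
    num = np.sum(((y - mu) ** 2 - mu) / mu**2)
    return float(num / (n - p))  # may be <= 0 (at or below the Poisson floor)


def estimate_dispersions(matrix: pd.DataFrame, info: pd.DataFrame,
                         treatment_role: str,
                         sf: pd.Series) -> pd.DataFrame:
    """Per-feature MoM dispersion, trend over the mean, and the 50/50
    log-space shrinkage of one toward the other."""
    X, _ = _design(info, treatment_role)
    offset = np.log(sf.loc[info["sample"]].to_numpy())
    disp = np.empty(len(matrix))
    base_mean = (matrix.to_numpy() / sf.loc[info["sample"]].to_numpy()).mean(axis=1)
    for i, (_, row) in enumerate(matrix.iterrows()):
        disp[i] = _mom_dispersion(row.to_numpy(dtype=float), X, offset)
    logm = np.log(np.maximum(base_mean, 1e-8))
    pos = disp > 0
    # the trend is smoothed over the *raw* MoM values in linear space:
    # keeping the non-positive estimates (features at or below the Poisson
    # floor) avoids the upward selection bias that conditioning on
    # positivity would introduce; the smoothed trend is clamped afterwards
    if len(disp) >= 10:
        # it=0: robustifying iterations would trim the right-skewed MoM
        # distribution and bias the trend low
        tr = lowess(disp, logm, frac=2 / 3, it=0, return_sorted=False)
        order = np.argsort(logm)
        trend = np.interp(logm, logm[order], tr[order])
    else:
        trend = np.full(len(disp), float(disp.mean()))
    trend = np.maximum(trend, _MIN_ALPHA)
    # 50/50 shrinkage in linear space (the geometric mean of a chi2-like
    # estimator is biased low); a non-positive per-feature estimate carries
    # no dispersion information of its own and falls back to the trend
    shrunk = np.where(pos, 0.5 * disp + 0.5 * trend, trend)
    return pd.DataFrame(
        {"base_mean": base_mean, "disp_mom": disp, "disp_trend": trend,
         "disp": shrunk}, index=matrix.index)


def _fit_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
            cond_ix: int) -> tuple[float, float]:
    """Condition coefficient (natural log) and its SE from the NB GLM."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, _MIN_ALPHA))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
        return float(fit.params[cond_ix]), float(fit.bse[cond_ix])
    except Exception:
        # degenerate feature (e.g. all-zero in one condition after pairing):
        # refit on counts + 0.5 to keep the coefficient finite
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y + 0.5, X, family=fam, offset=offset).fit(maxiter=100)
        return float(fit.params[cond_ix]), float(fit.bse[cond_ix])


def nb_wald_test(matrix: pd.DataFrame, info: pd.DataFrame,
                 treatment_role: str = "treatment",
                 mean_filter: float | None = 10.0,
                 dispersions: pd.Series | None = None,
                 mode: str = "nb") -> pd.DataFrame:
    """Paired enrichment test; one row per tested feature.

    ``matrix`` is features x samples raw counts; ``info`` carries one row
    per sample with at least ``sample``, ``role`` and ``pair`` columns.
    Features failing the mean-count filter are excluded from testing and
    from the BH denominator. With fewer than two pairs no p-values can be
    estimated and an exact-ratio report is returned (with a warning).
    ``mode='ratio_t'`` replaces the NB Wald test by a per-pair log-ratio
    t-test (cross-check mode). Reported log2fc uses a 0.5 normalized-count
    pseudocount on both sides; the Wald statistic comes from the GLM
    coefficient.
    """
    info = info.set_index("sample", drop=False).loc[matrix.columns].reset_index(drop=True)
    sf = size_factors(matrix)
    tested = mean_count_filter(matrix, mean_filter) if mean_filter is not None else matrix
    norm = tested / sf
    treat_cols = info.loc[info["role"] == treatment_role, "sample"].tolist()
    ctrl_cols = [s for s in matrix.columns if s not in treat_cols]
    mt = norm[treat_cols].mean(axis=1)
    mc = norm[ctrl_cols].mean(axis=1)
    log2fc = np.log2((mt + LFC_PSEUDOCOUNT) / (mc + LFC_PSEUDOCOUNT))
    base_mean = norm.mean(axis=1)

    n_pairs = info["pair"].nunique()
    out = pd.DataFrame({"feature": tested.index, "log2fc": log2fc.to_numpy(),
                        "base_mean": base_mean.to_numpy()})
    if n_pairs < 2:
        warnings.warn("fewer than 2 pairs: exact-ratio report, no p-values")
        out["se"] = np.nan
        out["pvalue"] = np.nan
        out["padj"] = np.nan
        return out.set_index("feature")

    if mode == "ratio_t":
        pvals = np.empty(len(tested))
        ses = np.empty(len(tested))
        for i, (_, row) in enumerate(norm.iterrows()):
            ratios = []
            for pr in info["pair"].unique():
                sub = info[info["pair"] == pr]
                t = row[sub.loc[sub["role"] == treatment_role, "sample"]].mean()
                c = row[sub.loc[sub["role"] != treatment_role, "sample"]].mean()
                ratios.append(np.log2((t + LFC_PSEUDOCOUNT) / (c + LFC_PSEUDOCOUNT)))
            r = np.asarray(ratios)
            tt = sps.ttest_1samp(r, 0.0)
            pvals[i] = tt.pvalue
            ses[i] = r.std(ddof=1) / np.sqrt(len(r))
    else:
        X, cond_ix = _design(info, treatment_role)
        offset = np.log(sf.loc[info["sample"]].to_numpy())
        if dispersions is None:
            disp = estimate_dispersions(tested, info, treatment_role, sf)["disp"]
        else:
            disp = dispersions.reindex(tested.index)
        pvals = np.empty(len(tested))
        ses = np.empty(len(tested))
        betas = np.empty(len(tested))
        for i, (feat, row) in enumerate(tested.iterrows()):
            beta, se = _fit_nb(row.to_numpy(dtype=float), X, offset,
                               float(disp.loc[feat]), cond_ix)
            betas[i] = beta
            ses[i] = se
            z = beta / se if se > 0 else 0.0
            pvals[i] = 2.0 * sps.norm.sf(abs(z))
        out["beta_log2"] = betas / np.log(2)
        ses = ses / np.log(2)  # report SE on the log2 scale

    out["se"] = ses
    out["pvalue"] = pvals
    out["padj"] = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    return out.set_index("feature")


def replicate_average(table: pd.DataFrame, value: str = "log2fc",
                      group: list[str] | None = None) -> pd.DataFrame:
    """Two-stage replicate mean: technical replicates are averaged within
    each biological replicate before biological replicates are averaged
    within each group (e.g. tissue x treatment)."""
    required = {"techrep", "biorep", value}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"replicate metadata missing: {sorted(missing)}")
    group = group or [c for c in ("tissue", "treatment", "feature")
                      if c in table.columns]
    bio = (table.groupby(group + ["biorep"], sort=False)[value]
           .mean().reset_index())
    return bio.groupby(group, sort=False)[value].mean().reset_index()


def call_psi_features(ip_results: pd.DataFrame, cmc_results: pd.DataFrame,
                      alpha: float = 0.01,
                      mn_features: set[str] | None = None
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Combine the three assay arms at one feature level.

    A feature is IP-positive when padj < alpha with positive log2FC
    (bound over unbound) and CMC-positive when padj < alpha with negative
    log2FC (depleted by treatment). The overlap table counts the regions
    of the three-way Venn with the Mn²⁺ mismatch caller.
    """
    feats = ip_results.index.union(cmc_results.index)
    df = pd.DataFrame(index=feats)
    ip = ip_results.reindex(feats)
    cmc = cmc_results.reindex(feats)
    df["ip_positive"] = (ip["padj"] < alpha) & (ip["log2fc"] > 0)
    df["cmc_positive"] = (cmc["padj"] < alpha) & (cmc["log2fc"] < 0)
    df[["ip_log2fc", "ip_padj"]] = ip[["log2fc", "padj"]]
    df[["cmc_log2fc", "cmc_padj"]] = cmc[["log2fc", "padj"]]
    mn = mn_features if mn_features is not None else set()
    df["mn_positive"] = [f in mn for f in feats]

    def klass(r):
        if r.ip_positive and r.cmc_positive:
            return "both"
        if r.ip_positive:
            return "IP-only"
        if r.cmc_positive:
            return "CMC-only"
        return "none"

    df["call"] = [klass(r) for r in df.itertuples()]
    a = set(df.index[df["ip_positive"].fillna(False)])
    b = set(df.index[df["cmc_positive"].fillna(False)])
    c = set(df.index[df["mn_positive"]])
    overlap = {
        "ip_only": len(a - b - c), "cmc_only": len(b - a - c),
        "mn_only": len(c - a - b),
        "ip_cmc": len((a & b) - c), "ip_mn": len((a & c) - b),
        "cmc_mn": len((b & c) - a), "all_three": len(a & b & c),
    }
    return df, overlap


RIP_PSEUDOCOUNT = {"snRNA": 0.1, "snoRNA": 0.1,
                   "pri_miRNA": 0.01, "pre_miRNA": 0.01}


def rip_reproducibility(lines: dict[str, pd.DataFrame],
                        control: pd.DataFrame,
                        classes: dict[str, str],
                        min_fc: float = 1.2,
                        min_lines: int = 2) -> pd.DataFrame:
    """Reproducibly RIP-enriched transcripts across transgenic lines.

    Every table has columns ``transcript``, ``ip`` and ``input`` (TPM).
    TPM values are adjusted with a class-specific pseudocount (0.1 for
    snRNA/snoRNA, 0.01 for pri-/pre-miRNA) so undetected transcripts give
    finite ratios; per line FC = (IP/input)_line / (IP/input)_control and
    a transcript is enriched when FC >= 1.2 in at least two lines.
    """
    def pc(t: str) -> float:
        cls = classes.get(t)
        if cls is None or cls not in RIP_PSEUDOCOUNT:
            warnings.warn(f"unknown RNA class for {t}; default pseudocount 0.01")
            return 0.01
        return RIP_PSEUDOCOUNT[cls]

    ctrl = control.set_index("transcript")
    fcs = {}
    for name, tab in lines.items():
        t = tab.set_index("transcript")
        common = t.index.union(ctrl.index)
        t = t.reindex(common).fillna(0.0)
        c = ctrl.reindex(common).fillna(0.0)
        p = pd.Series([pc(x) for x in common], index=common)
        line_ratio = (t["ip"] + p) / (t["input"] + p)
        ctrl_ratio = (c["ip"] + p) / (c["input"] + p)
        fcs[name] = line_ratio / ctrl_ratio
    fc = pd.DataFrame(fcs)
    fc["n_lines_passing"] = (fc >= min_fc).sum(axis=1)
    fc["enriched"] = fc["n_lines_passing"] >= min_lines
    fc.index.name = "transcript"
    return fc
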