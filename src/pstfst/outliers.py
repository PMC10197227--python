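"""Outlier-locus detection and the neutral SNP set.

Two complementary scans are implemented from scratch:

* a trimmed chi-square scan: the sample-size-uncorrected per-locus F_ST
  values are assumed (under neutrality) to follow a scaled chi-square
  distribution; its effective degrees of freedom are fitted by maximum
  likelihood to the trim-interior of the empirical distribution, and
  right-tail p-values / Benjamini-Hochberg q-values flag loci too
  differentiated for drift alone;
* a principal-component regression scan: each SNP is regressed on the
  leading K genotype PCs, the K z-scores are combined into a (robust)
  Mahalanobis distance, rescaled by a genomic inflation factor, and
  referred to a chi-square with K degrees of freedom.

Per-locus results from external software (e.g. a Bayesian allele-frequency
method) can be imported and merged, and a configurable consensus rule
produces the final outlier list; its complement is the neutral set used by
all drift-based statistics downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .containers import MISSING, GenotypeMatrix, PopulationMap
from .popgen import unit_counts, _unit_rows

logger = logging.getLogger(__name__)

__all__ = [
    "per_locus_fst_uncorrected",
    "trimmed_chi2_scan",
    "pc_regression_scan",
    "import_external_scan",
    "consensus_and_neutral_set",
    "OutlierReport",
    "build_report",
]

CONSENSUS_TIERS = ("none", "one-method", "two-methods", "all-methods")


def per_locus_fst_uncorrected(
    g: GenotypeMatrix, pmap: PopulationMap, level: str = "region",
) -> pd.DataFrame:
    """Per-locus F_ST without the finite-sample correction, plus He.

    The uncorrected variant (among-unit variance over total, with no
    correction of the numerator for sampling) is the statistic whose
    neutral distribution is well approximated by a scaled chi-square,
    which the trimmed fit requires.  Monomorphic loci yield NaN.
    """
    units = pmap.groups(level)
    if len(units) < 2:
        raise ValueError("need >= 2 units for a differentiation scan")
    rows = [_unit_rows(g, pmap, u, level) for u in units]
    r = len(rows)
    n = np.stack([unit_counts(g, rw)[0] for rw in rows]).astype(float)
    p = np.stack([unit_counts(g, rw)[1] for rw in rows])
    h = np.stack([unit_counts(g, rw)[2] for rw in rows])
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * s2
        b = pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        c = hbar / 2.0
        tot = a + b + c
        fst = np.where(tot > 0, a / tot, np.nan)
        he = 2.0 * pbar * (1.0 - pbar)
    ok = (n >= 1).all(axis=0) & (pbar > 0) & (pbar < 1)
    fst = np.where(ok, fst, np.nan)
    he = np.where((n >= 1).all(axis=0), he, np.nan)
    return pd.DataFrame({"fst_uncorrected": fst, "he": he},
                        index=g.locus_meta["id"])


def trimmed_chi2_scan(
    per_locus: pd.DataFrame,
    trim_low: float = 0.05,
    trim_high: float = 0.05,
    he_min: float = 0.10,
) -> pd.DataFrame:
    """Fit a scaled chi-square to the trim-interior F_ST values by ML.

    Under neutrality F_ST ~ Fbar * chisq(df) / df for an effective df
    reflecting the number of independent demes.  Loci below the He floor
    are excluded from both the fit and the calls.  Returns per-locus
    p-values (right tail) and BH q-values; excluded loci carry NaN.
    """
    fst = per_locus["fst_uncorrected"].to_numpy(dtype=float)
    he = per_locus["he"].to_numpy(dtype=float)
    usable = np.isfinite(fst) & np.isfinite(he) & (he >= he_min) & (fst > 0)
    n_use = int(usable.sum())
    if n_use < 50:
        warnings.warn(f"only {n_use} usable loci; trimmed fit may be unstable",
                      stacklevel=2)
    x = fst[usable]
    if n_use == 0 or np.ptp(x) == 0:
        raise ValueError("degenerate F_ST vector: cannot fit a distribution")
    lo_q, hi_q = np.quantile(x, [trim_low, 1.0 - trim_high])
    interior = x[(x >= lo_q) & (x <= hi_q)]
    fbar = float(interior.mean())

    def negloglik(df: float) -> float:
        # scaled chi-square truncated to the trim window
        scale = fbar / df
        ll = stats.chi2.logpdf(interior / scale, df) - np.log(scale)
        z = (stats.chi2.cdf(hi_q / scale, df)
             - stats.chi2.cdf(lo_q / scale, df))
        if z <= 0:
            return np.inf
        return float(-(ll.sum() - len(interior) * np.log(z)))

    opt = minimize_scalar(negloglik, bounds=(0.1, 200.0), method="bounded")
    df_hat = float(opt.x)
    scale = fbar / df_hat
    pvals = np.full(len(fst), np.nan)
    pvals[usable] = stats.chi2.sf(fst[usable] / scale, df_hat)
    qvals = np.full(len(fst), np.nan)
    qvals[usable] = multipletests(pvals[usable], method="fdr_bh")[1]
    out = pd.DataFrame(
        {"p_value": pvals, "q_value": qvals}, index=per_locus.index
    )
    out.attrs["df"] = df_hat
    out.attrs["fbar"] = fbar
    return out


def pc_regression_scan(
    g: GenotypeMatrix,
    K: int,
    min_maf: float = 0.0,
    robust: bool = True,
    random_state: int = 0,
) -> pd.DataFrame:
    """PCA-based scan: regress each SNP on K genotype PCs.

    Missing dosages are mean-imputed; loci are centred and scaled before
    the PCA over individuals.  The per-locus vector of K regression
    z-scores is summarised as a Mahalanobis distance (robust covariance by
    default), divided by a genomic inflation factor (median distance over
    the chi-square-K median) and referred to chisq(K) for p-values.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= min(g.n_samples, g.n_loci):
        raise ValueError("K must be < min(individuals, loci)")
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    p_hat = np.nanmean(d, axis=0) / 2.0
    col_mean = 2.0 * p_hat
    d = np.where(np.isnan(d), col_mean, d)
    sd = d.std(axis=0, ddof=0)
    poly = sd > 0
    maf = np.minimum(p_hat, 1 - p_hat)
    poly &= maf >= min_maf
    X = (d[:, poly] - col_mean[poly]) / sd[poly]

    # PCs over individuals from the thin SVD of the scaled genotype matrix
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :K] * S[:K]            # individuals x K
    # per-locus OLS of the scaled genotype on the K orthogonal scores
    norms = (scores ** 2).sum(axis=0)
    beta = (scores.T @ X) / norms[:, None]             # K x loci
    fitted = scores @ beta
    resid = X - fitted
    n = X.shape[0]
    dof = max(n - K - 1, 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2[None, :] / norms[:, None])
        z = beta / se                                   # K x loci
    z = z.T                                             # loci x K

    finite = np.isfinite(z).all(axis=1)
    d2 = np.full(z.shape[0], np.nan)
    zf = z[finite]
    if robust and zf.shape[0] > 5 * K:
        try:
            cov = MinCovDet(random_state=random_state).fit(zf)
            d2[finite] = cov.mahalanobis(zf)
        except Exception:  # singular support; fall back to classical
            robust = False
    if not robust or np.isnan(d2[finite]).any():
        mu = zf.mean(axis=0)
        cov = np.cov(zf, rowvar=False)
        cov = np.atleast_2d(cov)
        inv = np.linalg.pinv(cov)
        delta = zf - mu
        d2[finite] = np.einsum("ij,jk,ik->i", delta, inv, delta)

    gif = np.nanmedian(d2) / stats.chi2.median(K)
    pvals_poly = stats.chi2.sf(d2 / gif, K)
    qvals_poly = np.full(len(pvals_poly), np.nan)
    fin = np.isfinite(pvals_poly)
    qvals_poly[fin] = multipletests(pvals_poly[fin], method="fdr_bh")[1]

    pvals = np.full(g.n_loci, np.nan)
    qvals = np.full(g.n_loci, np.nan)
    pvals[np.flatnonzero(poly)] = pvals_poly
    qvals[np.flatnonzero(poly)] = qvals_poly
    out = pd.DataFrame({"p_value": pvals, "q_value": qvals},
                       index=g.locus_meta["id"])
    out.attrs["K"] = K
    out.attrs["gif"] = float(gif)
    out.attrs["singular_values"] = S[: min(20, len(S))].tolist()
    return out


def import_external_scan(
    path: str,
    locus_ids: pd.Index | list[str],
    method_label: str = "external",
) -> pd.Series:
    """Read a per-locus flag table from external software.

    Expected format: TSV with columns ``id`` and ``flag`` (0/1 or bool),
    optionally ``value`` (posterior probability or q-value, informational).
    Every id in the file must exist in ``locus_ids``.
    """
    t = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in t.columns or "flag" not in t.columns:
        raise ValueError("external scan file needs columns 'id' and 'flag'")
    idx = pd.Index(locus_ids)
    unknown = [i for i in t["id"] if i not in idx]
    if unknown:
        raise ValueError(f"external scan ids not in the dataset: {unknown[:10]}")
    flags = pd.Series(False, index=idx, name=method_label)
    flagged = t.loc[t["flag"].astype(bool), "id"]
    flags.loc[flagged] = True
    if not flags.any():
        warnings.warn(f"external scan {method_label!r} flags no loci", stacklevel=2)
    return flags


@dataclass
class OutlierReport:
    """Per-locus scan results, consensus tiers and the neutral locus set."""

    table: pd.DataFrame            # index: locus id; per-method flag/q columns
    methods: list[str]
    rule: str = "any"
    neutral_ids: list[str] = field(default_factory=list)
    outlier_ids: list[str] = field(default_factory=list)

    def neutral_indices(self, locus_ids: pd.Index | list[str]) -> np.ndarray:
        idx = pd.Index(locus_ids)
        return np.flatnonzero(idx.isin(self.neutral_ids))


def consensus_and_neutral_set(
    flags: pd.DataFrame, rule: str = "any",
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Combine per-method boolean flag columns into a consensus list.

    ``rule``: 'any' (a locus flagged by at least one method is an outlier;
    the convention that produces the usual neutral-set arithmetic),
    'at-least-2', or 'all'.  Returns the annotated table, the outlier ids
    and the complementary neutral ids (a partition of all loci).
    """
    if flags.shape[1] < 1:
        raise ValueError("at least one method column required")
    counts = flags.astype(bool).sum(axis=1)
    n_methods = flags.shape[1]
    tier = np.where(
        counts == 0, "none",
        np.where(counts == 1, "one-method",
                 np.where(counts < n_methods, "two-methods", "all-methods")),
    )
    # with exactly two methods, "both" is the all-methods tier
    if n_methods == 2:
        tier = np.where(counts == 2, "all-methods", tier)
    thresholds = {"any": 1, "at-least-2": 2, "all": n_methods}
    if rule not in thresholds:
        raise ValueError(f"unknown consensus rule {rule!r}")
    is_outlier = counts >= thresholds[rule]
    out = flags.copy()
    out["n_methods_flagging"] = counts
    out["consensus_tier"] = tier
    out["consensus_outlier"] = is_outlier
    outlier_ids = list(out.index[is_outlier])
    neutral_ids = list(out.index[~is_outlier])
    return out, outlier_ids, neutral_ids


def build_report(
    g: GenotypeMatrix,
    pmap: PopulationMap,
    level: str = "region",
    K: int | None = None,
    q_threshold: float = 0.05,
    trim_low: float = 0.05,
    trim_high: float = 0.05,
    he_min: float = 0.10,
    rule: str = "any",
    external: dict[str, str] | None = None,
    random_state: int = 0,
) -> OutlierReport:
    """Run both scans (plus optional imports) and form the consensus."""
    per_locus = per_locus_fst_uncorrected(g, pmap, level)
    chi2_res = trimmed_chi2_scan(per_locus, trim_low, trim_high, he_min)
    if K is None:
        K = max(1, len(pmap.groups(level)) - 1)
    pca_res = pc_regression_scan(g, K, random_state=random_state)

    idx = pd.Index(g.locus_meta["id"])
    flags = pd.DataFrame(index=idx)
    flags["trimmed_chi2"] = (chi2_res["q_value"] < q_threshold).fillna(False).to_numpy()
    flags["pc_regression"] = (pca_res["q_value"] < q_threshold).fillna(False).to_numpy()
    for label, path in (external or {}).items():
        flags[label] = import_external_scan(path, idx, label).to_numpy()

    combined, outlier_ids, neutral_ids = consensus_and_neutral_set(flags, rule)
    table = pd.concat(
        [per_locus.set_axis(idx),
         chi2_res.add_prefix("chi2_").set_axis(idx),
         pca_res.add_prefix("pca_").set_axis(idx),
         combined],
        axis=1,
    )
    logger.info("outlier scan: %d of %d loci flagged (%s rule)",
                len(outlier_ids), len(idx), rule)
    return OutlierReport(
        table=table, methods=list(flags.columns), rule=rule,
        neutral_ids=neutral_ids, outlier_ids=outlier_ids,
    )
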