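"""Population-genetic summary statistics on diploid dosage matrices.

Implements the neutral-structure toolkit of the pipeline: observed and
expected heterozygosity, rarefied allelic richness, the inbreeding
coefficient F_IS, the multi-locus Weir-Cockerham theta (F_ST) with a
percentile bootstrap over loci, and effective population size from
inter-locus linkage disequilibrium (Burrows composite measure with the
standard small-sample bias adjustment, random-mating model).

All statistics ignore missing genotypes: each locus is summarised over the
individuals genotyped at that locus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "unit_counts",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "allelic_richness",
    "inbreeding_coefficient",
    "wc_fst",
    "multilocus_theta",
    "FstResult",
    "ld_ne",
    "NeEstimate",
    "diversity_table",
    "pairwise_fst_table",
]


def _unit_rows(g: GenotypeMatrix, pmap: PopulationMap, unit: str, level: str) -> list[int]:
    ids = set(pmap.individuals_in(level, unit))
    rows = [i for i, s in enumerate(g.sample_ids) if s in ids]
    if not rows:
        raise ValueError(f"no genotyped individuals in {level} {unit!r}")
    return rows


def unit_counts(g: GenotypeMatrix, rows: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n genotyped, alt-allele frequency, het proportion) in a unit."""
    d = g.dosage[rows, :]
    called = d != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, np.where(called, d == 1, False).sum(axis=0) / n, np.nan)
    return n, p, h


def _polymorphic(p: np.ndarray) -> np.ndarray:
    return np.isfinite(p) & (p > 0) & (p < 1)


def observed_heterozygosity(
    g: GenotypeMatrix, pmap: PopulationMap, unit: str, level: str = "region",
    polymorphic_only: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-locus heterozygote fraction and its unit mean.

    The mean is taken over loci polymorphic within the unit by default
    (matching the usual reporting convention for RAD panels); pass
    ``polymorphic_only=False`` to average over all genotyped loci.
    """
    rows = _unit_rows(g, pmap, unit, level)
    n, p, h = unit_counts(g, rows)
    if not (n > 0).any():
        raise ValueError(f"no genotype calls in {level} {unit!r}")
    sel = _polymorphic(p) if polymorphic_only else np.isfinite(p)
    mean = float(np.nanmean(h[sel])) if sel.any() else float("nan")
    return h, mean


def expected_heterozygosity(
    g: GenotypeMatrix, pmap: PopulationMap, unit: str, level: str = "region",
    polymorphic_only: bool = True, unbiased: bool = False,
) -> tuple[np.ndarray, float]:
    """Per-locus gene diversity 2p(1-p) and its unit mean.

    ``unbiased`` applies the 2n/(2n-1) small-sample correction.
    """
    rows = _unit_rows(g, pmap, unit, level)
    n, p, _ = unit_counts(g, rows)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(n > 0, he * (2.0 * n) / np.maximum(2.0 * n - 1, 1), np.nan)
    sel = _polymorphic(p) if polymorphic_only else np.isfinite(p)
    mean = float(np.nanmean(he[sel])) if sel.any() else float("nan")
    return he, mean


def allelic_richness(
    g: GenotypeMatrix, pmap: PopulationMap, unit: str, level: str = "region",
    g_rarefaction: int | None = None,
) -> tuple[np.ndarray, float]:
    """Rarefied allelic richness per locus and its unit mean.

    For a locus with 2N sampled alleles of which n_a copies are allele a,
    the expected number of distinct alleles in a random subsample of g
    alleles is sum_a [1 - C(2N - n_a, g) / C(2N, g)].  When unset, g is
    rarefied to the smallest per-locus allele sample across all units of
    the level, so every unit is compared at a common depth.
    """
    if g_rarefaction is None:
        mins = []
        for u in pmap.groups(level):
            n_u, _, _ = unit_counts(g, _unit_rows(g, pmap, u, level))
            pos = n_u[n_u > 0]
            if len(pos):
                mins.append(2 * int(pos.min()))
        if not mins:
            raise ValueError("no genotyped loci in any unit")
        g_rarefaction = min(mins)
    if g_rarefaction < 2:
        raise ValueError("rarefaction size must be >= 2 alleles")
    rows = _unit_rows(g, pmap, unit, level)
    n, p, _ = unit_counts(g, rows)
    two_n = 2.0 * n
    alt = np.round(p * two_n)
    ar = np.full(g.n_loci, np.nan)
    ok = n > 0
    for counts in (alt, two_n - alt):
        m = two_n - counts  # alleles left after removing this allele's copies
        with np.errstate(invalid="ignore"):
            log_ratio = (
                gammaln(m + 1) - gammaln(m - g_rarefaction + 1)
                - gammaln(two_n + 1) + gammaln(two_n - g_rarefaction + 1)
            )
        prob_absent = np.where(m >= g_rarefaction, np.exp(log_ratio), 0.0)
        term = np.where(counts > 0, 1.0 - prob_absent, 0.0)
        ar = np.where(ok, np.nan_to_num(ar, nan=0.0) + term, np.nan)
    usable = ok & (two_n >= g_rarefaction)
    ar = np.where(usable, ar, np.nan)
    mean = float(np.nanmean(ar[usable])) if usable.any() else float("nan")
    return ar, mean


def inbreeding_coefficient(
    g: GenotypeMatrix, pmap: PopulationMap, unit: str, level: str = "region",
) -> float:
    """F_IS = 1 - sum(Ho) / sum(He) over loci polymorphic within the unit."""
    rows = _unit_rows(g, pmap, unit, level)
    n, p, h = unit_counts(g, rows)
    sel = _polymorphic(p)
    if not sel.any():
        warnings.warn(f"{level} {unit!r} has no polymorphic loci; F_IS undefined",
                      stacklevel=2)
        return float("nan")
    he = 2.0 * p[sel] * (1.0 - p[sel])
    return float(1.0 - h[sel].sum() / he.sum())


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def _wc_components(
    g: GenotypeMatrix, unit_rows: list[list[int]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) plus a usability mask.

    a: among populations; b: among individuals within populations;
    c: within individuals.  Loci where any unit has no genotype calls, or
    with a degenerate design (mean sample size <= 1), are masked out.
    """
    r = len(unit_rows)
    n = np.stack([unit_counts(g, rows)[0] for rows in unit_rows]).astype(float)
    p = np.stack([unit_counts(g, rows)[1] for rows in unit_rows])
    h = np.stack([unit_counts(g, rows)[2] for rows in unit_rows])
    ok = (n >= 1).all(axis=0)
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    ok &= (nbar > 1) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (nc > 0)
    return a, b, c, ok


@dataclass
class FstResult:
    """Multi-locus Weir-Cockerham theta for one pair of units."""

    unit_a: str
    unit_b: str
    theta: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    per_locus_theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_loci_used: int = 0

    def __str__(self) -> str:  # Table-2-style cell
        return f"{self.theta:.3f} ({self.ci_low:.2f}–{self.ci_high:.2f})"


def wc_fst(
    g: GenotypeMatrix,
    pmap: PopulationMap,
    unit_a: str,
    unit_b: str,
    level: str = "region",
    bootstrap_reps: int = 1000,
    rng: np.random.Generator | None = None,
    ci_mass: float = 0.95,
) -> FstResult:
    """Pairwise multi-locus theta with a percentile bootstrap CI over loci.

    theta is the ratio of sums over loci of the among-population component a
    to the total a + b + c (ratio-of-averages estimator); loci with zero
    total variance are excluded.
    """
    rows = [_unit_rows(g, pmap, pmap_unit, level) for pmap_unit in (unit_a, unit_b)]
    if any(len(rw) < 2 for rw in rows):
        raise ValueError("each unit needs >= 2 genotyped individuals")
    a, b, c, ok = _wc_components(g, rows)
    tot = a + b + c
    use = ok & (tot != 0)
    if use.sum() < 2:
        raise ValueError("fewer than 2 usable loci; cannot estimate theta or CI")
    a_use, tot_use = a[use], tot[use]
    theta = float(a_use.sum() / tot_use.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(use, a / tot, np.nan)
    lo = hi = float("nan")
    if bootstrap_reps > 0:
        rng = rng or np.random.default_rng()
        L = len(a_use)
        idx = rng.integers(0, L, size=(bootstrap_reps, L))
        reps = a_use[idx].sum(axis=1) / tot_use[idx].sum(axis=1)
        alpha = (1.0 - ci_mass) / 2.0
        lo, hi = (float(q) for q in np.quantile(reps, [alpha, 1.0 - alpha]))
    return FstResult(
        unit_a=unit_a, unit_b=unit_b, theta=theta, ci_low=lo, ci_high=hi,
        per_locus_theta=per_locus, n_loci_used=int(use.sum()),
    )


def multilocus_theta(
    g: GenotypeMatrix, pmap: PopulationMap, level: str = "region",
    units: list[str] | None = None,
    bootstrap_reps: int = 0,
    rng: np.random.Generator | None = None,
    ci_mass: float = 0.95,
) -> float | tuple[float, float, float]:
    """Multi-locus theta over all units at a level.

    With ``bootstrap_reps`` > 0, also returns the percentile bootstrap CI
    (over loci) as ``(theta, lo, hi)``.
    """
    units = units or pmap.groups(level)
    rows = [_unit_rows(g, pmap, u, level) for u in units]
    a, b, c, ok = _wc_components(g, rows)
    tot = a + b + c
    use = ok & (tot != 0)
    if not use.any():
        raise ValueError("no usable loci")
    a_use, tot_use = a[use], tot[use]
    theta = float(a_use.sum() / tot_use.sum())
    if bootstrap_reps <= 0:
        return theta
    rng = rng or np.random.default_rng()
    L = len(a_use)
    idx = rng.integers(0, L, size=(bootstrap_reps, L))
    reps = a_use[idx].sum(axis=1) / tot_use[idx].sum(axis=1)
    alpha = (1.0 - ci_mass) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return theta, float(lo), float(hi)


# ---------------------------------------------------------------------------
# Linkage-disequilibrium effective population size


@dataclass
class NeEstimate:
    ne: float                      # point estimate; may be math.inf
    r2_mean: float                 # weighted mean squared correlation
    r2_drift: float                # after sample-size bias adjustment
    n_loci: int
    n_pairs: int
    s_mean: float                  # weighted mean pairwise sample size
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def _expected_r2_no_drift(s: float) -> float:
    """Sampling expectation of r^2 with no drift signal (random mating)."""
    if s >= 30:
        return 1.0 / s + 3.19 / s ** 2
    return 0.0018 + 0.907 / s + 4.44 / s ** 2


def _ne_from_r2_drift(r2d: float) -> float:
    if r2d <= 0:
        return math.inf
    disc = 1.0 / 9.0 - 2.76 * r2d
    if disc < 0:
        return math.inf
    return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2d)


def ld_ne(
    g: GenotypeMatrix,
    pmap: PopulationMap | None = None,
    unit: str | None = None,
    level: str = "region",
    maf_crit: float = 0.05,
    jackknife_ci: bool = False,
) -> NeEstimate:
    """LD-based effective population size (random-mating model).

    For every pair of loci passing the allele-frequency screen, the Burrows
    composite disequilibrium Delta is computed over individuals genotyped at
    both loci, squared and standardised by p(1-p)q(1-q).  The weighted mean
    (weights = pairwise sample size S) is corrected by the no-drift sampling
    expectation of r^2, and Ne follows from the random-mating drift
    relation; a non-positive drift signal yields an infinite estimate.
    An optional delete-one-locus jackknife gives a CI.
    """
    if pmap is not None and unit is not None:
        rows = _unit_rows(g, pmap, unit, level)
    else:
        rows = list(range(g.n_samples))
    if len(rows) < 10:
        warnings.warn("fewer than 10 individuals: LD-Ne will be unstable",
                      stacklevel=2)
    d = g.dosage[rows, :].astype(float)
    mask = (g.dosage[rows, :] != MISSING).astype(float)
    d = d * mask  # missing entries contribute 0

    n_per = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_per > 0, d.sum(axis=0) / (2 * n_per), np.nan)
    maf = np.minimum(freq, 1 - freq)
    keep = np.isfinite(maf) & (maf >= maf_crit)
    if keep.sum() < 2:
        raise ValueError("need >= 2 loci passing the allele-frequency screen")
    d, mask = d[:, keep], mask[:, keep]
    L = d.shape[1]

    # pairwise-complete sums via matrix products
    N = mask.T @ mask                      # individuals complete for the pair
    Sx = d.T @ mask                        # sum of locus-i dosage on complete set
    Sxy = d.T @ d
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = Sx / (2 * N)
        p2 = p1.T
        # Burrows composite disequilibrium with the n/(n-1) bias correction
        delta = (N / (N - 1)) * (Sxy / (2 * N) - 2 * p1 * p2)
        denom = p1 * (1 - p1) * p2 * (1 - p2)
        r2 = np.where(denom > 0, delta ** 2 / denom, np.nan)

    iu = np.triu_indices(L, k=1)
    r2_pairs = r2[iu]
    s_pairs = N[iu]
    good = np.isfinite(r2_pairs) & (s_pairs >= 2)
    r2_pairs, s_pairs = r2_pairs[good], s_pairs[good]
    if len(r2_pairs) == 0:
        raise ValueError("no usable locus pairs")
    w = s_pairs
    r2_mean = float((w * r2_pairs).sum() / w.sum())
    s_mean = float((w * s_pairs).sum() / w.sum())
    r2_drift = r2_mean - _expected_r2_no_drift(s_mean)
    ne = _ne_from_r2_drift(r2_drift)

    est = NeEstimate(
        ne=ne, r2_mean=r2_mean, r2_drift=r2_drift, n_loci=int(L),
        n_pairs=int(len(r2_pairs)), s_mean=s_mean,
    )
    if jackknife_ci and L > 2:
        # delete-one-locus recomputation from per-locus pair sums
        full = np.nan_to_num(np.where(np.isfinite(r2), r2, 0.0))
        wfull = np.where(np.isfinite(r2), N, 0.0)
        np.fill_diagonal(full, 0.0)
        np.fill_diagonal(wfull, 0.0)
        num_rows = (wfull * full).sum(axis=1)
        w_rows = wfull.sum(axis=1)
        tot_num = num_rows.sum() / 2
        tot_w = w_rows.sum() / 2
        r2_jk = (tot_num - num_rows) / (tot_w - w_rows)
        theta_bar = r2_jk.mean()
        se = math.sqrt((L - 1) / L * ((r2_jk - theta_bar) ** 2).sum())
        lo_r2, hi_r2 = r2_mean - 1.96 * se, r2_mean + 1.96 * se
        adj = _expected_r2_no_drift(s_mean)
        # Ne is decreasing in r^2, so the CI ends swap through the transform
        est.ci_low = _ne_from_r2_drift(hi_r2 - adj)
        est.ci_high = _ne_from_r2_drift(lo_r2 - adj)
    return est


# ---------------------------------------------------------------------------
# Reporting tables


def diversity_table(
    g: GenotypeMatrix,
    pmap: PopulationMap,
    level: str = "region",
    g_rarefaction: int | None = None,
    estimate_ne: bool = True,
    maf_crit: float = 0.05,
) -> pd.DataFrame:
    """Per-unit diversity summary (N, Ar, Ho, He, Ne, F_IS)."""
    rows = []
    for u in pmap.groups(level):
        unit_ids = set(pmap.individuals_in(level, u))
        n_ind = sum(1 for s in g.sample_ids if s in unit_ids)
        _, ho = observed_heterozygosity(g, pmap, u, level)
        _, he = expected_heterozygosity(g, pmap, u, level)
        _, ar = allelic_richness(g, pmap, u, level, g_rarefaction)
        fis = inbreeding_coefficient(g, pmap, u, level)
        ne = float("nan")
        if estimate_ne:
            try:
                ne = ld_ne(g, pmap, u, level, maf_crit=maf_crit).ne
            except ValueError:
                pass
        rows.append({
            "unit": u,
            "range": pmap.table.loc[pmap.individuals_in(level, u)[0], "range"],
            "N": n_ind, "Ar": ar, "Ho": ho, "He": he, "Ne": ne, "Fis": fis,
        })
    return pd.DataFrame(rows)


def pairwise_fst_table(
    g: GenotypeMatrix,
    pmap: PopulationMap,
    level: str = "region",
    bootstrap_reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], FstResult]]:
    """Lower-triangular pairwise theta matrix with CI strings, plus results."""
    units = pmap.groups(level)
    rng = rng or np.random.default_rng()
    results: dict[tuple[str, str], FstResult] = {}
    cells = pd.DataFrame("-", index=units[1:], columns=units[:-1])
    for i, ua in enumerate(units):
        for ub in units[i + 1:]:
            res = wc_fst(g, pmap, ua, ub, level, bootstrap_reps, rng)
            results[(ua, ub)] = res
            cells.loc[ub, ua] = str(res)
    return cells, results
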