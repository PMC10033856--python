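"""Linkage-disequilibrium estimator of contemporary effective population size.

The single-sample LD method exploits the fact that in a closed,
randomly-mating population of effective size Ne, drift generates
associations between alleles at unlinked loci with expectation
E[r²_drift] ≈ 1/(3Ne).  The observable squared correlation of allele
dosages also carries a sampling component that depends only on the sample
size S, so subtracting the expected sample contribution and inverting the
(quadratic-corrected) relation yields an estimate of Ne.

Pipeline pieces implemented here:

* allele screening (p-crit frequency thresholds; singleton exclusion),
* the Burrows composite measure of LD between allele pairs, computed on
  individuals complete at both loci,
* the point estimator with the published small-/large-sample coefficient
  sets (random-mating and monogamy),
* jackknife (over individuals or over loci) and parametric chi-square
  confidence intervals,
* locus-subsampling runs to quantify pseudoreplication in genomic CIs,
* the physical-linkage bias correction Ne / (0.098 + 0.219 ln(n_chrom)),
* generation-time arithmetic T = alpha + s/(1-s) and Ne/N census ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clonal import ClonalPartition
from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

P_CRIT_DEFAULTS = (0.05, 0.02, 0.01, 0.0)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenedData:
    """Alleles retained per locus after frequency and singleton screening."""

    locus_indices: list[int]              # loci that survive (>= 2 retained alleles)
    retained: dict[int, list[int]]        # locus index -> retained allele codes
    p_crit: float
    drop_singletons: bool
    n_excluded_loci: int = 0

    @property
    def n_loci(self) -> int:
        return len(self.locus_indices)


def screen_alleles(g: GenotypeMatrix, p_crit: float = 0.0,
                   drop_singletons: bool = True,
                   sample_idx: np.ndarray | None = None) -> ScreenedData:
    """Mask rare alleles per locus before LD estimation.

    An allele is retained when its frequency among genotyped individuals
    is >= ``p_crit`` and (with ``drop_singletons``) it occurs in more
    than one copy — a singleton being an allele carried by exactly one
    heterozygote.  Loci left with fewer than two retained alleles drop
    out of estimation entirely.
    """
    if not (0 <= p_crit < 0.5):
        raise ValueError("p_crit must be in [0, 0.5)")
    idx = np.arange(g.n_samples) if sample_idx is None else np.asarray(sample_idx)
    retained: dict[int, list[int]] = {}
    kept_loci: list[int] = []
    n_excluded = 0
    for j in range(g.n_loci):
        counts = g.allele_counts(j, sample_idx=idx)
        tot = sum(counts.values())
        keep = []
        for a, c in sorted(counts.items()):
            if tot and c / tot >= p_crit and (not drop_singletons or c >= 2):
                keep.append(a)
        if len(keep) >= 2:
            kept_loci.append(j)
            retained[j] = keep
        else:
            n_excluded += 1
    if n_excluded:
        logger.info("screen_alleles: %d locus(es) fully masked", n_excluded)
    return ScreenedData(
        locus_indices=kept_loci, retained=retained, p_crit=p_crit,
        drop_singletons=drop_singletons, n_excluded_loci=n_excluded,
    )


# ---------------------------------------------------------------------------
# Burrows composite r^2
# ---------------------------------------------------------------------------

def burrows_r2_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Burrows composite r̂² for one allele pair from dosage vectors.

    ``x`` and ``y`` are copy counts (0/1/2) with NaN for missing; only
    individuals complete at both loci enter.  The composite disequilibrium
    Δ̂ = (Σ x_i y_i)/(2S) − 2 p̂_x p̂_y, rescaled by S/(S−1), is squared and
    divided by the product of Burrows-adjusted allele variances
    p(1−p) + (ĥ − p²) with ĥ the homozygote frequency for the allele.

    Returns (r̂², S).  r̂² is NaN when S < 2 or a denominator vanishes.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    S = int(ok.sum())
    if S < 2:
        return float("nan"), S
    xs, ys = x[ok], y[ok]
    px, py = xs.mean() / 2.0, ys.mean() / 2.0
    hx, hy = (xs == 2).mean(), (ys == 2).mean()
    delta = ((xs * ys).sum() / (2.0 * S) - 2.0 * px * py) * S / (S - 1.0)
    den = (px * (1 - px) + (hx - px ** 2)) * (py * (1 - py) + (hy - py ** 2))
    if den <= 0:
        return float("nan"), S
    return float(delta ** 2 / den), S


def _dosage_columns(g: GenotypeMatrix, screened: ScreenedData,
                    sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dosage matrix (S x K) and per-column locus ids.

    Biallelic loci contribute a single column (the two pairings are
    redundant: same r̂²); multiallelic loci contribute one column per
    retained allele, each comparison weighted equally.
    """
    cols, locus_of = [], []
    for j in screened.locus_indices:
        alleles = screened.retained[j]
        use = alleles[:1] if len(alleles) == 2 else alleles
        for a in use:
            pair = g.alleles[sample_idx, j, :]
            d = (pair == a).sum(axis=1).astype(float)
            d[pair[:, 0] == MISSING] = np.nan
            cols.append(d)
            locus_of.append(j)
    if not cols:
        return np.empty((len(sample_idx), 0)), np.empty(0, dtype=int)
    return np.column_stack(cols), np.asarray(locus_of, dtype=int)


def _pairwise_r2(X: np.ndarray, locus_of: np.ndarray,
                 return_per_locus: bool = False):
    """All between-locus Burrows r̂² comparisons, vectorised.

    Returns (sum_r2, n_pairs, sum_inv_S, optionally per-locus totals).
    Per-pair allele frequencies and homozygote frequencies are computed
    on the individuals complete at both loci, matching the pairwise
    handling of missing data in the reference LD-Ne implementations.
    """
    S, K = X.shape
    if K < 2:
        zero = (0.0, 0, 0.0)
        if return_per_locus:
            empty = (np.zeros(0, dtype=int), np.zeros(0), np.zeros(0, dtype=int), np.zeros(0))
            return zero + (empty,)
        return zero
    has_missing = np.isnan(X).any()
    diff_locus = locus_of[:, None] != locus_of[None, :]
    upper = np.triu(np.ones((K, K), dtype=bool), k=1)
    valid = diff_locus & upper

    if not has_missing:
        p = X.mean(axis=0) / 2.0
        h = (X == 2).mean(axis=0)
        Sxy = X.T @ X
        delta = (Sxy / (2.0 * S) - 2.0 * np.outer(p, p)) * (S / (S - 1.0))
        den_col = p * (1 - p) + (h - p ** 2)
        den = np.outer(den_col, den_col)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = delta ** 2 / den
        valid &= den > 0
        n_pair_S = np.full((K, K), float(S))
    else:
        M = (~np.isnan(X)).astype(float)
        X0 = np.nan_to_num(X)
        Z = (X == 2).astype(float)
        S_ab = M.T @ M
        Sxy = X0.T @ X0
        sum_x = X0.T @ M       # row a, col b: sum of x_a over pair-complete
        sum_h = Z.T @ M
        with np.errstate(divide="ignore", invalid="ignore"):
            pA = sum_x / (2.0 * S_ab)
            pB = pA.T
            hA = sum_h / S_ab
            hB = hA.T
            delta = (Sxy / (2.0 * S_ab) - 2.0 * pA * pB) * (S_ab / (S_ab - 1.0))
            denA = pA * (1 - pA) + (hA - pA ** 2)
            denB = pB * (1 - pB) + (hB - pB ** 2)
            den = denA * denB
            r2 = delta ** 2 / den
        valid &= (S_ab >= 2) & (den > 0)
        n_pair_S = S_ab

    r2v = r2[valid]
    Sv = n_pair_S[valid]
    out = (float(r2v.sum()), int(r2v.size), float((1.0 / Sv).sum()))
    if return_per_locus:
        # per-locus sums of r2 and counts over pairs involving that locus
        loci = np.unique(locus_of)
        sums = np.zeros(loci.size)
        cnts = np.zeros(loci.size, dtype=int)
        invs = np.zeros(loci.size)
        pos = {l: i for i, l in enumerate(loci)}
        ii, jj = np.nonzero(valid)
        for a, b, r, s in zip(locus_of[ii], locus_of[jj], r2[valid], n_pair_S[valid]):
            for l in (a, b):
                sums[pos[l]] += r
                cnts[pos[l]] += 1
                invs[pos[l]] += 1.0 / s
        return out + ((loci, sums, cnts, invs),)
    return out


# ---------------------------------------------------------------------------
# Point estimator
# ---------------------------------------------------------------------------

def sample_r2_component(S: float, mating: str = "random",
                        branch_at: float = 30.0) -> float:
    """Expected sampling contribution to r̂² for sample size S."""
    if S <= 2:
        raise ValueError("sample size must exceed 2")
    if S >= branch_at:
        return 1.0 / S + 3.19 / S ** 2
    return 0.0018 + 0.907 / S + 4.44 / S ** 2


def ldne_point(r2_mean: float, S_harm: float, mating: str = "random",
               branch_at: float = 30.0) -> float:
    """Invert drift-corrected r̂² to an Ne estimate.

    Subtracts the sampling component, then solves the quadratic relation
    between E[r²_drift] and Ne with the published coefficient sets.
    A non-positive drift signal maps to +inf (no evidence of drift at
    this sample size).  A drift signal beyond the quadratic's validity
    range (discriminant < 0, only reachable for very small Ne) floors
    the discriminant at zero so the mapping stays monotone decreasing.
    """
    if S_harm <= 2:
        raise ValueError("harmonic mean sample size must exceed 2")
    r2p = r2_mean - sample_r2_component(S_harm, mating, branch_at)
    if r2p <= 0:
        return float("inf")
    if mating == "random":
        if S_harm >= branch_at:
            b, c = 1.0 / 3.0, 2.76
        else:
            b, c = 0.308, 2.08
    elif mating == "monogamy":
        if S_harm >= branch_at:
            b, c = 2.0 / 3.0, 7.2
        else:
            b, c = 0.618, 5.24
    else:
        raise ValueError(f"unknown mating model {mating!r}")
    disc = max(b ** 2 - c * r2p, 0.0)
    ne = (b + np.sqrt(disc)) / (2.0 * r2p)
    return float(ne) if ne > 0 else float("inf")


# ---------------------------------------------------------------------------
# Full estimation with CIs
# ---------------------------------------------------------------------------

@dataclass
class LDNeResult:
    p_crit: float
    drop_singletons: bool
    r2_mean: float
    S_harm: float
    n_comparisons: int
    n_loci_used: int
    ne_point: float
    ci_jackknife: tuple[float, float] | None = None
    ci_parametric: tuple[float, float] | None = None
    effective_df: float = float("nan")
    mating: str = "random"
    extra: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "p_crit": self.p_crit,
            "drop_singletons": self.drop_singletons,
            "r2_mean": self.r2_mean,
            "S_harm": self.S_harm,
            "n_comparisons": self.n_comparisons,
            "n_loci_used": self.n_loci_used,
            "ne_point": self.ne_point,
            "ci_jackknife": list(self.ci_jackknife) if self.ci_jackknife else None,
            "ci_parametric": list(self.ci_parametric) if self.ci_parametric else None,
            "effective_df": self.effective_df,
            "mating": self.mating,
            **self.extra,
        }


def _chi2_ci_on_r2(r2_mean: float, df: float, alpha: float) -> tuple[float, float]:
    lo = r2_mean * df / stats.chi2.ppf(1 - alpha / 2, df)
    hi = r2_mean * df / stats.chi2.ppf(alpha / 2, df)
    return lo, hi


def _map_r2_ci_to_ne(r2_lo: float, r2_hi: float, S_harm: float, mating: str,
                     branch_at: float) -> tuple[float, float]:
    # ldne_point is decreasing in r2: high r2 -> low Ne
    ne_lo = ldne_point(r2_hi, S_harm, mating, branch_at)
    ne_hi = ldne_point(r2_lo, S_harm, mating, branch_at)
    return (min(ne_lo, ne_hi), max(ne_lo, ne_hi))


def parametric_ci(r2_mean: float, n_comparisons: int, S_harm: float,
                  alpha: float = 0.05, mating: str = "random",
                  branch_at: float = 30.0) -> tuple[float, float]:
    """Chi-square CI treating every comparison as an independent df.

    With thousands of loci this is generally too narrow, because the
    comparisons share the same sampled individuals (pseudoreplication);
    compare with the jackknife CI.
    """
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    r2_lo, r2_hi = _chi2_ci_on_r2(r2_mean, float(n_comparisons), alpha)
    return _map_r2_ci_to_ne(r2_lo, r2_hi, S_harm, mating, branch_at)


def ld_ne(g: GenotypeMatrix, p_crit: float = 0.0, drop_singletons: bool = True,
          partition: ClonalPartition | None = None, level: str = "raw",
          mating: str = "random", alpha: float = 0.05,
          ci: tuple[str, ...] = ("jackknife", "parametric"),
          jackknife_axis: str = "samples", branch_at: float = 30.0,
          sample_idx: np.ndarray | None = None) -> LDNeResult:
    """Full LD-Ne estimation on one sample set.

    Screening, all between-locus Burrows comparisons, the point estimate
    at the harmonic-mean comparison sample size, and the requested
    confidence intervals.  ``level``/``partition`` select clone-corrected
    data (LD at the ramet level reflects clonal replication, not drift,
    so Ne should be estimated on genets).

    ``jackknife_axis``: "samples" deletes one individual at a time
    (default); "loci" deletes one locus at a time.
    """
    if sample_idx is None:
        if level == "raw" or partition is None:
            sample_idx = np.arange(g.n_samples)
        else:
            sample_idx = partition.representatives(level)
    sample_idx = np.asarray(sample_idx)
    screened = screen_alleles(g, p_crit, drop_singletons, sample_idx)
    X, locus_of = _dosage_columns(g, screened, sample_idx)
    want_loci_jk = "jackknife" in ci and jackknife_axis == "loci"
    res = _pairwise_r2(X, locus_of, return_per_locus=want_loci_jk)
    sum_r2, n_cmp, sum_invS = res[:3]
    if n_cmp == 0:
        raise ValueError("no valid locus-pair comparisons after screening")
    r2_mean = sum_r2 / n_cmp
    S_harm = n_cmp / sum_invS
    point = ldne_point(r2_mean, S_harm, mating, branch_at)
    result = LDNeResult(
        p_crit=p_crit, drop_singletons=drop_singletons, r2_mean=float(r2_mean),
        S_harm=float(S_harm), n_comparisons=int(n_cmp),
        n_loci_used=screened.n_loci, ne_point=point, mating=mating,
    )
    if "parametric" in ci:
        result.ci_parametric = parametric_ci(
            r2_mean, n_cmp, S_harm, alpha, mating, branch_at
        )
    if "jackknife" in ci:
        if jackknife_axis == "samples":
            thetas = []
            n = len(sample_idx)
            if n < 10:
                raise ValueError("jackknife over samples needs >= 10 individuals")
            for i in range(n):
                Xi = np.delete(X, i, axis=0)
                s_r2, c, s_inv = _pairwise_r2(Xi, locus_of)
                if c:
                    thetas.append(s_r2 / c)
            thetas = np.asarray(thetas)
        elif jackknife_axis == "loci":
            loci, sums, cnts, _ = res[3]
            thetas = np.array([
                (sum_r2 - sums[k]) / (n_cmp - cnts[k])
                for k in range(loci.size) if n_cmp > cnts[k]
            ])
        else:
            raise ValueError(f"unknown jackknife axis {jackknife_axis!r}")
        nJ = thetas.size
        V_J = (nJ - 1) / nJ * np.sum((thetas - thetas.mean()) ** 2)
        if V_J <= 0:
            logger.warning("jackknife variance is zero; degenerate CI")
            result.ci_jackknife = (point, point)
            result.effective_df = float("inf")
        else:
            ndf = 2.0 * r2_mean ** 2 / V_J
            result.effective_df = float(ndf)
            r2_lo, r2_hi = _chi2_ci_on_r2(r2_mean, ndf, alpha)
            result.ci_jackknife = _map_r2_ci_to_ne(
                r2_lo, r2_hi, S_harm, mating, branch_at
            )
    return result


def ld_ne_profile(g: GenotypeMatrix, p_crits=P_CRIT_DEFAULTS,
                  **kwargs) -> list[LDNeResult]:
    """Run :func:`ld_ne` across the standard p-crit screening ladder."""
    return [ld_ne(g, p_crit=pc, **kwargs) for pc in p_crits]


# ---------------------------------------------------------------------------
# Locus subsampling (pseudoreplication experiment)
# ---------------------------------------------------------------------------

@dataclass
class SubsampleResult:
    per_subset: list[LDNeResult]
    median_ne: float
    empirical_ci: tuple[float, float]
    loci_per_subset: int
    n_subsets: int

    def to_dict(self):
        return {
            "n_subsets": self.n_subsets,
            "loci_per_subset": self.loci_per_subset,
            "median_ne": self.median_ne,
            "empirical_ci": list(self.empirical_ci),
            "per_subset_ne": [r.ne_point for r in self.per_subset],
            "per_subset_df": [r.effective_df for r in self.per_subset],
        }


def subsample_loci_ne(g: GenotypeMatrix, n_subsets: int = 40,
                      loci_per_subset: int = 800, seed: int = 0,
                      **ldne_kwargs) -> SubsampleResult:
    """LD-Ne over random locus subsets, with median and empirical CI.

    Each subset draws ``loci_per_subset`` loci without replacement
    (subsets independent of each other), runs the full estimator, and the
    spread of the per-subset point estimates gives an empirical 2.5/97.5
    percentile interval.  Because the subsets reuse the same individuals,
    this interval ignores individual-sampling uncertainty and is
    expected to be narrower than the jackknife CI.
    """
    if loci_per_subset > g.n_loci:
        raise ValueError(
            f"requested {loci_per_subset} loci per subset but only "
            f"{g.n_loci} available; reduce loci_per_subset"
        )
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_subsets):
        pick = np.sort(rng.choice(g.n_loci, size=loci_per_subset, replace=False))
        sub = g.subset(locus_idx=pick)
        results.append(ld_ne(sub, **ldne_kwargs))
    nes = np.array([r.ne_point for r in results])
    med = float(np.median(nes))
    lo, hi = np.percentile(nes, [2.5, 97.5])
    return SubsampleResult(
        per_subset=results, median_ne=med, empirical_ci=(float(lo), float(hi)),
        loci_per_subset=loci_per_subset, n_subsets=n_subsets,
    )


# ---------------------------------------------------------------------------
# Bias corrections and census arithmetic
# ---------------------------------------------------------------------------

def linkage_bias_correction(ne_point: float, n_chrom_haploid: int,
                            divisor_precision: int | None = 2) -> tuple[float, float]:
    """Correct the downward bias caused by physical linkage among loci.

    With thousands of loci packed on few chromosomes many locus pairs are
    physically linked, inflating mean r² and deflating Ne.  The expected
    proportional bias depends on the haploid chromosome number n:
    divisor = 0.098 + 0.219 ln(n).  The published correction applies the
    divisor at two decimals (0.60 for n = 10); pass
    ``divisor_precision=None`` for full precision.  Returns
    (corrected Ne, divisor used).
    """
    if ne_point <= 0:
        raise ValueError("ne_point must be positive")
    if n_chrom_haploid < 1:
        raise ValueError("need at least one chromosome")
    divisor = 0.098 + 0.219 * np.log(n_chrom_haploid)
    if divisor_precision is not None:
        divisor = round(divisor, divisor_precision)
    return float(ne_point / divisor), float(divisor)


def generation_time(alpha_maturity: float, adult_survival: float) -> float:
    """Generation time for an iteroparous perennial: T = alpha + s/(1-s)."""
    if not (0 <= adult_survival < 1):
        raise ValueError("adult survival must be in [0, 1)")
    return float(alpha_maturity + adult_survival / (1.0 - adult_survival))


def ne_census_ratios(ne_point: float, n_ramets: int, n_genets: int) -> dict:
    """Ne relative to ramet and genet census counts."""
    if n_ramets <= 0 or n_genets <= 0:
        raise ValueError("census counts must be positive")
    return {
        "ne_over_ramets": ne_point / n_ramets,
        "ne_over_genets": ne_point / n_genets,
        "ne_over_ramets_2dp": round(ne_point / n_ramets, 2),
        "ne_over_genets_2dp": round(ne_point / n_genets, 2),
    }
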