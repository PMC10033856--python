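"""Genet-level population-genetic summary statistics.

Heterozygosities (Ho, unbiased He), the inbreeding coefficient FIS,
rarefied allelic and private allelic richness, Hardy-Weinberg exact tests
with multiple-testing correction, Weir-Cockerham FST, and two diagnostic
correlations: individual heterozygosity vs clone size, and per-locus
missingness vs FIS (a proxy for allele-dropout artefacts).

All statistics operate on a clone-corrected view of the data (one
representative ramet per MLG or MLL) unless ``level="raw"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .clonal import ClonalPartition
from .io import MISSING, GenotypeMatrix


def _level_indices(g: GenotypeMatrix, partition: ClonalPartition | None,
                   level: str) -> np.ndarray:
    if level == "raw" or partition is None:
        return np.arange(g.n_samples)
    return partition.representatives(level)


@dataclass
class DiversityReport:
    per_locus: pd.DataFrame          # one row per (population, locus)
    per_population: pd.DataFrame     # multilocus summaries
    global_stats: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.per_locus

    def to_dict(self):
        return {
            "per_locus": self.per_locus.to_dict(orient="records"),
            "per_population": self.per_population.to_dict(orient="records"),
            "global": self.global_stats,
        }


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(allele_counts: dict[int, int], g_copies: int) -> float:
    """Rarefied allele count in a sample of ``g_copies`` gene copies.

    sum_a [1 - C(2n - n_a, g)/C(2n, g)] with 2n the observed copy total.
    At g = 2n this equals the observed allele count.
    """
    tot = sum(allele_counts.values())
    if g_copies > tot:
        raise ValueError("rarefaction size exceeds observed gene copies")
    r = 0.0
    for na in allele_counts.values():
        if tot - na >= g_copies:
            r += 1.0 - np.exp(_log_comb(tot - na, g_copies) - _log_comb(tot, g_copies))
        else:
            r += 1.0
    return float(r)


def _presence_prob(tot: int, na: int, g_copies: int) -> float:
    """P(allele with na/tot copies appears in a subsample of g copies)."""
    if na == 0:
        return 0.0
    if tot - na < g_copies:
        return 1.0
    return float(1.0 - np.exp(_log_comb(tot - na, g_copies) - _log_comb(tot, g_copies)))


def private_allelic_richness(counts_by_pop: dict[str, dict[int, int]],
                             focal: str, g_copies: int) -> float:
    """Kalinowski-style rarefied private allelic richness for one locus.

    Expected number of alleles present in a ``g_copies`` subsample of the
    focal population but absent from equal-sized subsamples of every
    other population.
    """
    alleles = set()
    for c in counts_by_pop.values():
        alleles.update(c)
    out = 0.0
    for a in alleles:
        p_in = _presence_prob(
            sum(counts_by_pop[focal].values()), counts_by_pop[focal].get(a, 0), g_copies
        )
        if p_in == 0.0:
            continue
        p_absent_rest = 1.0
        for pop, c in counts_by_pop.items():
            if pop == focal:
                continue
            p_absent_rest *= 1.0 - _presence_prob(sum(c.values()), c.get(a, 0), g_copies)
        out += p_in * p_absent_rest
    return float(out)


def summarize_diversity(g: GenotypeMatrix, partition: ClonalPartition | None = None,
                        level: str = "raw", rarefaction_g: int | None = None,
                        private_g_copies: int | None = None) -> DiversityReport:
    """Per-locus and per-population diversity summary.

    rarefaction_g
        Allelic-richness rarefaction size in diploid individuals
        (defaults to the smallest per-population genotyped count).
    private_g_copies
        Private-allelic-richness rarefaction size in gene copies
        (defaults to 2 * rarefaction_g).  Exposing both conventions
        explicitly avoids the factor-of-two ambiguity between them.

    Monomorphic loci get uHe = 0 and undefined FIS.  SNP loci also feed a
    per-population nucleotide diversity pi (mean per-site unbiased
    heterozygosity over variant sites; invariant sites are excluded,
    which the report flags).
    """
    idx = _level_indices(g, partition, level)
    sub = g.subset(sample_idx=idx)
    pops = sub.population_indices()

    # per (pop, locus) genotyped counts to resolve default rarefaction size
    n_table = {
        (p, j): int((sub.alleles[ix, j, 0] != MISSING).sum())
        for p, ix in pops.items() for j in range(sub.n_loci)
    }
    min_n = min(min(n_table[(p, j)] for j in range(sub.n_loci)) for p in pops) \
        if sub.n_loci else 0
    g_ind = rarefaction_g if rarefaction_g is not None else min_n
    if g_ind > min_n:
        raise ValueError(
            f"rarefaction size {g_ind} exceeds the smallest per-population "
            f"genotyped count {min_n}"
        )
    g_cop = private_g_copies if private_g_copies is not None else 2 * g_ind

    rows = []
    for p, ix in pops.items():
        for j, L in enumerate(sub.loci):
            counts = sub.allele_counts(j, sample_idx=ix)
            n = n_table[(p, j)]
            if n == 0:
                rows.append(dict(population=p, locus=L.name, marker_type=L.marker_type,
                                 n=0, Ho=np.nan, uHe=np.nan, FIS=np.nan,
                                 richness=np.nan, private_richness=np.nan))
                continue
            het = sub.heterozygous(j)[ix]
            Ho = float(np.nanmean(het))
            freqs = np.array(list(counts.values())) / (2 * n)
            He = 1.0 - float(np.sum(freqs ** 2))
            uHe = (2 * n) / (2 * n - 1) * He if n > 1 else He
            FIS = 1.0 - Ho / uHe if uHe > 0 else np.nan
            counts_by_pop = {
                q: sub.allele_counts(j, sample_idx=jx) for q, jx in pops.items()
            }
            rows.append(dict(
                population=p, locus=L.name, marker_type=L.marker_type, n=n,
                Ho=Ho, uHe=float(uHe), FIS=FIS,
                richness=allelic_richness(counts, 2 * g_ind) if g_ind else np.nan,
                private_richness=(
                    private_allelic_richness(counts_by_pop, p, g_cop) if g_cop else np.nan
                ),
            ))
    per_locus = pd.DataFrame(rows)

    pop_rows = []
    for p in pops:
        d = per_locus[per_locus.population == p]
        ho, uhe = d.Ho.mean(), d.uHe.mean()
        snp = d[d.marker_type == "SNP"]
        pi = float(snp.uHe.mean()) if len(snp) else np.nan
        pop_rows.append(dict(
            population=p, n=int(d.n.max()) if len(d) else 0,
            Ho=float(ho), uHe=float(uhe),
            FIS=float(1.0 - ho / uhe) if uhe > 0 else np.nan,  # ratio of averages
            mean_richness=float(d.richness.mean()),
            private_richness=float(d.private_richness.mean()),
            pi_variant_sites=pi,
        ))
    per_population = pd.DataFrame(pop_rows)
    return DiversityReport(
        per_locus=per_locus, per_population=per_population,
        global_stats={
            "level": level, "rarefaction_g_individuals": g_ind,
            "private_g_copies": g_cop,
            "pi_excludes_invariant_sites": True,
        },
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact tests
# ---------------------------------------------------------------------------

def _biallelic_exact(n_AA: int, n_AB: int, n_BB: int) -> tuple[float, float, float]:
    """Full-enumeration exact HWE test for a biallelic locus.

    Conditional (Levene/Haldane) distribution of the heterozygote count
    given allele counts.  Returns (two-sided by probability ordering,
    excess-side, deficit-side) p-values.
    """
    n = n_AA + n_AB + n_BB
    nA = 2 * n_AA + n_AB
    het_range = np.arange(nA % 2, min(nA, 2 * n - nA) + 1, 2)
    logp = []
    for h in het_range:
        aa = (nA - h) // 2
        bb = n - aa - h
        lp = (
            _log_comb(n, aa) + _log_comb(n - aa, h)  # multinomial n!/(aa! h! bb!)
            + h * np.log(2.0)
            - (_log_comb(2 * n, nA))
        )
        logp.append(lp)
    logp = np.array(logp)
    pr = np.exp(logp - logp.max())
    pr /= pr.sum()
    obs = np.flatnonzero(het_range == n_AB)[0]
    p_two = float(pr[pr <= pr[obs] * (1 + 1e-12)].sum())
    p_excess = float(pr[het_range >= n_AB].sum())
    p_deficit = float(pr[het_range <= n_AB].sum())
    return p_two, p_excess, p_deficit


def _table_logprob(genotype_counts: dict[tuple[int, int], int],
                   allele_counts: dict[int, int], n: int) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    lp = gammaln(n + 1) + sum(gammaln(c + 1) for c in allele_counts.values()) \
        - gammaln(2 * n + 1)
    for (a, b), c in genotype_counts.items():
        lp -= gammaln(c + 1)
        if a != b:
            lp += c * np.log(2.0)
    return float(lp)


def _mc_exact(genotypes: np.ndarray, n_mc: int, rng) -> tuple[float, float, float]:
    """Monte-Carlo exact HWE test for a (possibly multiallelic) locus."""
    n = genotypes.shape[0]
    alleles = genotypes.ravel()
    counts: dict[tuple[int, int], int] = {}
    for a, b in genotypes:
        counts[(a, b)] = counts.get((a, b), 0) + 1
    acounts: dict[int, int] = {}
    for a in alleles:
        acounts[a] = acounts.get(a, 0) + 1
    lp_obs = _table_logprob(counts, acounts, n)
    het_obs = int((genotypes[:, 0] != genotypes[:, 1]).sum())
    hits_two = hits_exc = hits_def = 0
    pool = alleles.copy()
    for _ in range(n_mc):
        rng.shuffle(pool)
        pairs = np.sort(pool.reshape(n, 2), axis=1)
        c: dict[tuple[int, int], int] = {}
        for a, b in pairs:
            c[(a, b)] = c.get((a, b), 0) + 1
        lp = _table_logprob(c, acounts, n)
        het = int((pairs[:, 0] != pairs[:, 1]).sum())
        if lp <= lp_obs + 1e-12:
            hits_two += 1
        if het >= het_obs:
            hits_exc += 1
        if het <= het_obs:
            hits_def += 1
    denom = n_mc + 1
    return ((1 + hits_two) / denom, (1 + hits_exc) / denom, (1 + hits_def) / denom)


def adjust_pvalues(p: np.ndarray, method: str = "fdr") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment (monotone in raw p)."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    m = int(ok.sum())
    if m == 0:
        return out
    if method == "bonferroni":
        out[ok] = np.minimum(p[ok] * m, 1.0)
    elif method == "fdr":
        order = np.argsort(p[ok])
        ranked = p[ok][order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        out[ok] = adj
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    return out


def hwe_exact(g: GenotypeMatrix, partition: ClonalPartition | None = None,
              level: str = "raw", n_mc: int = 10_000, seed: int = 0,
              adjust: str = "fdr") -> pd.DataFrame:
    """Per-locus, per-population exact tests of Hardy-Weinberg proportions.

    Biallelic loci use full enumeration of the conditional heterozygote
    distribution; multiallelic loci use a seeded Monte-Carlo permutation
    of alleles into genotypes.  One-sided heterozygote excess/deficit
    p-values are reported alongside the two-sided (probability-ordering)
    test.  Adjustment (``bonferroni`` or ``fdr``) is applied across loci
    within each population.  Loci with fewer than 5 genotyped samples are
    flagged low-power.
    """
    idx = _level_indices(g, partition, level)
    sub = g.subset(sample_idx=idx)
    rng = np.random.default_rng(seed)
    rows = []
    for p, ix in sub.population_indices().items():
        for j, L in enumerate(sub.loci):
            pair = sub.alleles[ix, j, :]
            pair = pair[pair[:, 0] != MISSING]
            n = pair.shape[0]
            codes = np.unique(pair)
            if n == 0 or codes.size < 2:
                rows.append(dict(population=p, locus=L.name, n=n,
                                 p_two=np.nan, p_excess=np.nan, p_deficit=np.nan,
                                 method="none", low_power=n < 5))
                continue
            if codes.size == 2:
                A = codes[0]
                n_AA = int(((pair == A).sum(axis=1) == 2).sum())
                n_AB = int((pair[:, 0] != pair[:, 1]).sum())
                n_BB = n - n_AA - n_AB
                p2, pe, pd_ = _biallelic_exact(n_AA, n_AB, n_BB)
                meth = "enumeration"
            else:
                p2, pe, pd_ = _mc_exact(pair.copy(), n_mc, rng)
                meth = "monte_carlo"
            rows.append(dict(population=p, locus=L.name, n=n,
                             p_two=p2, p_excess=pe, p_deficit=pd_,
                             method=meth, low_power=n < 5))
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    for p in df.population.unique():
        m = df.population == p
        df.loc[m, "p_adj"] = adjust_pvalues(df.loc[m, "p_two"].to_numpy(), adjust)
    return df


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(g: GenotypeMatrix, locus: int,
                   pop_idx: dict[str, np.ndarray]) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) variance components (a, b, c) for one locus,
    summed over alleles."""
    r = len(pop_idx)
    n_i, stats_per_pop = [], []
    for p, ix in pop_idx.items():
        pair = g.alleles[ix, locus, :]
        pair = pair[pair[:, 0] != MISSING]
        n_i.append(pair.shape[0])
        stats_per_pop.append(pair)
    n_i = np.array(n_i, dtype=float)
    if (n_i == 0).any() or r < 2:
        return np.nan, np.nan, np.nan
    alleles = np.unique(np.concatenate([pp.ravel() for pp in stats_per_pop]))
    if alleles.size < 2:
        return 0.0, 0.0, 0.0  # monomorphic across populations
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for a in alleles:
        p_i = np.array([(pp == a).sum() / (2 * pp.shape[0]) for pp in stats_per_pop])
        h_i = np.array([
            ((pp[:, 0] != pp[:, 1]) & ((pp == a).any(axis=1))).sum() / pp.shape[0]
            for pp in stats_per_pop
        ])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a_comp = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b_comp = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c_comp = hbar / 2
        A += a_comp
        B += b_comp
        C += c_comp
    return A, B, C


def fst_wc(g: GenotypeMatrix, partition: ClonalPartition | None = None,
           level: str = "raw") -> dict:
    """Weir-Cockerham theta per locus and multilocus, with jackknife SE.

    The multilocus estimate sums variance components over loci before
    taking the ratio; the SE is a delete-one-locus jackknife.  Loci
    monomorphic across all populations are excluded.
    """
    idx = _level_indices(g, partition, level)
    sub = g.subset(sample_idx=idx)
    pops = sub.population_indices()
    if len(pops) < 2:
        raise ValueError("FST needs at least two populations")
    comps = []
    per_locus = {}
    for j, L in enumerate(sub.loci):
        a, b, c = _wc_components(sub, j, pops)
        if np.isnan(a) or (a + b + c) == 0:
            per_locus[L.name] = np.nan
            continue
        comps.append((a, b, c))
        per_locus[L.name] = a / (a + b + c)
    if not comps:
        raise ValueError("no polymorphic loci")
    comps = np.array(comps)
    theta = comps[:, 0].sum() / comps.sum()
    # jackknife over loci
    if comps.shape[0] > 1:
        loo = np.array([
            np.delete(comps, k, axis=0)[:, 0].sum() / np.delete(comps, k, axis=0).sum()
            for k in range(comps.shape[0])
        ])
        L = comps.shape[0]
        se = float(np.sqrt((L - 1) / L * np.sum((loo - loo.mean()) ** 2)))
    else:
        se = float("nan")
    return {"theta": float(theta), "se": se, "per_locus": per_locus}


def pairwise_fst(g: GenotypeMatrix, partition=None, level: str = "raw") -> pd.DataFrame:
    idx = _level_indices(g, partition, level)
    sub = g.subset(sample_idx=idx)
    pops = list(sub.population_indices())
    rows = []
    for p, q in itertools.combinations(pops, 2):
        six = [i for i, lbl in enumerate(sub.populations) if lbl in (p, q)]
        res = fst_wc(sub.subset(sample_idx=six))
        rows.append(dict(pop1=p, pop2=q, theta=res["theta"], se=res["se"]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostic correlations
# ---------------------------------------------------------------------------

def heterozygosity_vs_clone_size(g: GenotypeMatrix, partition: ClonalPartition,
                                 level: str = "mll") -> dict:
    """Correlation of per-clone multilocus heterozygosity with ramet count.

    Heterozygosity is the proportion of typed loci at which the clone's
    representative is heterozygous.  A positive correlation would suggest
    outbred genets persist longer / grow larger.
    """
    reps = partition.representatives(level)
    sizes = partition.clone_sizes(level)
    het = []
    for i in reps:
        pair = g.alleles[i]
        obs = pair[:, 0] != MISSING
        het.append(
            float((pair[obs, 0] != pair[obs, 1]).mean()) if obs.any() else np.nan
        )
    het = np.array(het)
    ok = ~np.isnan(het)
    if ok.sum() < 3 or np.allclose(het[ok], het[ok][0]) or np.allclose(sizes[ok], sizes[ok][0]):
        return {"r": float("nan"), "p": float("nan"), "n": int(ok.sum())}
    r, p = stats.pearsonr(het[ok], sizes[ok])
    return {"r": float(r), "p": float(p), "n": int(ok.sum())}


def missingness_vs_fis(g: GenotypeMatrix, partition: ClonalPartition | None = None,
                       level: str = "raw") -> dict:
    """Spearman correlation of per-locus missing-data fraction with FIS.

    A strong positive correlation flags allele dropout as a likely cause
    of heterozygote deficits.
    """
    idx = _level_indices(g, partition, level)
    sub = g.subset(sample_idx=idx)
    miss, fis = [], []
    for j in range(sub.n_loci):
        pair = sub.alleles[:, j, :]
        obs = pair[:, 0] != MISSING
        miss.append(1.0 - obs.mean())
        p_ = pair[obs]
        n = p_.shape[0]
        if n < 2:
            fis.append(np.nan)
            continue
        counts = sub.allele_counts(j)
        freqs = np.array(list(counts.values())) / (2 * n)
        uhe = (2 * n) / (2 * n - 1) * (1 - np.sum(freqs ** 2))
        ho = (p_[:, 0] != p_[:, 1]).mean()
        fis.append(1 - ho / uhe if uhe > 0 else np.nan)
    miss, fis = np.array(miss), np.array(fis)
    ok = ~np.isnan(fis)
    if ok.sum() < 3 or np.allclose(miss[ok], miss[ok][0]) or np.allclose(fis[ok], fis[ok][0]):
        return {"rho": float("nan"), "p": float("nan"), "n": int(ok.sum())}
    rho, p = stats.spearmanr(miss[ok], fis[ok])
    return {"rho": float(rho), "p": float(p), "n": int(ok.sum())}


def association_checks(g: GenotypeMatrix, partition: ClonalPartition,
                       level: str = "mll") -> dict:
    """Both diagnostic correlations in one call."""
    return {
        "heterozygosity_vs_clone_size": heterozygosity_vs_clone_size(g, partition, level),
        "missingness_vs_fis": missingness_vs_fis(g, partition, level),
    }
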