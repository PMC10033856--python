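"""Clone discrimination and genotypic diversity.

In partially clonal plants the sampling unit is the ramet, but the genetic
unit is the genet.  This module identifies multilocus genotypes (MLGs),
tests repeated MLGs against chance identity under sexual reproduction
(psex), collapses scoring-error variants of the same genet into multilocus
lineages (MLLs) using Bruvo-distance thresholds, and computes the standard
genotypic (clonal) diversity statistics: richness R, rarefied eMLG,
Stoddart-Taylor G, Simpson lambda, evenness E5, the Pareto power-law slope
of the clone-size distribution, and the standardized index of association
r̄d with a permutation test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix, LocusSpec

logger = logging.getLogger(__name__)


@dataclass
class ClonalPartition:
    """Assignment of ramets to MLGs and (optionally coarser) MLLs.

    MLL ids always refine-up from MLGs: every MLG maps into exactly one
    MLL, so ``n_mll <= n_mlg <= n_samples``.  With ``threshold == 0`` the
    two levels coincide.
    """

    samples: list[str]
    mlg: np.ndarray  # sample -> MLG index
    mll: np.ndarray  # sample -> MLL index
    threshold: float = 0.0
    populations: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_mlg(self) -> int:
        return len(np.unique(self.mlg))

    @property
    def n_mll(self) -> int:
        return len(np.unique(self.mll))

    def ids(self, level: str) -> np.ndarray:
        if level == "mlg":
            return self.mlg
        if level == "mll":
            return self.mll
        if level == "raw":
            return np.arange(self.n_samples)
        raise ValueError(f"unknown level {level!r}")

    def clone_sizes(self, level: str = "mlg") -> np.ndarray:
        """Number of ramets per clone, ordered by clone id."""
        return np.bincount(self.ids(level))[np.unique(self.ids(level))]

    def representatives(self, level: str = "mlg") -> np.ndarray:
        """First-seen sample index of each clone, ordered by clone id."""
        ids = self.ids(level)
        reps = {}
        for i, c in enumerate(ids):
            reps.setdefault(int(c), i)
        return np.array([reps[c] for c in sorted(reps)], dtype=int)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"sample": self.samples, "mlg": self.mlg, "mll": self.mll}
        )

    def to_dict(self):
        return {
            "threshold": self.threshold,
            "n_samples": self.n_samples,
            "n_mlg": self.n_mlg,
            "n_mll": self.n_mll,
            "mlg": self.mlg.tolist(),
            "mll": self.mll.tolist(),
        }


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller root so labelling follows first-seen order
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _canonical_labels(uf: _UnionFind, n: int) -> np.ndarray:
    roots = [uf.find(i) for i in range(n)]
    order: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in order:
            order[r] = len(order)
        out[i] = order[r]
    return out


def identify_mlgs(g: GenotypeMatrix, missing_policy: str = "permissive") -> ClonalPartition:
    """Group ramets into multilocus genotypes.

    strict
        Two ramets share an MLG iff their genotypes — including the
        pattern of missing loci — are identical.
    permissive
        Equality is required only at mutually observed loci; links are
        closed transitively.  An all-missing ramet forms its own MLG.

    Labels follow first-seen sample order, so the partition is
    deterministic for a given input order (and, up to relabelling,
    independent of it).
    """
    n = g.n_samples
    a = g.alleles  # (n, L, 2), canonicalised pairs
    if missing_policy == "strict":
        uf = _UnionFind(n)
        seen: dict[bytes, int] = {}
        for i in range(n):
            key = a[i].tobytes()
            if key in seen:
                uf.union(seen[key], i)
            else:
                seen[key] = i
        labels = _canonical_labels(uf, n)
    elif missing_policy == "permissive":
        uf = _UnionFind(n)
        obs = a[:, :, 0] != MISSING  # (n, L)
        all_missing = ~obs.any(axis=1)
        if all_missing.any():
            logger.warning(
                "identify_mlgs: %d all-missing sample(s) form singleton MLGs",
                int(all_missing.sum()),
            )
        for i in range(n):
            if all_missing[i]:
                continue
            eq = (a[i + 1:] == a[i]).all(axis=2)  # (n-i-1, L)
            both = obs[i + 1:] & obs[i]
            compatible = (eq | ~both).all(axis=1) & both.any(axis=1)
            for off in np.nonzero(compatible)[0]:
                uf.union(i, i + 1 + int(off))
        labels = _canonical_labels(uf, n)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return ClonalPartition(
        samples=list(g.samples),
        mlg=labels,
        mll=labels.copy(),
        threshold=0.0,
        populations=list(g.populations),
    )


# ---------------------------------------------------------------------------
# psex
# ---------------------------------------------------------------------------

def pgen(g: GenotypeMatrix, sample_idx: int, freqs_per_locus: list[dict]) -> float:
    """Probability of the sample's multilocus genotype under HWE.

    Product over observed loci of ``2^h * p_a * p_b`` with ``h = 1`` for
    heterozygous loci.
    """
    p = 1.0
    for j in range(g.n_loci):
        a, b = g.alleles[sample_idx, j]
        if a == MISSING:
            continue
        fr = freqs_per_locus[j]
        pa, pb = fr.get(int(a), 0.0), fr.get(int(b), 0.0)
        p *= (2.0 * pa * pb) if a != b else pa * pb
    return p


def _frequency_basis(g: GenotypeMatrix, partition: ClonalPartition,
                     freq_basis: str) -> tuple[list[dict], int]:
    """Allele frequency tables per locus plus the basis sample count."""
    if freq_basis == "ramet":
        idx = np.arange(g.n_samples)
    elif freq_basis == "genet":
        idx = partition.representatives("mlg")
    elif freq_basis == "round_robin":
        # handled per-locus by the caller
        raise RuntimeError("round_robin handled in psex")
    else:
        raise ValueError(f"unknown freq_basis {freq_basis!r}")
    freqs = []
    for j in range(g.n_loci):
        fr = g.allele_freqs(j, sample_idx=idx)
        freqs.append(_floor_freqs(fr, len(idx)))
    return freqs, len(idx)


def _floor_freqs(fr: dict, n_basis: int) -> dict:
    # alleles absent from the basis get a floor of 1/(2*basis size); the
    # floor is applied lazily via dict.get default at lookup time
    fr = dict(fr)
    fr["__floor__"] = 1.0 / (2 * max(n_basis, 1))
    return fr


def psex(g: GenotypeMatrix, partition: ClonalPartition, method: str = "single",
         freq_basis: str = "genet") -> dict[int, float]:
    """Probability that each repeated MLG arose by sexual reproduction.

    For an MLG observed ``n`` times among ``N`` ramets with genotype
    probability ``pgen``:

    single
        P(at least n-1 further occurrences among the other N-1 ramets),
        i.e. the chance the observed repeats are independent sexual
        events given one ramet carries the genotype.
    multiple
        P(at least n occurrences among all N ramets) — the unconditional
        binomial upper tail.

    MLGs seen once get psex = 1 by convention.  ``freq_basis`` selects the
    allele-frequency reference: every ramet, one representative per MLG
    (default, the usual clone-corrected practice), or round-robin (for
    locus ℓ, frequencies from the partition rebuilt without locus ℓ).
    """
    N = g.n_samples
    if freq_basis == "round_robin":
        freqs = []
        basis_n = []
        for j in range(g.n_loci):
            others = np.array([k for k in range(g.n_loci) if k != j], dtype=int)
            sub = g.subset(locus_idx=others)
            part_j = identify_mlgs(sub, "permissive")
            idx = part_j.representatives("mlg")
            freqs.append(_floor_freqs(g.allele_freqs(j, sample_idx=idx), len(idx)))
            basis_n.append(len(idx))
    else:
        freqs, _ = _frequency_basis(g, partition, freq_basis)

    out: dict[int, float] = {}
    reps = partition.representatives("mlg")
    sizes = partition.clone_sizes("mlg")
    for mlg_id, (rep, n_copies) in enumerate(zip(reps, sizes)):
        if n_copies < 2:
            out[mlg_id] = 1.0
            continue
        pg = 1.0
        for j in range(g.n_loci):
            a, b = g.alleles[rep, j]
            if a == MISSING:
                continue
            fr = freqs[j]
            floor = fr["__floor__"]
            pa = fr.get(int(a), floor)
            pb = fr.get(int(b), floor)
            if fr.get(int(a)) is None or fr.get(int(b)) is None:
                logger.warning("psex: allele absent from frequency basis; floored")
            pg *= (2.0 * pa * pb) if a != b else pa * pb
        if method == "single":
            # 1 - P(at most n-2 of the other N-1 ramets share the MLG)
            out[mlg_id] = float(1.0 - stats.binom.cdf(n_copies - 2, N - 1, pg))
        elif method == "multiple":
            out[mlg_id] = float(stats.binom.sf(n_copies - 1, N, pg))
        else:
            raise ValueError(f"unknown psex method {method!r}")
    return out


# ---------------------------------------------------------------------------
# Bruvo distance
# ---------------------------------------------------------------------------

#: tolerance (repeat units) beyond which a fragment size is flagged off-ladder
OFF_LADDER_TOL = 0.15


def _repeat_units(sizes: np.ndarray, spec: LocusSpec) -> np.ndarray:
    """Convert fragment sizes (bp) to repeat units for one locus."""
    if spec.marker_type != "SSR" or not spec.repeat_length:
        raise ValueError(f"locus {spec.name}: Bruvo distance needs an SSR repeat length")
    obs = sizes[sizes != MISSING]
    offset = spec.offset if spec.offset is not None else (obs.min() if obs.size else 0)
    u = (sizes - offset) / spec.repeat_length
    frac = np.abs(u - np.round(u))
    off = (frac > OFF_LADDER_TOL) & (sizes != MISSING)
    if off.any():
        warnings.warn(
            f"locus {spec.name}: {int(off.sum())} off-ladder allele(s); rounded",
            stacklevel=2,
        )
    u = np.round(u).astype(int)
    u[sizes == MISSING] = MISSING
    return u


def _bruvo_locus_units(x: tuple[int, int], y: tuple[int, int]) -> float:
    """Diploid Bruvo distance at one locus, alleles already in repeat units."""
    m = lambda a, b: 1.0 - 2.0 ** (-abs(a - b))
    # two perfect matchings of {x1,x2} onto {y1,y2}
    d1 = (m(x[0], y[0]) + m(x[1], y[1])) / 2.0
    d2 = (m(x[0], y[1]) + m(x[1], y[0])) / 2.0
    return min(d1, d2)


def bruvo_distance(a, b, spec: LocusSpec) -> float:
    """Bruvo distance between two diploid genotypes at one SSR locus.

    ``a`` and ``b`` are (allele, allele) fragment sizes in bp; MISSING in
    either genotype gives NaN.  Alleles are converted to repeat units and
    the per-locus distance is the minimum over the two perfect matchings
    of the mean of ``1 - 2**(-|ux - uy|)``.
    """
    sizes = np.array([a[0], a[1], b[0], b[1]], dtype=np.int64)
    if MISSING in sizes:
        return float("nan")
    u = _repeat_units(sizes, spec)
    return _bruvo_locus_units((u[0], u[1]), (u[2], u[3]))


def bruvo_matrix(g: GenotypeMatrix, locus_idx=None) -> np.ndarray:
    """Pairwise mean Bruvo distance across SSR loci.

    The per-pair distance averages per-locus distances over loci observed
    in both samples; pairs sharing no observed locus get NaN.
    """
    li = g.ssr_loci() if locus_idx is None else np.asarray(locus_idx)
    n = g.n_samples
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for j in li:
        spec = g.loci[j]
        units = _repeat_units(g.alleles[:, j, :].ravel(), spec).reshape(n, 2)
        obs = units[:, 0] != MISSING
        u1 = units[:, 0].astype(float)
        u2 = units[:, 1].astype(float)
        mfun = lambda A, B: 1.0 - np.power(2.0, -np.abs(A[:, None] - B[None, :]))
        d_straight = (mfun(u1, u1) + mfun(u2, u2)) / 2.0
        d_cross = (mfun(u1, u2) + mfun(u2, u1)) / 2.0
        d = np.minimum(d_straight, d_cross)
        ok = obs[:, None] & obs[None, :]
        total += np.where(ok, d, 0.0)
        count += ok
    with np.errstate(invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# MLL threshold prediction and collapsing
# ---------------------------------------------------------------------------

def predict_mll_threshold(distances: np.ndarray, partition: ClonalPartition,
                          gap_min: float = 0.0) -> float:
    """Predict a Bruvo-distance cutoff separating scoring-error MLG pairs
    from genuinely distinct genets.

    Takes the between-MLG representative distance distribution, locates
    its major mode (the highest-count histogram bin; ties broken toward
    larger distances, so a small error-pair peak near zero never wins
    against the bulk of genuine between-genet distances), and returns
    the midpoint of the largest gap between consecutive sorted distances
    whose lower end lies below that mode.  Returns 0 with a warning when
    no gap exceeds ``gap_min`` (nothing to collapse).
    """
    reps = partition.representatives("mlg")
    if len(reps) < 2:
        raise ValueError("need at least two distinct MLGs")
    sub = distances[np.ix_(reps, reps)]
    iu = np.triu_indices(len(reps), k=1)
    d = np.sort(sub[iu])
    d = d[~np.isnan(d)]
    if d.size < 2 or np.allclose(d, d[0]):
        warnings.warn("degenerate distance distribution; threshold 0", stacklevel=2)
        return 0.0
    nbins = max(10, int(np.ceil(np.sqrt(d.size))))
    counts, edges = np.histogram(d, bins=nbins)
    peak = int(np.flatnonzero(counts == counts.max())[-1])
    mode = 0.5 * (edges[peak] + edges[peak + 1])
    gaps = np.diff(d)
    eligible = d[:-1] < mode
    if not eligible.any() or gaps[eligible].max() <= gap_min:
        warnings.warn("no gap below the first mode exceeds gap_min; threshold 0",
                      stacklevel=2)
        return 0.0
    # quantized ladders (e.g. Bruvo distances over few loci) produce exact
    # ties for the largest gap; take the tied gap nearest the mode
    gmax = gaps[eligible].max()
    k = int(np.flatnonzero(eligible & (gaps >= gmax - 1e-12))[-1])
    return float(0.5 * (d[k] + d[k + 1]))


def collapse_mlls(partition: ClonalPartition, distances: np.ndarray,
                  threshold: float) -> ClonalPartition:
    """Collapse MLGs into MLLs by single-linkage at ``threshold``.

    MLG representatives within ``threshold`` (inclusive) join one MLL;
    chains merge transitively.  ``threshold = 0`` collapses only exact
    ties (distance 0 between distinct MLGs is impossible for fully
    observed genotypes), i.e. MLLs == MLGs.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    reps = partition.representatives("mlg")
    k = len(reps)
    uf = _UnionFind(k)
    if threshold > 0:
        sub = distances[np.ix_(reps, reps)]
        for i in range(k):
            for j in range(i + 1, k):
                dij = sub[i, j]
                if np.isfinite(dij) and dij <= threshold:
                    uf.union(i, j)
    mlg_to_mll = _canonical_labels(uf, k)
    mll = mlg_to_mll[partition.mlg]
    return ClonalPartition(
        samples=list(partition.samples),
        mlg=partition.mlg.copy(),
        mll=mll,
        threshold=float(threshold),
        populations=list(partition.populations) if partition.populations else None,
    )


# ---------------------------------------------------------------------------
# Genotypic diversity
# ---------------------------------------------------------------------------

@dataclass
class GenotypicDiversity:
    N: int
    G_count: int
    richness_R: float
    eMLG: float
    eMLG_n: int
    stoddart_G: float
    lambda_: float
    evenness_E5: float
    pareto_beta: float = float("nan")
    pareto_r2: float = float("nan")
    rbarD: float = float("nan")
    rbarD_p: float = float("nan")

    def to_dict(self):
        return {
            "N": self.N, "G": self.G_count, "richness_R": self.richness_R,
            "eMLG": self.eMLG, "eMLG_n": self.eMLG_n,
            "stoddart_G": self.stoddart_G, "lambda": self.lambda_,
            "E5": self.evenness_E5, "pareto_beta": self.pareto_beta,
            "pareto_r2": self.pareto_r2, "rbarD": self.rbarD,
            "rbarD_p": self.rbarD_p,
        }


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def expected_mlg(clone_sizes: np.ndarray, g: int) -> float:
    """Rarefied expected clone count in a subsample of ``g`` ramets.

    Hypergeometric rarefaction: E[G_g] = sum_i 1 - C(N - n_i, g)/C(N, g).
    """
    sizes = np.asarray(clone_sizes)
    N = sizes.sum()
    if g > N:
        raise ValueError("rarefaction size exceeds sample size")
    terms = np.where(
        N - sizes >= g,
        np.exp(_log_comb(N - sizes, g) - _log_comb(N, g)),
        0.0,
    )
    return float(np.sum(1.0 - terms))


def genotypic_diversity(partition: ClonalPartition, level: str = "mlg",
                        rarefaction_n: int | None = None,
                        g: GenotypeMatrix | None = None,
                        n_perm: int = 0, seed: int = 0) -> GenotypicDiversity:
    """Genotypic diversity summary for one sample set.

    ``rarefaction_n`` is the ramet count at which eMLG is rarefied
    (conventionally the smallest population sample size >= 10); defaults
    to min(N, 10).  When a GenotypeMatrix and ``n_perm`` are supplied the
    index of association r̄d is included.
    """
    sizes = partition.clone_sizes(level)
    N = int(sizes.sum())
    if N < 2:
        raise ValueError("need at least two ramets")
    G = len(sizes)
    p = sizes / N
    sum_p2 = float(np.sum(p ** 2))
    lam = 1.0 - sum_p2
    stoddart = 1.0 / sum_p2
    H = -float(np.sum(p * np.log(p)))
    e5 = (stoddart - 1.0) / (np.exp(H) - 1.0) if G > 1 else 1.0
    rn = rarefaction_n if rarefaction_n is not None else min(N, 10)
    beta, _, pr2 = pareto_beta(sizes)
    gd = GenotypicDiversity(
        N=N, G_count=G,
        richness_R=(G - 1) / (N - 1),
        eMLG=expected_mlg(sizes, rn), eMLG_n=rn,
        stoddart_G=stoddart, lambda_=lam, evenness_E5=float(e5),
        pareto_beta=beta, pareto_r2=pr2,
    )
    if g is not None and n_perm > 0:
        gd.rbarD, gd.rbarD_p = index_of_association(
            g, partition, level=level, n_perm=n_perm, seed=seed
        )
    return gd


def pareto_beta(clone_sizes) -> tuple[float, float, float]:
    """Power-law slope of the reverse cumulative clone-size distribution.

    Regresses log(N_{>=c}/G) on log(c) over observed distinct sizes by
    OLS; returns (beta, intercept, R^2) with beta = -slope.  A single
    distinct size leaves the slope undefined (NaN).

    A steep slope (high beta) means clones of comparable size (high
    evenness); shallow slopes reflect dominance by a few large clones.
    """
    sizes = np.asarray(clone_sizes, dtype=float)
    distinct = np.unique(sizes)
    if distinct.size < 2:
        return float("nan"), float("nan"), float("nan")
    G = sizes.size
    frac = np.array([(sizes >= c).sum() / G for c in distinct])
    x, y = np.log(distinct), np.log(frac)
    res = stats.linregress(x, y)
    return float(-res.slope), float(res.intercept), float(res.rvalue ** 2)


# ---------------------------------------------------------------------------
# Index of association
# ---------------------------------------------------------------------------

def _locus_pair_distances(g: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    """Per-locus condensed pairwise mismatch distances.

    Distance between two diploid genotypes at a locus is the number of
    allele differences under the best pairing (0, 1, or 2).  Pairs with a
    missing genotype get the locus mean over observed pairs (mean
    imputation keeps the pair count identical across loci).
    """
    a = g.alleles[sample_idx]  # (n, L, 2) canonicalised
    n, L, _ = a.shape
    iu, ju = np.triu_indices(n, k=1)
    out = np.empty((L, iu.size))
    for l in range(L):
        x = a[:, l, :]
        obs = x[:, 0] != MISSING
        eq_both = (x[iu] == x[ju]).all(axis=1)
        # shared allele count under best pairing
        share_straight = (x[iu, 0] == x[ju, 0]).astype(int) + (x[iu, 1] == x[ju, 1]).astype(int)
        share_cross = (x[iu, 0] == x[ju, 1]).astype(int) + (x[iu, 1] == x[ju, 0]).astype(int)
        # degenerate double-count guard: identical genotypes share 2
        share = np.maximum(share_straight, share_cross)
        share[eq_both] = 2
        d = (2 - share).astype(float)
        ok = obs[iu] & obs[ju]
        if ok.any() and not ok.all():
            d[~ok] = d[ok].mean()
        elif not ok.any():
            d[:] = 0.0
        out[l] = d
    return out


def index_of_association(g: GenotypeMatrix, partition: ClonalPartition | None = None,
                         level: str = "raw", n_perm: int = 999,
                         seed: int = 0) -> tuple[float, float]:
    """Standardized index of association r̄d with a permutation p-value.

    r̄d = (V_O - V_E) / (2 * sum_{j<k} sqrt(v_j v_k)) where v_j is the
    variance of per-locus pairwise distances, V_O the variance of their
    sum over loci, and V_E = sum v_j.  Under linkage equilibrium r̄d ≈ 0;
    a perfectly duplicated locus pair gives 1.  The permutation null
    shuffles genotypes independently within each locus across the
    samples retained at ``level`` (clone-corrected shuffling avoids
    clone-driven pseudo-association).
    """
    if g.n_loci < 2:
        raise ValueError("need at least two loci")
    if level == "raw" or partition is None:
        idx = np.arange(g.n_samples)
    else:
        idx = partition.representatives(level)
    rng = np.random.default_rng(seed)

    def rbar_d(dmat: np.ndarray) -> float:
        v = dmat.var(axis=1)
        V_O = dmat.sum(axis=0).var()
        V_E = v.sum()
        sq = np.sqrt(v)
        denom = float(np.sum(np.outer(sq, sq)) - np.sum(v))  # 2 * sum_{j<k}
        if denom <= 0:
            return float("nan")
        return float((V_O - V_E) / denom)

    dmat = _locus_pair_distances(g, idx)
    obs = rbar_d(dmat)
    if np.isnan(obs):
        return float("nan"), float("nan")
    if n_perm <= 0:
        return obs, float("nan")
    count = 0
    sub = g.subset(sample_idx=idx)
    n = sub.n_samples
    all_idx = np.arange(n)
    for _ in range(n_perm):
        perm = sub.alleles.copy()
        for l in range(sub.n_loci):
            perm[:, l, :] = perm[rng.permutation(n), l, :]
        gp = GenotypeMatrix(
            samples=sub.samples, loci=sub.loci, alleles=perm,
            populations=sub.populations,
        )
        if rbar_d(_locus_pair_distances(gp, all_idx)) >= obs:
            count += 1
    return obs, (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Minimum spanning network
# ---------------------------------------------------------------------------

def spanning_network(distances: np.ndarray, partition: ClonalPartition,
                     level: str = "mll"):
    """Minimum spanning tree over clone representatives.

    Returns ``(edges, node_sizes)`` where edges are (u, v, weight) tuples
    over clone ids and node_sizes maps clone id -> ramet count.  Ties are
    broken by node index, so the tree is stable across runs.  NaN
    distances disconnect the graph; each component then gets its own
    tree (with a warning).
    """
    import networkx as nx

    reps = partition.representatives(level)
    sizes = partition.clone_sizes(level)
    k = len(reps)
    G = nx.Graph()
    G.add_nodes_from(range(k))
    sub = distances[np.ix_(reps, reps)]
    for i in range(k):
        for j in range(i + 1, k):
            if np.isfinite(sub[i, j]):
                G.add_edge(i, j, weight=float(sub[i, j]))
    if k > 1 and not nx.is_connected(G):
        warnings.warn("distance graph disconnected; per-component trees",
                      stacklevel=2)
    edges = []
    for comp in nx.connected_components(G):
        H = G.subgraph(comp)
        # Kruskal with ties pre-sorted by node index for determinism
        sorted_edges = sorted(
            ((min(u, v), max(u, v), d) for u, v, d in H.edges(data=True)),
            key=lambda e: (e[2]["weight"], e[0], e[1]),
        )
        uf = _UnionFind(k)
        for u, v, data in sorted_edges:
            if uf.find(u) != uf.find(v):
                uf.union(u, v)
                edges.append((min(u, v), max(u, v), data["weight"]))
    edges.sort()
    node_sizes = {i: int(s) for i, s in enumerate(sizes)}
    return edges, node_sizes
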