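import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genetne.clonal import (
    ClonalPartition, bruvo_distance, bruvo_matrix, collapse_mlls,
    genotypic_diversity, identify_mlgs, index_of_association, pareto_beta,
    predict_mll_threshold, psex, spanning_network,
)
from genetne.io import MISSING, LocusSpec

from conftest import make_matrix


# ---------------------------------------------------------------------------
# MLG identification
# ---------------------------------------------------------------------------

def test_identical_genotypes_one_mlg():
    g = make_matrix([[[1, 2], [3, 3]]] * 3)
    part = identify_mlgs(g)
    assert part.n_mlg == 1 and part.clone_sizes("mlg").tolist() == [3]


def test_distinct_genotypes_distinct_mlgs():
    g = make_matrix([[[120, 124]], [[120, 128]]])
    assert identify_mlgs(g).n_mlg == 2


def test_missing_policy_strict_vs_permissive():
    """A missing locus blocks a match under strict but not permissive."""
    a = [[10, 12]] * 10
    b = [[10, 12]] * 9 + [[MISSING, MISSING]]
    g = make_matrix([a, b])
    assert identify_mlgs(g, "strict").n_mlg == 2
    assert identify_mlgs(g, "permissive").n_mlg == 1


def test_all_missing_sample_is_singleton():
    g = make_matrix([[[MISSING, MISSING]], [[MISSING, MISSING]], [[1, 2]]])
    assert identify_mlgs(g, "permissive").n_mlg == 3


def test_mlg_partition_order_invariant():
    rng = np.random.default_rng(3)
    arr = rng.choice([100, 102, 104], size=(12, 4, 2))
    arr[::3] = arr[0]  # force some clones
    g = make_matrix(arr)
    base = identify_mlgs(g)
    perm = rng.permutation(12)
    gp = g.subset(sample_idx=perm)
    shuffled = identify_mlgs(gp)
    # same partition up to relabelling
    lab = {}
    for s, m in zip(gp.samples, shuffled.mlg):
        lab[s] = m
    orig = {s: m for s, m in zip(g.samples, base.mlg)}
    pairs_base = {(a, b) for a, b in itertools.combinations(g.samples, 2)
                  if orig[a] == orig[b]}
    pairs_shuf = {(a, b) for a, b in itertools.combinations(g.samples, 2)
                  if lab[a] == lab[b]}
    assert pairs_base == pairs_shuf


# ---------------------------------------------------------------------------
# psex
# ---------------------------------------------------------------------------

def test_psex_binomial_closed_form():
    """One locus, both alleles at 0.5, heterozygote seen twice among N=2:
    pgen = 0.5 so psex = 1 - (1 - 0.5)^1 = 0.5."""
    g = make_matrix([[[120, 124]], [[120, 124]]])
    part = identify_mlgs(g)
    ps = psex(g, part, method="single", freq_basis="ramet")
    assert ps[0] == pytest.approx(0.5)


def test_psex_singleton_mlg_is_one():
    g = make_matrix([[[120, 124]], [[120, 120]]])
    ps = psex(g, identify_mlgs(g), method="single", freq_basis="ramet")
    assert ps == {0: 1.0, 1: 1.0}


def test_psex_monotone_in_copies_and_pgen():
    """More copies of the same MLG make chance identity less likely;
    commoner genotypes (larger pgen) make it more likely."""
    from scipy import stats

    N, pg = 100, 0.05
    vals = [1 - stats.binom.cdf(n - 2, N - 1, pg) for n in range(2, 8)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    vals_p = [1 - stats.binom.cdf(1, N - 1, p) for p in (0.01, 0.05, 0.2)]
    assert vals_p == sorted(vals_p)


def test_psex_on_simulated_clones(clonal_sample):
    """All true clone MLGs at 10 polymorphic SSR loci are recognised as
    clonal (psex < 0.05) in a ~200-ramet simulated population."""
    g, truth = clonal_sample
    part = identify_mlgs(g)
    sizes = part.clone_sizes("mlg")
    for method in ("single", "multiple"):
        ps = psex(g, part, method=method, freq_basis="genet")
        repeated = [ps[i] for i in range(len(sizes)) if sizes[i] >= 2]
        assert repeated and max(repeated) < 0.05


# ---------------------------------------------------------------------------
# Bruvo distance
# ---------------------------------------------------------------------------

SPEC2 = LocusSpec("l", "SSR", repeat_length=2, offset=0)


def test_bruvo_identical_zero():
    assert bruvo_distance((20, 24), (20, 24), SPEC2) == 0.0


def test_bruvo_closed_forms():
    # units {10,10} vs {11,11}: 1 - 2^-1 = 0.5
    assert bruvo_distance((20, 20), (22, 22), SPEC2) == pytest.approx(0.5)
    # units {10,12} vs {10,13}: best matching mean = 0.25
    assert bruvo_distance((20, 24), (20, 26), SPEC2) == pytest.approx(0.25)


def _bruvo_brute(x, y):
    """Enumerate all perfect matchings of diploid alleles (oracle)."""
    best = np.inf
    for perm in itertools.permutations(y):
        d = np.mean([1 - 2.0 ** (-abs(a - b)) for a, b in zip(x, perm)])
        best = min(best, d)
    return best


def test_bruvo_matches_brute_force_enumeration():
    """Implementation equals matching enumeration on random 6-locus
    genotype pairs (repeat units)."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        units = rng.integers(8, 16, size=(2, 6, 2))
        sizes = 100 + 2 * units
        expect = np.mean([
            _bruvo_brute(tuple(units[0, j]), tuple(units[1, j])) for j in range(6)
        ])
        got = np.mean([
            bruvo_distance(tuple(sizes[0, j]), tuple(sizes[1, j]), SPEC2)
            for j in range(6)
        ])
        assert got == pytest.approx(expect)


def test_bruvo_matrix_symmetric_zero_diag_missing():
    arr = np.array([[[100, 102], [104, 104]],
                    [[100, 102], [MISSING, MISSING]],
                    [[MISSING, MISSING], [MISSING, MISSING]]])
    g = make_matrix(arr)
    d = bruvo_matrix(g)
    assert np.allclose(d[:2, :2], d[:2, :2].T)
    assert d[0, 0] == 0.0
    assert d[0, 1] == 0.0  # only comparable locus identical
    assert np.isnan(d[0, 2])


@given(st.lists(st.integers(8, 20), min_size=4, max_size=4),
       st.lists(st.integers(8, 20), min_size=4, max_size=4))
@settings(max_examples=60, deadline=None)
def test_bruvo_semimetric_properties(u, v):
    a, b = (100 + 2 * u[0], 100 + 2 * u[1]), (100 + 2 * u[2], 100 + 2 * u[3])
    c = (100 + 2 * v[0], 100 + 2 * v[1])
    d_ab = bruvo_distance(a, b, SPEC2)
    assert 0.0 <= d_ab <= 1.0
    assert d_ab == bruvo_distance(b, a, SPEC2)
    # zero iff identical allele multisets
    assert (d_ab == 0.0) == (sorted(a) == sorted(b))
    assert bruvo_distance(c, c, SPEC2) == 0.0


# ---------------------------------------------------------------------------
# Threshold prediction and collapsing
# ---------------------------------------------------------------------------

def _partition_for_distances(n):
    return ClonalPartition(samples=[f"s{i}" for i in range(n)],
                           mlg=np.arange(n), mll=np.arange(n))


def test_threshold_hand_sorted_gaps():
    """Distances {0.01, 0.012, 0.3, 0.31}: largest low-end gap is
    0.012 -> 0.3, midpoint 0.156."""
    d = np.array([
        [0.0, 0.01, 0.012, 0.31],
        [0.01, 0.0, 0.3, 0.4],
        [0.012, 0.3, 0.0, 0.35],
        [0.31, 0.4, 0.35, 0.0],
    ])
    # use a 4-sample partition; between-MLG pairs give 6 distances, the
    # relevant low-end structure is preserved
    dist = np.zeros((4, 4))
    vals = [0.01, 0.012, 0.3, 0.31, 0.305, 0.31]
    iu = np.triu_indices(4, 1)
    dist[iu] = vals
    dist += dist.T
    thr = predict_mll_threshold(dist, _partition_for_distances(4))
    assert thr == pytest.approx((0.012 + 0.3) / 2)


def test_threshold_degenerate_equal_distances():
    dist = np.full((3, 3), 0.2)
    np.fill_diagonal(dist, 0.0)
    with pytest.warns(UserWarning):
        assert predict_mll_threshold(dist, _partition_for_distances(3)) == 0.0


def test_threshold_separates_scoring_errors(clonal_sample):
    """At 1%-per-allele miscall rate the predicted cutoff falls between
    the error-pair distances and the smallest true between-genet
    distance."""
    from genetne.simulate import apply_genotyping_noise

    g, truth = clonal_sample
    gn = apply_genotyping_noise(g, 0.0, 0.01, seed=99)
    part = identify_mlgs(gn)
    dist = bruvo_matrix(gn)
    thr = predict_mll_threshold(dist, part)
    # distances between MLG representatives of the same true genet (error
    # pairs) vs different genets
    reps = part.representatives("mlg")
    genet_of = truth.ramet_to_genet[reps]
    sub = dist[np.ix_(reps, reps)]
    iu = np.triu_indices(len(reps), 1)
    same = genet_of[iu[0]] == genet_of[iu[1]]
    # every error-derived pair falls below the cutoff ...
    assert sub[iu][same].max() < thr
    # ... while almost no genuine between-genet pair does (the extreme
    # tails of the two distributions may touch on a quantized ladder)
    assert (sub[iu][~same] < thr).mean() < 0.02


def test_collapse_threshold_zero_identity():
    g = make_matrix([[[100, 102]], [[100, 104]], [[102, 104]]])
    part = identify_mlgs(g)
    d = bruvo_matrix(g)
    out = collapse_mlls(part, d, 0.0)
    assert np.array_equal(out.mll, out.mlg)


def test_collapse_single_linkage_chaining():
    """d(1,2)=0.01, d(2,3)=0.01, d(1,3)=0.5 at threshold 0.02 chain into
    one MLL."""
    part = _partition_for_distances(3)
    d = np.array([[0.0, 0.01, 0.5], [0.01, 0.0, 0.01], [0.5, 0.01, 0.0]])
    out = collapse_mlls(part, d, 0.02)
    assert out.n_mll == 1
    assert out.n_mlg == 3  # MLG level untouched


def test_mll_collapse_order_invariant(clonal_sample):
    from genetne.simulate import apply_genotyping_noise

    g, _ = clonal_sample
    gn = apply_genotyping_noise(g, 0.0, 0.01, seed=7)
    rng = np.random.default_rng(1)
    perm = rng.permutation(gn.n_samples)
    gp = gn.subset(sample_idx=perm)

    def mll_pairs(gx):
        part = identify_mlgs(gx)
        d = bruvo_matrix(gx)
        out = collapse_mlls(part, d, 0.05)
        lab = dict(zip(gx.samples, out.mll))
        return {frozenset((a, b)) for a, b in itertools.combinations(gx.samples, 2)
                if lab[a] == lab[b]}

    assert mll_pairs(gn) == mll_pairs(gp)


# ---------------------------------------------------------------------------
# Genotypic diversity
# ---------------------------------------------------------------------------

def _partition_from_sizes(sizes):
    mlg = np.concatenate([[i] * s for i, s in enumerate(sizes)])
    return ClonalPartition(samples=[f"s{i}" for i in range(mlg.size)],
                           mlg=mlg, mll=mlg.copy())


def test_diversity_single_clone():
    d = genotypic_diversity(_partition_from_sizes([5]), "mlg")
    assert d.richness_R == 0.0 and d.G_count == 1 and d.lambda_ == 0.0


def test_diversity_even_clones():
    d = genotypic_diversity(_partition_from_sizes([5, 5]), "mlg")
    assert d.stoddart_G == pytest.approx(2.0)
    assert d.lambda_ == pytest.approx(0.5)
    assert d.evenness_E5 == pytest.approx(1.0)


def test_diversity_skewed_clones_arithmetic():
    """Sizes {9,1}: sum p^2 = 0.82, G = 1.2195, lambda = 0.18."""
    d = genotypic_diversity(_partition_from_sizes([9, 1]), "mlg")
    assert d.stoddart_G == pytest.approx(1 / 0.82)
    assert d.lambda_ == pytest.approx(0.18)


def test_emlg_rarefaction_identity():
    """Rarefying at the full sample size returns the clone count."""
    from genetne.clonal import expected_mlg

    sizes = np.array([4, 3, 2, 1])
    assert expected_mlg(sizes, 10) == pytest.approx(4.0)
    assert expected_mlg(sizes, 1) == pytest.approx(1.0)


def test_pareto_constructed_power_law():
    """Clone sizes built so that N_{>=c}/G = c^-2 over c in {1,2,4,8}
    give beta = 2 exactly."""
    sizes = [1] * 48 + [2] * 12 + [4] * 3 + [8]
    beta, _, r2 = pareto_beta(sizes)
    assert beta == pytest.approx(2.0)
    assert r2 == pytest.approx(1.0)


def test_pareto_single_size_undefined():
    beta, _, _ = pareto_beta([1, 1, 1, 1])
    assert np.isnan(beta)


def test_pareto_steeper_for_even_sizes():
    """At equal G and N, even clone sizes give a steeper slope than
    skewed ones."""
    even = [5] * 8 + [3] * 8            # mild spread around equal sizes
    skew = [20, 10, 8, 5, 3, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1]
    assert sum(even) == sum(skew) and len(even) == len(skew)
    b_even, _, _ = pareto_beta(even)
    b_skew, _, _ = pareto_beta(skew)
    assert b_even > b_skew


# ---------------------------------------------------------------------------
# Index of association
# ---------------------------------------------------------------------------

def test_rbard_duplicated_locus_is_one():
    arr = np.array([[[1, 2], [1, 2]], [[1, 1], [1, 1]], [[2, 2], [2, 2]],
                    [[1, 2], [1, 2]], [[2, 2], [2, 2]]])
    g = make_matrix(arr)
    rbar, _ = index_of_association(g, n_perm=0)
    assert rbar == pytest.approx(1.0)


def test_rbard_monomorphic_undefined():
    g = make_matrix([[[1, 1], [2, 2]]] * 4)
    rbar, p = index_of_association(g, n_perm=0)
    assert np.isnan(rbar)


def test_rbard_near_zero_under_random_mating():
    """Loci drawn independently (random mating, effectively infinite
    population) show no multilocus association: r̄d ~ 0 and the
    permutation test is non-significant in nearly all replicates.
    (A finite-Ne sample would genuinely carry drift LD.)"""
    rng = np.random.default_rng(17)
    n_sig, rbars = 0, []
    for _ in range(5):
        p = rng.uniform(0.3, 0.7, 12)
        arr = (rng.random((100, 12, 2)) < p[None, :, None]).astype(np.int64)
        g = make_matrix(arr, marker_type="SNP", repeat_length=None)
        rbar, pval = index_of_association(g, n_perm=199, seed=int(rng.integers(2**31)))
        rbars.append(rbar)
        n_sig += pval <= 0.05
    assert max(abs(r) for r in rbars) < 0.05
    assert n_sig <= 1


def test_rbard_decreases_after_clone_correction(clonal_sample):
    """Clonal replication inflates multilocus associations; removing
    clone copies deflates r̄d."""
    g, _ = clonal_sample
    part = identify_mlgs(g)
    raw, _ = index_of_association(g, part, level="raw", n_perm=0)
    cc, _ = index_of_association(g, part, level="mlg", n_perm=0)
    assert cc < raw


# ---------------------------------------------------------------------------
# Minimum spanning network
# ---------------------------------------------------------------------------

def test_msn_two_nodes_single_edge():
    part = _partition_for_distances(2)
    d = np.array([[0.0, 0.3], [0.3, 0.0]])
    edges, sizes = spanning_network(d, part, level="mlg")
    assert edges == [(0, 1, 0.3)]
    assert sizes == {0: 1, 1: 1}


def test_msn_matches_brute_force_enumeration():
    """4-node MST equals the exhaustive minimum over all 16 spanning
    trees."""
    rng = np.random.default_rng(5)
    d = rng.random((4, 4))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    part = _partition_for_distances(4)
    edges, _ = spanning_network(d, part, level="mlg")
    got = sum(w for _, _, w in edges)
    all_edges = list(itertools.combinations(range(4), 2))
    best = np.inf
    import networkx as nx
    for combo in itertools.combinations(all_edges, 3):
        G = nx.Graph(combo)
        if G.number_of_nodes() == 4 and nx.is_connected(G):
            best = min(best, sum(d[u, v] for u, v in combo))
    assert got == pytest.approx(best)


def test_msn_tie_break_deterministic():
    d = np.full((3, 3), 0.5)
    np.fill_diagonal(d, 0.0)
    part = _partition_for_distances(3)
    e1, _ = spanning_network(d, part, level="mlg")
    e2, _ = spanning_network(d, part, level="mlg")
    assert e1 == e2 == [(0, 1, 0.5), (0, 2, 0.5)]
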