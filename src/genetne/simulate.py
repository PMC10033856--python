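"""Synthetic-data generation with known ground truth.

Two generators:

``simulate_wf``
    An idealized Wright-Fisher population of known effective size —
    discrete non-overlapping generations, random mating, no mutation —
    used to validate the LD-Ne estimator against a known truth.

``simulate_clonal_population``
    A partially clonal, spatially clumped population: founder genets drawn
    from a Wright-Fisher standing pool, yearly clonal ramet addition
    (phalanx clumps), sexual recruits with parents sampled proportional to
    ramet count (larger clumps flower more, inflating variance in
    reproductive success), optional selfing, stepwise SSR mutation at
    meiosis only, and genotyping noise (missing calls, +/-1-repeat
    miscalls) applied last.  Clonal copies are genotype-identical before
    noise, so clone-identity ground truth stays crisp.

Two bundled scenarios mirror contrasting demographies: a stable, diverse
population dominated by clonal replication, and a founder-bottlenecked,
expanding population with abundant sexual recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import MISSING, GenotypeMatrix, LocusSpec


@dataclass
class SimParams:
    """Parameters for both simulator modes.

    Wright-Fisher mode uses ``true_ne``, ``n_generations``, the locus
    counts, and ``sample_size``.  The clonal simulator additionally uses
    the demographic block (founder_size, growth_rate, clonality_rate c,
    flowering_fraction, selfing_rate, n_years) and the spatial/noise
    block.  ``clonality_rate`` is the probability that a new ramet is a
    clonal copy rather than a sexual recruit.
    """

    true_ne: int = 50
    n_generations: int = 20
    n_loci_snp: int = 200
    n_loci_ssr: int = 0
    ssr_repeat_length: int = 2
    ssr_mutation_rate: float = 5e-4   # per transmitted allele, stepwise +/-1
    sample_size: int | None = None

    # clonal-population demography
    clonality_rate: float = 0.9
    founder_size: int = 10
    growth_rate: float = 0.3          # expected new ramets per genet per year
    flowering_fraction: float = 0.5
    selfing_rate: float = 0.02
    n_years: int = 50
    ancestral_ne: int = 200

    # spatial layout (documentation/plots only, never inference)
    clump_radius_coef: float = 0.3    # clump radius = coef * sqrt(ramets), metres
    recruit_dispersal: float = 1.0    # sd of recruit displacement, metres

    # genotyping noise
    missing_rate: float = 0.0
    scoring_error_rate: float = 0.0

    seed: int = 0
    name: str = "sim"

    def __post_init__(self):
        for f in ("clonality_rate", "flowering_fraction", "selfing_rate",
                  "missing_rate", "scoring_error_rate"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.true_ne < 2:
            raise ValueError("true_ne must be >= 2")

    def to_dict(self):
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated genotype matrix."""

    ramet_to_genet: np.ndarray            # per output sample
    pedigree: list                        # (genet, mother, father, year); -1 founders
    ramet_coords: np.ndarray              # (n_ramets, 2)
    clump_coords: dict                    # genet -> (x, y) clump centre
    census: list                          # (year, n_ramets, n_genets)
    true_ne_trace: list
    params: SimParams | None = None

    def to_dict(self):
        return {
            "ramet_to_genet": self.ramet_to_genet.tolist(),
            "pedigree": [list(p) for p in self.pedigree],
            "census": [list(c) for c in self.census],
            "true_ne_trace": list(self.true_ne_trace),
        }


def _make_loci(params: SimParams) -> list[LocusSpec]:
    loci = [
        LocusSpec(name=f"ssr{k:02d}", marker_type="SSR",
                  repeat_length=params.ssr_repeat_length)
        for k in range(params.n_loci_ssr)
    ]
    loci += [
        LocusSpec(name=f"snp{k:04d}", marker_type="SNP")
        for k in range(params.n_loci_snp)
    ]
    return loci


def _init_pool(params: SimParams, rng) -> np.ndarray:
    """Initial diploid genotypes (N, L, 2) for the ancestral/WF population.

    SNP alleles are 0/1 with starting frequencies uniform on (0.1, 0.9);
    SSR alleles are fragment sizes on a stepwise ladder (motif length
    ``ssr_repeat_length``) with 4-8 starting alleles at Dirichlet-drawn
    frequencies, emulating standing microsatellite variation.
    """
    N = params.true_ne
    L_ssr, L_snp = params.n_loci_ssr, params.n_loci_snp
    out = np.empty((N, L_ssr + L_snp, 2), dtype=np.int64)
    for j in range(L_ssr):
        k = rng.integers(4, 9)
        units = np.arange(10, 10 + k)
        freqs = rng.dirichlet(np.ones(k) * 2.0)
        sizes = 100 + params.ssr_repeat_length * units
        out[:, j, :] = rng.choice(sizes, size=(N, 2), p=freqs)
    for j in range(L_snp):
        p = rng.uniform(0.1, 0.9)
        out[:, L_ssr + j, :] = (rng.random((N, 2)) < p).astype(np.int64)
    return out


def _wf_generation(pool: np.ndarray, n_offspring: int, rng) -> np.ndarray:
    """One Wright-Fisher generation: random union of gametes.

    Each offspring draws two parents uniformly (multinomial family
    sizes); each gamete transmits one allele per locus independently
    (free recombination among unlinked loci).
    """
    N, L, _ = pool.shape
    mothers = rng.integers(N, size=n_offspring)
    fathers = rng.integers(N, size=n_offspring)
    pick_m = rng.integers(2, size=(n_offspring, L))
    pick_f = rng.integers(2, size=(n_offspring, L))
    child = np.empty((n_offspring, L, 2), dtype=pool.dtype)
    child[:, :, 0] = pool[mothers[:, None], np.arange(L)[None, :], pick_m]
    child[:, :, 1] = pool[fathers[:, None], np.arange(L)[None, :], pick_f]
    return child


def simulate_wf(params: SimParams) -> tuple[GenotypeMatrix, SimTruth]:
    """Wright-Fisher population of known Ne; returns sampled genotypes.

    Runs ``n_generations`` (>= 5 recommended so LD equilibrates), then
    samples ``sample_size`` individuals without replacement from the
    final generation (all of it when None).  No mutation: a locus fixed
    at the start stays fixed.
    """
    if params.n_generations < 1:
        raise ValueError("need at least one generation")
    S = params.sample_size if params.sample_size is not None else params.true_ne
    if S > params.true_ne:
        raise ValueError("sample_size cannot exceed true_ne")
    rng = np.random.default_rng(params.seed)
    pool = _init_pool(params, rng)
    for _ in range(params.n_generations):
        pool = _wf_generation(pool, params.true_ne, rng)
    pick = rng.choice(params.true_ne, size=S, replace=False)
    loci = _make_loci(params)
    g = GenotypeMatrix(
        samples=[f"{params.name}_{i:04d}" for i in range(S)],
        loci=loci,
        alleles=pool[pick].copy(),
        populations=[params.name] * S,
        metadata={"mode": "wright_fisher", "true_ne": params.true_ne},
    )
    truth = SimTruth(
        ramet_to_genet=np.arange(S),
        pedigree=[],
        ramet_coords=np.zeros((S, 2)),
        clump_coords={},
        census=[(params.n_generations, params.true_ne, params.true_ne)],
        true_ne_trace=[params.true_ne] * params.n_generations,
        params=params,
    )
    if params.missing_rate or params.scoring_error_rate:
        g = apply_genotyping_noise(
            g, params.missing_rate, params.scoring_error_rate,
            seed=int(rng.integers(2 ** 31)),
        )
    return g, truth


def _gamete(genotype: np.ndarray, params: SimParams, rng,
            ssr_slice: slice) -> np.ndarray:
    """One meiotic gamete with stepwise SSR mutation."""
    L = genotype.shape[0]
    gam = genotype[np.arange(L), rng.integers(2, size=L)].copy()
    if params.ssr_mutation_rate > 0 and ssr_slice.stop > ssr_slice.start:
        n_ssr = ssr_slice.stop - ssr_slice.start
        mut = rng.random(n_ssr) < params.ssr_mutation_rate
        if mut.any():
            step = rng.choice([-1, 1], size=int(mut.sum())) * params.ssr_repeat_length
            seg = gam[ssr_slice]
            seg[mut] = seg[mut] + step
            gam[ssr_slice] = seg
    return gam


def simulate_clonal_population(params: SimParams) -> tuple[GenotypeMatrix, SimTruth]:
    """Partially clonal, spatially clumped population with truth tables.

    Founder genets are drawn from a Wright-Fisher standing pool of size
    ``ancestral_ne``.  Each year every genet adds clonal ramets
    (Poisson, mean ``growth_rate * c``) inside its clump, and the
    population gains sexual recruits (Poisson, mean
    ``n_genets * growth_rate * (1 - c) * flowering_fraction``) whose
    parents are sampled proportional to ramet count; recruits establish
    near the maternal clump.  Genets persist across years (overlapping
    generations — the realistic, mixed-age sampling regime).
    """
    if params.founder_size < 2:
        raise ValueError("founder_size must be >= 2")
    rng = np.random.default_rng(params.seed)
    pool_params = SimParams(
        true_ne=params.ancestral_ne, n_generations=params.n_generations,
        n_loci_snp=params.n_loci_snp, n_loci_ssr=params.n_loci_ssr,
        ssr_repeat_length=params.ssr_repeat_length,
        seed=int(rng.integers(2 ** 31)), name="ancestral",
    )
    pool_g, _ = simulate_wf(pool_params)
    loci = list(pool_g.loci)
    L = len(loci)
    ssr_slice = slice(0, params.n_loci_ssr)

    founders = rng.choice(params.ancestral_ne, size=params.founder_size, replace=False)
    genotypes = [pool_g.alleles[i].copy() for i in founders]
    ramets = [1] * params.founder_size
    centres = [rng.uniform(-20, 20, size=2) for _ in range(params.founder_size)]
    pedigree = [(i, -1, -1, 0) for i in range(params.founder_size)]
    census = [(0, sum(ramets), len(ramets))]

    for year in range(1, params.n_years + 1):
        n_genets = len(genotypes)
        # clonal ramet addition (phalanx growth within the clump)
        new_clonal = rng.poisson(params.growth_rate * params.clonality_rate,
                                 size=n_genets)
        for k in range(n_genets):
            ramets[k] += int(new_clonal[k])
        # sexual recruits: parents proportional to ramet count
        mean_recruits = (n_genets * params.growth_rate
                         * (1.0 - params.clonality_rate) * params.flowering_fraction)
        n_recruits = rng.poisson(mean_recruits)
        if n_recruits:
            w = np.asarray(ramets[:n_genets], dtype=float)
            w = w / w.sum()
            for _ in range(n_recruits):
                mother = int(rng.choice(n_genets, p=w))
                father = mother if rng.random() < params.selfing_rate \
                    else int(rng.choice(n_genets, p=w))
                child = np.empty((L, 2), dtype=np.int64)
                child[:, 0] = _gamete(genotypes[mother], params, rng, ssr_slice)
                child[:, 1] = _gamete(genotypes[father], params, rng, ssr_slice)
                genotypes.append(child)
                ramets.append(1)
                centres.append(centres[mother] + rng.normal(0, params.recruit_dispersal, 2))
                pedigree.append((len(genotypes) - 1, mother, father, year))
        if sum(ramets) == 0:
            raise RuntimeError(f"population extinct at year {year}")
        census.append((year, sum(ramets), len(genotypes)))

    # expand genets into ramet-level rows
    ramet_genet, rows, coords = [], [], []
    for gid, (geno, count, centre) in enumerate(zip(genotypes, ramets, centres)):
        radius = params.clump_radius_coef * np.sqrt(count)
        for _ in range(count):
            rows.append(geno)
            ramet_genet.append(gid)
            r = radius * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            coords.append(centre + r * np.array([np.cos(th), np.sin(th)]))
    arr = np.stack(rows, axis=0)
    n = arr.shape[0]
    g = GenotypeMatrix(
        samples=[f"{params.name}_r{i:04d}" for i in range(n)],
        loci=loci,
        alleles=arr,
        populations=[params.name] * n,
        metadata={"mode": "clonal", "n_genets": len(genotypes)},
    )
    truth = SimTruth(
        ramet_to_genet=np.asarray(ramet_genet),
        pedigree=pedigree,
        ramet_coords=np.asarray(coords),
        clump_coords={i: tuple(c) for i, c in enumerate(centres)},
        census=census,
        true_ne_trace=[len(genotypes)],
        params=params,
    )
    if params.missing_rate or params.scoring_error_rate:
        g = apply_genotyping_noise(
            g, params.missing_rate, params.scoring_error_rate,
            seed=int(rng.integers(2 ** 31)),
        )
    return g, truth


def apply_genotyping_noise(g: GenotypeMatrix, missing_rate: float,
                           scoring_error_rate: float, seed: int = 0) -> GenotypeMatrix:
    """Overlay missing calls and scoring errors on a genotype matrix.

    Each genotype independently becomes MISSING with ``missing_rate``.
    Each surviving allele is miscalled with ``scoring_error_rate``: SSR
    alleles shift one repeat up or down (fair coin); SNP alleles flip.
    """
    if not (0 <= missing_rate <= 1 and 0 <= scoring_error_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arr = g.alleles.copy()
    n, L, _ = arr.shape
    if missing_rate > 0:
        drop = rng.random((n, L)) < missing_rate
        arr[drop] = MISSING
    if scoring_error_rate > 0:
        observed = arr[:, :, 0] != MISSING
        err = (rng.random((n, L, 2)) < scoring_error_rate) & observed[:, :, None]
        is_ssr = np.array([Lc.marker_type == "SSR" for Lc in g.loci])
        steps = rng.choice([-1, 1], size=(n, L, 2))
        for j in range(L):
            e = err[:, j, :]
            if not e.any():
                continue
            if is_ssr[j]:
                arr[:, j, :][e] += steps[:, j, :][e] * (g.loci[j].repeat_length or 1)
            else:
                arr[:, j, :][e] = 1 - arr[:, j, :][e]
    return GenotypeMatrix(
        samples=list(g.samples), loci=list(g.loci), alleles=arr,
        populations=list(g.populations), metadata=dict(g.metadata),
    )


def load_scenario(name_or_path) -> SimParams:
    """Load a bundled scenario ("stable", "founder") or a YAML file."""
    import importlib.resources as ir

    import yaml

    if str(name_or_path) in ("stable", "founder"):
        text = (ir.files("genetne") / "scenarios" / f"{name_or_path}.yaml").read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    known = set(SimParams.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return SimParams(**data)
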