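"""Genotype containers and readers/writers for the formats the pipeline touches.

The central container is :class:`GenotypeMatrix`: a ramet-by-locus table of
diploid genotypes.  Microsatellite (SSR) alleles are stored as fragment sizes
in base pairs; SNP alleles as 0/1.  A genotype is either fully observed (two
alleles) or fully missing — half calls are collapsed to missing on input.

Supported formats: GenAlEx-style CSV and Genepop (2- and 3-digit) for SSR
tables, VCF 4.x for SNPs (via cyvcf2), and TSV/JSON for analysis reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel allele code for missing data.  SSR tables use allele 0 and VCF
#: uses "." for missing; both map here.
MISSING = -1


@dataclass(frozen=True)
class LocusSpec:
    """Description of one locus.

    Parameters
    ----------
    name : str
        Locus identifier.
    marker_type : {"SSR", "SNP"}
    repeat_length : int, optional
        Repeat-motif length in bp (SSR only); required for Bruvo distances.
    offset : int, optional
        Per-locus fragment-size offset subtracted before converting SSR
        fragment sizes to repeat units.  If omitted, the smallest observed
        allele is used as the ladder origin.
    """

    name: str
    marker_type: str = "SSR"
    repeat_length: int | None = None
    offset: int | None = None

    def __post_init__(self):
        if self.marker_type not in ("SSR", "SNP"):
            raise ValueError(f"unknown marker_type {self.marker_type!r}")


@dataclass
class GenotypeMatrix:
    """Ramet x locus diploid genotype table.

    Attributes
    ----------
    samples : list of str
        Ordered ramet identifiers.
    loci : list of LocusSpec
    alleles : ndarray of shape (n_samples, n_loci, 2), dtype int
        Allele codes; both slots equal :data:`MISSING` for missing calls.
        Pairs are unordered: ``(a, b)`` and ``(b, a)`` denote the same
        genotype (canonicalised so the smaller code comes first).
    populations : list of str
        Population label per sample.
    """

    samples: list[str]
    loci: list[LocusSpec]
    alleles: np.ndarray
    populations: list[str]
    metadata: dict = field(default_factory=dict)

    ploidy: int = 2

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.shape != (len(self.samples), len(self.loci), 2):
            raise ValueError("alleles array shape does not match samples/loci")
        if len(self.populations) != len(self.samples):
            raise ValueError("every sample needs a population label")
        # enforce "no half calls" and order-independence
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            self.alleles[half] = MISSING
        self.alleles = np.sort(self.alleles, axis=2)
        # sort puts MISSING (-1) first; fully-missing pairs stay (-1, -1)

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci): True where the call is missing."""
        return self.alleles[:, :, 0] == MISSING

    def allele_counts(self, locus: int, sample_idx=None) -> dict[int, int]:
        """Counts of each observed allele code at ``locus``."""
        a = self.alleles[:, locus, :] if sample_idx is None else self.alleles[sample_idx, locus, :]
        a = a[a != MISSING]
        codes, counts = np.unique(a, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    def allele_freqs(self, locus: int, sample_idx=None) -> dict[int, float]:
        counts = self.allele_counts(locus, sample_idx)
        tot = sum(counts.values())
        return {a: c / tot for a, c in counts.items()} if tot else {}

    def dosage(self, locus: int, allele: int) -> np.ndarray:
        """Per-sample copy count of ``allele`` at ``locus`` (NaN if missing)."""
        pair = self.alleles[:, locus, :]
        d = (pair == allele).sum(axis=1).astype(float)
        d[pair[:, 0] == MISSING] = np.nan
        return d

    def heterozygous(self, locus: int) -> np.ndarray:
        """Per-sample bool (float NaN for missing): genotype heterozygous?"""
        pair = self.alleles[:, locus, :]
        h = (pair[:, 0] != pair[:, 1]).astype(float)
        h[pair[:, 0] == MISSING] = np.nan
        return h

    def population_indices(self) -> dict[str, np.ndarray]:
        pops: dict[str, list[int]] = {}
        for i, p in enumerate(self.populations):
            pops.setdefault(p, []).append(i)
        return {p: np.asarray(ix) for p, ix in pops.items()}

    # -- subsetting ----------------------------------------------------

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            loci=[self.loci[j] for j in li],
            alleles=self.alleles[np.ix_(si, li)].copy(),
            populations=[self.populations[i] for i in si],
            metadata=dict(self.metadata),
        )

    def ssr_loci(self) -> np.ndarray:
        return np.array([j for j, L in enumerate(self.loci) if L.marker_type == "SSR"], dtype=int)

    def snp_loci(self) -> np.ndarray:
        return np.array([j for j, L in enumerate(self.loci) if L.marker_type == "SNP"], dtype=int)


def concat_populations(*matrices: GenotypeMatrix) -> GenotypeMatrix:
    """Stack matrices sample-wise; loci must match by name and order."""
    first = matrices[0]
    names = [L.name for L in first.loci]
    for m in matrices[1:]:
        if [L.name for L in m.loci] != names:
            raise ValueError("loci do not match across matrices")
    return GenotypeMatrix(
        samples=[s for m in matrices for s in m.samples],
        loci=list(first.loci),
        alleles=np.concatenate([m.alleles for m in matrices], axis=0),
        populations=[p for m in matrices for p in m.populations],
    )


# ---------------------------------------------------------------------------
# SSR tables: GenAlEx CSV and Genepop
# ---------------------------------------------------------------------------

def read_ssr_table(path, dialect: str = "genalex", repeat_lengths=None) -> GenotypeMatrix:
    """Read a microsatellite genotype table.

    Parameters
    ----------
    path : str or Path
    dialect : {"genalex", "genepop"}
    repeat_lengths : dict, optional
        Locus name -> repeat motif length (bp); attached to the LocusSpecs
        so Bruvo distances can be computed downstream.

    Allele code 0 is the conventional missing marker and maps to MISSING;
    a genotype with one missing allele is treated as fully missing.
    """
    if dialect == "genalex":
        g = _read_genalex(path)
    elif dialect == "genepop":
        g = _read_genepop(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if repeat_lengths:
        g.loci = [
            replace(L, repeat_length=repeat_lengths.get(L.name, L.repeat_length))
            for L in g.loci
        ]
    return g


def _is_all_numeric(cells) -> bool:
    vals = [c for c in cells if c.strip() != ""]
    if not vals:
        return False
    try:
        for v in vals:
            float(v)
    except ValueError:
        return False
    return True


def _read_genalex(path) -> GenotypeMatrix:
    with open(path, "r", newline="") as fh:
        rows = [line.rstrip("\n").rstrip("\r").split(",") for line in fh if line.strip()]
    # GenAlEx files open with two bookkeeping lines (counts; titles).  They are
    # auto-detected: if line 1 is all numeric it is a counts line.
    if _is_all_numeric(rows[0]):
        rows = rows[2:]
    header = rows[0]
    locus_names = [h.strip() for h in header[2::2]]
    locus_names = [n for n in locus_names if n]
    n_loci = len(locus_names)
    samples, pops, calls = [], [], []
    for lineno, row in enumerate(rows[1:], start=2):
        cells = [c.strip() for c in row]
        if not any(cells):
            continue
        allele_cells = [c for c in cells[2:] if c != ""]
        if len(allele_cells) != 2 * n_loci:
            raise ValueError(
                f"{path}: line {lineno}: expected {2 * n_loci} allele columns, "
                f"got {len(allele_cells)}"
            )
        samples.append(cells[0])
        pops.append(cells[1] if cells[1] else "pop1")
        calls.append([int(c) for c in allele_cells])
    arr = np.asarray(calls, dtype=np.int64).reshape(len(samples), n_loci, 2)
    arr[arr == 0] = MISSING
    loci = [LocusSpec(name=n, marker_type="SSR") for n in locus_names]
    return GenotypeMatrix(samples=samples, loci=loci, alleles=arr, populations=pops)


def _parse_genepop_token(tok: str) -> tuple[int, int]:
    tok = tok.strip()
    if len(tok) not in (4, 6) or not tok.isdigit():
        raise ValueError(f"malformed Genepop allele token {tok!r}")
    w = len(tok) // 2
    return int(tok[:w]), int(tok[w:])


def _read_genepop(path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    # line 0 is a free title
    body = lines[1:]
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # loci may be one per line or comma-separated
        locus_names.extend(n.strip() for n in body[i].split(",") if n.strip())
        i += 1
    samples, pops, calls = [], [], []
    pop_counter = 0
    while i < len(body):
        if body[i].strip().lower() == "pop":
            pop_counter += 1
            i += 1
            continue
        line = body[i]
        if "," not in line:
            raise ValueError(f"{path}: sample line without comma: {line!r}")
        name, rest = line.split(",", 1)
        toks = rest.split()
        if len(toks) != len(locus_names):
            raise ValueError(
                f"{path}: sample {name.strip()!r}: {len(toks)} genotypes for "
                f"{len(locus_names)} loci"
            )
        samples.append(name.strip())
        pops.append(f"pop{pop_counter}")
        calls.append([a for t in toks for a in _parse_genepop_token(t)])
        i += 1
    arr = np.asarray(calls, dtype=np.int64).reshape(len(samples), len(locus_names), 2)
    arr[arr == 0] = MISSING
    loci = [LocusSpec(name=n, marker_type="SSR") for n in locus_names]
    return GenotypeMatrix(samples=samples, loci=loci, alleles=arr, populations=pops)


def write_genalex(g: GenotypeMatrix, path) -> None:
    pops = list(dict.fromkeys(g.populations))
    pop_sizes = [sum(1 for p in g.populations if p == q) for q in pops]
    with open(path, "w", newline="") as fh:
        fh.write(",".join(str(x) for x in [g.n_loci, g.n_samples, len(pops)] + pop_sizes) + "\n")
        fh.write("genetne export," + "," * 2 + ",".join(pops) + "\n")
        cells = ["Sample", "Pop"]
        for L in g.loci:
            cells += [L.name, ""]
        fh.write(",".join(cells) + "\n")
        out = np.where(g.alleles == MISSING, 0, g.alleles)
        for i, s in enumerate(g.samples):
            row = [s, g.populations[i]] + [str(int(a)) for a in out[i].ravel()]
            fh.write(",".join(row) + "\n")


def write_genepop(g: GenotypeMatrix, path, digits: int = 3) -> None:
    out = np.where(g.alleles == MISSING, 0, g.alleles)
    if out.max() >= 10 ** digits:
        raise ValueError(f"allele codes do not fit in {digits} digits")
    with open(path, "w") as fh:
        fh.write("genetne export\n")
        for L in g.loci:
            fh.write(L.name + "\n")
        pop_order = list(dict.fromkeys(g.populations))
        for pop in pop_order:
            fh.write("Pop\n")
            for i, s in enumerate(g.samples):
                if g.populations[i] != pop:
                    continue
                toks = [
                    f"{out[i, j, 0]:0{digits}d}{out[i, j, 1]:0{digits}d}"
                    for j in range(g.n_loci)
                ]
                fh.write(f"{s}, " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, one_snp_per_locus: str | None = "first", seed: int = 0,
             population_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read diploid biallelic SNP genotypes from a VCF.

    RAD loci are identified by CHROM; at most one site is retained per locus
    under ``one_snp_per_locus``: "first" keeps the lowest-position site,
    "random" draws one reproducibly under ``seed``, None keeps all sites.
    Multiallelic sites are skipped (count logged).  ``./.`` and ``.|.``
    become MISSING; phasing is ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    sites = []  # (chrom, pos, genotype array)
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # list of [a1, a2, phased]
        if gts is None:
            raise ValueError(f"{path}: no GT field at {var.CHROM}:{var.POS}")
        pair = np.array([[gt[0], gt[1]] for gt in gts], dtype=np.int64)
        pair[pair < 0] = MISSING
        sites.append((var.CHROM, var.POS, pair))
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic sites", n_multi)

    by_locus: dict[str, list] = {}
    for chrom, pos, pair in sites:
        by_locus.setdefault(chrom, []).append((pos, pair))
    rng = np.random.default_rng(seed)
    chosen = []
    for chrom in by_locus:  # insertion order = file order
        group = sorted(by_locus[chrom], key=lambda t: t[0])
        if one_snp_per_locus is None:
            chosen.extend((chrom, pos, pair) for pos, pair in group)
        elif one_snp_per_locus == "first":
            pos, pair = group[0]
            chosen.append((chrom, pos, pair))
        elif one_snp_per_locus == "random":
            pos, pair = group[rng.integers(len(group))]
            chosen.append((chrom, pos, pair))
        else:
            raise ValueError(f"unknown rule {one_snp_per_locus!r}")

    loci = [LocusSpec(name=f"{chrom}:{pos}", marker_type="SNP") for chrom, pos, _ in chosen]
    if chosen:
        arr = np.stack([pair for _, _, pair in chosen], axis=1)
    else:
        arr = np.empty((len(sample_names), 0, 2), dtype=np.int64)
    pops = (
        [population_map.get(s, "pop1") for s in sample_names]
        if population_map
        else ["pop1"] * len(sample_names)
    )
    return GenotypeMatrix(samples=sample_names, loci=loci, alleles=arr, populations=pops)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _format_float(x) -> str:
    if isinstance(x, float):
        if math.isinf(x):
            return "Inf" if x > 0 else "-Inf"
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if math.isinf(x):
            return "Inf" if x > 0 else "-Inf"
        if math.isnan(x):
            return None
        return float(f"{x:.6g}")
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_report(result, path, format: str = "json") -> None:
    """Serialize a report object to TSV or JSON.

    Field order is deterministic; floats are written at 6 significant
    digits; infinities serialize as the token ``Inf``.  JSON output
    round-trips via :func:`read_report_json`.
    """
    if format == "json":
        payload = _jsonable(result.to_dict() if hasattr(result, "to_dict") else result)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "tsv":
        frame = result.to_frame() if hasattr(result, "to_frame") else pd.DataFrame(result)
        with open(path, "w") as fh:
            fh.write("\t".join(map(str, frame.columns)) + "\n")
            for _, row in frame.iterrows():
                fh.write("\t".join(_format_float(v) for v in row) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path):
    """Inverse of :func:`write_report` for JSON: restores Inf tokens."""

    def restore(obj):
        if isinstance(obj, dict):
            return {k: restore(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [restore(v) for v in obj]
        if obj == "Inf":
            return math.inf
        if obj == "-Inf":
            return -math.inf
        return obj

    with open(path) as fh:
        return restore(json.load(fh))
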