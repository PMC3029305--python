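"""Biparental mapping populations and QTL phenotype models.

Simulates recombinant inbred line (RIL) and F2 genotypes on a
multi-chromosome genetic map, assigns genetic values under single- or
two-locus QTL models (additive, dominance, overdominance, repulsion
linkage, epistasis), adds environmental noise as the mean of repeated
measurements per line, and selects extreme phenotype pools for bulk
segregant analysis.

Genotypes are coded as the count of reference-parent (Col-0-like "A")
alleles: ``0`` = BB (homozygous alternate), ``1`` = AB (heterozygous),
``2`` = AA (homozygous reference).

Meiosis follows the Haldane model (no crossover interference): the
recombination fraction between markers ``d`` cM apart is
``r = (1 - exp(-2d/100)) / 2``.  RILs are modelled at the
infinite-selfing limit, where the fraction of recombinant lines between
adjacent markers is ``R = 2r / (1 + 2r)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BB",
    "AB",
    "AA",
    "GeneticMap",
    "QTLLocus",
    "QTLModel",
    "GenotypeMatrix",
    "PoolSelection",
    "haldane_r",
    "ril_r",
    "simulate_gametes",
    "simulate_population",
    "genetic_value",
    "simulate_phenotypes",
    "select_pools",
    "marginal_allele_effect",
    "model_preset",
    "MODEL_PRESETS",
    "default_map",
    "DEFAULT_CHROM_LENGTHS_CM",
]

BB, AB, AA = 0, 1, 2

#: Arabidopsis-like genetic lengths (cM) for the five default chromosomes.
DEFAULT_CHROM_LENGTHS_CM: dict[str, float] = {
    "1": 135.0,
    "2": 88.0,
    "3": 101.0,
    "4": 125.0,
    "5": 139.0,
}


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction between loci ``d_cM`` apart (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def ril_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Fraction of selfed-RIL lines recombinant between loci ``d_cM`` apart.

    Infinite-selfing limit ``R = 2r / (1 + 2r)`` of the per-meiosis
    Haldane fraction ``r``.
    """
    r = haldane_r(d_cM)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass(frozen=True, eq=False)
class GeneticMap:
    """Chromosome genetic lengths plus ordered marker positions (cM).

    Parameters
    ----------
    lengths_cM
        Mapping of chromosome name to genetic length in cM.
    markers
        Mapping of chromosome name to a strictly increasing array of
        marker positions in cM, within ``[0, length]``, at least two
        markers per chromosome.
    """

    lengths_cM: dict[str, float]
    markers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.lengths_cM:
            raise ValueError("map must contain at least one chromosome")
        if set(self.markers) != set(self.lengths_cM):
            raise ValueError("marker chromosomes do not match map chromosomes")
        frozen = {}
        for chrom, length in self.lengths_cM.items():
            pos = np.asarray(self.markers[chrom], dtype=float)
            if pos.size < 2:
                raise ValueError(f"chromosome {chrom!r} needs >= 2 markers")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions on {chrom!r} must be strictly increasing")
            if pos[0] < 0 or pos[-1] > length:
                raise ValueError(f"marker positions on {chrom!r} outside [0, {length}]")
            pos.setflags(write=False)
            frozen[chrom] = pos
        object.__setattr__(self, "markers", frozen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return self.lengths_cM == other.lengths_cM and all(
            np.array_equal(self.markers[c], other.markers[c]) for c in self.lengths_cM
        )

    __hash__ = object.__hash__

    @classmethod
    def uniform(
        cls,
        lengths_cM: dict[str, float] | None = None,
        spacing_cM: float = 0.5,
    ) -> "GeneticMap":
        """Map with equally spaced markers from 0 to each chromosome end."""
        if lengths_cM is None:
            lengths_cM = dict(DEFAULT_CHROM_LENGTHS_CM)
        markers = {
            chrom: np.arange(0.0, length + spacing_cM / 2, spacing_cM)
            for chrom, length in lengths_cM.items()
        }
        # clip a final marker that overshoots through float accumulation
        markers = {c: p[p <= lengths_cM[c] + 1e-9] for c, p in markers.items()}
        return cls(lengths_cM=dict(lengths_cM), markers=markers)

    @property
    def chromosome_names(self) -> list[str]:
        return list(self.lengths_cM)

    @property
    def n_markers(self) -> int:
        return sum(p.size for p in self.markers.values())

    def chrom_slices(self) -> dict[str, slice]:
        """Slice of each chromosome's markers in the concatenated marker vector."""
        out, start = {}, 0
        for chrom in self.chromosome_names:
            m = self.markers[chrom].size
            out[chrom] = slice(start, start + m)
            start += m
        return out

    def marker_index(self, chrom: str, pos_cM: float) -> int:
        """Index (in the concatenated marker vector) of the marker nearest ``pos_cM``."""
        if chrom not in self.markers:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos_cM <= self.lengths_cM[chrom]:
            raise ValueError(f"position {pos_cM} cM off chromosome {chrom!r}")
        local = int(np.argmin(np.abs(self.markers[chrom] - pos_cM)))
        return self.chrom_slices()[chrom].start + local


def default_map(spacing_cM: float = 0.5) -> GeneticMap:
    """Five-chromosome Arabidopsis-like map with uniform marker spacing."""
    return GeneticMap.uniform(DEFAULT_CHROM_LENGTHS_CM, spacing_cM)


@dataclass(frozen=True)
class QTLLocus:
    """One QTL: chromosome, map position, additive effect a, dominance d.

    Genetic value contribution is ``+a`` for AA, ``d`` for AB, ``-a``
    for BB (AA carries two reference-parent alleles).
    """

    chrom: str
    pos_cM: float
    a: float
    d: float = 0.0


@dataclass(frozen=True)
class QTLModel:
    """Genetic model: QTL effects, optional two-locus epistasis, noise.

    Parameters
    ----------
    loci
        One or two QTL.
    epistasis
        Optional 3x3 table of genetic values for every two-locus
        genotype combination, indexed ``[g1, g2]`` with each ``g`` the
        reference-allele count (0=BB, 1=AB, 2=AA).  When present it
        *replaces* the per-locus additive/dominance sum.
    env_sd
        Environmental standard deviation of a single measurement.
    reps_per_line
        Number of measurements averaged per individual.
    """

    loci: tuple[QTLLocus, ...]
    epistasis: np.ndarray | None = None
    env_sd: float = 1.0
    reps_per_line: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        if self.epistasis is not None:
            tab = np.asarray(self.epistasis, dtype=float)
            if tab.shape != (3, 3):
                raise ValueError("epistasis table must be 3x3")
            if len(self.loci) != 2:
                raise ValueError("epistasis table requires exactly 2 loci")
            tab.setflags(write=False)
            object.__setattr__(self, "epistasis", tab)
        if self.env_sd < 0:
            raise ValueError("env_sd must be >= 0")
        if self.reps_per_line < 1:
            raise ValueError("reps_per_line must be >= 1")

    @property
    def linked_chromosomes(self) -> set[str]:
        return {locus.chrom for locus in self.loci}


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x markers genotype codes on a map.

    ``codes[i, j]`` counts reference-parent alleles (0/1/2) of
    individual ``i`` at marker ``j`` of the concatenated marker vector.
    """

    codes: np.ndarray
    map: GeneticMap
    population_type: str

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape[1] != self.map.n_markers:
            raise ValueError("codes shape does not match the map's marker count")
        if self.population_type not in ("RIL", "F2"):
            raise ValueError(f"unknown population_type {self.population_type!r}")
        codes.setflags(write=False)
        object.__setattr__(self, "codes", codes)

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    def subset(self, individuals: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes[np.asarray(individuals)], self.map, self.population_type)


@dataclass(frozen=True)
class PoolSelection:
    """Disjoint index sets for the high and low phenotype bulks."""

    high_pool: np.ndarray
    low_pool: np.ndarray
    selection_fraction: float | None = None

    def __post_init__(self) -> None:
        high = np.asarray(self.high_pool, dtype=np.intp)
        low = np.asarray(self.low_pool, dtype=np.intp)
        if high.size == 0 or low.size == 0:
            raise ValueError("pools must be non-empty")
        if np.intersect1d(high, low).size:
            raise ValueError("high and low pools must be disjoint")
        for arr in (high, low):
            arr.setflags(write=False)
        object.__setattr__(self, "high_pool", high)
        object.__setattr__(self, "low_pool", low)


def simulate_gametes(gmap: GeneticMap, n_gametes: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate meiotic products on the map.

    Returns an ``n_gametes x n_markers`` 0/1 array (1 = reference-parent
    allele).  Crossovers follow a Markov chain along each chromosome
    with adjacent-marker switch probability given by the Haldane
    recombination fraction; chromosomes assort independently.
    """
    if n_gametes < 1:
        raise ValueError("n_gametes must be >= 1")
    chunks = []
    for chrom in gmap.chromosome_names:
        pos = gmap.markers[chrom]
        r = haldane_r(np.diff(pos))
        first = rng.integers(0, 2, size=(n_gametes, 1), dtype=np.int8)
        switches = (rng.random((n_gametes, pos.size - 1)) < r).astype(np.int8)
        alleles = (first + np.cumsum(switches, axis=1, dtype=np.int32)) % 2
        chunks.append(np.concatenate([first, alleles.astype(np.int8)], axis=1))
    return np.concatenate(chunks, axis=1)


def simulate_population(
    gmap: GeneticMap, pop_type: str, n: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Simulate ``n`` individuals of an F2 or selfed-RIL population.

    F2 individuals are the union of two independent gametes.  RILs are
    fully homozygous mosaics with adjacent-marker recombination fraction
    ``R = 2r/(1+2r)``.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pop_type == "F2":
        gametes = simulate_gametes(gmap, 2 * n, rng)
        codes = gametes[0::2] + gametes[1::2]
    elif pop_type == "RIL":
        chunks = []
        for chrom in gmap.chromosome_names:
            pos = gmap.markers[chrom]
            R = ril_r(np.diff(pos))
            first = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
            switches = (rng.random((n, pos.size - 1)) < R).astype(np.int8)
            alleles = (first + np.cumsum(switches, axis=1, dtype=np.int32)) % 2
            chunks.append(np.concatenate([first, alleles.astype(np.int8)], axis=1))
        codes = 2 * np.concatenate(chunks, axis=1)
    else:
        raise ValueError(f"unknown pop_type {pop_type!r} (expected 'RIL' or 'F2')")
    return GenotypeMatrix(codes, gmap, pop_type)


def _locus_indices(genotypes: GenotypeMatrix, model: QTLModel) -> list[int]:
    return [genotypes.map.marker_index(l.chrom, l.pos_cM) for l in model.loci]


def genetic_value(genotypes: GenotypeMatrix, model: QTLModel) -> np.ndarray:
    """Genetic value of every individual under ``model``.

    Each QTL is snapped to the nearest simulated marker.  Single-locus
    values (+a / d / -a for AA / AB / BB) are summed over loci; a
    two-locus epistasis table, when present, replaces that sum.
    """
    idx = _locus_indices(genotypes, model)
    if model.epistasis is not None:
        g1 = genotypes.codes[:, idx[0]]
        g2 = genotypes.codes[:, idx[1]]
        return model.epistasis[g1, g2]
    values = np.zeros(genotypes.n_individuals)
    for locus, j in zip(model.loci, idx):
        lookup = np.array([-locus.a, locus.d, locus.a])
        values += lookup[genotypes.codes[:, j]]
    return values


def simulate_phenotypes(
    values: np.ndarray, model: QTLModel, seed: int | np.random.Generator
) -> np.ndarray:
    """Phenotype per individual: genetic value plus the mean of
    ``reps_per_line`` independent Normal(0, env_sd) measurement errors."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    if model.env_sd == 0:
        return values.copy()
    noise = rng.normal(0.0, model.env_sd, size=(values.size, model.reps_per_line))
    return values + noise.mean(axis=1)


def select_pools(phenotypes: np.ndarray, fraction: float) -> PoolSelection:
    """Select the top and bottom ``round(fraction * N)`` individuals.

    Ties are broken by ascending individual index (stable sort), so the
    selection is deterministic and invariant to positive affine
    transformations of the phenotype.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    if not 0 < fraction <= 0.5:
        raise ValueError("selection fraction must be in (0, 0.5]")
    k = int(round(fraction * phenotypes.size))
    if k < 1:
        raise ValueError("selection fraction yields an empty pool")
    order = np.argsort(phenotypes, kind="stable")
    low = np.sort(order[:k])
    high = np.sort(order[-k:])
    return PoolSelection(high_pool=high, low_pool=low, selection_fraction=fraction)


def marginal_allele_effect(model: QTLModel, locus_index: int, population_type: str = "F2") -> float:
    """Marginal effect of the reference allele at one QTL.

    ``E[value | AA] - E[value | BB]`` at the focal locus, marginalising
    the other locus over its population genotype frequencies (1:2:1 for
    F2, 1:0:1 for RIL).  Determines the expected sign of the
    pool-difference peak on the linked chromosome; zero for pure
    overdominance.
    """
    probs = np.array([0.25, 0.5, 0.25]) if population_type == "F2" else np.array([0.5, 0.0, 0.5])
    if model.epistasis is not None:
        tab = model.epistasis if locus_index == 0 else model.epistasis.T
        marg = tab @ probs
        return float(marg[2] - marg[0])
    return 2.0 * model.loci[locus_index].a


# ---------------------------------------------------------------------------
# Model preset catalog
# ---------------------------------------------------------------------------

_MAJOR_H2 = 0.75  # fraction of single-measurement phenotypic variance
_MODERATE_H2 = 0.30


def _additive_effect(h2: float, env_sd: float) -> float:
    # F2 additive genetic variance a^2/2; solve a^2/2 = h2/(1-h2) * sd^2
    return env_sd * math.sqrt(2.0 * h2 / (1.0 - h2))


def _dominant_effect(h2: float, env_sd: float) -> float:
    # full dominance d = a: F2 genetic variance 3a^2/4
    return env_sd * math.sqrt(4.0 * h2 / (3.0 * (1.0 - h2)))


def _overdominant_effect(h2: float, env_sd: float) -> float:
    # a = 0: F2 genetic variance d^2/4
    return 2.0 * env_sd * math.sqrt(h2 / (1.0 - h2))


def _epistatic_effect(h2: float, env_sd: float) -> float:
    # dominant-complementary +-e coding: variance 4 e^2 (9/16)(7/16)
    return env_sd * math.sqrt(h2 / (1.0 - h2) / (4.0 * (9 / 16) * (7 / 16)))


def model_preset(number: int, env_sd: float = 1.0, reps_per_line: int = 3) -> QTLModel:
    """One of the eight catalogued genetic models.

    1. major additive QTL, chromosome 2 @ 36 cM
    2. major dominant (d = a), chromosome 2 @ 36 cM
    3. moderate additive, chromosome 2 @ 36 cM
    4. major overdominant (a = 0), chromosome 2 @ 36 cM
    5. major additive near the telomere, chromosome 2 @ 2 cM
    6. two moderate additive unlinked QTL, chr 2 @ 36 + chr 5 @ 41
    7. two major additive QTL linked in repulsion, chr 2 @ 36 and @ 56
    8. two major unlinked epistatic QTL (dominant-complementary),
       chr 2 @ 36 + chr 5 @ 41

    "Major" scales the QTL to explain 75% of the phenotypic variance of
    a single measurement, "moderate" 30%.
    """
    a_maj = _additive_effect(_MAJOR_H2, env_sd)
    a_mod = _additive_effect(_MODERATE_H2, env_sd)
    kwargs = dict(env_sd=env_sd, reps_per_line=reps_per_line)
    if number == 1:
        loci = (QTLLocus("2", 36.0, a_maj),)
    elif number == 2:
        a = _dominant_effect(_MAJOR_H2, env_sd)
        loci = (QTLLocus("2", 36.0, a, d=a),)
    elif number == 3:
        loci = (QTLLocus("2", 36.0, a_mod),)
    elif number == 4:
        loci = (QTLLocus("2", 36.0, 0.0, d=_overdominant_effect(_MAJOR_H2, env_sd)),)
    elif number == 5:
        loci = (QTLLocus("2", 2.0, a_maj),)
    elif number == 6:
        loci = (QTLLocus("2", 36.0, a_mod), QTLLocus("5", 41.0, a_mod))
    elif number == 7:
        loci = (QTLLocus("2", 36.0, a_maj), QTLLocus("2", 56.0, -a_maj))
    elif number == 8:
        e = _epistatic_effect(_MAJOR_H2, env_sd)
        # high phenotype requires >= 1 reference allele at both loci
        tab = np.full((3, 3), -e)
        tab[1:, 1:] = e
        return QTLModel(
            loci=(QTLLocus("2", 36.0, 0.0), QTLLocus("5", 41.0, 0.0)),
            epistasis=tab,
            **kwargs,
        )
    else:
        raise ValueError(f"unknown model preset {number!r} (expected 1-8)")
    return QTLModel(loci=loci, **kwargs)


MODEL_PRESETS: dict[int, str] = {
    1: "major additive",
    2: "major dominant",
    3: "moderate additive",
    4: "major overdominance",
    5: "major additive (telomeric)",
    6: "moderate additive (unlinked pair)",
    7: "major additive (linked in repulsion)",
    8: "major epistasis (unlinked pair)",
}
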