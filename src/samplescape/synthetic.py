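"""Synthetic isolation-by-resistance data generator.

Emulates the structure of a pond-breeding amphibian microsatellite study:
a classed land-cover raster with a continuous slope-like surface, ~40
breeding sites with uneven sample sizes (1–25 individuals, a subset
reaching the population-level threshold of 11), 8 loci with multiple
alleles, and genetic divergence that increases with circuit-theory
effective resistance through one causal cover type.

The demographic model is a frequency-level stepping-stone Wright–Fisher
process: migration is deterministic mixing with rates decaying
exponentially in effective resistance, followed by multinomial drift with
2*Ne gene copies per deme per generation.  Optional symmetric stepwise
mutation is available for richer allele spectra (off by default).
All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .genotypes import GenotypeTable, SiteRegistry
from .raster import Raster
from .resistance import SurfaceSpec, parameterize, resistance_distances
from .distance import DistanceMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_landscape",
    "place_sites",
    "simulate_genotypes",
    "generate_dataset",
]

# per-site target sample sizes: 40 sites, 334 individuals, 18 sites with
# >= 11 (five of them exactly 11), the rest 1-4 — the uneven field
# collection pattern the pipeline is designed around
DEFAULT_SAMPLE_SIZES = (
    11, 11, 11, 11, 11, 12, 14, 14, 15, 15, 16, 16, 17, 18, 18, 20, 21, 25,
    1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 3, 3, 3, 3, 3, 3, 4, 4, 4, 4, 4, 4,
)

DEFAULT_COVER_FRACTIONS = {
    "forest_ld": 0.30,
    "shrub": 0.20,
    "ag": 0.15,
    "grass": 0.10,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    The defaults mirror the structure of the field system the pipeline
    targets: a 60x60 landscape, 40 ponds with uneven sample sizes
    totalling 334 individuals, 8 loci with 10 founding alleles, and
    strong isolation by resistance through low-density forest.
    """

    nrows: int = 60
    ncols: int = 60
    cellsize: float = 1.0
    cover_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_COVER_FRACTIONS)
    )
    autocorr_sigma: float = 6.0  # smoothing length of the random fields, cells
    n_sites: int = 40
    min_separation: float = 5.0  # cells
    causal_class: str = "forest_ld"
    # demography
    Ne: int = 50  # diploid deme size (2Ne gene copies drift per generation)
    m0: float = 0.02  # per-pair base migration rate before resistance decay
    rho: float | None = None  # resistance decay scale; None -> 0.3 * median R_eff
    generations: int = 200
    mutation_rate: float = 0.0  # symmetric stepwise, per copy per generation
    # loci
    n_loci: int = 8
    n_alleles: int = 10
    sample_sizes: tuple = DEFAULT_SAMPLE_SIZES
    connectivity: int = 8

    def __post_init__(self):
        if sum(self.cover_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("cover class fractions must sum to <= 1")
        if not 0.0 <= self.m0 < 1.0:
            raise ValueError("base migration rate m0 must be in [0, 1)")
        if self.Ne < 2 or self.generations < 1:
            raise ValueError("Ne >= 2 and generations >= 1 required")
        if len(self.sample_sizes) != self.n_sites:
            raise ValueError("need one sample size per site")
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if self.causal_class not in self.cover_fractions:
            raise ValueError("causal class must be one of the cover classes")


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream verification."""

    causal_surface: str
    resistance: DistanceMatrix
    migration: np.ndarray
    final_frequencies: np.ndarray  # (sites, loci, alleles)


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_landscape(config: SyntheticConfig, seed=None):
    """Cover raster (integer class codes), class-code map, and slope raster.

    Cover classes are realized by cutting a smoothed Gaussian random field
    at its empirical quantiles, so realized area fractions match the
    targets up to ties.  Code 0 is the background ("other") class.  The
    slope surface is an independent smoothed field, min-shifted positive.
    """
    rng = np.random.default_rng(seed)
    shape = (config.nrows, config.ncols)
    f = _smooth_field(shape, config.autocorr_sigma, rng)
    order = np.argsort(f, axis=None)
    cover = np.zeros(shape, dtype=float)
    codes = {}
    start = 0
    ncells = f.size
    for code, (name, frac) in enumerate(config.cover_fractions.items(), 1):
        stop = start + int(round(frac * ncells))
        flat_idx = order[start:stop]
        cover.flat[flat_idx] = code
        codes[name] = code
        start = stop
    slope = _smooth_field(shape, config.autocorr_sigma, rng)
    slope = slope - slope.min() + 0.1
    cs = config.cellsize
    return (
        Raster(cover, cellsize=cs),
        codes,
        Raster(slope, cellsize=cs),
    )


def place_sites(raster: Raster, n_sites: int, min_sep: float, seed=None,
                max_tries: int = 20_000) -> SiteRegistry:
    """Place sites on unmasked cells with pairwise distance >= min_sep."""
    rng = np.random.default_rng(seed)
    ok = np.argwhere(raster.mask)
    placed = []
    tries = 0
    while len(placed) < n_sites:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_sites} sites at separation {min_sep} "
                f"after {max_tries} tries ({len(placed)} placed)"
            )
        tries += 1
        cand = ok[rng.integers(len(ok))]
        if all(np.hypot(*(cand - p)) >= min_sep for p in placed):
            placed.append(cand)
    cells = {
        f"S{k+1:02d}": (int(r), int(c)) for k, (r, c) in enumerate(placed)
    }
    return SiteRegistry(cells=cells)


def _migration_matrix(R: np.ndarray, m0: float, rho: float,
                      min_retention: float = 0.5) -> np.ndarray:
    """Row-stochastic migration with rates m0*exp(-R/rho), scaled so every
    deme retains at least ``min_retention`` of itself."""
    P = R.shape[0]
    M = m0 * np.exp(-R / rho)
    np.fill_diagonal(M, 0.0)
    row = M.sum(axis=1)
    worst = row.max()
    if worst > 1.0 - min_retention:
        M *= (1.0 - min_retention) / worst
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    return M


def _mutate(p: np.ndarray, mu: float) -> np.ndarray:
    """Symmetric stepwise mutation on the allele-frequency axis."""
    if mu == 0.0:
        return p
    left = np.roll(p, 1, axis=-1)
    right = np.roll(p, -1, axis=-1)
    left[..., 0] = p[..., 0]
    right[..., -1] = p[..., -1]
    return (1 - 2 * mu) * p + mu * left + mu * right


def simulate_genotypes(resistance: DistanceMatrix, config: SyntheticConfig,
                       seed=None):
    """Forward Wright–Fisher simulation conditioned on a resistance matrix.

    Returns ``(GenotypeTable, GroundTruth)``.  Migration mixes allele
    frequencies deterministically each generation, then multinomial drift
    resamples 2*Ne gene copies per deme and locus.  Individuals are drawn
    from the final deme frequencies with the configured sample sizes.
    """
    rng = np.random.default_rng(seed)
    R = np.asarray(resistance.values, dtype=float)
    sites = resistance.labels
    P, L, K = len(sites), config.n_loci, config.n_alleles
    off = R[~np.eye(P, dtype=bool)]
    if (off <= 0).any():
        raise ValueError("resistance matrix must be positive off-diagonal")
    rho = config.rho if config.rho is not None else 0.3 * float(np.median(off))
    M = _migration_matrix(R, config.m0, rho)

    p = np.full((P, L, K), 1.0 / K)
    two_ne = 2 * config.Ne
    for _ in range(config.generations):
        p = np.einsum("ij,jlk->ilk", M, p)
        p = _mutate(p, config.mutation_rate)
        p /= p.sum(axis=-1, keepdims=True)  # guard against rounding drift
        counts = rng.multinomial(two_ne, p)
        p = counts / two_ne

    individuals, site_labels, calls = [], [], []
    for i, site in enumerate(sites):
        n_i = config.sample_sizes[i]
        geno = np.zeros((n_i, L, 2), dtype=np.int64)
        for l in range(L):
            # allele codes 1..K (0 is reserved for missing)
            geno[:, l, :] = (
                rng.choice(K, size=(n_i, 2), p=p[i, l]) + 1
            )
        for j in range(n_i):
            individuals.append(f"{site}_{j+1:02d}")
            site_labels.append(site)
        calls.append(geno)
    table = GenotypeTable(
        individuals, np.array(site_labels, object),
        [f"L{l+1}" for l in range(L)], np.concatenate(calls),
    )
    truth = GroundTruth(
        causal_surface=config.causal_class,
        resistance=resistance,
        migration=M,
        final_frequencies=p,
    )
    return table, truth


@dataclass
class SyntheticDataset:
    """Bundle of every artifact one simulated study produces."""

    config: SyntheticConfig
    cover: Raster
    class_codes: dict
    slope: Raster
    registry: SiteRegistry
    genotypes: GenotypeTable
    truth: GroundTruth


def generate_dataset(config: SyntheticConfig | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Landscape → site placement → causal resistance → genotypes.

    Randomness is split into named substreams (landscape, placement,
    genotypes) derived from the master seed, so each stage is
    independently reproducible.
    """
    config = config or SyntheticConfig()
    streams = np.random.SeedSequence(seed).spawn(3)
    cover, codes, slope = generate_landscape(config, streams[0])
    registry = place_sites(
        cover, config.n_sites, config.min_separation, streams[1]
    )
    causal = parameterize(
        cover,
        SurfaceSpec(config.causal_class, "binary_cover",
                    codes[config.causal_class]),
    )
    R = resistance_distances(causal, registry, config.connectivity)
    table, truth = simulate_genotypes(R, config, streams[2])
    for s, n in zip(registry.sites, config.sample_sizes):
        registry.counts[s] = n
    return SyntheticDataset(config, cover, codes, slope, registry, table,
                            truth)
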