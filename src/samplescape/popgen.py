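"""Population-genetic summary statistics for microsatellite data.

Per-population summaries: unbiased expected heterozygosity, hypergeometric
rarefaction of allelic richness, private alleles, monomorphic loci, and
Monte Carlo tests of Hardy–Weinberg equilibrium and pairwise linkage
disequilibrium with Bonferroni correction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeTable, allele_counts

__all__ = [
    "unbiased_He",
    "allelic_richness",
    "private_alleles",
    "hwe_exact_test",
    "ld_permutation_test",
    "bonferroni",
    "population_summaries",
]

NOT_TESTABLE = None  # sentinel p-value for monomorphic (untestable) cases


def unbiased_He(freqs, n: int) -> float:
    """Unbiased expected heterozygosity for one locus.

    uHe = (2n / (2n - 1)) * (1 - sum p_a^2), with ``n`` the diploid sample
    size and ``freqs`` the allele frequency vector.  Equals 0 for a
    monomorphic locus.
    """
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    p = np.asarray(freqs, dtype=float)
    if p.size and abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("allele frequencies must sum to 1")
    he = 1.0 - float(np.sum(p**2))
    return (2 * n) / (2 * n - 1) * he


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(counts, g: int) -> float:
    """Expected number of alleles in a random subsample of ``g`` gene copies.

    Hypergeometric rarefaction: sum over alleles of
    ``1 - C(N - N_a, g) / C(N, g)`` with ``N`` the total gene copies and
    ``N_a`` the copies of allele ``a``.  At ``g = N`` this equals the
    observed allele count.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    N = c.sum()
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds gene count N={int(N)}")
    # C(N - N_a, g) is zero when N - N_a < g
    rest = N - c
    with np.errstate(invalid="ignore"):
        log_ratio = np.where(
            rest >= g, _log_comb(rest, g) - _log_comb(N, g), -np.inf
        )
    return float(np.sum(1.0 - np.exp(log_ratio)))


def private_alleles(pop_counts: dict) -> pd.Series:
    """Mean private alleles per locus for each population.

    ``pop_counts`` maps population label → per-locus allele count dict (as
    returned by :func:`samplescape.genotypes.allele_counts`).  An allele is
    private to a population when it is observed there and in no other
    population.  The result for each population is the total number of
    private alleles across loci divided by the number of loci.
    """
    pops = list(pop_counts)
    if len(pops) < 2:
        raise ValueError("private alleles need at least two populations")
    loci = list(next(iter(pop_counts.values())))
    out = {}
    for p in pops:
        n_private = 0
        for locus in loci:
            mine = set(pop_counts[p][locus].index[pop_counts[p][locus] > 0])
            others = set()
            for q in pops:
                if q != p:
                    cq = pop_counts[q][locus]
                    others |= set(cq.index[cq > 0])
            n_private += len(mine - others)
        out[p] = n_private / len(loci)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Monte Carlo tests
# ---------------------------------------------------------------------------


def _hwe_log_prob(genos: np.ndarray) -> float:
    """Log conditional probability of a genotype array given allele counts.

    Levene's distribution: P = n! * prod_a m_a! * 2^h / ((2n)! * prod_g n_g!)
    with h the number of heterozygotes; used as the exactness statistic.
    """
    n = genos.shape[0]
    copies = genos.ravel()
    m = np.bincount(copies)
    key = genos.min(1) * (copies.max() + 1) + genos.max(1)
    _, gcounts = np.unique(key, return_counts=True)
    h = int((genos[:, 0] != genos[:, 1]).sum())
    return float(
        gammaln(n + 1)
        + gammaln(m[m > 0] + 1).sum()
        + h * np.log(2.0)
        - gammaln(2 * n + 1)
        - gammaln(gcounts + 1).sum()
    )


def hwe_exact_test(genotypes, n_perm: int = 10_000, seed=None):
    """Monte Carlo exact test of Hardy–Weinberg equilibrium at one locus.

    ``genotypes`` is an (n, 2) array of allele codes for one population
    (missing calls excluded beforehand).  Gene copies are shuffled into
    random diploid genotypes conditional on the allele counts; the test
    statistic is the Levene conditional probability of the array, with
    small probabilities extreme.  Returns the add-one estimate
    ``(1 + #{perm <= obs}) / (n_perm + 1)``, or ``None`` when the locus is
    monomorphic (not testable).
    """
    g = np.asarray(genotypes, dtype=np.int64)
    g = g[(g > 0).all(axis=1)]
    if g.size == 0 or np.unique(g).size < 2:
        return NOT_TESTABLE
    rng = np.random.default_rng(seed)
    obs = _hwe_log_prob(g)
    copies = g.ravel().copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(copies)
        if _hwe_log_prob(copies.reshape(-1, 2)) <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _geno_key(g: np.ndarray) -> np.ndarray:
    """Unordered-genotype integer key per individual."""
    lo = g.min(axis=1)
    hi = g.max(axis=1)
    return lo * 10_000 + hi


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood-ratio (G) statistic of a two-way contingency table."""
    _, ix = np.unique(x, return_inverse=True)
    _, iy = np.unique(y, return_inverse=True)
    kx, ky = ix.max() + 1, iy.max() + 1
    tab = np.bincount(ix * ky + iy, minlength=kx * ky).reshape(kx, ky)
    tab = tab.astype(float)
    n = tab.sum()
    exp = np.outer(tab.sum(1), tab.sum(0)) / n
    mask = tab > 0
    return float(2.0 * np.sum(tab[mask] * np.log(tab[mask] / exp[mask])))


def ld_permutation_test(geno1, geno2, n_perm: int = 10_000, seed=None):
    """Permutation test of genotypic linkage disequilibrium between two loci.

    Association between unordered single-locus genotypes is measured by the
    G statistic of the two-locus genotype contingency table; the null is
    generated by permuting one locus's genotypes across individuals.
    Returns the add-one p-value, or ``None`` if either locus is monomorphic
    among co-called individuals.
    """
    g1 = np.asarray(geno1, dtype=np.int64)
    g2 = np.asarray(geno2, dtype=np.int64)
    ok = (g1 > 0).all(axis=1) & (g2 > 0).all(axis=1)
    g1, g2 = g1[ok], g2[ok]
    if g1.shape[0] < 2 or np.unique(g1).size < 2 or np.unique(g2).size < 2:
        return NOT_TESTABLE
    k1, k2 = _geno_key(g1), _geno_key(g2)
    obs = _g_statistic(k1, k2)
    rng = np.random.default_rng(seed)
    k2p = k2.copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(k2p)
        if _g_statistic(k1, k2p) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def bonferroni(pvalues, alpha: float = 0.05, m: int | None = None):
    """Bonferroni significance flags: p < alpha / m.

    ``m`` defaults to the number of performed tests, i.e. entries that are
    not ``None`` (untestable combinations do not count toward the
    correction denominator).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pvals = list(pvalues)
    if m is None:
        m = sum(p is not None for p in pvals)
    if m == 0:
        return [False for _ in pvals]
    return [(p is not None) and (p < alpha / m) for p in pvals]


# ---------------------------------------------------------------------------
# Table of per-population summaries
# ---------------------------------------------------------------------------


def population_summaries(
    table: GenotypeTable,
    populations,
    rarefaction_g: int | None = None,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Per-population summary statistics table.

    Columns: N (individuals), A (total alleles over loci), uHe (mean
    unbiased expected heterozygosity), ML (monomorphic loci), AR (mean
    rarefied allelic richness at ``rarefaction_g`` gene copies), PA (mean
    private alleles per locus), HWE (loci failing the HWE test after
    Bonferroni correction across all populations × testable loci), LD
    (locus pairs failing the LD test likewise).

    ``rarefaction_g`` defaults to twice the smallest population's diploid
    sample size.
    """
    populations = list(populations)
    rng = np.random.default_rng(seed)
    counts_by_pop = {p: allele_counts(table, [p]) for p in populations}
    sizes = {p: len(table.individuals_at(p)) for p in populations}
    if rarefaction_g is None:
        rarefaction_g = 2 * min(sizes.values())

    pa = private_alleles(counts_by_pop) if len(populations) > 1 else None

    # run all HWE / LD tests first so the Bonferroni m spans every
    # population × testable combination, as in the headline analyses
    hwe_p, hwe_ix = [], []
    ld_p, ld_ix = [], []
    for p in populations:
        idx = table.individuals_at(p)
        sub = table.subset(idx)
        for j, locus in enumerate(table.loci):
            pv = hwe_exact_test(
                sub.calls[:, j, :], n_perm=n_perm,
                seed=rng.integers(2**31),
            )
            if pv is not None:
                hwe_p.append(pv)
                hwe_ix.append((p, locus))
        for j, k in combinations(range(table.n_loci), 2):
            pv = ld_permutation_test(
                sub.calls[:, j, :], sub.calls[:, k, :], n_perm=n_perm,
                seed=rng.integers(2**31),
            )
            if pv is not None:
                ld_p.append(pv)
                ld_ix.append((p, table.loci[j], table.loci[k]))
    hwe_sig = dict(zip(hwe_ix, bonferroni(hwe_p, alpha)))
    ld_sig = dict(zip(ld_ix, bonferroni(ld_p, alpha)))

    rows = []
    for p in populations:
        cts = counts_by_pop[p]
        per_locus_he, n_mono, n_alleles, ar = [], 0, 0, []
        n_p = sizes[p]
        for locus in table.loci:
            c = cts[locus]
            c = c[c > 0]
            n_alleles += len(c)
            if len(c) <= 1:
                n_mono += 1
            if len(c) == 0:
                continue
            per_locus_he.append(unbiased_He(c / c.sum(), n_p))
            g = min(rarefaction_g, int(c.sum()))
            ar.append(allelic_richness(c, g))
        rows.append(
            {
                "pop": p,
                "N": n_p,
                "A": n_alleles,
                "uHe": float(np.mean(per_locus_he)),
                "ML": n_mono,
                "LD": sum(
                    flag for (q, *_), flag in ld_sig.items() if q == p
                ),
                "HWE": sum(
                    flag for (q, _), flag in hwe_sig.items() if q == p
                ),
                "AR": float(np.mean(ar)),
                "PA": float(pa[p]) if pa is not None else 0.0,
            }
        )
    df = pd.DataFrame(rows).set_index("pop")
    df.attrs["hwe_tests_performed"] = len(hwe_p)
    df.attrs["ld_tests_performed"] = len(ld_p)
    df.attrs["rarefaction_g"] = rarefaction_g
    return df
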