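"""Genetic distance matrices at the individual and population level.

The workhorse response metric is the allele-sharing distance
``1 - Dps``, where Dps is the proportion of shared alleles between two
diploid multilocus genotypes:

    Dps = sum_l sum_a min(c1_la, c2_la) / (2 * L_obs)

with ``c`` the per-individual allele counts (0, 1 or 2) and ``L_obs`` the
number of loci called in both individuals (pairwise deletion of missing
data).  Bray–Curtis dissimilarity on the concatenated allele-count vectors
reduces algebraically to the same quantity for complete diploid data.

Population-level metrics: the mean of interindividual allele-sharing
distances over all cross-site pairs, Nei's Da, and Weir–Cockerham's
theta (Fst).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = [
    "DistanceMatrix",
    "dps_pair",
    "bray_curtis_pair",
    "dps_matrix",
    "average_to_population",
    "nei_da",
    "nei_da_matrix",
    "fst_pair",
    "fst_matrix",
    "index_correlation",
]


class DistanceMatrix:
    """Symmetric labeled pairwise matrix with a metric tag.

    ``level`` is ``"individual"`` or ``"population"``.  The diagonal is
    zero by convention; Fst estimates may carry small negative
    off-diagonal values and are stored as-is.
    """

    def __init__(self, labels, values, metric: str, level: str):
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        self.metric = metric
        self.level = level
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def __repr__(self):
        return (
            f"DistanceMatrix({len(self.labels)} {self.level}s, "
            f"metric={self.metric!r})"
        )

    def loc(self, a, b) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in row-major pair order."""
        iu = np.tril_indices(len(self.labels), k=-1)
        return self.values[iu]

    def pairs(self):
        """Unordered label pairs matching :meth:`condensed` order."""
        out = []
        for i in range(1, len(self.labels)):
            for j in range(i):
                out.append((self.labels[i], self.labels[j]))
        return out

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels, self.values[np.ix_(idx, idx)], self.metric, self.level
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"a": a, "b": b, "value": v}
            for (a, b), v in zip(self.pairs(), self.condensed())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, metric="unknown", level="population"):
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(), metric, level)


# ---------------------------------------------------------------------------
# allele-sharing distances
# ---------------------------------------------------------------------------


def _shared_count(g1: np.ndarray, g2: np.ndarray):
    """(shared alleles, co-called loci) for two (L, 2) genotype arrays."""
    ok = (g1[:, 0] > 0) & (g2[:, 0] > 0)
    shared = 0
    for l in np.flatnonzero(ok):
        a = {}
        for x in g1[l]:
            a[x] = a.get(x, 0) + 1
        for x, c1 in a.items():
            c2 = int(np.sum(g2[l] == x))
            shared += min(c1, c2)
    return shared, int(ok.sum())


def dps_pair(g1, g2) -> float:
    """Allele-sharing distance 1 - Dps between two individuals."""
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    shared, L_obs = _shared_count(g1, g2)
    if L_obs == 0:
        raise ValueError("no locus called in both individuals")
    return 1.0 - shared / (2.0 * L_obs)


def bray_curtis_pair(g1, g2) -> float:
    """Bray–Curtis dissimilarity on concatenated allele-count vectors.

    Computed over co-called loci; for complete diploid data it equals
    ``dps_pair`` exactly since every locus contributes 2 gene copies per
    individual.
    """
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    shared, L_obs = _shared_count(g1, g2)
    if L_obs == 0:
        raise ValueError("no locus called in both individuals")
    tot = 4.0 * L_obs  # sum of both count vectors over co-called loci
    return 1.0 - 2.0 * shared / tot


def _count_indicators(table: GenotypeTable):
    """Stacked per-allele indicator matrices for fast pairwise sharing.

    Returns (U1, U2, called) where U1[i, m] = 1 if individual i carries
    >= 1 copy of stacked allele m and U2 likewise for 2 copies; then
    shared alleles between i and j total U1 U1^T + U2 U2^T because counts
    are in {0, 1, 2} and min(x, y) = [x>=1][y>=1] + [x>=2][y>=2].
    """
    n, L = table.n_individuals, table.n_loci
    cols1, cols2 = [], []
    for j in range(L):
        alleles = np.unique(table.calls[:, j, :])
        alleles = alleles[alleles > 0]
        for a in alleles:
            hits = (table.calls[:, j, :] == a).sum(axis=1)
            cols1.append(hits >= 1)
            cols2.append(hits >= 2)
    U1 = np.array(cols1, dtype=np.float64).T
    U2 = np.array(cols2, dtype=np.float64).T
    return U1, U2, table.called().astype(np.float64)


def dps_matrix(table: GenotypeTable, metric: str = "dps_distance") -> DistanceMatrix:
    """All pairwise allele-sharing distances between individuals.

    ``metric`` may be ``"dps_distance"`` (1 - Dps) or ``"bray_curtis"``;
    both use pairwise deletion and coincide on the co-called loci.
    """
    U1, U2, M = _count_indicators(table)
    shared = U1 @ U1.T + U2 @ U2.T
    L_obs = M @ M.T
    if (L_obs[~np.eye(len(L_obs), dtype=bool)] == 0).any():
        raise ValueError("some individual pair shares no called locus")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - shared / (2.0 * L_obs)
    np.fill_diagonal(d, 0.0)
    if metric not in ("dps_distance", "bray_curtis"):
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(table.individuals, d, metric, "individual")


def average_to_population(ind_matrix: DistanceMatrix, site_of: dict) -> DistanceMatrix:
    """Average an interindividual matrix over all cross-site pairs.

    Entry (A, B) is the mean of d(i, j) over individuals i at site A and
    j at site B; the diagonal is zero by convention.  Sites with a single
    individual are allowed (the mean runs over 1 × n_B pairs).
    """
    labels = ind_matrix.labels
    sites = [site_of[l] for l in labels]
    unique_sites = sorted(set(sites))
    idx_of = {s: [i for i, x in enumerate(sites) if x == s] for s in unique_sites}
    for s, idx in idx_of.items():
        if not idx:
            raise ValueError(f"site {s} has no individuals")
    P = len(unique_sites)
    out = np.zeros((P, P))
    for a in range(P):
        ia = idx_of[unique_sites[a]]
        for b in range(a + 1, P):
            ib = idx_of[unique_sites[b]]
            block = ind_matrix.values[np.ix_(ia, ib)]
            out[a, b] = out[b, a] = block.mean()
    return DistanceMatrix(unique_sites, out, ind_matrix.metric, "population")


# ---------------------------------------------------------------------------
# population-level metrics
# ---------------------------------------------------------------------------


def nei_da(freqs_a: dict, freqs_b: dict) -> float:
    """Nei's Da distance between two allele-frequency profiles.

    Da = 1 - (1/L) * sum_l sum_alleles sqrt(x_a * y_a); 0 for identical
    profiles, 1 for fully disjoint allele sets.  ``freqs_a``/``freqs_b``
    map locus → Series of allele frequencies.
    """
    if set(freqs_a) != set(freqs_b):
        raise ValueError("locus sets do not match")
    total = 0.0
    L = 0
    for locus in freqs_a:
        xa, xb = freqs_a[locus], freqs_b[locus]
        if len(xa) == 0 or len(xb) == 0:
            continue
        L += 1
        common = xa.index.intersection(xb.index)
        total += float(np.sum(np.sqrt(xa[common].to_numpy() * xb[common].to_numpy())))
    if L == 0:
        raise ValueError("no locus observed in both groups")
    return 1.0 - total / L


def _wc_components(calls_a: np.ndarray, calls_b: np.ndarray):
    """Weir–Cockerham (1984) variance components a, b, c summed over
    alleles at one locus for two populations.

    ``calls_*`` are (n, 2) genotype arrays with missing rows removed.
    Returns (sum_a, sum_abc) or None when fewer than 2 individuals in
    either sample or the locus is monomorphic overall.
    """
    if calls_a.shape[0] < 2 or calls_b.shape[0] < 2:
        return None
    alleles = np.unique(np.concatenate([calls_a.ravel(), calls_b.ravel()]))
    alleles = alleles[alleles > 0]
    if alleles.size < 2:
        return None
    r = 2
    n_i = np.array([calls_a.shape[0], calls_b.shape[0]], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    sum_a = sum_all = 0.0
    for al in alleles:
        p_i = np.array(
            [(calls_a == al).mean(), (calls_b == al).mean()]
        )
        h_i = np.array(
            [
                ((calls_a == al).sum(1) == 1).mean(),
                ((calls_b == al).sum(1) == 1).mean(),
            ]
        )
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_all += a + b + c
    return sum_a, sum_all


def fst_pair(table: GenotypeTable, site_a, site_b) -> float:
    """Weir–Cockerham theta between two populations, summed over loci.

    Theta is the ratio of the summed among-population variance component
    to the summed total; small negative estimates are possible and are
    retained.  Returns NaN when every shared locus is monomorphic.
    """
    ia = table.individuals_at(site_a)
    ib = table.individuals_at(site_b)
    num = den = 0.0
    informative = False
    for j in range(table.n_loci):
        ca = table.calls[ia, j, :]
        cb = table.calls[ib, j, :]
        ca = ca[(ca > 0).all(1)]
        cb = cb[(cb > 0).all(1)]
        comp = _wc_components(ca, cb)
        if comp is None:
            continue
        informative = True
        num += comp[0]
        den += comp[1]
    if not informative or den == 0:
        return float("nan")
    return num / den


def fst_matrix(table: GenotypeTable, sites) -> DistanceMatrix:
    sites = list(sites)
    P = len(sites)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            out[i, j] = out[j, i] = fst_pair(table, sites[i], sites[j])
    return DistanceMatrix(sites, out, "fst", "population")


def nei_da_matrix(table: GenotypeTable, sites) -> DistanceMatrix:
    from .genotypes import allele_frequencies

    sites = list(sites)
    freqs = {s: {l: f for l, (f, _) in allele_frequencies(table, [s]).items()}
             for s in sites}
    P = len(sites)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            out[i, j] = out[j, i] = nei_da(freqs[sites[i]], freqs[sites[j]])
    return DistanceMatrix(sites, out, "nei_da", "population")


def index_correlation(dm1: DistanceMatrix, dm2: DistanceMatrix,
                      statistic: str = "r") -> float:
    """Pearson correlation of two distance matrices over lower-triangle pairs.

    ``statistic`` is ``"r"`` or ``"r2"``.  Labels and level must match.
    """
    if dm1.labels != dm2.labels or dm1.level != dm2.level:
        raise ValueError("distance matrices must share labels and level")
    if len(dm1.labels) < 3:
        raise ValueError("need at least 3 labels")
    x, y = dm1.condensed(), dm2.condensed()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant matrix: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if statistic == "r":
        return r
    if statistic == "r2":
        return r * r
    raise ValueError(f"unknown statistic {statistic!r}")
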