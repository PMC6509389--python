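"""Diploid microsatellite genotype tables: I/O, validation, and site classification.

A :class:`GenotypeTable` holds individuals with a site label and an unordered
pair of integer allele codes at each locus.  Missing data is encoded as the
allele code 0 at *both* gene copies of a locus (a half-missing call is
rejected at validation).  Two text dialects are supported:

* CSV — one row per individual with columns ``id, site, <locus>.a1,
  <locus>.a2, ...``; missing encoded as 0.
* GenePop — 2- or 3-digit allele coding on read, 3-digit on write; allele
  code 000 is missing.  The site label of each POP block is taken from the
  last comma-separated identifier token of the block's first individual.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "SiteRegistry",
    "read_genotypes",
    "write_genotypes",
    "classify_sites",
    "allele_frequencies",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class GenotypeValidationError(ValueError):
    """Raised when a parsed table violates a structural invariant."""


@dataclass
class GenotypeTable:
    """Individuals × loci diploid genotype calls with site labels.

    Attributes
    ----------
    individuals : list of str
        Unique individual identifiers, length ``n``.
    sites : ndarray of str, shape (n,)
        Site label of each individual.
    loci : list of str
        Locus names, length ``L``.
    calls : ndarray of int, shape (n, L, 2)
        Allele codes; 0 means missing.  A call is either fully observed
        (both copies > 0) or fully missing (both 0).
    """

    individuals: list
    sites: np.ndarray
    loci: list
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        n, L = len(self.individuals), len(self.loci)
        if L < 1:
            raise GenotypeValidationError("table must have at least one locus")
        if self.calls.shape != (n, L, 2):
            raise GenotypeValidationError(
                f"calls shape {self.calls.shape} != {(n, L, 2)}"
            )
        if len(set(self.individuals)) != n:
            raise GenotypeValidationError("individual ids must be unique")
        if len(self.sites) != n:
            raise GenotypeValidationError("one site label per individual required")
        if (self.calls < 0).any():
            raise GenotypeValidationError("allele codes must be non-negative")
        half = (self.calls == 0).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise GenotypeValidationError(
                f"half-missing call for {self.individuals[i]} at {self.loci[l]}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def site_of(self) -> dict:
        return dict(zip(self.individuals, self.sites))

    def site_counts(self) -> pd.Series:
        """Number of individuals per site, index sorted by site label."""
        return pd.Series(self.sites).value_counts().sort_index()

    def called(self) -> np.ndarray:
        """Boolean (n, L) mask of observed (non-missing) calls."""
        return self.calls[:, :, 0] > 0

    # -- subsetting --------------------------------------------------------

    def subset(self, indices) -> "GenotypeTable":
        idx = np.asarray(indices, dtype=int)
        return GenotypeTable(
            [self.individuals[i] for i in idx],
            self.sites[idx],
            list(self.loci),
            self.calls[idx],
        )

    def subset_sites(self, sites) -> "GenotypeTable":
        keep = set(sites)
        idx = [i for i, s in enumerate(self.sites) if s in keep]
        if not idx:
            raise GenotypeValidationError("no individuals at the requested sites")
        return self.subset(idx)

    def individuals_at(self, site) -> list:
        return [i for i, s in enumerate(self.sites) if s == site]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"id": self.individuals, "site": self.sites}
        for j, locus in enumerate(self.loci):
            cols[f"{locus}.a1"] = self.calls[:, j, 0]
            cols[f"{locus}.a2"] = self.calls[:, j, 1]
        return pd.DataFrame(cols)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        # genotypes are unordered pairs: compare sorted copies
        return (
            self.individuals == other.individuals
            and list(self.sites) == list(other.sites)
            and self.loci == other.loci
            and np.array_equal(np.sort(self.calls, 2), np.sort(other.calls, 2))
        )


@dataclass
class SiteRegistry:
    """Site → raster cell index plus per-site sample count."""

    cells: dict = field(default_factory=dict)  # site -> (row, col)
    counts: dict = field(default_factory=dict)  # site -> n_i

    @property
    def sites(self) -> list:
        return sorted(self.cells)

    def validate_extent(self, nrows: int, ncols: int) -> None:
        for s, (r, c) in self.cells.items():
            if not (0 <= r < nrows and 0 <= c < ncols):
                raise ValueError(f"site {s} cell ({r},{c}) outside raster extent")

    def to_csv(self, path) -> None:
        rows = [
            {"site": s, "row": r, "col": c, "n": self.counts.get(s, "")}
            for s, (r, c) in sorted(self.cells.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SiteRegistry":
        df = pd.read_csv(path, dtype={"site": str})
        cells = {row.site: (int(row.row), int(row.col)) for row in df.itertuples()}
        counts = {}
        if "n" in df.columns:
            counts = {
                str(r.site): int(r.n) for r in df.itertuples() if pd.notna(r.n)
            }
        return cls(cells, counts)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str | None = None) -> GenotypeTable:
    """Read a genotype table from CSV or GenePop text.

    ``format`` is ``"csv"`` or ``"genepop"``; inferred from the extension
    (.csv vs anything else) when omitted.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "genepop"
    if format == "csv":
        return _read_csv(path)
    if format == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_genotypes(table: GenotypeTable, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "genepop"
    if format == "csv":
        table.to_dataframe().to_csv(path, index=False)
    elif format == "genepop":
        _write_genepop(table, path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


def _read_csv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"id": str, "site": str})
    if "id" not in df.columns or "site" not in df.columns:
        raise GenotypeParseError(f"{path}: CSV needs 'id' and 'site' columns")
    loci = []
    for col in df.columns:
        if col.endswith(".a1"):
            locus = col[:-3]
            if f"{locus}.a2" not in df.columns:
                raise GenotypeParseError(f"{path}: missing column {locus}.a2")
            loci.append(locus)
    if not loci:
        raise GenotypeParseError(f"{path}: no '<locus>.a1' columns found")
    calls = np.zeros((len(df), len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        calls[:, j, 0] = df[f"{locus}.a1"].to_numpy()
        calls[:, j, 1] = df[f"{locus}.a2"].to_numpy()
    return GenotypeTable(list(df["id"]), df["site"].to_numpy(), loci, calls)


_GENEPOP_POP = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _read_genepop(path: Path) -> GenotypeTable:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    # header: title line, then locus names (one per line or comma-separated)
    loci: list = []
    i = 1
    while i < len(lines) and not _GENEPOP_POP.match(lines[i]):
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise GenotypeParseError(f"{path}: no locus names before first POP")
    individuals, sites, rows = [], [], []
    site_label = None
    while i < len(lines):
        line = lines[i]
        i += 1
        if _GENEPOP_POP.match(line):
            site_label = None
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenotypeParseError(f"{path}:{i}: expected 'id , genotypes'")
        parts = line.split(",")
        geno_field = parts[-1].strip()
        ident = [t.strip() for t in parts[:-1]]
        tokens = geno_field.split()
        if len(tokens) != len(loci):
            raise GenotypeParseError(
                f"{path}:{i}: {len(tokens)} genotype fields for {len(loci)} loci"
            )
        if site_label is None:
            site_label = ident[-1]
        row = np.zeros((len(loci), 2), dtype=np.int64)
        for j, tok in enumerate(tokens):
            if len(tok) == 4:
                a1, a2 = int(tok[:2]), int(tok[2:])
            elif len(tok) == 6:
                a1, a2 = int(tok[:3]), int(tok[3:])
            else:
                raise GenotypeParseError(
                    f"{path}:{i}: genotype field {tok!r} is not 4 or 6 digits"
                )
            row[j] = (a1, a2)
        ind_id = ident[0]
        individuals.append(ind_id)
        sites.append(site_label)
        rows.append(row)
    if not individuals:
        raise GenotypeParseError(f"{path}: no individuals found")
    if len(set(individuals)) != len(individuals):
        # files that repeat the pop name as the id: disambiguate
        individuals = [f"{s}_{k}" for k, s in enumerate(individuals)]
    calls = np.stack(rows)
    # treat half-missing GenePop calls (e.g. 000120) as wholly missing
    half = (calls == 0).any(axis=2)
    calls[half] = 0
    return GenotypeTable(individuals, np.array(sites, object), loci, calls)


def _write_genepop(table: GenotypeTable, path: Path) -> None:
    out = ["samplescape genotype export"]
    out.extend(table.loci)
    order = []
    seen = []
    for s in table.sites:
        if s not in seen:
            seen.append(s)
    for site in seen:
        out.append("POP")
        for i in table.individuals_at(site):
            geno = " ".join(
                f"{a1:03d}{a2:03d}" for a1, a2 in table.calls[i]
            )
            out.append(f"{table.individuals[i]},{site} ,  {geno}")
        order.append(site)
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Site classification and allele frequencies
# ---------------------------------------------------------------------------


def classify_sites(table: GenotypeTable, min_pop_size: int = 11):
    """Partition sites into population-level (n ≥ ``min_pop_size``) and below.

    Returns ``(population_sites, below_sites, counts)`` where the site lists
    are sorted and ``counts`` is a Series of per-site sample sizes.  The
    default threshold of 11 individuals is the conventional cut separating
    sites that can support population-level distance estimates.
    """
    if min_pop_size < 1:
        raise ValueError("min_pop_size must be >= 1")
    counts = table.site_counts()
    pop = sorted(counts.index[counts >= min_pop_size])
    below = sorted(counts.index[counts < min_pop_size])
    return pop, below, counts


def allele_frequencies(table: GenotypeTable, group="pooled"):
    """Per-locus allele frequencies and gene counts for a group of sites.

    ``group`` is ``"pooled"`` (all individuals) or an iterable of site
    labels.  Returns a dict ``locus -> (freqs, gene_count)`` with ``freqs``
    a Series indexed by allele code summing to 1 over observed gene copies;
    a locus with no observed calls in the group gets an empty Series and
    gene count 0.
    """
    if isinstance(group, str) and group == "pooled":
        sub = table
    else:
        sub = table.subset_sites(group)
    out = {}
    for j, locus in enumerate(sub.loci):
        copies = sub.calls[:, j, :].ravel()
        copies = copies[copies > 0]
        if copies.size == 0:
            out[locus] = (pd.Series(dtype=float), 0)
            continue
        counts = pd.Series(copies).value_counts().sort_index()
        out[locus] = (counts / counts.sum(), int(counts.sum()))
    return out


def allele_counts(table: GenotypeTable, group="pooled"):
    """Per-locus gene-copy counts (Series indexed by allele code)."""
    freqs = allele_frequencies(table, group)
    return {
        locus: (f * n).round().astype(int) if n else pd.Series(dtype=int)
        for locus, (f, n) in freqs.items()
    }
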