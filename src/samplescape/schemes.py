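"""Sampling-scheme construction and the bootstrap resampling experiment.

Three designs are compared:

* ISS — individual sampling: draw 1–11 individuals per site without
  replacement, many bootstrap replicates;
* PSS — population sampling: every individual, but only at sites meeting
  a minimum sample size (deterministic, one realization);
* PASS — proportion-available sampling: every individual at every site
  regardless of count (deterministic).

For each replicate the allele-sharing response is rebuilt, every
candidate MLPE model refit, and the model ranked; a model "competes" in a
replicate when its delta-IC is below 2.  Summaries count competitive
replicates and average IC weights, and the convergence analysis locates
the smallest per-site sample size at which the ISS competitive sets agree
with a reference (PSS or PASS) top-model set in more than a target
fraction of replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distance import dps_matrix, average_to_population
from .genotypes import GenotypeTable
from .mlpe import fit_candidates

__all__ = [
    "make_scheme_dataset",
    "run_replicates",
    "summarize_replicates",
    "competitive_models",
    "convergence_analysis",
]

DELTA_COMPETITIVE = 2.0


def make_scheme_dataset(
    table: GenotypeTable,
    scheme: str,
    sites,
    n_per_site="all",
    seed=None,
    min_pop_size: int = 11,
) -> GenotypeTable:
    """Subset a genotype table according to a sampling scheme.

    ISS draws ``min(n_per_site, n_i)`` individuals per site uniformly
    without replacement (sites smaller than the draw contribute everyone,
    mirroring the proportion-available logic); PSS keeps all individuals
    at the given sites, which must each meet ``min_pop_size``; PASS keeps
    every individual at every given site.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("empty site set")
    if scheme in ("PSS", "PASS"):
        if scheme == "PSS":
            counts = table.site_counts()
            small = [s for s in sites if counts.get(s, 0) < min_pop_size]
            if small:
                raise ValueError(
                    f"PSS sites below the minimum size {min_pop_size}: {small}"
                )
        return table.subset_sites(sites)
    if scheme != "ISS":
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_per_site == "all":
        raise ValueError("ISS requires an integer n_per_site")
    if n_per_site < 1:
        raise ValueError("ISS n_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    idx = []
    for site in sites:
        members = table.individuals_at(site)
        if not members:
            raise ValueError(f"site {site} has no individuals")
        take = min(n_per_site, len(members))
        chosen = rng.choice(len(members), size=take, replace=False)
        idx.extend(members[c] for c in sorted(chosen))
    return table.subset(sorted(idx))


def _one_ranking(sub: GenotypeTable, predictors: dict, models, method: str):
    ind = dps_matrix(sub)
    pop = average_to_population(ind, sub.site_of)
    preds = {k: v.submatrix(pop.labels) for k, v in predictors.items()}
    tbl, _ = fit_candidates(pop, preds, models, method=method)
    return tbl


def run_replicates(
    table: GenotypeTable,
    sites,
    predictors: dict,
    models,
    n_values=range(1, 12),
    R: int = 100,
    methods=("ML", "REML"),
    base_seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap the ISS design over per-site sample sizes.

    For each ``n`` in ``n_values`` and each of ``R`` replicates, draws an
    ISS dataset (replicate r uses seed ``base_seed + r``), rebuilds the
    population-averaged allele-sharing response, fits every candidate
    model under each estimation method and records delta-IC, IC weight
    and the competitive flag (delta < 2) for both AICc and BIC.

    Returns a long DataFrame with one row per
    (method, n, replicate, model).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    sites = list(sites)
    records = []
    for n in n_values:
        for r in range(R):
            sub = make_scheme_dataset(
                table, "ISS", sites, n_per_site=n, seed=base_seed + r
            )
            for method in methods:
                tbl = _one_ranking(sub, predictors, models, method)
                for model, row in tbl.iterrows():
                    records.append(
                        {
                            "method": method,
                            "n": int(n),
                            "replicate": r,
                            "model": model,
                            "dAICc": row["dAICc"],
                            "wAICc": row["wAICc"],
                            "dBIC": row["dBIC"],
                            "wBIC": row["wBIC"],
                            "comp_AICc": row["dAICc"] < DELTA_COMPETITIVE,
                            "comp_BIC": row["dBIC"] < DELTA_COMPETITIVE,
                        }
                    )
    return pd.DataFrame(records)


def summarize_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Per (method, n, model) summary: competitive counts out of R and
    mean IC weight ± SE over replicates."""
    def agg(g):
        R = g["replicate"].nunique()
        return pd.Series(
            {
                "R": R,
                "n_comp_AICc": int(g["comp_AICc"].sum()),
                "n_comp_BIC": int(g["comp_BIC"].sum()),
                "mean_wAICc": g["wAICc"].mean(),
                "se_wAICc": g["wAICc"].std(ddof=1) / np.sqrt(R) if R > 1 else 0.0,
                "mean_wBIC": g["wBIC"].mean(),
                "se_wBIC": g["wBIC"].std(ddof=1) / np.sqrt(R) if R > 1 else 0.0,
                "mean_dAICc": g["dAICc"].mean(),
                "se_dAICc": g["dAICc"].std(ddof=1) / np.sqrt(R) if R > 1 else 0.0,
            }
        )
    out = (
        replicates.groupby(["method", "n", "model"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return out


def competitive_models(
    summary: pd.DataFrame,
    weight_threshold: float = 0.1,
    count_threshold: int = 30,
    criterion: str = "AICc",
) -> pd.DataFrame:
    """Models admitted by either the mean-weight or the replicate-count rule.

    A model is competitive when its mean IC weight strictly exceeds
    ``weight_threshold`` (a weight exactly at the threshold is excluded)
    or when it was competitive (delta < 2) in at least ``count_threshold``
    replicates (the boundary count is included).  Each returned row is
    flagged with which rule(s) admitted it.
    """
    if weight_threshold <= 0 or count_threshold <= 0:
        raise ValueError("thresholds must be positive")
    w = summary[f"mean_w{criterion}"] > weight_threshold
    c = summary[f"n_comp_{criterion}"] >= count_threshold
    out = summary.loc[w | c, ["model"] + [
        col for col in ("method", "n") if col in summary.columns
    ]].copy()
    out["by_weight"] = w[w | c].to_numpy()
    out["by_count"] = c[w | c].to_numpy()
    return out.reset_index(drop=True)


def convergence_analysis(
    replicates: pd.DataFrame,
    reference: set,
    agreement_threshold: float = 0.9,
    criterion: str = "AICc",
    mode: str = "intersect",
) -> dict:
    """Fraction of replicates whose competitive set agrees with a reference.

    ``reference`` is the top-model set of the deterministic PSS or PASS
    analysis.  Agreement for one replicate means its delta<2 competitive
    set intersects the reference (``mode="intersect"``), or that its
    single best model is in the reference (``mode="top_match"``).

    Returns ``{"fractions": Series indexed by n, "converged_n": int or
    None}`` with ``converged_n`` the smallest n whose agreement fraction
    strictly exceeds the threshold.
    """
    reference = set(reference)
    if not reference:
        raise ValueError("reference model set is empty")
    comp_col = f"comp_{criterion}"
    d_col = f"d{criterion}"
    fracs = {}
    for n, g_n in replicates.groupby("n"):
        agree = 0
        total = 0
        for _, g in g_n.groupby("replicate"):
            total += 1
            if mode == "intersect":
                comp = set(g.loc[g[comp_col], "model"])
                if comp & reference:
                    agree += 1
            elif mode == "top_match":
                best = g.loc[g[d_col].idxmin(), "model"]
                if best in reference:
                    agree += 1
            else:
                raise ValueError(f"unknown agreement mode {mode!r}")
        fracs[int(n)] = agree / total
    fracs = pd.Series(fracs).sort_index()
    over = fracs[fracs > agreement_threshold]
    converged_n = int(over.index[0]) if len(over) else None
    return {"fractions": fracs, "converged_n": converged_n}
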