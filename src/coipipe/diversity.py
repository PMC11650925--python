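"""Per-site diversity summaries over identified mOTUs.

Only specimens whose mOTU was identified (>= 98% database match) enter the
site x mOTU abundance table. Diversity is reported as Shannon entropy in
nats, Gini-Simpson (1 - sum p^2, optionally inverse Simpson), shared-mOTU
region counts over all site subsets, hypergeometric rarefaction (expected
richness at subsample size m, interpolation only), and the
singleton/doubleton sample-coverage estimate.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln


def _counts(row) -> np.ndarray:
    counts = np.asarray(row, dtype=float)
    if counts.ndim != 1 or np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be a 1-d vector of non-negative integers")
    if counts.sum() == 0:
        raise ValueError("all-zero abundance row")
    return counts


def shannon(row) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats)."""
    counts = _counts(row)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def simpson(row, variant: str = "gini") -> float:
    """Simpson diversity: Gini-Simpson 1 - sum p^2 (default) or inverse."""
    counts = _counts(row)
    p = counts / counts.sum()
    ss = float((p**2).sum())
    if variant == "gini":
        return 1.0 - ss
    if variant == "inverse":
        return 1.0 / ss
    raise ValueError(f"unknown Simpson variant: {variant}")


def shared_motus(table: pd.DataFrame) -> dict[frozenset[str], int]:
    """mOTUs present in *exactly* each non-empty subset of sites.

    ``table`` is sites x mOTUs. Counts over all subsets sum to the total
    number of (non-absent) mOTUs, so the regions form a Venn partition.
    """
    if len(table.index) < 2:
        raise ValueError("shared_motus requires at least two sites")
    sites = list(table.index)
    presence = table > 0
    out: dict[frozenset[str], int] = {}
    for r in range(1, len(sites) + 1):
        for subset in combinations(sites, r):
            mask = presence.loc[list(subset)].all(axis=0)
            others = [s for s in sites if s not in subset]
            if others:
                mask &= ~presence.loc[others].any(axis=0)
            out[frozenset(subset)] = int(mask.sum())
    return out


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(row, m: int) -> float:
    """Expected mOTU richness in a random subsample of m individuals.

    E[S_m] = sum_i [1 - C(n - x_i, m) / C(n, m)] (hypergeometric
    interpolation). Extrapolation (m > n) is out of scope and raises.
    """
    counts = _counts(row)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}] (interpolation only), got {m}")
    terms = np.where(
        n - counts >= m,
        np.exp(_log_comb(n - counts, m) - _log_comb(n, m)),
        0.0,
    )
    return float((1.0 - terms).sum())


def sample_coverage(row) -> float:
    """Sample-coverage estimate from singletons and doubletons.

    C-hat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)], the estimated
    fraction of individuals in the community belonging to mOTUs already
    observed; 1 exactly when there are no singletons.
    """
    counts = _counts(row)
    counts = counts[counts > 0]
    n = counts.sum()
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2)))


def abundance_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Site x mOTU counts over identified specimens.

    ``assignments`` needs columns specimen, site, motu, final_name; rows
    with a null final_name (unidentified mOTUs) are excluded, and all-zero
    mOTU columns cannot occur by construction.
    """
    identified = assignments[assignments["final_name"].notna()]
    table = (identified.groupby(["site", "motu"]).size().unstack(fill_value=0))
    return table.sort_index(axis=0).sort_index(axis=1)


def site_diversity_table(table: pd.DataFrame, simpson_variant: str = "gini") -> pd.DataFrame:
    """Observed richness, Shannon, Simpson and coverage per site."""
    rows = []
    for site in table.index:
        row = table.loc[site].to_numpy()
        rows.append((site, int((row > 0).sum()), int(row.sum()),
                     shannon(row), simpson(row, simpson_variant), sample_coverage(row)))
    return pd.DataFrame(rows, columns=["site", "richness", "n_individuals",
                                       "shannon_H", "simpson_D", "coverage_Chat"])


def rarefaction_curve(row, n_points: int = 20) -> pd.DataFrame:
    """Interpolated rarefaction curve (m, E[S_m], C-hat at full n)."""
    counts = _counts(row)
    n = int(counts.sum())
    ms = np.unique(np.linspace(1, n, min(n_points, n)).astype(int))
    chat = sample_coverage(row)
    return pd.DataFrame({"m": ms, "expected_richness": [rarefy(row, int(m)) for m in ms],
                         "coverage_Chat": chat})
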