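"""Statistical battery: chi-square with adjusted residuals, Kruskal-Wallis with
Dunn post-hoc under a global FDR, and two-sample Kolmogorov-Smirnov tests.

The contingency analysis pairs the Pearson chi-square statistic with
Haberman's adjusted standardized residuals,

    d_ij = (O_ij - E_ij) / sqrt(E_ij (1 - R_i/N) (1 - C_j/N)),

which are approximately standard normal per cell under independence, so cells
with |d| above the two-sided normal critical value are flagged as harbouring
an excess or deficit of counts.  Trait distributions across richness
categories are compared with tie-corrected Kruskal-Wallis tests; a global
Benjamini-Hochberg correction over all traits decides significance, and
Dunn's pairwise rank comparisons (BH-adjusted within trait) localize the
differences.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyResult",
    "TraitComparison",
    "chi2_haberman",
    "kruskal_dunn",
    "dunn_posthoc",
    "ks_median_ages",
]

EXCESS, DEFICIT, NONE = "excess", "deficit", "none"


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    adj_residuals: pd.DataFrame
    flags: pd.DataFrame  # excess / deficit / none
    critical_value: float

    def summary(self) -> dict:
        flagged = [
            {"row": r, "col": c, "flag": self.flags.loc[r, c],
             "residual": float(self.adj_residuals.loc[r, c])}
            for r in self.flags.index
            for c in self.flags.columns
            if self.flags.loc[r, c] != NONE
        ]
        return {"chi2": self.chi2, "df": self.df, "p": self.p, "flagged_cells": flagged}


def chi2_haberman(observed, alpha: float = 0.05) -> ContingencyResult:
    """Pearson chi-square with Haberman adjusted residuals on a count table.

    ``observed`` is a 2-D array or labelled DataFrame of counts (>= 2x2).  No
    continuity correction is applied.  Cells whose adjusted residual exceeds
    the two-sided standard-normal critical value at ``alpha`` are flagged
    excess (positive) or deficit (negative).  Expected counts below 5 only
    raise a warning; the method is not switched.
    """
    obs = observed if isinstance(observed, pd.DataFrame) else pd.DataFrame(np.asarray(observed))
    O = obs.to_numpy(dtype=float)
    if O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(O < 0):
        raise ValueError("counts must be nonnegative")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    N = O.sum()
    if np.any(row == 0) or np.any(col == 0) or N == 0:
        raise ValueError("degenerate table: a zero marginal total")

    E = np.outer(row, col) / N
    chi2 = float(((O - E) ** 2 / E).sum())
    dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, dof))
    if np.any(E < 5):
        warnings.warn(f"{int((E < 5).sum())} cell(s) have expected counts < 5")

    denom = np.sqrt(E * np.outer(1 - row / N, 1 - col / N))
    adj = (O - E) / denom
    crit = float(stats.norm.ppf(1 - alpha / 2))
    flags = np.full(O.shape, NONE, dtype=object)
    flags[adj > crit] = EXCESS
    flags[adj < -crit] = DEFICIT

    idx, cols = obs.index, obs.columns
    return ContingencyResult(
        observed=obs,
        expected=pd.DataFrame(E, index=idx, columns=cols),
        chi2=chi2,
        df=dof,
        p=p,
        adj_residuals=pd.DataFrame(adj, index=idx, columns=cols),
        flags=pd.DataFrame(flags, index=idx, columns=cols),
        critical_value=crit,
    )


@dataclass
class TraitComparison:
    trait_name: str
    kw_H: float
    kw_p: float
    kw_p_adjusted: float
    significant: bool
    dunn_pairs: pd.DataFrame | None = None  # columns group_a, group_b, z, p, p_adjusted
    group_sizes: dict[str, int] = field(default_factory=dict)


def _tie_correction_sum(pooled: np.ndarray) -> float:
    """Sum of (t^3 - t) over tied groups in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def dunn_posthoc(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks with tie-corrected variance.

    p-values are two-sided normal and BH-adjusted across the pairs of one
    trait.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for name, v in zip(names, values):
        mean_ranks[name] = float(ranks[offset : offset + v.size].mean())
        sizes[name] = v.size
        offset += v.size
    tie_term = _tie_correction_sum(pooled) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def kruskal_dunn(
    traits: Mapping[str, Mapping[str, Sequence[float]]],
    fdr_q: float = 0.1,
) -> tuple[list[TraitComparison], float]:
    """Kruskal-Wallis per trait with a global BH-FDR, then Dunn for hits.

    ``traits`` maps trait name -> {category -> per-family values}.  The BH
    procedure runs once over all trait-level KW p-values at ``fdr_q``; Dunn
    post-hoc comparisons are computed only for traits declared significant.
    Returns the comparisons and the realized p-value threshold (largest KW p
    among significant traits; nan when none).
    """
    names = list(traits)
    results: list[TraitComparison] = []
    pvals = []
    for name in names:
        groups = traits[name]
        if any(len(v) < 1 for v in groups.values()) or len(groups) < 2:
            raise ValueError(f"trait {name!r}: every group needs >= 1 value, >= 2 groups")
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
        if np.ptp(np.concatenate(arrays)) == 0:
            H, p = 0.0, 1.0  # scipy raises on all-identical data
        else:
            H, p = stats.kruskal(*arrays)
        pvals.append(p)
        results.append(
            TraitComparison(
                trait_name=name,
                kw_H=float(H),
                kw_p=float(p),
                kw_p_adjusted=np.nan,
                significant=False,
                group_sizes={g: len(v) for g, v in groups.items()},
            )
        )

    reject, p_adj, _, _ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
    for res, rej, pa in zip(results, reject, p_adj):
        res.kw_p_adjusted = float(pa)
        res.significant = bool(rej)
        if rej:
            res.dunn_pairs = dunn_posthoc(traits[res.trait_name])
    sig_p = [r.kw_p for r in results if r.significant]
    realized_threshold = max(sig_p) if sig_p else float("nan")
    return results, realized_threshold


def ks_median_ages(
    ages_by_category: Mapping[str, Sequence[float]],
) -> dict:
    """Pairwise two-sample Kolmogorov-Smirnov tests on median family ages.

    Empty categories are skipped with a warning.  Returns per-pair (D, p)
    with asymptotic p-values, plus the maximum D across pairs.
    """
    cats = {}
    for name, vals in ages_by_category.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size == 0:
            warnings.warn(f"category {name!r} has no ages; skipped")
            continue
        cats[name] = v
    if len(cats) < 2:
        raise ValueError("need at least two non-empty categories")
    pairs = {}
    max_d = 0.0
    for a, b in itertools.combinations(cats, 2):
        res = stats.ks_2samp(cats[a], cats[b], method="asymp")
        pairs[(a, b)] = (float(res.statistic), float(res.pvalue))
        max_d = max(max_d, float(res.statistic))
    return {"pairs": pairs, "max_D": max_d}
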