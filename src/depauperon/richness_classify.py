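"""Classify families as low/predicted/high richness and build cross-dataset consensus.

A family is compared against the widest 95% clade-size interval obtained by
sweeping the fitted birth-death parameters over the +-1 log-unit
profile-likelihood region at the family's crown age: ``low`` when its
richness falls below k_lower, ``high`` above k_upper, ``predicted``
otherwise.  Bounds are real-valued and compared without rounding.  A family
classified identically in all datasets gets a strict-consensus label
(poor/expected/high); agreement in at least ``majority_min`` datasets gives a
majority label; anything else is ``undefined``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association_tests import ContingencyResult, chi2_haberman
from .birthdeath_core import DiversificationFit
from .io_ingest import FamilyRecord

__all__ = [
    "IntervalPartition",
    "RichnessCall",
    "ConsensusCall",
    "classify_family",
    "classify_dataset",
    "consensus",
    "category_counts",
    "period_independence",
    "calls_to_frame",
    "consensus_to_frame",
]

LOW, PREDICTED, HIGH = "low", "predicted", "high"
#: strict-consensus output vocabulary
STRICT_LABEL = {LOW: "poor", PREDICTED: "expected", HIGH: "high"}


@dataclass(frozen=True)
class IntervalPartition:
    """Geological intervals defined by age breakpoints (My before present).

    ``breakpoints`` are the internal interval edges, e.g. [100.0, 66.0] splits
    ages into (inf, 100], (100, 66], (66, 0).  Interval 0 is the oldest.
    """

    breakpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        bp = list(self.breakpoints)
        if bp != sorted(bp, reverse=True) or len(set(bp)) != len(bp):
            raise ValueError("breakpoints must be strictly decreasing ages")
        if any(b <= 0 for b in bp):
            raise ValueError("breakpoints must be positive ages")

    @property
    def n_intervals(self) -> int:
        return len(self.breakpoints) + 1

    def interval_of(self, t: float) -> int:
        """Index of the interval containing age t (0 = oldest)."""
        if t <= 0:
            raise ValueError(f"age must be > 0, got {t}")
        idx = 0
        for b in self.breakpoints:
            if t > b:
                return idx
            idx += 1
        return idx


@dataclass(frozen=True)
class RichnessCall:
    family_name: str
    dataset_id: str
    category: str  # low | predicted | high
    n: int
    bounds_used: tuple[float, float]
    interval_id: int
    age_used: float
    age_source: str


@dataclass(frozen=True)
class ConsensusCall:
    family_name: str
    strict_category: str  # poor | expected | high | undefined
    majority_category: str
    votes: dict[str, int] = field(hash=False)


def classify_family(
    record: FamilyRecord,
    fit: DiversificationFit,
    dataset_id: str,
    partition: IntervalPartition | None = None,
    use_profile_region: bool = True,
) -> RichnessCall | None:
    """Classify one family in one dataset against a fitted interval model.

    With ``use_profile_region`` the bounds are the widest clade-size interval
    over the +-1 log-unit likelihood region ("maximum width"); otherwise the
    bounds at the MLE point are used.  Returns None (with a warning) when the
    family has no age in this dataset.
    """
    t = record.crown_age_t.get(dataset_id)
    if t is None:
        warnings.warn(f"{record.family_name}: no age in dataset {dataset_id}; skipped")
        return None
    k_lo, k_hi = (
        fit.widest_bounds_at(t) if use_profile_region else fit.point_bounds_at(t)
    )
    n = record.richness_n
    if n < k_lo:
        category = LOW
    elif n > k_hi:
        category = HIGH
    else:
        category = PREDICTED
    interval_id = partition.interval_of(t) if partition is not None else fit.interval_id
    return RichnessCall(
        family_name=record.family_name,
        dataset_id=dataset_id,
        category=category,
        n=n,
        bounds_used=(k_lo, k_hi),
        interval_id=interval_id,
        age_used=t,
        age_source=record.age_source.get(dataset_id, ""),
    )


def classify_dataset(
    records: Sequence[FamilyRecord],
    fits: Mapping[int, DiversificationFit],
    dataset_id: str,
    partition: IntervalPartition,
    use_profile_region: bool = True,
    exclude_imputed: bool = False,
) -> list[RichnessCall]:
    """Classify every family of one dataset, routing each to its interval's fit.

    ``exclude_imputed`` restricts to ages observed in the original phylogeny
    (a sensitivity analysis); by default imputed ages participate.
    """
    calls = []
    for rec in records:
        t = rec.crown_age_t.get(dataset_id)
        if t is None:
            continue
        if exclude_imputed and rec.age_source.get(dataset_id) != "observed":
            continue
        fit = fits.get(partition.interval_of(t))
        if fit is None:
            raise KeyError(
                f"no fit for interval {partition.interval_of(t)} of dataset {dataset_id}"
            )
        call = classify_family(rec, fit, dataset_id, partition, use_profile_region)
        if call is not None:
            calls.append(call)
    return calls


def consensus(
    calls_by_dataset: Mapping[str, Sequence[RichnessCall]],
    n_datasets: int = 5,
    majority_min: int = 4,
) -> list[ConsensusCall]:
    """Aggregate per-dataset calls into strict and majority consensus labels.

    Strict consensus needs all ``n_datasets`` votes to agree (families absent
    from any dataset are ineligible); majority needs ``majority_min``
    agreeing votes.
    """
    votes: dict[str, dict[str, int]] = {}
    for ds, calls in calls_by_dataset.items():
        seen = set()
        for call in calls:
            if call.family_name in seen:
                raise ValueError(f"{call.family_name} appears twice in dataset {ds}")
            seen.add(call.family_name)
            votes.setdefault(call.family_name, {}).setdefault(call.category, 0)
            votes[call.family_name][call.category] += 1

    out = []
    for family in sorted(votes):
        v = votes[family]
        top_cat = max(v, key=lambda c: v[c])
        top = v[top_cat]
        strict = STRICT_LABEL[top_cat] if top == n_datasets else "undefined"
        major = STRICT_LABEL[top_cat] if top >= majority_min else "undefined"
        out.append(ConsensusCall(family, strict, major, dict(v)))
    return out


def category_counts(calls: Sequence[ConsensusCall], which: str = "strict") -> pd.DataFrame:
    """Counts and percentages per consensus category (undefined excluded).

    Percentages are of the consensus-classified total, one decimal place.
    """
    attr = "strict_category" if which == "strict" else "majority_category"
    labels = [getattr(c, attr) for c in calls if getattr(c, attr) != "undefined"]
    total = len(labels)
    rows = []
    for cat in ("poor", "expected", "high"):
        count = sum(1 for x in labels if x == cat)
        pct = round(100.0 * count / total, 1) if total else 0.0
        rows.append({"category": cat, "count": count, "percent": pct})
    return pd.DataFrame(rows)


def period_independence(calls: Sequence[RichnessCall], alpha: float = 0.05) -> ContingencyResult:
    """Chi-square independence of richness category and origin interval.

    Builds the interval x category contingency table from one dataset's calls
    and delegates to the adjusted-residual analysis.
    """
    df = calls_to_frame(calls)
    table = pd.crosstab(df["interval_id"], df["category"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"need >=2 intervals and >=2 categories represented, got table shape {table.shape}"
        )
    return chi2_haberman(table, alpha=alpha)


def calls_to_frame(calls: Sequence[RichnessCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [c.family_name for c in calls],
            "dataset": [c.dataset_id for c in calls],
            "category": [c.category for c in calls],
            "n": [c.n for c in calls],
            "k_lower": [c.bounds_used[0] for c in calls],
            "k_upper": [c.bounds_used[1] for c in calls],
            "interval_id": [c.interval_id for c in calls],
            "age": [c.age_used for c in calls],
            "age_source": [c.age_source for c in calls],
        }
    )


def consensus_to_frame(calls: Sequence[ConsensusCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"family": c.family_name, "strict": c.strict_category, "majority": c.majority_category}
        for cat in (LOW, PREDICTED, HIGH):
            row[f"votes_{cat}"] = c.votes.get(cat, 0)
        rows.append(row)
    return pd.DataFrame(rows)
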