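"""Reading, validating and harmonizing family tables, trees, and mating-system data.

The unit of analysis is the plant family: its species richness ``n`` and its
crown age ``t`` (in million years) in each of several independently calibrated
phylogenetic datasets.  Families absent from a given phylogeny can have their
age imputed from a designated sister family (or its stem age).  Mating-system
profiles (fractions of scored species that are self-compatible,
self-incompatible/self-sterile, or dioecious) are collapsed to a categorical
label with >80% / 20-80% thresholds.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "FamilyRecord",
    "AgeImputationMap",
    "MatingSystemProfile",
    "SchemaError",
    "DuplicateFamilyError",
    "ImputationError",
    "TreeValidationError",
    "read_family_table",
    "write_family_table",
    "merge_family_tables",
    "extract_crown_ages",
    "read_tip_to_family",
    "impute_missing_ages",
    "categorize_mating_system",
]

AGE_OBSERVED = "observed"
AGE_SISTER = "sister_imputed"
AGE_STEM = "stem_imputed"

#: relative spread of root-to-tip distances tolerated before a tree is
#: rejected as non-ultrametric
ULTRAMETRIC_RTOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class DuplicateFamilyError(ValueError):
    """The same family appears more than once within one dataset."""


class ImputationError(ValueError):
    """Age imputation could not be resolved (missing proxy, chain, or cycle)."""


class TreeValidationError(ValueError):
    """Input tree violates a structural requirement (e.g. ultrametricity)."""


@dataclass
class FamilyRecord:
    """One family's richness and per-dataset crown ages.

    crown_age_t maps dataset_id -> age in My; age_source tags each present
    age as observed, sister_imputed, or stem_imputed.
    """

    family_name: str
    richness_n: int
    crown_age_t: dict[str, float] = field(default_factory=dict)
    age_source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.richness_n < 1:
            raise ValueError(f"{self.family_name}: richness must be >= 1, got {self.richness_n}")
        for ds, t in self.crown_age_t.items():
            if not t > 0:
                raise ValueError(f"{self.family_name}: crown age for {ds} must be > 0, got {t}")
            if ds not in self.age_source:
                raise ValueError(f"{self.family_name}: age for {ds} lacks an age_source tag")


@dataclass(frozen=True)
class AgeImputationMap:
    """Directive to copy a missing family's age from a proxy (sister) family."""

    family_name: str
    proxy_family: str
    mode: str = "sister_crown"  # or "stem"

    def __post_init__(self) -> None:
        if self.family_name == self.proxy_family:
            raise ValueError(f"{self.family_name}: proxy must differ from the family itself")
        if self.mode not in ("sister_crown", "stem"):
            raise ValueError(f"unknown imputation mode {self.mode!r}")


@dataclass(frozen=True)
class MatingSystemProfile:
    """Fractions of scored species per mating/sexual system in one family."""

    family_name: str
    prop_sc: float
    prop_si_or_ss: float
    prop_dioecious: float
    n_species_scored: int

    def __post_init__(self) -> None:
        if self.n_species_scored < 0:
            raise ValueError("n_species_scored must be >= 0")
        if self.n_species_scored and self.prop_sc + self.prop_si_or_ss > 1 + 1e-9:
            raise ValueError(
                f"{self.family_name}: SC and SI/SS fractions sum to more than 1"
            )


_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:-|–|—|to)\s*(\d+(?:\.\d+)?)\s*$")


def _parse_richness(cell) -> int:
    """Parse a richness cell; 'a-b' / 'a–b' / 'a to b' ranges become their mean.

    The mean of a range is rounded half-up to an integer.
    """
    if isinstance(cell, (int, float)) and not isinstance(cell, bool):
        if float(cell) != int(cell):
            raise SchemaError(f"non-integer richness {cell!r}")
        return int(cell)
    text = str(cell).strip()
    m = _RANGE_RE.match(text)
    if m:
        mean = (Decimal(m.group(1)) + Decimal(m.group(2))) / 2
        return int(mean.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    try:
        return int(text)
    except ValueError as exc:
        raise SchemaError(f"cannot parse richness cell {text!r}") from exc


def read_family_table(path, dataset_id: str) -> list[FamilyRecord]:
    """Read a delimited family table (columns family, richness, age).

    Comma or tab delimiters are autodetected.  Richness ranges are resolved
    to their mean.  Empty age cells yield records without an age for this
    dataset; rows with a non-positive age are rejected with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"family", "richness", "age"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")

    records: list[FamilyRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        family = str(row["family"]).strip()
        if family in seen:
            raise DuplicateFamilyError(f"{path}: family {family!r} appears more than once")
        seen.add(family)
        n = _parse_richness(row["richness"])
        age_cell = row["age"]
        ages: dict[str, float] = {}
        sources: dict[str, str] = {}
        if age_cell is not None and str(age_cell).strip() not in ("", "nan", "NA"):
            t = float(age_cell)
            if t <= 0:
                warnings.warn(
                    f"{path}: rejecting row for {family!r} with non-positive age {t}"
                )
                continue
            ages[dataset_id] = t
            sources[dataset_id] = AGE_OBSERVED
        records.append(FamilyRecord(family, n, ages, sources))
    return records


def write_family_table(records, path, dataset_id: str, sep: str = ",") -> None:
    """Write records back to the delimited layout read_family_table consumes."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["family", "richness", "age"])
        for rec in records:
            age = rec.crown_age_t.get(dataset_id, "")
            writer.writerow([rec.family_name, rec.richness_n, age])


def merge_family_tables(tables: dict[str, list[FamilyRecord]]) -> list[FamilyRecord]:
    """Merge per-dataset record lists into one multi-dataset record per family.

    Richness may differ between source tables (they were compiled at
    different times); the maximum is retained as the family's richness.
    """
    merged: dict[str, FamilyRecord] = {}
    for dataset_id, records in tables.items():
        for rec in records:
            tgt = merged.get(rec.family_name)
            if tgt is None:
                merged[rec.family_name] = FamilyRecord(
                    rec.family_name,
                    rec.richness_n,
                    dict(rec.crown_age_t),
                    dict(rec.age_source),
                )
            else:
                tgt.richness_n = max(tgt.richness_n, rec.richness_n)
                tgt.crown_age_t.update(rec.crown_age_t)
                tgt.age_source.update(rec.age_source)
    return list(merged.values())


def read_tip_to_family(path) -> dict[str, str]:
    """Read a two-column delimited tip-label -> family mapping."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected two columns (tip, family)")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def extract_crown_ages(
    tree, tip_to_family: dict[str, str], rtol: float = ULTRAMETRIC_RTOL
) -> dict[str, tuple[float, str]]:
    """Crown ages per family from an ultrametric tree.

    ``tree`` is a dendropy.Tree or a path to a newick file.  For families
    with >= 2 assigned tips the age is the depth of their MRCA below the
    present; single-tip (monotypic) families take their stem age -- the depth
    of the node their terminal branch originates from -- and are tagged
    ``stem_imputed``.  Returns family -> (age, source_tag).

    Raises TreeValidationError when root-to-tip distances spread by more than
    ``rtol`` of the tree depth.  Unmapped tips are excluded with a warning.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = dendropy.Tree.get(path=str(tree), schema="newick")
    tree.is_rooted = True
    tree.encode_bipartitions()
    dists = {leaf: leaf.distance_from_root() for leaf in tree.leaf_node_iter()}
    depth = max(dists.values())
    if depth <= 0:
        raise TreeValidationError("tree has zero depth")
    spread = depth - min(dists.values())
    if spread > rtol * depth:
        raise TreeValidationError(
            f"tree is not ultrametric: tip depths spread by {spread:g} (> {rtol:g} of depth {depth:g})"
        )

    by_family: dict[str, list] = {}
    unmapped = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        family = tip_to_family.get(label)
        if family is None:
            unmapped.append(label)
            continue
        by_family.setdefault(family, []).append(leaf)
    if unmapped:
        warnings.warn(f"excluding {len(unmapped)} tip(s) with no family assignment: {unmapped}")

    ages: dict[str, tuple[float, str]] = {}
    for family, leaves in by_family.items():
        if len(leaves) >= 2:
            taxa = [lf.taxon for lf in leaves]
            mrca = tree.mrca(taxa=taxa)
            ages[family] = (depth - mrca.distance_from_root(), AGE_OBSERVED)
        else:
            parent = leaves[0].parent_node
            stem_node = parent if parent is not None else leaves[0]
            ages[family] = (depth - stem_node.distance_from_root(), AGE_STEM)
    return ages


def impute_missing_ages(
    records: list[FamilyRecord], imputation_map: list[AgeImputationMap]
) -> list[FamilyRecord]:
    """Fill per-dataset missing crown ages from proxy (sister) families.

    The map must be one hop deep: a proxy may not itself be a mapped family
    (chains and cycles are rejected).  If a needed proxy lacks an observed
    age in some dataset, an ImputationError lists every offender.
    """
    mapped = {m.family_name for m in imputation_map}
    chained = [m for m in imputation_map if m.proxy_family in mapped]
    if chained:
        names = [(m.family_name, m.proxy_family) for m in chained]
        raise ImputationError(f"imputation chains/cycles are not allowed: {names}")

    by_name = {rec.family_name: rec for rec in records}
    datasets = {ds for rec in records for ds in rec.crown_age_t}
    offenders: list[str] = []
    for m in imputation_map:
        rec = by_name.get(m.family_name)
        proxy = by_name.get(m.proxy_family)
        if rec is None:
            continue
        for ds in datasets:
            if ds in rec.crown_age_t:
                continue
            if proxy is None or ds not in proxy.crown_age_t:
                offenders.append(f"{m.family_name} <- {m.proxy_family} in {ds}")
                continue
            rec.crown_age_t[ds] = proxy.crown_age_t[ds]
            rec.age_source[ds] = AGE_SISTER if m.mode == "sister_crown" else AGE_STEM
    if offenders:
        raise ImputationError(f"proxy family missing an observed age: {offenders}")
    return records


def categorize_mating_system(profile: MatingSystemProfile) -> str:
    """Collapse a mating-system profile to one categorical label.

    Dioecious requires every scored species to be dioecious.  SC and SI need
    >80% of scored species in the respective class; an SI/SS fraction in
    [0.2, 0.8] gives the mixed SC-SI label (threshold equality is assigned to
    the mixed class).  Profiles with no scored species, or too weak a signal
    for any class, are Unknown.
    """
    if profile.n_species_scored == 0:
        return "Unknown"
    if profile.prop_dioecious >= 1.0 - 1e-12:
        return "Dioecious"
    if profile.prop_sc > 0.8:
        return "SC"
    if profile.prop_si_or_ss > 0.8:
        return "SI"
    if 0.2 <= profile.prop_si_or_ss <= 0.8:
        return "SC-SI"
    return "Unknown"
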