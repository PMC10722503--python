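"""Occurrence cleaning, per-family diversification rates, 1-degree grid maps,
and realm/biome range summaries.

Occurrence tables follow a Darwin-Core-like layout (species, family,
decimalLongitude, decimalLatitude, basisOfRecord, optional realm and biome
labels).  Cleaning keeps georeferenced preserved-specimen and literature
records with full binomials, dropping exact duplicate (taxon, lon, lat)
tuples and taxa on a caller-supplied exclusion list (crops, cultivated and
garden material).  Each record then inherits its family's net
diversification rate and contributes it to the 1-degree grid cell containing
the point; a cell's value is the mean rate over its records.

Range categorization replaces hand assessment with a deterministic rule set
(see ``realm_biome_summary``); disjunct distributions are detected by
single-linkage clustering on great-circle distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "REQUIRED_COLUMNS",
    "ACCEPTED_BASIS",
    "FamilyGeoSummary",
    "clean_occurrences",
    "family_dr",
    "grid_mean_dr",
    "realm_biome_summary",
    "haversine_km",
]

REQUIRED_COLUMNS = ("species", "family", "decimalLongitude", "decimalLatitude", "basisOfRecord")
#: record bases retained by cleaning (case/underscore-insensitive)
ACCEPTED_BASIS = frozenset({"preservedspecimen", "literature", "materialcitation"})
EARTH_RADIUS_KM = 6371.0


def _norm_basis(value: str) -> str:
    return str(value).replace("_", "").replace(" ", "").strip().lower()


def _is_binomial(name) -> bool:
    parts = str(name).strip().split()
    return len(parts) >= 2 and all(p.strip() for p in parts[:2]) and parts[1].lower() != "sp."


def clean_occurrences(
    records: pd.DataFrame,
    exclusion_list: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter an occurrence table; returns (clean records, per-rule rejection log).

    Rules, applied in order: full binomial taxon name; accepted basisOfRecord;
    coordinates present and within bounds; taxon not excluded; exact
    (taxon, lon, lat) duplicates dropped keeping the first.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"occurrence table missing column(s) {missing}")
    df = records.copy()
    log: dict[str, int] = {}

    ok = df["species"].map(_is_binomial).astype(bool)
    log["not_binomial"] = int((~ok).sum())
    df = df[ok]

    ok = df["basisOfRecord"].map(_norm_basis).isin(ACCEPTED_BASIS).astype(bool)
    log["basis_rejected"] = int((~ok).sum())
    df = df[ok]

    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    ok = lon.between(-180, 180) & lat.between(-90, 90)
    log["bad_coordinates"] = int((~ok).sum())
    df = df[ok].assign(decimalLongitude=lon[ok], decimalLatitude=lat[ok])

    if exclusion_list:
        excluded = set(exclusion_list)
        ok = ~df["species"].isin(excluded)
        log["excluded_taxa"] = int((~ok).sum())
        df = df[ok]
    else:
        log["excluded_taxa"] = 0

    before = len(df)
    df = df.drop_duplicates(subset=["species", "decimalLongitude", "decimalLatitude"], keep="first")
    log["duplicates"] = before - len(df)

    return df.reset_index(drop=True), log


def family_dr(n: int, t: float, estimator: str = "stem", eps: float = 0.0) -> float:
    """Net diversification rate of a family from its richness and age.

    stem:  r = ln(n (1-eps) + eps) / t   (reduces to ln(n)/t at eps = 0)
    crown: r = [ln( n(1-eps^2)/2 + 2 eps + (1-eps)/2 *
                sqrt(n (n eps^2 - 8 eps + 2 n eps + n) + 4 eps^2) ) - ln 2] / t
           (reduces to (ln n - ln 2)/t at eps = 0; requires n >= 2)
    """
    if t <= 0:
        raise ValueError(f"age must be > 0, got {t}")
    if n < 1:
        raise ValueError(f"richness must be >= 1, got {n}")
    if not 0 <= eps < 1:
        raise ValueError(f"extinction fraction must be in [0, 1), got {eps}")
    if estimator == "stem":
        return math.log(n * (1 - eps) + eps) / t
    if estimator == "crown":
        if n < 2:
            raise ValueError("crown estimator needs n >= 2 (a crown group has two daughters)")
        inner = (
            0.5 * n * (1 - eps**2)
            + 2 * eps
            + 0.5 * (1 - eps) * math.sqrt(n * (n * eps**2 - 8 * eps + 2 * n * eps + n) + 4 * eps**2)
        )
        return (math.log(inner) - math.log(2)) / t
    raise ValueError(f"unknown estimator {estimator!r}")


def grid_mean_dr(records: pd.DataFrame, family_dr_map: Mapping[str, float]) -> pd.DataFrame:
    """Aggregate mean family diversification rate on a 1-degree global grid.

    Cells are half-open [i, i+1) x [j, j+1) via floor of the coordinates; the
    antimeridian (lon = 180) and the pole (lat = 90) fold into the last cell.
    Every record contributes its family's rate once.  Records whose family
    has no rate raise a KeyError (they must be resolved upstream).
    """
    missing = sorted(set(records["family"]) - set(family_dr_map))
    if missing:
        raise KeyError(f"no diversification rate for family(ies) {missing}")
    lon = records["decimalLongitude"].to_numpy(dtype=float)
    lat = records["decimalLatitude"].to_numpy(dtype=float)
    ix = np.floor(lon).astype(int)
    iy = np.floor(lat).astype(int)
    ix[ix == 180] = 179
    iy[iy == 90] = 89
    dr = records["family"].map(family_dr_map).to_numpy(dtype=float)
    df = pd.DataFrame({"cell_lon_index": ix, "cell_lat_index": iy, "dr": dr})
    out = (
        df.groupby(["cell_lon_index", "cell_lat_index"], as_index=False)
        .agg(mean_dr=("dr", "mean"), n_records=("dr", "size"))
        .sort_values(["cell_lon_index", "cell_lat_index"])
        .reset_index(drop=True)
    )
    return out


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class FamilyGeoSummary:
    family_name: str
    realm_percentages: dict[str, float]
    biome_percentages: dict[str, float]
    n_realms: int
    n_biomes: int
    range_class: str  # highly_localized | localized | widespread | cosmopolitan
    pattern_class: str  # disjunct | continuous
    n_records: int
    n_unassigned: int


def _spatial_clusters(lon: np.ndarray, lat: np.ndarray, gap_km: float, max_points: int) -> int:
    """Number of single-linkage clusters at the great-circle gap threshold."""
    n = lon.size
    if n <= 1:
        return n
    if n > max_points:  # deterministic thinning for large families
        step = int(np.ceil(n / max_points))
        lon, lat = lon[::step], lat[::step]
        n = lon.size
    i, j = np.triu_indices(n, k=1)
    d = haversine_km(lon[i], lat[i], lon[j], lat[j])
    Z = linkage(d, method="single")
    labels = fcluster(Z, t=gap_km, criterion="distance")
    return int(labels.max())


def realm_biome_summary(
    family_name: str,
    records: pd.DataFrame,
    window_deg: float = 10.0,
    widespread_min_realms: int = 2,
    cosmopolitan_min_realms: int = 4,
    gap_km: float = 2000.0,
    max_cluster_points: int = 2000,
) -> FamilyGeoSummary:
    """Realm/biome percentages, range class, and distribution pattern for one family.

    Percentages are over records carrying a label (unassigned records are
    excluded with a warning).  The range classes are rule-based: all records
    inside one ``window_deg`` x ``window_deg`` window -> highly_localized;
    a single realm -> localized; >= ``cosmopolitan_min_realms`` realms ->
    cosmopolitan; otherwise (>= ``widespread_min_realms``) widespread.  The
    pattern is disjunct when single-linkage clustering at ``gap_km`` finds
    more than one spatial cluster.
    """
    if len(records) == 0:
        raise ValueError(f"{family_name}: no records")
    lon = records["decimalLongitude"].to_numpy(dtype=float)
    lat = records["decimalLatitude"].to_numpy(dtype=float)

    def pct_table(column: str) -> tuple[dict[str, float], int]:
        if column not in records.columns:
            return {}, len(records)
        labels = records[column].fillna("").astype(str)
        assigned = labels[labels.str.strip() != ""]
        n_un = len(records) - len(assigned)
        if len(assigned) == 0:
            return {}, n_un
        counts = assigned.value_counts()
        return {k: float(100.0 * v / len(assigned)) for k, v in counts.items()}, n_un

    realm_pct, un_realm = pct_table("realm")
    biome_pct, un_biome = pct_table("biome")
    n_unassigned = max(un_realm, un_biome)
    if n_unassigned:
        warnings.warn(
            f"{family_name}: {n_unassigned} record(s) lack realm/biome labels; excluded from percentages"
        )
    n_realms = len(realm_pct)
    n_biomes = len(biome_pct)

    if np.ptp(lon) <= window_deg and np.ptp(lat) <= window_deg:
        range_class = "highly_localized"
    elif n_realms <= 1:
        range_class = "localized"
    elif n_realms >= cosmopolitan_min_realms:
        range_class = "cosmopolitan"
    else:
        range_class = "widespread"

    n_clusters = _spatial_clusters(lon, lat, gap_km, max_cluster_points)
    pattern_class = "disjunct" if n_clusters >= 2 else "continuous"

    return FamilyGeoSummary(
        family_name=family_name,
        realm_percentages=realm_pct,
        biome_percentages=biome_pct,
        n_realms=n_realms,
        n_biomes=n_biomes,
        range_class=range_class,
        pattern_class=pattern_class,
        n_records=len(records),
        n_unassigned=int(n_unassigned),
    )
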