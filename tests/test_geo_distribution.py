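"""Occurrence cleaning, diversification-rate estimators, grid maps, range rules."""

import math

import numpy as np
import pandas as pd
import pytest

from depauperon.geo_distribution import (
    clean_occurrences,
    family_dr,
    grid_mean_dr,
    haversine_km,
    realm_biome_summary,
)


def occ(rows):
    return pd.DataFrame(
        rows,
        columns=["species", "family", "decimalLongitude", "decimalLatitude", "basisOfRecord"],
    )


GOOD = ["Quercus robur", "Fagaceae", 10.5, 45.2, "PRESERVED_SPECIMEN"]


class TestCleaning:
    def test_duplicates_keep_first(self):
        df, log = clean_occurrences(occ([GOOD, GOOD]))
        assert len(df) == 1
        assert log["duplicates"] == 1

    def test_genus_only_rejected(self):
        df, log = clean_occurrences(occ([["Quercus", "Fagaceae", 1, 1, "PRESERVED_SPECIMEN"]]))
        assert len(df) == 0
        assert log["not_binomial"] == 1

    def test_basis_filter_accepts_literature_case_insensitive(self):
        rows = [
            ["Aa bb", "F", 0, 0, "literature"],
            ["Cc dd", "F", 1, 1, "HUMAN_OBSERVATION"],
            ["Ee ff", "F", 2, 2, "Preserved_Specimen"],
        ]
        df, log = clean_occurrences(occ(rows))
        assert len(df) == 2
        assert log["basis_rejected"] == 1

    def test_out_of_bounds_coordinates_rejected(self):
        df, log = clean_occurrences(occ([["Aa bb", "F", 999, 0, "LITERATURE"]]))
        assert len(df) == 0
        assert log["bad_coordinates"] == 1

    def test_exclusion_list(self):
        df, log = clean_occurrences(
            occ([["Zea mays", "Poaceae", 0, 0, "PRESERVED_SPECIMEN"], GOOD]),
            exclusion_list=["Zea mays"],
        )
        assert list(df["species"]) == ["Quercus robur"]
        assert log["excluded_taxa"] == 1

    def test_empty_input(self):
        df, _ = clean_occurrences(occ([]))
        assert len(df) == 0

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            clean_occurrences(pd.DataFrame({"species": []}))


class TestFamilyDR:
    def test_monotypic_family_has_zero_rate(self):
        assert family_dr(1, 100.0, "stem", eps=0.0) == 0.0

    def test_stem_pure_birth_value(self):
        assert family_dr(8, 20.0, "stem", eps=0.0) == pytest.approx(math.log(8) / 20, rel=1e-12)

    def test_crown_pure_birth_reduces_to_log_n_over_two(self):
        assert family_dr(8, 20.0, "crown", eps=0.0) == pytest.approx(
            (math.log(8) - math.log(2)) / 20, rel=1e-9
        )

    def test_extinction_correction_lowers_the_rate(self):
        assert family_dr(100, 50.0, "stem", eps=0.9) < family_dr(100, 50.0, "stem", eps=0.0)

    def test_nondecreasing_in_richness(self):
        rates = [family_dr(n, 30.0, "stem") for n in range(1, 200)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    @pytest.mark.parametrize("kwargs", [dict(n=5, t=0.0), dict(n=0, t=10.0), dict(n=5, t=10.0, eps=1.0)])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            family_dr(kwargs.get("n"), kwargs.get("t"), "stem", eps=kwargs.get("eps", 0.0))

    def test_crown_needs_two_species(self):
        with pytest.raises(ValueError):
            family_dr(1, 10.0, "crown")


class TestGrid:
    def test_single_record_cell(self):
        df = occ([GOOD])
        grid = grid_mean_dr(df, {"Fagaceae": 0.1})
        assert len(grid) == 1
        row = grid.iloc[0]
        assert (row["cell_lon_index"], row["cell_lat_index"]) == (10, 45)
        assert row["mean_dr"] == 0.1

    def test_cell_mean_over_two_families(self):
        rows = [
            ["Aa bb", "F1", 10.2, 45.2, "LITERATURE"],
            ["Cc dd", "F2", 10.8, 45.8, "LITERATURE"],
        ]
        grid = grid_mean_dr(occ(rows), {"F1": 0.0, "F2": 0.2})
        assert grid.iloc[0]["mean_dr"] == pytest.approx(0.1)
        assert grid.iloc[0]["n_records"] == 2

    def test_half_open_cell_edges(self):
        rows = [["Aa bb", "F", 10.0, 0.5, "LITERATURE"]]
        grid = grid_mean_dr(occ(rows), {"F": 0.1})
        assert grid.iloc[0]["cell_lon_index"] == 10

    def test_antimeridian_and_pole_fold_into_last_cell(self):
        rows = [["Aa bb", "F", 180.0, 90.0, "LITERATURE"]]
        grid = grid_mean_dr(occ(rows), {"F": 0.1})
        assert (grid.iloc[0]["cell_lon_index"], grid.iloc[0]["cell_lat_index"]) == (179, 89)

    def test_record_total_preserved(self):
        rng = np.random.default_rng(0)
        rows = [
            [f"Aa b{i}", "F", float(rng.uniform(-180, 180)), float(rng.uniform(-90, 90)), "LITERATURE"]
            for i in range(200)
        ]
        grid = grid_mean_dr(occ(rows), {"F": 0.1})
        assert grid["n_records"].sum() == 200

    def test_uniform_family_rate_in_every_cell(self):
        rows = [[f"Aa b{i}", "F", float(i), 0.5, "LITERATURE"] for i in range(10)]
        grid = grid_mean_dr(occ(rows), {"F": 0.07})
        assert np.allclose(grid["mean_dr"], 0.07)

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            grid_mean_dr(occ([GOOD]), {"Other": 0.1})


def geo_df(points, realm=None, biome=None):
    df = pd.DataFrame(points, columns=["decimalLongitude", "decimalLatitude"])
    df["realm"] = realm if realm is not None else "realm_1"
    df["biome"] = biome if biome is not None else "biome_1"
    return df


class TestRealmBiomeSummary:
    def test_single_realm_percentages(self):
        s = realm_biome_summary("F", geo_df([(0, 0), (1, 1), (2, 2)]))
        assert s.n_realms == 1
        assert s.realm_percentages["realm_1"] == 100.0
        assert s.range_class == "highly_localized"

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(1)
        pts = [(float(lon), 0.0) for lon in rng.uniform(-170, 170, 50)]
        realms = [f"realm_{i % 8 + 1}" for i in range(50)]
        s = realm_biome_summary("F", geo_df(pts, realm=realms))
        assert sum(s.realm_percentages.values()) == pytest.approx(100.0, abs=0.1)
        assert s.n_realms == 8
        assert s.range_class == "cosmopolitan"

    def test_single_realm_wide_spread_is_localized(self):
        pts = [(0, 0), (20, 15), (35, 5)]
        s = realm_biome_summary("F", geo_df(pts))
        assert s.range_class == "localized"

    def test_two_realms_is_widespread(self):
        pts = [(0, 0), (100, 0)]
        s = realm_biome_summary("F", geo_df(pts, realm=["realm_1", "realm_5"]))
        assert s.range_class == "widespread"

    def test_antipodal_clusters_are_disjunct(self):
        pts = [(0, 0), (0.5, 0.5), (179, 0), (179.5, 0.5)]
        s = realm_biome_summary("F", geo_df(pts, realm=["realm_1"] * 2 + ["realm_8"] * 2))
        assert s.pattern_class == "disjunct"

    def test_tight_cluster_is_continuous(self):
        pts = [(10 + 0.1 * i, 45) for i in range(5)]
        s = realm_biome_summary("F", geo_df(pts))
        assert s.pattern_class == "continuous"

    def test_unlabeled_records_warn_and_are_excluded(self):
        df = geo_df([(0, 0), (1, 1)])
        df.loc[1, "realm"] = ""
        with pytest.warns(UserWarning, match="lack realm/biome"):
            s = realm_biome_summary("F", df)
        assert s.realm_percentages["realm_1"] == 100.0
        assert s.n_unassigned == 1

    def test_haversine_known_distance(self):
        # one degree of longitude at the equator is ~111.19 km
        assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(111.19, abs=0.1)
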