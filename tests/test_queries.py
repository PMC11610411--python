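"""Query, filter and CSV-export semantics over checklists."""

import random

import pytest

from floramine.model import ACCEPTED, Distribution, GenusSummary, NameRecord, SpeciesRecord
from floramine.queries import (
    Checklist,
    QueryFilter,
    SPECIES_COLUMNS,
    UnknownCountryError,
    UnknownTaxonError,
    export_csv,
    family_species_count,
    genus_list,
    genus_rows,
    megadiverse_genera,
    read_csv_rows,
    species_distribution,
    species_list,
    species_rows,
    top_genera,
)
from floramine.synthetic import SyntheticFloraSpec, generate_flora


def counts_checklist(counts: dict, mapping, family="Testaceae") -> Checklist:
    """A checklist with a prescribed accepted-species count per genus."""
    species = [
        SpeciesRecord(
            NameRecord(genus, f"sp{i}", "L.", "T. 1: 1 (1800)", 1800, ACCEPTED,
                       f"{genus}-{i}", ""),
            (),
            Distribution(frozenset({"Peru"})),
            family=family,
        )
        for genus, n in counts.items()
        for i in range(n)
    ]
    return Checklist(species, mapping)


class TestFamilySpeciesCount:
    def test_demo_family_counts_accepted_only(self, demo_checklist):
        assert family_species_count(demo_checklist, "Demoaceae") == 4

    def test_unknown_family_is_a_named_lookup_error(self, demo_checklist):
        with pytest.raises(UnknownTaxonError, match="Nullaceae"):
            family_species_count(demo_checklist, "Nullaceae")

    def test_family_known_only_from_extras_counts_zero(self, flora, mapping):
        cl = Checklist(flora.species, mapping, family_names=["Synonymaceae"])
        assert family_species_count(cl, "Synonymaceae") == 0

    def test_matches_brute_force_on_random_flora(self, mapping):
        flora = generate_flora(SyntheticFloraSpec(seed=3))
        cl = Checklist(flora.species, mapping)
        for fam in flora.family_names:
            brute = len({s.binomial for s in flora.species if s.family == fam})
            assert family_species_count(cl, fam) == brute

    def test_equals_species_list_length_with_same_filter(self, mapping):
        flora = generate_flora(SyntheticFloraSpec(seed=5))
        cl = Checklist(flora.species, mapping)
        for fam in flora.family_names:
            rows = species_list(cl, QueryFilter(families=(fam,)))
            assert family_species_count(cl, fam) == len(rows)


class TestGenusList:
    def test_demo_counts(self, demo_checklist):
        rows = genus_list(demo_checklist)
        assert [(g.genus, g.species_count) for g in rows] == [("Alpha", 3), ("Beta", 1)]
        assert rows[0].authorship == "L."  # metadata from the genus index

    def test_country_constraint_restricts_counts(self, demo_checklist):
        rows = genus_list(demo_checklist, QueryFilter(countries=("Peru",)))
        assert [(g.genus, g.species_count) for g in rows] == [("Alpha", 1), ("Beta", 1)]

    def test_country_absent_from_flora_gives_empty_list(self, demo_checklist):
        assert genus_list(demo_checklist, QueryFilter(countries=("Finland",))) == []

    def test_unresolvable_country_is_named_error(self, demo_checklist):
        with pytest.raises(UnknownCountryError, match="Atlantis"):
            genus_list(demo_checklist, QueryFilter(countries=("Atlantis",)))


class TestSpeciesList:
    def test_genus_filter(self, demo_checklist):
        rows = species_list(demo_checklist, QueryFilter(genera=("Alpha",)))
        assert [r.binomial for r in rows] == ["Alpha unus", "Alpha duo", "Alpha tres"]

    def test_country_filter_goes_through_conversion(self, demo_checklist):
        rows = species_list(demo_checklist, QueryFilter(countries=("Brunei",)))
        assert [r.binomial for r in rows] == ["Alpha unus", "Beta quattuor"]

    def test_introduced_occurrence_needs_flag(self, demo_checklist):
        assert species_list(demo_checklist, QueryFilter(countries=("Madagascar",))) == []
        rows = species_list(
            demo_checklist,
            QueryFilter(countries=("Madagascar",), include_introduced=True),
        )
        assert [r.binomial for r in rows] == ["Beta quattuor"]

    def test_unknown_distribution_species_included_and_flagged(self, demo_checklist):
        rows = species_list(demo_checklist)
        tres = next(r for r in rows if r.binomial == "Alpha tres")
        assert tres.countries.is_unknown

    def test_constrained_list_equals_brute_force_filter(self, mapping):
        flora = generate_flora(SyntheticFloraSpec(seed=9))
        cl = Checklist(flora.species, mapping)
        rng = random.Random(0)
        countries = rng.sample(sorted(mapping.political_countries), 4)
        got = {r.binomial for r in species_list(cl, QueryFilter(countries=tuple(countries)))}
        brute = set()
        for sp in flora.species:
            natives = set()
            for region in sp.distribution.native_botanical:
                natives |= mapping.countries_for(region) or set()
            if natives & set(countries):
                brute.add(sp.binomial)
        assert got == brute


class TestSpeciesDistribution:
    def test_single_binomial(self, demo_checklist):
        found, misses = species_distribution(demo_checklist, ["Alpha duo"])
        assert len(found) == 1 and misses == []
        assert found[0].countries.native_countries == {"Peru"}

    def test_missing_binomials_reported_not_dropped(self, demo_checklist):
        found, misses = species_distribution(
            demo_checklist, ["Alpha duo", "Nonexistens absum"]
        )
        assert [f.binomial for f in found] == ["Alpha duo"]
        assert misses == ["Nonexistens absum"]

    def test_equals_filtered_species_list(self, demo_checklist):
        wanted = ("Alpha unus", "Beta quattuor")
        found, _ = species_distribution(demo_checklist, wanted)
        via_filter = species_list(demo_checklist, QueryFilter(species=wanted))
        assert found == via_filter


class TestMegadiverseAndTop:
    def test_default_threshold_is_strictly_more_than_500(self, mapping):
        cl = counts_checklist({"Big": 501, "Edge": 500, "Small": 12}, mapping)
        assert [g.genus for g in megadiverse_genera(cl)] == ["Big"]

    def test_threshold_zero_keeps_every_nonempty_genus(self, demo_checklist):
        rows = megadiverse_genera(demo_checklist, threshold=0)
        assert [g.genus for g in rows] == ["Alpha", "Beta"]

    def test_negative_threshold_rejected(self, demo_checklist):
        with pytest.raises(ValueError):
            megadiverse_genera(demo_checklist, threshold=-1)

    def test_threshold_monotonicity(self, mapping):
        cl = counts_checklist({"A": 9, "B": 7, "C": 7, "D": 3, "E": 1}, mapping)
        for t in range(0, 10):
            upper = {g.genus for g in megadiverse_genera(cl, threshold=t)}
            lower = {g.genus for g in megadiverse_genera(cl, threshold=t + 1)}
            assert lower <= upper

    def test_top_includes_all_ties_with_nth_count(self, mapping):
        cl = counts_checklist({"A": 5, "B": 3, "C": 3, "D": 1}, mapping)
        assert [g.genus for g in top_genera(cl, n=2)] == ["A", "B", "C"]

    def test_top_n_larger_than_genus_count_returns_all(self, demo_checklist):
        assert len(top_genera(demo_checklist, n=10)) == 2

    def test_demo_top_one_is_alpha(self, demo_checklist):
        assert [g.genus for g in top_genera(demo_checklist, n=1)] == ["Alpha"]

    def test_top_n_monotone_containment(self, mapping):
        cl = counts_checklist({"A": 8, "B": 6, "C": 6, "D": 4, "E": 2, "F": 1}, mapping)
        for n in range(1, 6):
            smaller = {g.genus for g in top_genera(cl, n=n)}
            larger = {g.genus for g in top_genera(cl, n=n + 1)}
            assert smaller <= larger

    def test_invalid_n_rejected(self, demo_checklist):
        with pytest.raises(ValueError):
            top_genera(demo_checklist, n=0)


class TestExportCsv:
    def test_species_export_schema_and_rows(self, demo_checklist, tmp_path):
        rows = species_rows(species_list(demo_checklist))
        path = export_csv(rows, tmp_path / "out", "species")
        lines = path.read_text().splitlines()
        assert lines[0] == ",".join(SPECIES_COLUMNS)
        assert len(lines) == 5
        assert path.parent.is_dir()

    def test_unknown_distribution_prints_unknown(self, demo_checklist, tmp_path):
        rows = species_rows(species_list(demo_checklist))
        tres = next(r for r in rows if r["species"] == "tres")
        assert tres["native_botanical"] == "unknown"
        assert tres["native_countries"] == "unknown"

    def test_multivalue_cells_are_pipe_joined(self, demo_checklist):
        rows = species_rows(species_list(demo_checklist))
        quattuor = next(r for r in rows if r["species"] == "quattuor")
        assert quattuor["native_botanical"] == "Borneo|Peru"

    def test_empty_result_writes_header_only(self, tmp_path):
        path = export_csv([], tmp_path, "empty")
        assert path.read_text() == ",".join(SPECIES_COLUMNS) + "\n"

    def test_write_read_write_is_byte_identical(self, demo_checklist, tmp_path):
        rows = species_rows(species_list(demo_checklist))
        first = export_csv(rows, tmp_path, "a")
        second = export_csv(read_csv_rows(first), tmp_path, "b")
        assert first.read_bytes() == second.read_bytes()

    def test_genus_rows_export(self, demo_checklist, tmp_path):
        path = export_csv(genus_rows(genus_list(demo_checklist)), tmp_path, "genera")
        rows = read_csv_rows(path)
        assert [(r["genus"], r["species_count"]) for r in rows] == [("Alpha", "3"), ("Beta", "1")]
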