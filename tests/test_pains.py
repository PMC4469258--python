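"""PAINS catalogue loading, screening, and cross-engine concordance."""

import pytest
from rdkit import Chem
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from molscreen import (
    concordance_report,
    default_catalogue,
    load_catalogue,
    match_compound,
    screen_set,
)
from molscreen.fixtures import expected_flagged_ids, make_fixture_set
from molscreen.pains import FilterCatalogue, ScreenSummary, SmartsFilter, mcs_similarity_flag


def reference_engine():
    """Independently maintained matcher over the same merged filter set."""
    params = FilterCatalogParams()
    params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
    return FilterCatalog(params)


class TestCatalogue:
    def test_packaged_catalogue_has_480_compiled_filters(self, catalogue):
        assert len(catalogue) == 480

    def test_three_source_families(self, catalogue):
        assert catalogue.families() == {"A", "B", "C"}
        by_family = {f: sum(1 for x in catalogue.filters if x.family == f)
                     for f in "ABC"}
        assert sum(by_family.values()) == 480

    def test_filter_ids_unique(self, catalogue):
        ids = [f.filter_id for f in catalogue.filters]
        assert len(set(ids)) == len(ids)

    def test_lenient_load_drops_bad_line(self, tmp_path, caplog):
        p = tmp_path / "cat.smt"
        p.write_text("[OH]c1ccccc1[OH] cat_ok A\n((((bad broken A\n")
        with caplog.at_level("WARNING"):
            cat = load_catalogue(p, strict=False)
        assert len(cat) == 1
        assert any("dropped 1" in r.message for r in caplog.records)

    def test_strict_load_names_offending_line(self, tmp_path):
        p = tmp_path / "cat.smt"
        p.write_text("[OH]c1ccccc1[OH] cat_ok A\n((((bad broken A\n")
        with pytest.raises(ValueError, match=r"\[2\]"):
            load_catalogue(p, strict=True)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "cat.smt"
        p.write_text("# nothing here\n")
        with pytest.raises(ValueError, match="no filters"):
            load_catalogue(p)


class TestMatchCompound:
    def test_ethanol_clean(self, catalogue):
        assert match_compound(Chem.MolFromSmiles("CCO"), catalogue) == []

    def test_benzoquinone_hits_quinone_family(self, catalogue, molecules):
        hits = match_compound(molecules["benzoquinone"].mol, catalogue,
                              compound_id="bq")
        assert hits
        assert any(h.filter_id.startswith("quinone") for h in hits)
        mol = molecules["benzoquinone"].mol
        for h in hits:
            assert all(0 <= i < mol.GetNumAtoms() for i in h.matched_atoms)

    def test_empty_catalogue_no_hits(self, molecules):
        cat = FilterCatalogue(filters=[SmartsFilter("f1", "[Se]", "A")])
        assert match_compound(molecules["benzoquinone"].mol, cat) == []

    def test_deterministic(self, catalogue, molecules):
        mol = molecules["benzoquinone"].mol
        assert match_compound(mol, catalogue) == match_compound(mol, catalogue)


class TestScreenSet:
    def test_mixed_bench_flags_exactly_the_exemplars(self, catalogue, bench_set):
        summary = screen_set(bench_set, catalogue)
        assert sorted(summary.flagged_ids) == sorted(expected_flagged_ids(bench_set))
        assert summary.n_flagged == len(summary.flagged_ids)
        assert summary.n_compounds == len(bench_set)

    def test_agrees_with_reference_engine_pattern_for_pattern(self, catalogue,
                                                              bench_set):
        ref = reference_engine()
        for rec in bench_set:
            ours = {h.filter_id for h in match_compound(rec.mol, catalogue)}
            theirs = {e.GetDescription() for e in ref.GetMatches(rec.mol)}
            assert ours == theirs, rec.name

    def test_screening_twice_identical(self, catalogue, bench_set):
        a = screen_set(bench_set, catalogue)
        b = screen_set(bench_set, catalogue)
        assert a.flagged_ids == b.flagged_ids
        assert a.hits_per_filter == b.hits_per_filter

    def test_empty_set_all_zero(self, catalogue):
        from molscreen.model import CompoundSet
        s = screen_set(CompoundSet(set_number=1), catalogue)
        assert (s.n_compounds, s.n_flagged, s.flagged_ids) == (0, 0, [])

    def test_flagging_monotone_in_catalogue(self, catalogue, bench_set):
        subset = FilterCatalogue(filters=catalogue.filters[:100])
        small = set(screen_set(bench_set, subset).flagged_ids)
        full = set(screen_set(bench_set, catalogue).flagged_ids)
        assert small <= full

    def test_adding_compound_changes_counts_by_at_most_one(self, catalogue):
        base = make_fixture_set("mixed_bench", 10, rng_seed=3)
        bigger = make_fixture_set("mixed_bench", 11, rng_seed=3)
        a, b = screen_set(base, catalogue), screen_set(bigger, catalogue)
        assert b.n_compounds == a.n_compounds + 1
        assert b.n_flagged - a.n_flagged in (0, 1)


class TestConcordance:
    def summary(self, ids, n=10):
        return ScreenSummary(n_compounds=n, n_flagged=len(ids),
                             hits_per_filter={}, flagged_ids=list(ids))

    def test_identical_summaries(self):
        s = self.summary(["a", "b", "c"])
        assert concordance_report(s, s) == (3, 0, 0)

    def test_disjoint_flagged_sets(self):
        a, b = self.summary(["a", "b"]), self.summary(["c", "d", "e"])
        assert concordance_report(a, b) == (0, 2, 3)

    def test_partial_overlap(self):
        a, b = self.summary(["x", "y", "z"]), self.summary(["y", "z", "w"])
        assert concordance_report(a, b) == (2, 1, 1)

    def test_set_algebra_identities(self):
        a, b = self.summary(["x", "y", "z"]), self.summary(["y", "q"])
        matching, only_a, only_b = concordance_report(a, b)
        assert matching + only_a == a.n_flagged
        assert matching + only_b == b.n_flagged

    def test_different_universes_rejected(self):
        a, b = self.summary(["x"]), self.summary(["x"])
        with pytest.raises(ValueError, match="universe"):
            concordance_report(a, b, universe_a={"x", "y"}, universe_b={"x"})


class TestMcsCriterion:
    def test_self_similarity_flags(self, molecules):
        mol = molecules["benzoquinone"].mol
        assert mcs_similarity_flag(mol, mol, threshold=1.0) is True

    def test_different_graphs_below_one(self, molecules):
        assert mcs_similarity_flag(molecules["benzene"].mol,
                                   molecules["cyclohexane"].mol,
                                   threshold=1.0) is False

    def test_benzene_toluene_above_0p8(self, molecules):
        assert mcs_similarity_flag(molecules["benzene"].mol,
                                   molecules["toluene"].mol,
                                   threshold=0.8) is True

    def test_timeout_is_undetermined_not_false(self, molecules):
        out = mcs_similarity_flag(molecules["aspirin"].mol,
                                  molecules["toluene"].mol,
                                  threshold=0.9, timeout=1e-9)
        assert out is None
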