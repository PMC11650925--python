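"""Database search, outlier flagging and conservative reconciliation."""

import pytest

from coipipe.datasets import conflict_cases, curated_overrides, outlier_reference_case
from coipipe.simdata import mutate_fixed_distance
from coipipe.taxassign import (
    AssignParams,
    Hit,
    RefDB,
    RefRecord,
    assign_all,
    flag_outlier_reference,
    load_overrides,
    lowest_common_rank,
    reconcile,
    search,
)

BASE = mutate_fixed_distance("ACGT" * 163, 0, seed=0)


def _lin(genus, species, family="Gobiidae", order="Gobiiformes"):
    return {"kingdom": "Animalia", "phylum": "Chordata", "class": "Actinopterygii",
            "order": order, "family": family, "genus": genus, "species": species}


def _hit(acc, ident, genus, species, **kw):
    return Hit(acc, ident, _lin(genus, species, **kw))


@pytest.fixture()
def small_db():
    return RefDB("nt", [
        RefRecord("A1", BASE, _lin("Genus1", "Genus1 alpha")),
        RefRecord("A2", mutate_fixed_distance(BASE, 25, seed=1),
                  _lin("Genus1", "Genus1 beta")),
        RefRecord("A3", mutate_fixed_distance(BASE, 200, seed=2),
                  _lin("Genus2", "Genus2 gamma")),
    ])


class TestSearch:
    def test_exact_match_is_top_hit(self, small_db):
        hits = search(BASE, small_db)
        assert hits[0].accession == "A1" and hits[0].percent_identity == 100.0

    def test_25_substitutions_below_identifiable(self, small_db):
        db = RefDB("nt", [small_db.records[1]])
        hits = search(BASE, db)
        assert hits[0].percent_identity == 96.2
        assert hits[0].percent_identity < AssignParams().identifiable_threshold

    def test_floor_excludes_distant_records(self, small_db):
        hits = search(BASE, small_db)
        assert "A3" not in [h.accession for h in hits]  # ~69% identity
        assert search(BASE, RefDB("nt", [small_db.records[2]])) == []

    def test_sorted_by_identity_then_accession(self, small_db):
        db = RefDB("nt", small_db.records + [RefRecord("A0", BASE, _lin("G", "G x"))])
        hits = search(BASE, db)
        assert [h.accession for h in hits[:2]] == ["A0", "A1"]


class TestOutlierFlagging:
    def test_single_wrong_hit_outvoted(self):
        """The recorded real-world pattern: one >=98% hit to a species
        implausible for the region, against three concordant accessions."""
        case = outlier_reference_case()
        res = flag_outlier_reference(case.hits)
        assert res.consensus_species == case.expected_species
        assert res.flagged_accessions == case.expected_flagged

    def test_unanimous_hits_unflagged(self):
        hits = [_hit("X1", 99.5, "G", "G a"), _hit("X2", 99.0, "G", "G a")]
        res = flag_outlier_reference(hits)
        assert res.consensus_species == "G a" and not res.flagged_accessions

    def test_one_vs_one_keeps_top_marked_ambiguous(self):
        hits = [_hit("X1", 99.5, "G", "G a"), _hit("X2", 99.0, "G", "G b")]
        res = flag_outlier_reference(hits)
        assert res.consensus_species == "G a"
        assert not res.flagged_accessions
        assert res.note == "ambiguous_majority"

    def test_requires_an_identifiable_hit(self):
        with pytest.raises(ValueError):
            flag_outlier_reference([_hit("X1", 97.0, "G", "G a")])


class TestLowestCommonRank:
    def test_congeners_collapse_to_genus(self):
        assert lowest_common_rank(
            _lin("Ambassis", "Ambassis nalua", family="Ambassidae"),
            _lin("Ambassis", "Ambassis kopsii", family="Ambassidae"),
        ) == ("Ambassis sp.", "genus")

    def test_confamilials_collapse_to_family(self):
        assert lowest_common_rank(
            _lin("Photopectoralis", "Photopectoralis bindus", family="Leiognathidae"),
            _lin("Nuchequula", "Nuchequula sp1", family="Leiognathidae"),
        ) == ("Leiognathidae sp.", "family")

    def test_identical_lineages_return_species(self):
        lin = _lin("G", "G a")
        assert lowest_common_rank(lin, lin) == ("G a", "species")

    def test_disjoint_lineages_fall_back(self):
        a = {"kingdom": "Animalia", "species": "X y"}
        b = {"kingdom": "Plantae", "species": "Z w"}
        assert lowest_common_rank(a, b) == ("Animalia sp.", None)

    def test_empty_lineage_rejected(self):
        with pytest.raises(ValueError):
            lowest_common_rank({}, _lin("G", "G a"))


class TestReconcile:
    def test_decision_table_totality(self):
        """Every (>=98 present/absent) x (same/nested/disjoint) combination
        has a defined outcome."""
        sp_a = _hit("N1", 99.0, "G", "G a")
        sp_b = _hit("L1", 99.0, "G", "G b")
        sp_gen = _hit("L2", 99.0, "G", "G sp.")
        weak = _hit("N2", 90.0, "G", "G c")

        # neither database identifiable
        idn = reconcile([weak], [weak])
        assert idn.provenance == "unidentified" and idn.final_name is None
        # exactly one
        assert reconcile([sp_a], [weak]).provenance == "nt"
        assert reconcile([weak], [sp_b]).provenance == "local"
        # both, same species
        same = reconcile([sp_a], [_hit("L3", 99.8, "G", "G a")])
        assert (same.final_name, same.provenance) == ("G a", "nt")
        # both, nested ("G sp." vs "G a")
        nested = reconcile([_hit("N3", 99.0, "G", "G sp.")], [sp_a.__class__(
            "L4", 99.0, sp_a.lineage)])
        assert (nested.final_name, nested.provenance) == ("G a", "local")
        nested2 = reconcile([sp_a], [sp_gen])
        assert (nested2.final_name, nested2.provenance) == ("G a", "nt")
        # both, disjoint species -> conservative genus
        disjoint = reconcile([sp_a], [sp_b])
        assert (disjoint.final_name, disjoint.final_rank) == ("G sp.", "genus")
        assert disjoint.provenance == "conservative"

    def test_conservatism_never_more_specific_than_inputs(self):
        """Disjoint species-level inputs never reconcile to species rank
        without an override."""
        for case in conflict_cases():
            idn = reconcile(case.hits_nt, case.hits_local, overrides=None,
                            motu=case.motu)
            if idn.provenance == "conservative":
                assert idn.final_rank != "species"

    def test_override_applied(self):
        idn = reconcile(
            [_hit("N1", 100.0, "Apogon", "Apogon sp.", family="Apogonidae")],
            [_hit("L1", 100.0, "Ostorhinchus", "Ostorhinchus cavitensis",
                  family="Apogonidae")],
            curated_overrides())
        assert (idn.final_name, idn.provenance) == ("Ostorhinchus cavitensis", "revised")

    @pytest.mark.parametrize("case", conflict_cases(), ids=lambda c: c.motu)
    def test_recorded_conflicts_reproduce_accepted_finals(self, case):
        """All 18 recorded dual-database conflicts resolve to the accepted
        final identifications under the decision table + overrides."""
        idn = reconcile(case.hits_nt, case.hits_local, curated_overrides(),
                        motu=case.motu)
        assert idn.final_name == case.expected_final
        assert idn.final_rank == case.expected_rank
        assert idn.provenance == case.expected_provenance


class TestOverridesFile:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "ov.tsv"
        p.write_text("name_a\tname_b\tfinal_name\tfinal_rank\n"
                     "A x\tB y\tB y\tspecies\n")
        ov = load_overrides(p)
        assert ov[frozenset(("A x", "B y"))] == ("B y", "species")

    def test_malformed_row_reports_number(self, tmp_path):
        p = tmp_path / "ov.tsv"
        p.write_text("name_a\tname_b\tfinal_name\tfinal_rank\n"
                     "A x\tB y\tB y\tnotarank\n")
        with pytest.raises(ValueError, match="row 1"):
            load_overrides(p)


class TestAssignAll:
    def test_full_coverage_all_correct(self, clean_run):
        """With complete databases and no mislabels, every true barcode is
        identified to its own species."""
        from coipipe.motu import DistanceMatrix, objective_cluster

        seqs = {row.specimen: row.true_barcode
                for row in clean_run.specimen_truth.itertuples()}
        from coipipe.consensus import Barcode
        barcodes = [Barcode(sid, "pair1", seq, 100, 25, "compliant")
                    for sid, seq in seqs.items()]
        partition = objective_cluster(DistanceMatrix.from_sequences(seqs), 0.02)
        table, summary = assign_all(partition, barcodes, clean_run.db_nt,
                                    clean_run.db_local,
                                    n_specimens=len(barcodes))
        assert summary["identification_success"] == 100.0
        truth = clean_run.specimen_truth.set_index("specimen")["true_species"]
        merged = table.set_index("barcode_id")["final_name"]
        assert (merged == truth.loc[merged.index]).all()
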