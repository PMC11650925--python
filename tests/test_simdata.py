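"""Ground-truth generator: divergence structure, determinism, error model."""

from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest

from coipipe.motu import DistanceMatrix, objective_cluster, p_distance
from coipipe.seqs import revcomp, translatable_frames
from coipipe.simdata import (
    PRIMER_PAIRS,
    SimulationConfig,
    generate_community,
    generate_reference_dbs,
    generate_tag_scheme,
    mutate_fixed_distance,
    simulate_dataset,
    simulate_reads,
)


class TestCommunity:
    def test_species_count_and_divergence_separation(self, tiny_config):
        species = generate_community(tiny_config)
        assert len(species) == 8
        inter = [p_distance(a.true_barcode, b.true_barcode)
                 for a, b in combinations(species, 2)]
        assert min(inter) >= tiny_config.min_interspecific_p
        for sp in species:
            for hap in sp.haplotypes:
                assert p_distance(sp.true_barcode, hap) <= tiny_config.max_intraspecific_p
        # interspecific spread sits strictly above intraspecific spread
        intra = [p_distance(sp.true_barcode, h) for sp in species for h in sp.haplotypes]
        assert min(inter) > max(intra)

    def test_barcodes_translate_without_stops(self, tiny_config):
        for sp in generate_community(tiny_config):
            for hap in sp.haplotypes:
                assert 0 in translatable_frames(hap)
                assert set(hap) <= set("ACGT")

    def test_deterministic_for_fixed_seed(self, tiny_config):
        a = generate_community(tiny_config)
        b = generate_community(tiny_config)
        assert [sp.haplotypes for sp in a] == [sp.haplotypes for sp in b]
        assert [sp.site_abundances for sp in a] == [sp.site_abundances for sp in b]

    def test_clustering_true_barcodes_recovers_species(self, tiny_config):
        """At t = 2% with >= 2% interspecific divergence, the true-barcode
        partition is exactly one mOTU per species."""
        cfg = replace(tiny_config, min_interspecific_p=0.02)
        species = generate_community(cfg)
        matrix = DistanceMatrix.from_sequences(
            {sp.species_id: sp.true_barcode for sp in species})
        partition = objective_cluster(matrix, 0.02)
        assert len(partition.clusters) == len(species)

    def test_unsatisfiable_divergence_raises(self):
        cfg = SimulationConfig(seed=1, n_families=1, n_genera_per_family=1,
                               n_species_per_genus=50, barcode_length=12,
                               min_interspecific_p=0.9, max_intraspecific_p=0.01)
        with pytest.raises(RuntimeError, match="divergence"):
            generate_community(cfg)

    def test_invalid_config_rejected(self):
        cfg = SimulationConfig(min_interspecific_p=0.01, max_intraspecific_p=0.04)
        with pytest.raises(ValueError, match="min_interspecific_p"):
            generate_community(cfg)


class TestMutateFixedDistance:
    @pytest.mark.parametrize("n_subs", [0, 1, 18, 76, 652])
    def test_exact_hamming_distance(self, n_subs):
        seq = mutate_fixed_distance("ACGT" * 163, 0, seed=0)  # any 652-mer
        out = mutate_fixed_distance(seq, n_subs, seed=7)
        assert len(out) == len(seq)
        assert sum(a != b for a, b in zip(seq, out)) == n_subs

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            mutate_fixed_distance("ACGT", 5, seed=0)


class TestSimulateReads:
    def test_zero_error_reads_contain_exact_haplotype(self, clean_run):
        scheme = clean_run.tag_scheme
        truth = clean_run.specimen_truth.set_index("specimen")
        manifest = clean_run.read_manifest.set_index("read_id")
        for rid, seq in clean_run.reads[:200]:
            row = manifest.loc[rid]
            if row.orientation == "-":
                seq = revcomp(seq)
            tag_f, tag_r = scheme.tags[row.specimen]
            primer_f, primer_r = scheme.primer_pairs[row.primer_pair]
            insert = seq[len(tag_f) + len(primer_f): len(seq) - len(tag_r) - len(primer_r)]
            assert insert == truth.loc[row.specimen, "true_barcode"]

    def test_substitution_rate_matches_binomial_expectation(self, tiny_config):
        cfg = replace(tiny_config, sub_rate=0.01, ins_rate=0.0, del_rate=0.0,
                      coverage_mean=50.0)
        species = generate_community(cfg)[0]
        scheme = generate_tag_scheme(["S1", "S2"], seed=1)
        reads, manifest = simulate_reads(species, 2, scheme, cfg,
                                         specimen_ids=["S1", "S2"], seed=5)
        total_mismatch = total_bases = 0
        for (rid, seq), (_, row) in zip(reads, manifest.iterrows()):
            if row.orientation == "-":
                seq = revcomp(seq)
            tag_f, tag_r = scheme.tags[row.specimen]
            primer_f, primer_r = scheme.primer_pairs[row.primer_pair]
            template = (tag_f + primer_f + species.haplotypes[row.haplotype]
                        + revcomp(tag_r + primer_r))
            assert len(seq) == len(template)  # no indels configured
            total_mismatch += sum(a != b for a, b in zip(seq, template))
            total_bases += len(seq)
        rate = total_mismatch / total_bases
        se = np.sqrt(0.01 * 0.99 / total_bases)
        assert abs(rate - 0.01) < 3 * se

    def test_coverage_median_near_mean(self, tiny_config):
        cfg = replace(tiny_config, coverage_mean=500.0, sub_rate=0, ins_rate=0,
                      del_rate=0)
        species = generate_community(cfg)[0]
        ids = [f"S{i}" for i in range(100)]
        scheme = generate_tag_scheme(ids, seed=2)
        _reads, manifest = simulate_reads(species, 100, scheme, cfg,
                                          specimen_ids=ids, seed=9)
        per_bin = manifest.groupby(["specimen", "primer_pair"]).size()
        assert abs(np.median(per_bin) - 500) < 0.2 * 500

    def test_both_orientations_emitted(self, tiny_run):
        frac = (tiny_run.read_manifest.orientation == "-").mean()
        assert 0.4 < frac < 0.6


class TestTagScheme:
    def test_tags_unique_and_separated(self, tiny_run):
        import edlib

        tags = [t for pair in tiny_run.tag_scheme.tags.values() for t in pair]
        assert all(len(t) == 13 for t in tags)
        assert len(set(tags)) == len(tags)
        for a, b in combinations(tags[:30], 2):  # spot-check separation
            assert edlib.align(a, b, task="distance")["editDistance"] >= 3

    def test_primer_sequences_are_the_cocktail(self):
        assert PRIMER_PAIRS["pair1"][0].startswith("TCGACTAATCATAAAGATATCGGCAC")
        assert PRIMER_PAIRS["pair2"][1].startswith("CACCTCAGGGTG")


class TestReferenceDbs:
    def test_no_mislabels_when_rate_zero(self, tiny_config):
        species = generate_community(tiny_config)
        db_nt, db_local, manifest = generate_reference_dbs(species, tiny_config)
        assert not manifest.mislabeled.any()
        truth = {sp.lineage["species"] for sp in species}
        for db in (db_nt, db_local):
            assert {r.lineage["species"] for r in db.records} <= truth

    def test_db_coverage_binomial(self, tiny_config):
        cfg = replace(tiny_config, n_families=5, n_genera_per_family=4,
                      n_species_per_genus=5, db_coverage_local=0.7)
        species = generate_community(cfg)
        _nt, local, _m = generate_reference_dbs(species, cfg)
        present = {r.lineage["species"] for r in local.records}
        n, p = len(species), 0.7
        tol = 3 * np.sqrt(n * p * (1 - p))
        assert abs(len(present) - n * p) <= tol

    def test_mislabels_recorded_in_manifest(self, tiny_config):
        cfg = replace(tiny_config, mislabel_rate=0.5)
        species = generate_community(cfg)
        _nt, _local, manifest = generate_reference_dbs(species, cfg)
        wrong = manifest[manifest.mislabeled]
        assert len(wrong) > 0
        assert (wrong.true_species != wrong.label_species).all()


def test_dataset_determinism(tiny_config):
    """Identical seeds give byte-identical reads, manifests and databases."""
    a = simulate_dataset(tiny_config)
    b = simulate_dataset(tiny_config)
    assert a.reads == b.reads
    assert a.read_manifest.equals(b.read_manifest)
    assert a.sample_sheet.equals(b.sample_sheet)
    assert [(r.accession, r.sequence) for r in a.db_nt.records] == \
           [(r.accession, r.sequence) for r in b.db_nt.records]
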