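"""Demultiplexing: tag tolerance, conflicts, partitioning, orientation."""

import numpy as np
import pytest

from coipipe.demux import DemuxParams, TaggedRead, assign_read, demultiplex, length_filter
from coipipe.seqs import revcomp
from coipipe.simdata import PRIMER_PAIRS, TagScheme


@pytest.fixture(scope="module")
def toy_scheme():
    # Three specimens, tags mutually >= 3 edits apart.
    return TagScheme(tags={
        "S7": ("AAAAAAAAAAAAA", "CCCCCCCCCCCCC"),
        "S9": ("GGGGGGGGGGGGG", "TTTTTTTTTTTTT"),
        "S11": ("ACACACACACACA", "GTGTGTGTGTGTG"),
    })


def _read(tag_f, tag_r, pair="pair1", insert="ACGT" * 163):
    primer_f, primer_r = PRIMER_PAIRS[pair]
    return tag_f + primer_f + insert + revcomp(tag_r + primer_r)


class TestLengthFilter:
    def test_window_boundaries(self):
        params = DemuxParams(length_window=(600, 1000))
        reads = [("a", "A" * 750), ("b", "A" * 100), ("c", "A" * 600), ("d", "A" * 1001)]
        retained, rejected = length_filter(reads, params)
        assert [r[0] for r in retained] == ["a", "c"]
        assert [r[0] for r in rejected] == ["b", "d"]

    def test_zero_error_synthetic_fully_retained(self, clean_run):
        retained, rejected = length_filter(clean_run.reads, DemuxParams())
        assert not rejected and len(retained) == len(clean_run.reads)


class TestAssignRead:
    def test_exact_tags_assigned(self, toy_scheme):
        seq = _read(*toy_scheme.tags["S7"])
        tr = assign_read(("r1", seq), toy_scheme)
        assert (tr.assigned_sample, tr.assigned_primer_pair) == ("S7", "pair1")
        assert tr.orientation == "+"
        assert tr.insert == "ACGT" * 163

    def test_second_primer_pair_recognised(self, toy_scheme):
        tr = assign_read(("r1", _read(*toy_scheme.tags["S9"], pair="pair2")), toy_scheme)
        assert (tr.assigned_sample, tr.assigned_primer_pair) == ("S9", "pair2")

    def test_one_tag_substitution_tolerated(self, toy_scheme):
        tag_f, tag_r = toy_scheme.tags["S7"]
        seq = _read("C" + tag_f[1:], tag_r)
        tr = assign_read(("r1", seq), toy_scheme)
        assert tr.assigned_sample == "S7"

    def test_two_tag_substitutions_rejected_by_default(self, toy_scheme):
        tag_f, tag_r = toy_scheme.tags["S7"]
        seq = _read("CC" + tag_f[2:], tag_r)
        tr = assign_read(("r1", seq), toy_scheme)
        assert not tr.assigned
        tr2 = assign_read(("r1", seq), toy_scheme, DemuxParams(max_tag_mismatch=2))
        assert tr2.assigned_sample == "S7"

    def test_all_crossed_tag_pairs_conflict(self, toy_scheme):
        """Any forward/reverse tag combination from two different specimens
        is reported as a tag conflict, never assigned."""
        ids = list(toy_scheme.tags)
        for a in ids:
            for b in ids:
                seq = _read(toy_scheme.tags[a][0], toy_scheme.tags[b][1])
                tr = assign_read(("r", seq), toy_scheme)
                if a == b:
                    assert tr.assigned_sample == a
                else:
                    assert not tr.assigned and tr.reason == "tag_conflict"

    def test_orientation_invariance(self, toy_scheme):
        seq = _read(*toy_scheme.tags["S11"], pair="pair2")
        fwd = assign_read(("r", seq), toy_scheme)
        rev = assign_read(("r", revcomp(seq)), toy_scheme)
        assert fwd.assigned_sample == rev.assigned_sample == "S11"
        assert fwd.assigned_primer_pair == rev.assigned_primer_pair == "pair2"
        assert fwd.insert == rev.insert
        assert {fwd.orientation, rev.orientation} == {"+", "-"}

    def test_assigned_fields_all_or_none(self, toy_scheme):
        ok = assign_read(("r", _read(*toy_scheme.tags["S7"])), toy_scheme)
        bad = assign_read(("r", "ACGT" * 200), toy_scheme)
        assert ok.assigned_sample and ok.assigned_primer_pair and ok.orientation
        assert bad.assigned_sample is None and bad.assigned_primer_pair is None


class TestDemultiplex:
    def test_zero_error_run_matches_truth_exactly(self, clean_run):
        bins, unassigned, stats = demultiplex(
            clean_run.reads, clean_run.tag_scheme, DemuxParams())
        assert stats.success_rate == 100.0
        assert not unassigned
        truth = clean_run.read_manifest.set_index("read_id")
        for (sid, pair), tagged in bins.items():
            for tr in tagged:
                assert truth.loc[tr.read_id, "specimen"] == sid
                assert truth.loc[tr.read_id, "primer_pair"] == pair

    def test_partition_property(self, tiny_run):
        """Bins are disjoint and bins + unassigned == retained reads."""
        params = DemuxParams()
        retained, _ = length_filter(tiny_run.reads, params)
        bins, unassigned, stats = demultiplex(tiny_run.reads, tiny_run.tag_scheme, params)
        ids = [t.read_id for reads in bins.values() for t in reads]
        ids += [t.read_id for t in unassigned]
        assert len(ids) == len(set(ids)) == len(retained)
        assert stats.n_assigned + len(unassigned) == stats.n_retained

    def test_fully_corrupted_tags_never_assigned(self, clean_run):
        # Replace every tag with its complement (13 substitutions).
        reads = []
        for rid, seq in clean_run.reads[:50]:
            wrong = seq.translate(str.maketrans("ACGT", "CGTA"))[:13] + seq[13:]
            wrong = wrong[:-13] + seq[-13:].translate(str.maketrans("ACGT", "TGAC"))
            reads.append((rid, wrong))
        _bins, _un, stats = demultiplex(reads, clean_run.tag_scheme, DemuxParams())
        assert stats.n_assigned == 0

    def test_spiked_unassignable_fraction(self, clean_run):
        """Spiking 20% alien reads drops success to ~80%."""
        rng = np.random.default_rng(0)
        n = len(clean_run.reads)
        n_alien = int(round(0.25 * n))  # alien/(real+alien) = 0.2
        alien = [(f"alien{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 730)))
                 for i in range(n_alien)]
        mixed = clean_run.reads + alien
        _bins, _un, stats = demultiplex(mixed, clean_run.tag_scheme, DemuxParams())
        expected = 100.0 * n / (n + n_alien)
        assert abs(stats.success_rate - expected) < 2.0

    def test_malformed_record_reports_index(self, toy_scheme):
        reads = [("ok", _read(*toy_scheme.tags["S7"])), ("bad", ["A"] * 700)]
        with pytest.raises(RuntimeError, match="index 1"):
            demultiplex(reads, toy_scheme, DemuxParams(length_window=(0, 10**6)))


def test_previous_run_tags_screened(toy_scheme):
    prev = "TATATATATATAT"
    params = DemuxParams(previous_tags=frozenset({prev}))
    seq = _read(prev, toy_scheme.tags["S7"][1])
    tr = assign_read(("r", seq), toy_scheme, params)
    assert not tr.assigned and tr.reason == "previous_tag"
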