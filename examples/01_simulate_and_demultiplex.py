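"""Simulate a small tagged sequencing run and demultiplex it.

Builds an 8-species community across 2 sites, emits noisy dual-tagged
reads for both primer pairs, then assigns every read back to its
(specimen, primer pair) bin. The printed success rate is the fraction of
length-filtered reads carrying a recognisable tag pair at both ends;
reads whose tags were destroyed by indel errors stay unassigned.
"""

from coipipe import DemuxParams, SimulationConfig, demultiplex, simulate_dataset

config = SimulationConfig(
    seed=42, n_families=2, n_genera_per_family=2, n_species_per_genus=2,
    n_sites=2, specimens_per_site=8, coverage_mean=60.0,
)
run = simulate_dataset(config)
print(f"community: {len(run.species)} species, "
      f"{len(run.sample_sheet)} specimens, {len(run.reads)} reads")

bins, unassigned, stats = demultiplex(run.reads, run.tag_scheme, DemuxParams())
print(f"demultiplexed {stats.n_assigned}/{stats.n_retained} reads "
      f"({stats.success_rate:.1f}% success) into {len(bins)} bins")
print(f"unassigned reasons: {dict(stats.unassigned_reasons)}")

truth = run.read_manifest.set_index("read_id")
wrong = sum(1 for (sid, pair), reads in bins.items() for t in reads
            if truth.loc[t.read_id, "specimen"] != sid)
print(f"misassigned reads: {wrong} (tag pairs are >=3 edits apart, so "
      f"1-mismatch matching never crosses specimens)")
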