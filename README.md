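# coipipe

A reverse-workflow COI barcoding pipeline for specimen-rich surveys of
fish larvae: sequence every specimen first, sort the barcodes into
molecular operational taxonomic units (mOTUs), and only then decide where
morphology is needed. The package covers the full desk-side analysis of a
dual-tagged nanopore-style amplicon run:

1. **Demultiplexing** — reads carry specimen-specific 13-nt tags on both
   primers of two Folmer-cocktail pairs (FishF2/FishR2 and VF2/FR1d);
   assignment requires the same specimen's forward and reverse tag (≤1
   substitution each) plus a primer match, in either orientation.
2. **Consensus barcodes** — per (specimen, primer pair) bin, reads are
   subsampled at 25×, 50×, 100×, 200×, 500× tiers, aligned, and collapsed
   by majority rule; a barcode is *QC-compliant* when it is exactly 652 nt,
   free of ambiguous bases, and stop-free in some forward frame of the
   vertebrate mitochondrial code. Bins failing every tier get a
   consensus-by-similarity fallback (closest 100 reads realigned).
3. **Primer-pair merging** — identical barcodes from the two primer pairs
   merge; barcodes fewer than 10 bp apart with the same top database match
   are accepted; larger conflicts drop the specimen. Barcodes with more
   than 10× coverage are retained.
4. **mOTU delimitation** — objective clustering: single-linkage connected
   components of the uncorrected p-distance graph at an inclusive cut
   (default 2%), named `ClusterN`/`SingletonN`, with a stability report
   across a 2–4.5% threshold ladder.
5. **Identification** — exhaustive percent-identity search against two
   reference databases (a broad "nt" and a curated "local" one). A mOTU is
   identifiable at ≥98%; conflicting ≥98% identifications reconcile
   conservatively to the lowest common rank (`Ambassis nalua` +
   `Ambassis kopsii` → `Ambassis sp.`) unless a curated override applies;
   a lone ≥98% hit outvoted by a multi-accession majority is flagged as a
   putative misidentified reference record.
6. **Diversity** — per-site abundance of identified mOTUs, Shannon
   diversity (nats), Gini–Simpson diversity, shared-mOTU regions over all
   site subsets, hypergeometric rarefaction E[S_m] and the
   singleton/doubleton sample-coverage estimate Ĉ.

A fully seeded synthetic-data generator (`coipipe.simdata`) produces
ground-truthed communities (hierarchical taxonomy, interspecific
p-distances above and intraspecific below the clustering threshold),
imperfect overlapping reference databases, per-site geometric abundance
structure, and noisy tagged reads — so every stage can be validated
against known truth.

## Worked example

```python
from coipipe import DistanceMatrix, objective_cluster, percent_identity
from coipipe.simdata import mutate_fixed_distance

base  = mutate_fixed_distance("ACGT" * 163, 0, seed=0)   # a 652-mer
close = mutate_fixed_distance(base, 18, seed=1)          # 18 substitutions
print(percent_identity(base, close))                     # 97.2
m = DistanceMatrix.from_sequences({"u1": base, "u2": close})
print(len(objective_cluster(m, 0.02).clusters))          # 2
print(len(objective_cluster(m, 0.028).clusters))         # 1
```

Two barcodes 18 substitutions apart sit at p = 18/652 = 2.76% (97.2%
identity): distinct mOTUs at the 2% threshold, one mOTU once the cut is
raised to 2.8% — the behaviour a borderline intraspecific split shows on
a threshold ladder.

Running the whole pipeline on a seeded synthetic run
(`python examples/05_full_pipeline_and_diversity.py`) prints:

```
specimens: 30   raw reads: 3545
demux success: 89.3%
barcoding success: 100.0%   identification success: 100.0%
mOTUs at 2%: 12
specimen accounting exact: True

per-site diversity (H in nats, D = Gini-Simpson, Chat = sample coverage):
 site  richness  n_individuals  shannon_H  simpson_D  coverage_Chat
Site1         8             10   2.025326       0.86       0.441379
```

i.e. all 30 specimens yielded QC-compliant barcodes recovering their true
haplotypes, the 2% partition found the 12 observed species, and Site1's
10 identified specimens spread over 8 mOTUs (H = 2.03 nats; a sample
coverage of 0.44 says fewer than half of the community's individuals
belong to mOTUs already seen — keep sampling).

The same stages are available as a thin CLI:

```bash
coipipe simulate --seed 1 --outdir run/
coipipe demux --reads run/reads.fastq --sample-sheet run/sample_sheet.tsv --outdir run/
coipipe run-all --seed 1 --outdir run/
```

See `examples/` for one short narrative script per capability.

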