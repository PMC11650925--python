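# Methods

## The model

The package implements a *reverse workflow* for COI barcoding: every
specimen of a bulk larval-fish sample is sequenced first, consensus
barcodes are delimited into mOTUs purely by sequence distance, and
taxonomic names are attached afterwards by reference-database matching.
The unit of analysis is the 652-nt 5' Folmer fragment of mitochondrial
COI; species proxies are single-linkage clusters of uncorrected
p-distance at a 2% cut.

## Synthetic data generator

`simdata` emulates the statistical structure the pipeline assumes, not a
sequencing instrument:

- **Community.** `n_families × n_genera_per_family × n_species_per_genus`
  species with a 7-rank lineage. Barcodes are derived family → genus →
  species by seeded substitution and accepted only if every interspecific
  p-distance is ≥ `min_interspecific_p` (default 4%); haplotypes sit
  within `max_intraspecific_p` (default 1%) of the species barcode. All
  barcodes are built from sense codons of the vertebrate mitochondrial
  code in frame 0, so generated truth always passes the translation QC
  (which itself scans all three forward frames, because a consensus's
  frame is not known a priori). The 652-nt default is not a codon
  multiple; translation reads ⌊L/3⌋ codons and ignores the trailing base.
- **Abundance.** Per site, a geometric rank-abundance series (ratio 0.9)
  over an independently shuffled species ranking, sampled multinomially
  to `specimens_per_site` (default 40 over 4 sites → 160 specimens).
  Some rare species draw zero specimens; scoring is always against the
  *observed* species set.
- **Reads.** Each read is `tagF + primerF + haplotype +
  revcomp(tagR + primerR)` with i.i.d. per-base errors over the whole
  read (default 1.6% substitution, 0.2% insertion, 0.2% deletion ≈ 2%
  total) and random orientation. Coverage per (specimen, primer pair) is
  negative-binomial (mean 100, dispersion 5). Tags are random 13-mers
  kept ≥3 edits apart so ≤1-mismatch demultiplexing cannot cross
  specimens; the published tag sets themselves are not reproduced, so
  behaviour on those exact tags is unverified. There is no
  homopolymer-aware or signal-level error structure, no chimeras
  (a knob exists, default off) — passing tests show the *logic* of the
  pipeline is right at these error regimes, not that real flow-cell
  artefacts are handled.
- **Reference databases.** Two databases drawn independently from the
  species pool (`db_coverage_nt`, `db_coverage_local`), 1–3 accessions
  per included species within intraspecific distance of truth, and an
  optional `mislabel_rate` that swaps a record's name for a congener
  (ground truth recorded in a manifest).

## Pipeline choices

- **Demultiplexing.** Tags are matched by substitution-only Hamming
  distance (default tolerance 1) at offsets 0–6 from each read end;
  primers behind the tags are located by semi-global edlib alignment with
  IUPAC degeneracy (tolerance 5), which also sets the trim point.
  Any ambiguity — two tags in tolerance, conflicting specimens between
  ends, tied primer pairs, tied orientations — leaves the read
  unassigned rather than guessed. Reads matching a supplied previous-run
  tag list are screened out. The default length window is the expected
  tagged-amplicon span ±25%.
- **Consensus.** The aligner is a star alignment around the median-length
  read using edlib global alignments, with one round of refinement
  (realign against the draft consensus) when the first draft fails QC —
  the refinement matters above ~10% read error, where a noisy centre read
  degrades the stack. Majority rule per column: gap-plurality columns are
  dropped, a base needs ≥50% frequency (else `N`), base ties break
  alphabetically, and a base tied with the gap count keeps the base.
  Subsampling per tier is seeded per bin (seed recorded), so runs are
  byte-reproducible.
- **Merging.** "Fewer than 10 bp difference" is read strictly (<10), and
  "close to 100% alignment" is operationalised as ≤2 gap columns in the
  global alignment. Of an accepted discordant pair, the higher-coverage
  barcode is kept (tie → pair A); the choice is ours, either copy passes
  identically downstream. The coverage filter is strictly exclusive:
  coverage 10 is removed, 11 retained.
- **Clustering.** Single linkage (connected components of the
  threshold graph) with an *inclusive* comparison, so a pair at exactly
  the cut co-clusters — this is what makes a 2.76% pair merge at a
  "2.8%" threshold. Reported identities are rounded half-away-from-zero
  to 1 decimal; distances use pairwise deletion at non-ACGT sites and no
  realignment (QC guarantees fixed-length, indel-free barcodes). Two of
  the printed reference similarities (86.6, 83.5) are unreachable by any
  integer substitution count over 652 ungapped sites and are treated as
  gapped/partial-overlap artefacts of upstream tooling, not modelled.
- **Identification.** Search is exhaustive global-alignment identity,
  exact at desk scale (≤10⁴ references) and free of heuristic seed
  effects; the ≥80% reporting floor stands in for an e-value cutoff.
  The ≥98% identifiability rule, outlier flagging (a 1-accession top
  species outvoted by ≥2 concordant accessions), curated overrides, and
  lowest-common-rank reconciliation are applied in that order. "Genus
  sp." names count as genus-rank; numbered morphospecies ("Istigobius
  sp1") as local species-rank names. Identification success is
  identified/compliant barcodes; barcoding success is compliant
  specimens/all specimens. Geographic-plausibility judgement enters only
  through override rows, never as an algorithm.
- **Diversity.** Shannon in nats and Gini–Simpson (1 − Σp²) by default —
  the variants are a declared choice, with inverse Simpson available.
  Rarefaction is interpolation-only hypergeometric E[S_m] (computed with
  log-gamma for stability); Ĉ is the singleton/doubleton coverage
  estimator; no extrapolation or confidence intervals.

## Validation experiments

`coipipe.validation` runs the full pipeline on the default study
conditions — 50 species × 4 sites × ~160 specimens, ~100× coverage, 2%
read error, complete databases — and scores against generator truth:
exact per-specimen barcode recovery (≥95% required; observed 100% across
seeds), equality of the 2% partition with the true species partition,
and species-level identification accuracy (100% with complete
databases). The partial-coverage experiment keeps each species in the
reference material with probability 0.75 under a single inclusion draw
shared by both databases (modelling species with no references
anywhere); barcode-level identification success then tracks the covered
barcode fraction, whose variance is dominated by species-level binomial
sampling amplified by abundance weighting — the steadier mOTU-level
success is reported alongside. These problem sizes were chosen as the
smallest community that exercises every rule (multi-genus families,
singleton mOTUs, threshold-straddling pairs) while keeping a full run
under a minute.

## Known limitations

- The consensus caller is a stand-in with the same contract as the
  published barcode-calling tool, not a reimplementation of its
  internals; above ~15–20% read error the star alignment degrades and
  the similarity fallback cannot always rescue a bin.
- Reconciliation operates on the two databases' consensus species; it
  never consults raw chromatograms, vouchers or ranges — such evidence
  enters only as override rows.
- `stability_analysis` pairs clusters by shared label or mutual
  nearest-neighbour; it does not enumerate all cluster pairs, so a
  three-way near-merge appears as its two closest pairs.
- Diversity metrics assume the identified-specimen table is a fair
  sample per site; no detection-probability or extrapolation model.
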