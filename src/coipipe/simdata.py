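"""Ground-truthed synthetic communities, reference databases and tagged reads.

The generator emulates the data structure of a specimen-rich larval-fish
barcoding run: a hierarchical species pool whose COI barcodes are separated
by more than the clustering threshold between species and by less within
species, two overlapping but imperfect reference databases, per-site
abundance structure, and noisy dual-tagged amplicon reads from two primer
pairs. Everything is driven by a single integer seed and is byte-for-byte
reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
import pandas as pd

from coipipe.seqs import BASES, SENSE_CODONS, VERTEBRATE_MITO_STOPS, revcomp
from coipipe.taxassign import RANKS, RefDB, RefRecord

# Folmer-cocktail primer pairs used for amplification (two pairs per specimen).
PRIMER_PAIRS = {
    "pair1": ("TCGACTAATCATAAAGATATCGGCAC",   # FishF2_t1
              "ACTTCAGGGTGACCGAAGAATCAGAA"),  # FishR2_t1
    "pair2": ("TCAACCAACCACAAAGACATTGGCAC",   # VF2_t1
              "CACCTCAGGGTGTCCGAARAAYCARAA"), # FR1d_t1
}

TAG_LENGTH = 13
MIN_TAG_DISTANCE = 3


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the desk-scale study conditions: 50 species
    (5 families x 2 genera x 5 species) across 4 sites, 652-nt barcodes,
    >=4% interspecific and <=1% intraspecific divergence, ~100x read
    coverage per specimen and primer pair, and a 2% total read error rate
    split 1.6% substitutions / 0.2% insertions / 0.2% deletions.
    """

    seed: int = 0
    n_families: int = 5
    n_genera_per_family: int = 2
    n_species_per_genus: int = 5
    barcode_length: int = 652
    min_interspecific_p: float = 0.04
    max_intraspecific_p: float = 0.01
    sub_rate: float = 0.016
    ins_rate: float = 0.002
    del_rate: float = 0.002
    coverage_mean: float = 100.0
    coverage_dispersion: float = 5.0
    n_sites: int = 4
    specimens_per_site: int = 40
    abundance_ratio: float = 0.9  # geometric rank-abundance decay per site
    max_haplotypes: int = 3
    db_coverage_nt: float = 1.0
    db_coverage_local: float = 1.0
    mislabel_rate: float = 0.0
    chimera_rate: float = 0.0  # reserved knob, off by default
    forced_pair_disagreement_subs: int = 0  # force k-substitution cross-primer differences
    site_names: tuple[str, ...] | None = None

    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        bad = []
        if self.min_interspecific_p <= self.max_intraspecific_p:
            bad.append("min_interspecific_p must exceed max_intraspecific_p")
        for name in ("sub_rate", "ins_rate", "del_rate", "db_coverage_nt",
                     "db_coverage_local", "mislabel_rate", "chimera_rate",
                     "min_interspecific_p", "max_intraspecific_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(f"{name} must be in [0, 1], got {v}")
        if self.barcode_length < 3:
            bad.append("barcode_length must be at least one codon")
        for name in ("n_families", "n_genera_per_family", "n_species_per_genus",
                     "n_sites", "specimens_per_site"):
            if getattr(self, name) < 1:
                bad.append(f"{name} must be positive")
        if not 0 < self.abundance_ratio <= 1:
            bad.append("abundance_ratio must be in (0, 1]")
        return bad

    @property
    def n_species(self) -> int:
        return self.n_families * self.n_genera_per_family * self.n_species_per_genus

    @property
    def sites(self) -> list[str]:
        if self.site_names is not None:
            return list(self.site_names)
        return [f"Site{i + 1}" for i in range(self.n_sites)]


@dataclass
class SpeciesTruth:
    """Ground truth for one simulated species."""

    species_id: str
    lineage: dict[str, str]  # the 7 ranks, kingdom .. species
    true_barcode: str
    haplotypes: list[str]  # haplotypes[0] is the true barcode itself
    site_abundances: dict[str, int] = field(default_factory=dict)


@dataclass
class TagScheme:
    """Per-specimen 13-nt dual tags plus the two primer pairs."""

    tags: dict[str, tuple[str, str]]  # sample_id -> (forward tag, reverse tag)
    primer_pairs: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(PRIMER_PAIRS)
    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tags)


def _require_valid(config: SimulationConfig) -> None:
    bad = config.validate()
    if bad:
        raise ValueError("invalid SimulationConfig: " + "; ".join(bad))


def _random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    """Random sequence of sense codons (frame 0), plus trailing bases."""
    n_codons = length // 3
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    seq = "".join(SENSE_CODONS[i] for i in idx)
    for _ in range(length - 3 * n_codons):
        seq += BASES[rng.integers(0, 4)]
    return seq


def _mutate_no_stop(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``n_subs`` positions without creating a frame-0 stop."""
    if n_subs == 0:
        return seq
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    coding_end = 3 * (len(seq) // 3)
    for pos in sorted(int(p) for p in positions):
        choices = [b for b in BASES if b != out[pos]]
        order = rng.permutation(len(choices))
        for j in order:
            out[pos] = choices[j]
            if pos >= coding_end:
                break
            start = 3 * (pos // 3)
            if "".join(out[start : start + 3]) not in VERTEBRATE_MITO_STOPS:
                break
        else:  # pragma: no cover - every codon has a non-stop single-base variant
            raise RuntimeError("could not avoid stop codon")
    return "".join(out)


def mutate_fixed_distance(seq: str, n_subs: int, seed: int) -> str:
    """Return a copy of ``seq`` differing at exactly ``n_subs`` positions.

    Substitutions only — the output has the same length and an exact Hamming
    distance of ``n_subs`` to the input. Used to build sequence pairs with a
    prescribed percent identity.
    """
    if not 0 <= n_subs <= len(seq):
        raise ValueError(f"n_subs={n_subs} outside [0, {len(seq)}]")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [b for b in BASES if b != out[pos]]
        out[pos] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _hamming_fast(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_community(config: SimulationConfig) -> list[SpeciesTruth]:
    """Generate the species pool with hierarchical taxonomy and barcodes.

    Species barcodes are derived family -> genus -> species by seeded
    substitution, then accepted only if every pairwise interspecific
    p-distance is >= ``min_interspecific_p``; haplotypes sit within
    ``max_intraspecific_p`` of the species barcode. All barcodes translate
    without stops in frame 0 of the vertebrate mitochondrial code.
    """
    _require_valid(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    L = config.barcode_length
    min_inter_subs = int(np.ceil(config.min_interspecific_p * L))
    species_div = min(L, max(min_inter_subs,
                             int(round(1.25 * config.min_interspecific_p * L))))
    genus_div = min(L, int(round(2.5 * config.min_interspecific_p * L)))
    max_intra_subs = int(np.floor(config.max_intraspecific_p * L))

    species: list[SpeciesTruth] = []
    barcodes: list[str] = []
    max_attempts = 200
    for fi in range(config.n_families):
        family_seq = _random_coding_sequence(L, rng)
        family = f"Simfam{fi + 1}idae"
        order = f"Simorder{fi + 1}formes"
        for gi in range(config.n_genera_per_family):
            genus_seq = _mutate_no_stop(family_seq, genus_div, rng)
            genus = f"Simgenus{fi + 1}{chr(ord('a') + gi)}"
            for si in range(config.n_species_per_genus):
                for _ in range(max_attempts):
                    cand = _mutate_no_stop(genus_seq, species_div, rng)
                    if all(_hamming_fast(cand, b) >= min_inter_subs for b in barcodes):
                        break
                else:
                    raise RuntimeError(
                        "could not satisfy interspecific divergence constraint "
                        f"after {max_attempts} attempts"
                    )
                name = f"{genus} species{si + 1}"
                lineage = dict(zip(RANKS, (
                    "Animalia", "Chordata", "Actinopterygii",
                    order, family, genus, name,
                )))
                n_hap = int(rng.integers(1, config.max_haplotypes + 1))
                haps = [cand]
                for _ in range(n_hap - 1):
                    k = int(rng.integers(1, max_intra_subs + 1)) if max_intra_subs else 0
                    haps.append(_mutate_no_stop(cand, k, rng))
                sp_id = f"SP{len(species) + 1:03d}"
                species.append(SpeciesTruth(sp_id, lineage, cand, haps))
                barcodes.append(cand)

    # Geometric rank-abundance per site; ranks are shuffled independently
    # per site so inventories overlap but differ.
    for site in config.sites:
        ranks = rng.permutation(len(species))
        weights = config.abundance_ratio ** np.argsort(ranks)
        weights = weights / weights.sum()
        counts = rng.multinomial(config.specimens_per_site, weights)
        for sp, c in zip(species, counts):
            sp.site_abundances[site] = int(c)
    return species


def generate_tag_scheme(sample_ids: list[str], seed: int) -> TagScheme:
    """Random 13-nt tag pairs, all tags mutually >= 3 edits apart."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    accepted: list[str] = []
    need = 2 * len(sample_ids)
    attempts = 0
    while len(accepted) < need:
        attempts += 1
        if attempts > 1000 * need:
            raise RuntimeError("could not generate enough well-separated tags")
        cand = "".join(BASES[i] for i in rng.integers(0, 4, size=TAG_LENGTH))
        if all(
            edlib.align(cand, t, task="distance")["editDistance"] >= MIN_TAG_DISTANCE
            for t in accepted
        ):
            accepted.append(cand)
    tags = {
        sid: (accepted[2 * i], accepted[2 * i + 1])
        for i, sid in enumerate(sample_ids)
    }
    return TagScheme(tags=tags)


def _apply_errors(seq: str, rng: np.random.Generator,
                  sub: float, ins: float, dele: float) -> str:
    """i.i.d. per-base substitution/insertion/deletion errors."""
    if sub == ins == dele == 0:
        return seq
    out = []
    for base in seq:
        r = rng.random()
        if r < dele:
            continue
        if r < dele + sub:
            out.append(BASES[(BASES.index(base) + 1 + rng.integers(0, 3)) % 4]
                       if base in BASES else base)
        else:
            out.append(base)
        if rng.random() < ins:
            out.append(BASES[rng.integers(0, 4)])
    return "".join(out)


def simulate_reads(
    species: SpeciesTruth,
    specimen_count: int,
    tags: TagScheme,
    config: SimulationConfig,
    specimen_ids: list[str] | None = None,
    haplotype_choice: list[int] | None = None,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate tagged reads for ``specimen_count`` specimens of one species.

    Each read is ``fwd_tag + fwd_primer + amplicon + revcomp(rev_tag +
    rev_primer)`` with i.i.d. errors over the whole read; about half the
    reads are emitted reverse-complemented. Returns ``(reads, manifest)``
    where reads are ``(read_id, sequence)`` and the manifest maps read id to
    (specimen, primer pair, true species, haplotype, orientation).
    """
    _require_valid(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 303])
    )
    if specimen_ids is None:
        specimen_ids = [f"{species.species_id}_S{i + 1}" for i in range(specimen_count)]
    reads: list[tuple[str, str]] = []
    rows = []
    p_nb = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)
    for k, sid in enumerate(specimen_ids):
        if sid not in tags.tags:
            raise KeyError(f"no tags for specimen {sid}")
        tag_f, tag_r = tags.tags[sid]
        hap_idx = (haplotype_choice[k] if haplotype_choice is not None
                   else int(rng.integers(0, len(species.haplotypes))))
        amplicon = species.haplotypes[hap_idx]
        for pair_name, (primer_f, primer_r) in tags.primer_pairs.items():
            if config.forced_pair_disagreement_subs and pair_name == "pair2":
                insert = mutate_fixed_distance(
                    amplicon, config.forced_pair_disagreement_subs,
                    int(rng.integers(0, 2**31)),
                )
            else:
                insert = amplicon
            template = tag_f + primer_f + insert + revcomp(tag_r + primer_r)
            n_reads = int(rng.negative_binomial(config.coverage_dispersion, p_nb))
            for j in range(n_reads):
                seq = _apply_errors(template, rng, config.sub_rate,
                                    config.ins_rate, config.del_rate)
                orient = "+"
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                    orient = "-"
                rid = f"read_{sid}_{pair_name}_{j:04d}"
                reads.append((rid, seq))
                rows.append((rid, sid, pair_name, species.lineage["species"],
                             hap_idx, orient))
    manifest = pd.DataFrame(
        rows, columns=["read_id", "specimen", "primer_pair",
                       "true_species", "haplotype", "orientation"],
    )
    return reads, manifest


def generate_reference_dbs(
    species: list[SpeciesTruth],
    config: SimulationConfig,
) -> tuple[RefDB, RefDB, pd.DataFrame]:
    """Build the two imperfect reference databases.

    Each database independently includes a ``db_coverage_*`` fraction of
    the species pool with 1-3 accessions per included species (the true
    barcode plus near-identical variants); ``mislabel_rate`` of records are
    assigned a wrong species name drawn from the community (same genus
    preferred). The returned manifest records every label and whether it is
    wrong, providing ground truth for identification accuracy.
    """
    _require_valid(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    L = config.barcode_length
    max_intra_subs = int(np.floor(config.max_intraspecific_p * L))
    rows = []
    dbs = {}
    for db_name, coverage, acc_prefix in (
        ("nt", config.db_coverage_nt, "NT"),
        ("local", config.db_coverage_local, "LC"),
    ):
        included = [sp for sp in species if rng.random() < coverage]
        records = []
        for sp in included:
            n_acc = int(rng.integers(1, 4))
            for a in range(n_acc):
                seq = sp.true_barcode if a == 0 else _mutate_no_stop(
                    sp.true_barcode,
                    int(rng.integers(0, max_intra_subs + 1)) if max_intra_subs else 0,
                    rng,
                )
                label_lineage = dict(sp.lineage)
                mislabeled = rng.random() < config.mislabel_rate
                if mislabeled:
                    same_genus = [
                        o for o in species
                        if o.lineage["genus"] == sp.lineage["genus"]
                        and o.lineage["species"] != sp.lineage["species"]
                    ]
                    pool = same_genus if same_genus else [
                        o for o in species if o.lineage["species"] != sp.lineage["species"]
                    ]
                    wrong = pool[int(rng.integers(0, len(pool)))]
                    label_lineage = dict(wrong.lineage)
                acc = f"{acc_prefix}{len(records) + 1:06d}"
                records.append(RefRecord(acc, seq, label_lineage))
                rows.append((db_name, acc, sp.lineage["species"],
                             label_lineage["species"], mislabeled))
        dbs[db_name] = RefDB(name=db_name, records=records)
    manifest = pd.DataFrame(
        rows, columns=["db", "accession", "true_species", "label_species", "mislabeled"],
    )
    return dbs["nt"], dbs["local"], manifest


@dataclass
class SimulatedRun:
    """Bundle of everything a synthetic sequencing run produces."""

    config: SimulationConfig
    species: list[SpeciesTruth]
    tag_scheme: TagScheme
    sample_sheet: pd.DataFrame  # sample_id, site, tag_fwd, tag_rev
    reads: list[tuple[str, str]]
    read_manifest: pd.DataFrame
    specimen_truth: pd.DataFrame  # specimen, site, true_species, true_barcode
    db_nt: RefDB
    db_local: RefDB
    db_manifest: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulatedRun:
    """Run the whole generator: community, tags, specimens, reads and DBs."""
    _require_valid(config)
    species = generate_community(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))

    # Allocate specimens per the ground-truth site abundances.
    specimen_rows = []  # (specimen_id, site, species index, haplotype index)
    counter = itertools.count(1)
    for site in config.sites:
        for idx, sp in enumerate(species):
            for _ in range(sp.site_abundances.get(site, 0)):
                sid = f"FISH{next(counter):04d}"
                hap = int(rng.integers(0, len(sp.haplotypes)))
                specimen_rows.append((sid, site, idx, hap))

    scheme = generate_tag_scheme([r[0] for r in specimen_rows], config.seed)
    sample_sheet = pd.DataFrame(
        [(sid, site, scheme.tags[sid][0], scheme.tags[sid][1])
         for sid, site, _, _ in specimen_rows],
        columns=["sample_id", "site", "tag_fwd", "tag_rev"],
    )
    specimen_truth = pd.DataFrame(
        [(sid, site, species[i].lineage["species"], species[i].haplotypes[h])
         for sid, site, i, h in specimen_rows],
        columns=["specimen", "site", "true_species", "true_barcode"],
    )

    all_reads: list[tuple[str, str]] = []
    manifests = []
    by_species: dict[int, list[tuple[str, int]]] = {}
    for sid, _site, i, h in specimen_rows:
        by_species.setdefault(i, []).append((sid, h))
    for i, members in by_species.items():
        reads, manifest = simulate_reads(
            species[i], len(members), scheme, config,
            specimen_ids=[m[0] for m in members],
            haplotype_choice=[m[1] for m in members],
            seed=int(rng.integers(0, 2**31)),
        )
        all_reads.extend(reads)
        manifests.append(manifest)
    read_manifest = (pd.concat(manifests, ignore_index=True) if manifests
                     else pd.DataFrame(columns=["read_id", "specimen", "primer_pair",
                                                "true_species", "haplotype", "orientation"]))
    # Stable read order regardless of species iteration order.
    order = np.argsort([r[0] for r in all_reads], kind="stable")
    all_reads = [all_reads[i] for i in order]
    read_manifest = read_manifest.sort_values("read_id", kind="stable").reset_index(drop=True)

    db_nt, db_local, db_manifest = generate_reference_dbs(species, config)
    return SimulatedRun(
        config=config, species=species, tag_scheme=scheme,
        sample_sheet=sample_sheet, reads=all_reads, read_manifest=read_manifest,
        specimen_truth=specimen_truth, db_nt=db_nt, db_local=db_local,
        db_manifest=db_manifest,
    )


def config_with(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Copy a config with selected fields replaced."""
    return replace(config, **kwargs)
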