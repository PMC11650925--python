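"""End-to-end orchestration: reads -> barcodes -> mOTUs -> identities -> diversity.

A single ``RunConfig`` drives every stage with one seed; re-running with
the same config reproduces all outputs byte-identically. Each stage writes
its artefacts under the output directory and the run report accounts for
every specimen exactly once (identified + unidentified + non_compliant +
dropped_incompatible + below_coverage).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coipipe import io as cio
from coipipe.consensus import Barcode, ConsensusParams, barcode_for_bin
from coipipe.demux import DemuxParams, demultiplex, length_filter
from coipipe.diversity import abundance_table, rarefaction_curve, shared_motus, site_diversity_table
from coipipe.motu import DEFAULT_THRESHOLDS, DistanceMatrix, objective_cluster, stability_analysis
from coipipe.primer_merge import ReconcileParams, coverage_filter, merge_primer_sets
from coipipe.simdata import MIN_TAG_DISTANCE, SimulationConfig, simulate_dataset
from coipipe.taxassign import AssignParams, assign_all, load_overrides, search

ALL_STAGES = ("simulate", "demux", "consensus", "merge", "cluster", "assign", "diversity")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "coipipe_run"
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    demux: DemuxParams = field(default_factory=DemuxParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    merge: ReconcileParams = field(default_factory=ReconcileParams)
    assign: AssignParams = field(default_factory=AssignParams)
    cluster_threshold: float = 0.02
    stability_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    simpson_variant: str = "gini"
    # External inputs, used when the corresponding stage is toggled off.
    reads_fastq: str | None = None
    sample_sheet: str | None = None
    barcodes_fasta: str | None = None
    db_nt_prefix: str | None = None
    db_local_prefix: str | None = None
    overrides_tsv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        nested = {"sim": SimulationConfig, "demux": DemuxParams,
                  "consensus": ConsensusParams, "merge": ReconcileParams,
                  "assign": AssignParams}
        for key, value in raw.items():
            if key in nested:
                if isinstance(value, dict):
                    value = {k: tuple(v) if isinstance(v, list) else v
                             for k, v in value.items()}
                    kwargs[key] = nested[key](**value)
                else:
                    raise ValueError(f"config block '{key}' must be a mapping")
            elif isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: plain(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, frozenset):
                return sorted(plain(v) for v in obj)
            if isinstance(obj, (tuple, list)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj
        with open(path, "w") as fh:
            yaml.safe_dump(plain(self), fh, sort_keys=False)


def validate_config(config: RunConfig) -> list[str]:
    """Collect every module-invariant violation in the parameter blocks."""
    bad = []
    bad += [f"sim: {v}" for v in config.sim.validate()]
    bad += [f"consensus: {v}" for v in config.consensus.validate()]
    bad += [f"merge: {v}" for v in config.merge.validate()]
    bad += [f"assign: {v}" for v in config.assign.validate()]
    if config.demux.max_tag_mismatch < 0:
        bad.append("demux: max_tag_mismatch must be non-negative")
    if config.demux.max_tag_mismatch >= MIN_TAG_DISTANCE / 2:
        bad.append(
            f"demux: max_tag_mismatch={config.demux.max_tag_mismatch} is not below "
            f"half the minimum tag distance ({MIN_TAG_DISTANCE}); assignments may be ambiguous"
        )
    if not 0 < config.cluster_threshold < 1:
        bad.append("cluster_threshold must be a fraction in (0, 1)")
    if len(set(config.stability_thresholds)) < 2:
        bad.append("stability_thresholds needs at least two distinct values")
    for stage in config.stages:
        if stage not in ALL_STAGES:
            bad.append(f"unknown stage: {stage}")
    for name in ("reads_fastq", "sample_sheet", "barcodes_fasta",
                 "db_nt_prefix", "db_local_prefix", "overrides_tsv"):
        path = getattr(config, name)
        if path is not None and name.endswith("prefix"):
            if not Path(path).with_suffix(".fasta").exists():
                bad.append(f"{name}: {path}.fasta does not exist")
        elif path is not None and not Path(path).exists():
            bad.append(f"{name}: {path} does not exist")
    return bad


@dataclass
class RunReport:
    seed: int = 0
    raw_reads: int = 0
    reads_retained: int = 0
    demultiplexed: dict = field(default_factory=dict)  # per primer pair
    demux_success_pct: float = float("nan")
    barcodes_per_pair: dict = field(default_factory=dict)  # compliant counts
    merge_statuses: dict = field(default_factory=dict)
    n_specimens: int = 0
    n_barcodes_final: int = 0
    n_motus: int = 0
    n_identified: int = 0
    n_unidentified: int = 0
    n_non_compliant: int = 0
    n_dropped_incompatible: int = 0
    n_below_coverage: int = 0
    barcoding_success_pct: float = float("nan")
    identification_success_pct: float = float("nan")

    def conservation_holds(self) -> bool:
        return self.n_specimens == (
            self.n_identified + self.n_unidentified + self.n_non_compliant
            + self.n_dropped_incompatible + self.n_below_coverage
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _bin_seed(seed: int, sid: str, pair: str) -> int:
    return zlib.crc32(f"{seed}|{sid}|{pair}".encode()) & 0x7FFFFFFF


def run_all(config: RunConfig) -> RunReport:
    """Execute the configured stages and write every intermediate."""
    bad = validate_config(config)
    if bad:
        raise ValueError("invalid config: " + "; ".join(bad))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    report = RunReport(seed=config.seed)

    # ------------------------------------------------------------ inputs
    sim_run = None
    db_nt = db_local = None
    overrides = {}
    if "simulate" in stages:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        sim_run = simulate_dataset(sim)
        reads = sim_run.reads
        sheet = sim_run.sample_sheet
        db_nt, db_local = sim_run.db_nt, sim_run.db_local
        cio.write_fastq(reads, out / "reads.fastq")
        cio.write_sample_sheet(sheet, out / "sample_sheet.tsv")
        sim_run.read_manifest.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        sim_run.specimen_truth.to_csv(out / "truth_specimens.tsv", sep="\t", index=False)
        cio.write_refdb(db_nt, out / "refdb_nt")
        cio.write_refdb(db_local, out / "refdb_local")
        sim_run.db_manifest.to_csv(out / "truth_refdb.tsv", sep="\t", index=False)
    else:
        reads = cio.read_fastq(config.reads_fastq) if config.reads_fastq else []
        sheet = (cio.read_sample_sheet(config.sample_sheet)
                 if config.sample_sheet else pd.DataFrame(
                     columns=["sample_id", "site", "tag_fwd", "tag_rev"]))
        if config.db_nt_prefix:
            db_nt = cio.read_refdb(config.db_nt_prefix, "nt")
        if config.db_local_prefix:
            db_local = cio.read_refdb(config.db_local_prefix, "local")
    if config.overrides_tsv:
        overrides = load_overrides(config.overrides_tsv)
    site_of = dict(zip(sheet["sample_id"], sheet["site"]))
    report.n_specimens = len(sheet)

    # ------------------------------------------------------------- demux
    barcodes: list[Barcode] = []
    merge_report = pd.DataFrame(columns=["specimen", "status", "distance", "kept_pair"])
    if "demux" in stages:
        scheme = (sim_run.tag_scheme if sim_run is not None
                  else cio.scheme_from_sample_sheet(sheet))
        report.raw_reads = len(reads)
        retained, _ = length_filter(reads, config.demux)
        report.reads_retained = len(retained)
        bins, unassigned, stats = demultiplex(reads, scheme, config.demux)
        report.demultiplexed = dict(stats.per_pair)
        report.demux_success_pct = stats.success_rate
        stats.to_frame().to_csv(out / "demux_stats.tsv", sep="\t", index=False)
    else:
        bins = {}

    # --------------------------------------------------------- consensus
    if "consensus" in stages and bins:
        for (sid, pair), tagged in sorted(bins.items()):
            bin_reads = [t.insert for t in tagged]
            barcodes.append(barcode_for_bin(
                bin_reads, config.consensus, specimen_id=sid, primer_pair=pair,
                seed=_bin_seed(config.seed, sid, pair)))
        cio.write_barcodes(barcodes, out / "barcodes_all.fasta")
        pd.DataFrame(
            [(b.specimen_id, b.primer_pair, b.coverage, b.tier, b.qc_status,
              ";".join(b.qc_failures)) for b in barcodes],
            columns=["specimen", "primer_pair", "coverage", "tier", "qc_status",
                     "qc_failures"],
        ).to_csv(out / "barcode_stats.tsv", sep="\t", index=False)

    # ------------------------------------------------------------- merge
    if "merge" in stages and barcodes:
        compliant = [b for b in barcodes if b.qc_status == "compliant"]
        pairs = sorted({b.primer_pair for b in compliant})
        for pair in pairs:
            report.barcodes_per_pair[pair] = sum(
                1 for b in compliant if b.primer_pair == pair)
        set_a = [b for b in compliant if b.primer_pair == pairs[0]] if pairs else []
        set_b = [b for b in compliant if len(pairs) > 1
                 and b.primer_pair == pairs[1]]

        def top_taxon(seq: str) -> str | None:
            for db in (db_nt, db_local):
                if db is not None:
                    hits = search(seq, db, config.assign)
                    if hits:
                        return hits[0].species
            return None

        matcher = top_taxon if (db_nt or db_local) else None
        merged, merge_report = merge_primer_sets(set_a, set_b, config.merge, matcher)
        report.merge_statuses = merge_report["status"].value_counts().to_dict()
        final = coverage_filter(merged, config.merge)
        report.n_below_coverage = len(merged) - len(final)
        merge_report.to_csv(out / "merge_report.tsv", sep="\t", index=False)
        cio.write_barcodes(final, out / "barcodes_final.fasta")
        barcodes_final = final
    elif config.barcodes_fasta:
        barcodes_final = [b for b in cio.read_barcodes(config.barcodes_fasta)
                          if b.qc_status == "compliant"]
        barcodes_final = coverage_filter(barcodes_final, config.merge)
    else:
        barcodes_final = []
    report.n_barcodes_final = len(barcodes_final)

    # ----------------------------------------------------------- cluster
    partition = None
    matrix = None
    if "cluster" in stages and barcodes_final:
        matrix = DistanceMatrix.from_sequences(
            {b.specimen_id: b.sequence for b in barcodes_final})
        matrix.to_phylip(out / "distances.phy")
        partition = objective_cluster(matrix, config.cluster_threshold)
        partition.to_frame().to_csv(out / "membership.tsv", sep="\t", index=False)
        report.n_motus = len(partition.names)

    # ------------------------------------------------------------ assign
    assignments = None
    if "assign" in stages and partition is not None and db_nt and db_local:
        table, summary = assign_all(partition, barcodes_final, db_nt, db_local,
                                    overrides, config.assign,
                                    n_specimens=report.n_specimens or None)
        table.to_csv(out / "identifications.tsv", sep="\t", index=False)
        report.n_identified = int(table["final_name"].notna().sum())
        report.n_unidentified = int(table["final_name"].isna().sum())
        report.identification_success_pct = summary["identification_success"]
        assignments = table
        labels = {row.barcode_id: row.final_name for row in table.itertuples()
                  if row.final_name is not None}
        stability = stability_analysis(matrix, config.stability_thresholds, labels)
        stability.to_csv(out / "stability.tsv", sep="\t", index=False)

    # --------------------------------------------------------- diversity
    if "diversity" in stages and assignments is not None:
        assignments = assignments.assign(
            site=assignments["barcode_id"].map(site_of),
            specimen=assignments["barcode_id"],
        )
        table = abundance_table(assignments)
        if not table.empty:
            table.to_csv(out / "abundance.tsv", sep="\t")
            site_diversity_table(table, config.simpson_variant).to_csv(
                out / "diversity.tsv", sep="\t", index=False)
            if len(table.index) >= 2:
                regions = shared_motus(table)
                pd.DataFrame(
                    [("+".join(sorted(k)), v) for k, v in sorted(
                        regions.items(), key=lambda kv: ("+".join(sorted(kv[0]))))],
                    columns=["sites", "n_motus"],
                ).to_csv(out / "shared_motus.tsv", sep="\t", index=False)
            curves = []
            for site in table.index:
                c = rarefaction_curve(table.loc[site].to_numpy())
                c.insert(0, "site", site)
                curves.append(c)
            pd.concat(curves, ignore_index=True).to_csv(
                out / "rarefaction.tsv", sep="\t", index=False)

    # -------------------------------------------------------- accounting
    if report.n_specimens:
        resolved = set()
        if assignments is not None:
            resolved |= set(assignments["barcode_id"])
        dropped = set(merge_report.loc[merge_report["status"] == "incompatible",
                                       "specimen"]) if len(merge_report) else set()
        report.n_dropped_incompatible = len(dropped)
        kept_final = {b.specimen_id for b in barcodes_final}
        merged_all = set(merge_report.loc[merge_report["status"] != "incompatible",
                                          "specimen"]) if len(merge_report) else set()
        report.n_below_coverage = len(merged_all - kept_final)
        report.n_non_compliant = (report.n_specimens - len(kept_final)
                                  - report.n_dropped_incompatible
                                  - report.n_below_coverage)
        if assignments is None:
            report.n_unidentified = len(kept_final) - report.n_identified
        # Barcoding success: specimens that yielded a compliant barcode.
        report.barcoding_success_pct = 100.0 * len(merged_all | dropped) / report.n_specimens
    report.to_json(out / "report.json")
    return report
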