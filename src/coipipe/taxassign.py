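"""Taxonomic identification of mOTUs against two reference databases.

Each mOTU representative is searched against the broad ("nt") and the
curated ("local") database by exhaustive global-alignment percent identity.
A mOTU is *identifiable* when at least one database yields a hit at >= 98%
identity. Conflicting >=98% identifications from the two databases are
reconciled conservatively: curated overrides are honoured first, otherwise
the lowest common taxonomic rank encompassing both names is accepted
(e.g. two congeners collapse to "Genus sp."). A single >=98% hit whose
species disagrees with a multi-accession majority is flagged as a putative
misidentified reference record and the majority species is used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import pandas as pd

from coipipe.seqs import round_half_up

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class RefRecord:
    accession: str
    sequence: str
    lineage: dict[str, str]  # the 7 ranks, kingdom .. species


@dataclass
class RefDB:
    """A reference database: sequences plus 7-rank lineages."""

    name: str
    records: list[RefRecord]

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.records]
        if len(set(accs)) != len(accs):
            dupes = [a for a, c in Counter(accs).items() if c > 1]
            raise ValueError(f"duplicate accessions in {self.name}: {dupes}")


@dataclass
class Hit:
    accession: str
    percent_identity: float  # 1 decimal, half-away-from-zero
    lineage: dict[str, str]

    @property
    def species(self) -> str:
        return self.lineage["species"]


@dataclass
class AssignParams:
    min_report_identity: float = 80.0
    identifiable_threshold: float = 98.0
    outlier_min_majority: int = 2
    fallback_name: str = "Animalia sp."

    def validate(self) -> list[str]:
        bad = []
        for name in ("min_report_identity", "identifiable_threshold"):
            v = getattr(self, name)
            if not 80.0 <= v <= 100.0:
                bad.append(f"{name} must be in [80, 100], got {v}")
        if self.outlier_min_majority < 2:
            bad.append("outlier_min_majority must be at least 2")
        return bad


@dataclass
class Identification:
    motu: str
    final_name: str | None
    final_rank: str | None
    provenance: str  # nt | local | conservative | revised | unidentified
    nt_top: tuple[str, float] | None = None
    local_top: tuple[str, float] | None = None
    flags: list[str] = field(default_factory=list)
    supporting_hits: dict[str, list[Hit]] = field(default_factory=dict)


def global_identity(a: str, b: str) -> float:
    """Percent identity of a global (NW) alignment, to 1 decimal.

    Identity = matched columns / alignment columns, so indels count
    against identity the way a BLAST-style global comparison would.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    n = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            n += ch
        else:
            k = int(n)
            n = ""
            columns += k
            if ch == "=":
                matches += k
    return round_half_up(100.0 * matches / columns)


def search(query: str, db: RefDB, params: AssignParams | None = None) -> list[Hit]:
    """Exhaustive identity search of ``query`` against every DB record.

    Returns hits at >= ``min_report_identity``, best identity first, ties
    broken by accession. Exhaustive comparison is exact at desk scale and
    avoids heuristic seed effects.
    """
    params = params or AssignParams()
    hits = [
        Hit(r.accession, ident, r.lineage)
        for r in db.records
        if (ident := global_identity(query, r.sequence)) >= params.min_report_identity
    ]
    hits.sort(key=lambda h: (-h.percent_identity, h.accession))
    return hits


@dataclass
class OutlierResult:
    consensus_species: str
    consensus_lineage: dict[str, str]
    top_identity: float
    flagged_accessions: list[str]
    note: str | None = None


def flag_outlier_reference(hits: list[Hit], params: AssignParams | None = None) -> OutlierResult:
    """Detect a single misidentified reference record among >=98% hits.

    If the top hit's species is supported by exactly one accession while a
    different species is supported by at least ``outlier_min_majority``
    accessions, the top accession is flagged and the majority species
    returned (the pattern of a lone mislabeled GenBank entry outvoted by
    concordant records). A 1-vs-1 split keeps the top hit but is marked
    ``ambiguous_majority``.
    """
    params = params or AssignParams()
    top98 = [h for h in hits if h.percent_identity >= params.identifiable_threshold]
    if not top98:
        raise ValueError("flag_outlier_reference requires at least one hit >= 98%")
    top = top98[0]
    counts = Counter(h.species for h in top98)
    if counts[top.species] == 1:
        rivals = {sp: c for sp, c in counts.items() if sp != top.species}
        if rivals:
            best_rival, rival_count = max(
                rivals.items(),
                key=lambda kv: (kv[1], max(h.percent_identity for h in top98
                                           if h.species == kv[0])),
            )
            if rival_count >= params.outlier_min_majority:
                rival_hit = next(h for h in top98 if h.species == best_rival)
                return OutlierResult(
                    best_rival, rival_hit.lineage, rival_hit.percent_identity,
                    flagged_accessions=[top.accession],
                )
            if rival_count == 1 and len(counts) == 2:
                return OutlierResult(top.species, top.lineage, top.percent_identity,
                                     [], note="ambiguous_majority")
    return OutlierResult(top.species, top.lineage, top.percent_identity, [])


def _species_rank(name: str) -> str:
    """Effective rank of a species-field name.

    Open nomenclature "Genus sp." is a genus-rank identification; numbered
    morphospecies such as "Genus sp1" are treated as (local) species-rank
    names.
    """
    if name.endswith(" sp."):
        return "genus"
    return "species"


def lowest_common_rank(lineage_a: dict[str, str], lineage_b: dict[str, str],
                       fallback_name: str = "Animalia sp.") -> tuple[str, str | None]:
    """Deepest rank at which two lineages agree, as a usable name.

    Species-level agreement returns the species itself; genus-level returns
    "Genus sp."; family and shallower return "<Taxon> sp.". Fully disjoint
    lineages fall back to ``fallback_name`` with rank None.
    """
    if not lineage_a or not lineage_b:
        raise ValueError("both lineages must be non-empty")
    for rank in reversed(RANKS):
        a, b = lineage_a.get(rank), lineage_b.get(rank)
        if a and a == b:
            if rank == "species":
                return a, "species"
            return f"{a} sp.", rank
    return fallback_name, None


def reconcile(
    hits_nt: list[Hit],
    hits_local: list[Hit],
    overrides: dict[frozenset[str], tuple[str, str]] | None = None,
    params: AssignParams | None = None,
    motu: str = "",
) -> Identification:
    """Reconcile the two databases' hit lists into one identification.

    Decision table: no database >=98% -> unidentified; exactly one ->
    that database's consensus species (after outlier flagging); both and
    same species -> that species (provenance nt); both and nested
    ("Genus sp." vs "Genus species") -> the more specific; both and
    disjoint -> curated override if present (revised), else the lowest
    common rank (conservative).
    """
    params = params or AssignParams()
    overrides = overrides or {}
    t = params.identifiable_threshold
    res_nt = flag_outlier_reference(hits_nt, params) if any(
        h.percent_identity >= t for h in hits_nt) else None
    res_local = flag_outlier_reference(hits_local, params) if any(
        h.percent_identity >= t for h in hits_local) else None

    nt_top = (hits_nt[0].species, hits_nt[0].percent_identity) if hits_nt else None
    local_top = (hits_local[0].species, hits_local[0].percent_identity) if hits_local else None
    flags = []
    for res, db in ((res_nt, "nt"), (res_local, "local")):
        if res:
            flags.extend(f"outlier_reference:{db}:{acc}" for acc in res.flagged_accessions)
            if res.note:
                flags.append(f"{res.note}:{db}")

    def ident(name, rank, prov):
        return Identification(motu, name, rank, prov, nt_top, local_top, flags,
                              {"nt": hits_nt, "local": hits_local})

    if res_nt is None and res_local is None:
        return ident(None, None, "unidentified")
    if res_local is None:
        return ident(res_nt.consensus_species, _species_rank(res_nt.consensus_species), "nt")
    if res_nt is None:
        return ident(res_local.consensus_species,
                     _species_rank(res_local.consensus_species), "local")

    name_nt, name_local = res_nt.consensus_species, res_local.consensus_species
    if name_nt == name_local:
        return ident(name_nt, _species_rank(name_nt), "nt")

    rank_nt, rank_local = _species_rank(name_nt), _species_rank(name_local)
    genus_nt = res_nt.consensus_lineage.get("genus")
    genus_local = res_local.consensus_lineage.get("genus")
    if genus_nt == genus_local and {rank_nt, rank_local} == {"genus", "species"}:
        # Nested: one database only reached the genus; accept the specific one.
        if rank_nt == "species":
            return ident(name_nt, "species", "nt")
        return ident(name_local, "species", "local")

    key = frozenset((name_nt, name_local))
    if key in overrides:
        final_name, final_rank = overrides[key]
        return ident(final_name, final_rank, "revised")
    final_name, final_rank = lowest_common_rank(
        res_nt.consensus_lineage, res_local.consensus_lineage, params.fallback_name)
    return ident(final_name, final_rank, "conservative")


def load_overrides(path) -> dict[frozenset[str], tuple[str, str]]:
    """Load a curated-override TSV: name_a, name_b, final_name, final_rank."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name_a", "name_b", "final_name", "final_rank"}
    if not required.issubset(df.columns):
        raise ValueError(f"override file missing columns {required - set(df.columns)}")
    out = {}
    for i, row in df.iterrows():
        if row[["name_a", "name_b", "final_name", "final_rank"]].isna().any():
            raise ValueError(f"malformed override row {i + 1}: {row.to_dict()}")
        if row["final_rank"] not in RANKS:
            raise ValueError(f"malformed override row {i + 1}: bad rank {row['final_rank']}")
        out[frozenset((row["name_a"], row["name_b"]))] = (row["final_name"], row["final_rank"])
    return out


def assign_all(
    partition,
    barcodes,
    db_nt: RefDB,
    db_local: RefDB,
    overrides: dict[frozenset[str], tuple[str, str]] | None = None,
    params: AssignParams | None = None,
    n_specimens: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Identify every mOTU and propagate to members.

    The representative of each mOTU is its highest-coverage member (ties by
    lexicographically smallest id). Returns a per-barcode identification
    table and summary rates: barcoding success (compliant barcodes /
    specimens, when ``n_specimens`` is given) and identification success
    (identified barcodes / compliant barcodes).
    """
    params = params or AssignParams()
    by_id = {b.specimen_id: b for b in barcodes}
    rows = []
    n_identified = 0
    for name, members in zip(partition.names, partition.clusters):
        rep = min(members, key=lambda m: (-by_id[m].coverage, m))
        idn = reconcile(
            search(by_id[rep].sequence, db_nt, params),
            search(by_id[rep].sequence, db_local, params),
            overrides, params, motu=name,
        )
        identified = idn.final_name is not None
        for m in members:
            rows.append((m, name, rep, idn.final_name, idn.final_rank,
                         idn.provenance,
                         idn.nt_top[0] if idn.nt_top else None,
                         idn.nt_top[1] if idn.nt_top else None,
                         idn.local_top[0] if idn.local_top else None,
                         idn.local_top[1] if idn.local_top else None,
                         ";".join(idn.flags)))
            if identified:
                n_identified += 1
    table = pd.DataFrame(rows, columns=[
        "barcode_id", "motu", "representative", "final_name", "final_rank",
        "provenance", "nt_top", "nt_identity", "local_top", "local_identity", "flags",
    ]).sort_values("barcode_id", kind="stable").reset_index(drop=True)
    n_compliant = len(rows)
    summary = {
        "n_motus": len(partition.names),
        "n_barcodes": n_compliant,
        "n_identified": n_identified,
        "identification_success": (100.0 * n_identified / n_compliant
                                   if n_compliant else float("nan")),
    }
    if n_specimens:
        summary["n_specimens"] = n_specimens
        summary["barcoding_success"] = 100.0 * n_compliant / n_specimens
    return table, summary
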