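"""File-format plumbing: FASTQ/FASTA, sample sheets, reference databases.

All on-disk formats are plain text: FASTQ/FASTA via Biopython, tabular
artefacts as TSV, distance matrices as square PHYLIP (written by
``DistanceMatrix.to_phylip``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from coipipe.consensus import Barcode
from coipipe.simdata import TagScheme
from coipipe.taxassign import RANKS, RefDB, RefRecord


def write_fastq(reads: list[tuple[str, str]], path, quality: int = 30) -> None:
    records = [
        SeqRecord(Seq(seq), id=rid, description="",
                  letter_annotations={"phred_quality": [quality] * len(seq)})
        for rid, seq in reads
    ]
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    try:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ {path}: {exc}") from exc


def write_fasta(entries: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def barcode_header(b: Barcode) -> str:
    qc = ";".join(b.qc_failures) if b.qc_failures else "-"
    return f"{b.specimen_id}|{b.primer_pair}|{b.coverage}|{b.tier}|{b.qc_status}|{qc}"


def parse_barcode_header(header: str) -> Barcode:
    parts = header.split("|")
    if len(parts) != 6:
        raise ValueError(f"bad barcode header: {header}")
    sid, pair, cov, tier, status, qc = parts
    return Barcode(sid, pair, "", int(cov), int(tier) if tier.isdigit() else tier,
                   status, [] if qc == "-" else qc.split(";"))


def write_barcodes(barcodes: list[Barcode], path) -> None:
    write_fasta([(barcode_header(b), b.sequence) for b in barcodes], path)


def read_barcodes(path) -> list[Barcode]:
    out = []
    for header, seq in read_fasta(path):
        b = parse_barcode_header(header)
        b.sequence = seq
        out.append(b)
    return out


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "site", "tag_fwd", "tag_rev"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet missing columns {required - set(df.columns)}")
    return df


def scheme_from_sample_sheet(sheet: pd.DataFrame) -> TagScheme:
    tags = {row.sample_id: (row.tag_fwd, row.tag_rev) for row in sheet.itertuples()}
    return TagScheme(tags=tags)


def write_refdb(db: RefDB, prefix) -> None:
    """Write a reference DB as <prefix>.fasta + <prefix>.taxonomy.tsv."""
    prefix = Path(prefix)
    write_fasta([(r.accession, r.sequence) for r in db.records],
                prefix.with_suffix(".fasta"))
    rows = [{"accession": r.accession, **{rank: r.lineage.get(rank, "") for rank in RANKS}}
            for r in db.records]
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".taxonomy.tsv"), sep="\t", index=False)


def read_refdb(prefix, name: str) -> RefDB:
    prefix = Path(prefix)
    seqs = dict(read_fasta(prefix.with_suffix(".fasta")))
    tax = pd.read_csv(prefix.with_suffix(".taxonomy.tsv"), sep="\t", dtype=str)
    records = []
    for row in tax.itertuples():
        lineage = {rank: getattr(row, rank) for rank in RANKS}
        records.append(RefRecord(row.accession, seqs[row.accession], lineage))
    return RefDB(name=name, records=records)
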