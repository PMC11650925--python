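"""Reconciling per-primer-pair barcode sets into one barcode per specimen.

The same specimen is amplified with two primer pairs, so it may yield two
independent consensus barcodes. Identical barcodes are merged; barcodes
differing by fewer than 10 bp that still give the same top database match
are accepted (the higher-coverage copy is kept); larger or taxonomically
discordant differences drop the specimen. The merged set is then filtered
to retain barcodes with strictly more than 10x read coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import edlib
import pandas as pd

from coipipe.consensus import Barcode
from coipipe.seqs import hamming


@dataclass
class ReconcileParams:
    max_disagreement_bp: int = 10  # strict <
    min_coverage_exclusive: int = 10  # strict >
    require_same_assignment: bool = True
    max_gap_columns: int = 2  # operationalises "close to 100% alignment"

    def validate(self) -> list[str]:
        bad = []
        if self.max_disagreement_bp <= 0:
            bad.append("max_disagreement_bp must be positive")
        if self.min_coverage_exclusive <= 0:
            bad.append("min_coverage_exclusive must be positive")
        return bad


def _distance_and_gaps(a: str, b: str) -> tuple[int, int]:
    """(edit distance, gap columns) of a global alignment of two barcodes."""
    if len(a) == len(b):
        return hamming(a, b), 0
    res = edlib.align(a, b, mode="NW", task="path")
    gaps = 0
    n = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            n += ch
        else:
            if ch in ("I", "D"):
                gaps += int(n)
            n = ""
    return res["editDistance"], gaps


def _index(barcodes: list[Barcode], label: str) -> dict[str, Barcode]:
    out: dict[str, Barcode] = {}
    for b in barcodes:
        if b.specimen_id in out:
            raise ValueError(f"specimen {b.specimen_id} appears twice in set {label}")
        out[b.specimen_id] = b
    return out


def merge_primer_sets(
    set_a: list[Barcode],
    set_b: list[Barcode],
    params: ReconcileParams | None = None,
    matcher: Callable[[str], str | None] | None = None,
) -> tuple[list[Barcode], pd.DataFrame]:
    """Merge the two primer pairs' QC-compliant barcode sets per specimen.

    Statuses per specimen: ``merged_identical`` (identical sequences, one
    kept), ``accepted_discordant`` (1..9 bp apart and same top taxon via
    ``matcher``; higher-coverage copy kept, ties to set A),
    ``incompatible`` (>=10 bp apart, poor alignment, or different top
    taxa; both dropped), ``single_pair`` (seen by one primer pair only).
    """
    params = params or ReconcileParams()
    a_by, b_by = _index(set_a, "A"), _index(set_b, "B")
    merged: list[Barcode] = []
    rows = []
    for sid in sorted(set(a_by) | set(b_by)):
        a, b = a_by.get(sid), b_by.get(sid)
        if a is None or b is None:
            kept = a or b
            merged.append(kept)
            rows.append((sid, "single_pair", None, kept.primer_pair))
            continue
        dist, gaps = _distance_and_gaps(a.sequence, b.sequence)
        if dist == 0:
            kept = a if a.coverage >= b.coverage else b
            merged.append(kept)
            rows.append((sid, "merged_identical", 0, kept.primer_pair))
            continue
        same_taxon = True
        if params.require_same_assignment and matcher is not None:
            same_taxon = matcher(a.sequence) == matcher(b.sequence)
        if dist < params.max_disagreement_bp and gaps <= params.max_gap_columns and same_taxon:
            kept = a if a.coverage >= b.coverage else b
            merged.append(kept)
            rows.append((sid, "accepted_discordant", dist, kept.primer_pair))
        else:
            rows.append((sid, "incompatible", dist, None))
    report = pd.DataFrame(rows, columns=["specimen", "status", "distance", "kept_pair"])
    return merged, report


def coverage_filter(barcodes: list[Barcode],
                    params: ReconcileParams | None = None) -> list[Barcode]:
    """Retain barcodes with coverage strictly above the threshold.

    The boundary is exclusive: coverage exactly 10 is removed.
    """
    params = params or ReconcileParams()
    return [b for b in barcodes if b.coverage > params.min_coverage_exclusive]
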