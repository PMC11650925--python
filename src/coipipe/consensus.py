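"""Consensus barcode calling with tiered subsampling and QC compliance.

Per (specimen, primer pair) bin, reads are subsampled at escalating
coverage tiers (25x, 50x, 100x, 200x, 500x), aligned, and collapsed to a
majority-rule consensus; the first tier whose consensus passes QC wins.
A QC-compliant barcode is exactly the expected length (652 nt), contains
no ambiguous bases, and translates without stop codons in at least one
forward frame of the vertebrate mitochondrial code. Bins that fail every
tier get a consensus-by-similarity fallback: reads are re-ranked by
identity to the best preliminary consensus and the closest 100 realigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from coipipe.seqs import translatable_frames


@dataclass
class ConsensusParams:
    expected_length: int = 652
    tiers: tuple[int, ...] = (25, 50, 100, 200, 500)
    similarity_coverage: int = 100
    column_majority_threshold: float = 0.5
    min_final_coverage: int = 10  # strict > applied by the downstream filter
    subsample_seed: int = 0

    def validate(self) -> list[str]:
        bad = []
        if list(self.tiers) != sorted(set(self.tiers)):
            bad.append("tiers must be strictly increasing")
        if not 0 < self.column_majority_threshold <= 1:
            bad.append("column_majority_threshold must be in (0, 1]")
        if self.expected_length < 3:
            bad.append("expected_length must be at least one codon")
        return bad


@dataclass
class Barcode:
    """A consensus barcode for one specimen and primer pair."""

    specimen_id: str
    primer_pair: str
    sequence: str
    coverage: int
    tier: int | str  # subsampling tier, or "similarity"
    qc_status: str  # "compliant" | "non_compliant"
    qc_failures: list[str] = field(default_factory=list)


def _parse_cigar(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def build_msa(reads: list[str], centre: str | None = None) -> list[str]:
    """Star multiple alignment of reads around a centre sequence.

    The centre defaults to the read of median length; every read is
    globally aligned to it and the pairwise alignments are stacked, with
    insertion columns opened between centre positions. Passing a
    preliminary consensus as ``centre`` gives one round of iterative
    refinement. Rows are equal length and gap-stripping row i reproduces
    read i exactly; the centre itself is not a row unless it is a read.
    """
    if not reads:
        raise ValueError("build_msa requires at least one read")
    if len(reads) == 1 and centre is None:
        return [reads[0]]
    if centre is None:
        centre_idx = sorted(range(len(reads)),
                            key=lambda i: (len(reads[i]), i))[len(reads) // 2]
        centre = reads[centre_idx]
    M = len(centre)

    # Per read: base (or gap) at each centre position, plus insertions keyed
    # by the centre position they precede (M == after the last position).
    aligned_rows = []
    max_ins = np.zeros(M + 1, dtype=int)
    for read in reads:
        if read == centre:
            row = list(centre)
            ins: dict[int, str] = {}
        else:
            res = edlib.align(read, centre, mode="NW", task="path")
            row = []
            ins = {}
            qpos = 0
            tpos = 0
            for k, op in _parse_cigar(res["cigar"]):
                if op in ("=", "X"):
                    row.extend(read[qpos : qpos + k])
                    qpos += k
                    tpos += k
                elif op == "I":  # extra bases in the read
                    ins[tpos] = ins.get(tpos, "") + read[qpos : qpos + k]
                    qpos += k
                elif op == "D":  # centre bases missing from the read
                    row.extend("-" * k)
                    tpos += k
        for pos, s in ins.items():
            if len(s) > max_ins[pos]:
                max_ins[pos] = len(s)
        aligned_rows.append((row, ins))

    out = []
    for row, ins in aligned_rows:
        parts = []
        for pos in range(M + 1):
            width = int(max_ins[pos])
            if width:
                s = ins.get(pos, "")
                parts.append(s + "-" * (width - len(s)))
            if pos < M:
                parts.append(row[pos])
        out.append("".join(parts))
    return out


def call_consensus(alignment: list[str], params: ConsensusParams | None = None) -> str:
    """Majority-rule consensus of an alignment.

    Columns where the gap is the strict plurality are dropped. Otherwise
    the plurality base is emitted when its frequency over all rows reaches
    ``column_majority_threshold``, else 'N'. Base ties break to the
    alphabetically first base; a base tied with the gap count keeps the
    base.
    """
    params = params or ConsensusParams()
    if not alignment:
        raise ValueError("empty alignment")
    n_rows = len(alignment)
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("alignment rows must have equal length")
    mat = np.frombuffer("".join(alignment).encode("ascii"),
                        dtype=np.uint8).reshape(n_rows, width)
    symbols = [ord(c) for c in "ACGT"]
    counts = np.stack([(mat == s).sum(axis=0) for s in symbols])  # (4, width)
    gap_counts = (mat == ord("-")).sum(axis=0)
    best = counts.argmax(axis=0)  # alphabetical tie-break via argmax order
    best_counts = counts.max(axis=0)
    out = []
    for j in range(width):
        if gap_counts[j] > best_counts[j]:
            continue
        if best_counts[j] == 0:
            out.append("N")  # column of non-ACGT symbols only
        elif best_counts[j] / n_rows >= params.column_majority_threshold:
            out.append("ACGT"[best[j]])
        else:
            out.append("N")
    return "".join(out)


def qc_compliance(seq: str, params: ConsensusParams | None = None,
                  reference: str | None = None) -> tuple[str, list[str]]:
    """Classify a consensus as QC compliant or list every failing reason.

    Compliant means: exactly ``expected_length`` nt, alphabet restricted to
    A/C/G/T, and at least one forward frame free of vertebrate-mitochondrial
    stop codons. When a compliant ``reference`` profile is supplied, the
    consensus must additionally align to it without inserting gaps into the
    reference.
    """
    params = params or ConsensusParams()
    reasons = []
    if len(seq) != params.expected_length:
        reasons.append("length")
    if set(seq) - set("ACGT"):
        reasons.append("ambiguous_bases")
    if not translatable_frames(seq):
        reasons.append("stop_codon")
    if reference is not None:
        res = edlib.align(seq, reference, mode="NW", task="path")
        if any(op == "I" for _k, op in _parse_cigar(res["cigar"])):
            reasons.append("reference_gaps")
    return ("compliant" if not reasons else "non_compliant"), reasons


def _subsample(n: int, k: int, rng: np.random.Generator) -> list[int]:
    if k >= n:
        return list(range(n))
    return sorted(int(i) for i in rng.choice(n, size=k, replace=False))


def barcode_for_bin(
    reads: list[str],
    params: ConsensusParams | None = None,
    specimen_id: str = "",
    primer_pair: str = "",
    seed: int | None = None,
    reference: str | None = None,
) -> Barcode:
    """Tiered consensus calling for one bin of (oriented, trimmed) reads.

    Tiers are tried in order; the first QC-compliant consensus is returned
    with its tier and the number of reads used. If every tier fails, the
    similarity fallback realigns the ``similarity_coverage`` reads closest
    to the best preliminary consensus; if that also fails, the best attempt
    is returned flagged non-compliant.
    """
    params = params or ConsensusParams()
    if not reads:
        raise ValueError("empty_bin")
    rng = np.random.default_rng(
        np.random.SeedSequence([params.subsample_seed if seed is None else seed, 17])
    )
    attempts = []  # (n_reasons, -coverage, seq, reasons, tier, coverage)
    for tier in params.tiers:
        idx = _subsample(len(reads), tier, rng)
        sub = [reads[i] for i in idx]
        cons = call_consensus(build_msa(sub), params)
        status, reasons = qc_compliance(cons, params, reference)
        if status != "compliant" and cons:
            # One round of refinement: realign against the draft consensus,
            # which rescues bins whose centre read was unusually noisy.
            cons = call_consensus(build_msa(sub, centre=cons), params)
            status, reasons = qc_compliance(cons, params, reference)
        if status == "compliant":
            return Barcode(specimen_id, primer_pair, cons, len(idx), tier, "compliant")
        attempts.append((len(reasons), -len(idx), cons, reasons, tier, len(idx)))
        if len(idx) == len(reads):
            break

    # Consensus by similarity: rank all reads by distance to the best
    # preliminary consensus and realign the closest ones.
    attempts.sort(key=lambda a: (a[0], a[1]))
    prelim = attempts[0][2]
    ranked = sorted(
        range(len(reads)),
        key=lambda i: (edlib.align(reads[i], prelim, mode="NW",
                                   task="distance")["editDistance"], i),
    )[: params.similarity_coverage]
    sub = [reads[i] for i in sorted(ranked)]
    cons = call_consensus(build_msa(sub, centre=prelim) if prelim else build_msa(sub),
                          params)
    status, reasons = qc_compliance(cons, params, reference)
    if status != "compliant" and cons:
        cons = call_consensus(build_msa(sub, centre=cons), params)
        status, reasons = qc_compliance(cons, params, reference)
    if status == "compliant":
        return Barcode(specimen_id, primer_pair, cons, len(ranked), "similarity", "compliant")
    _, _, best_seq, best_reasons, best_tier, best_cov = attempts[0]
    return Barcode(specimen_id, primer_pair, best_seq, best_cov, best_tier,
                   "non_compliant", list(best_reasons))
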