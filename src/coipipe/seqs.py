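"""Shared nucleotide-sequence primitives.

Everything downstream assumes plain upper-case strings over the IUPAC
alphabet; barcodes proper are restricted to A/C/G/T by QC. Translation
checks use the vertebrate mitochondrial genetic code (NCBI table 2),
whose stop codons differ from the standard code (AGA/AGG are stops).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC degeneracy map used for primer matching (primers may carry R/Y...).
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: Stop codons of the vertebrate mitochondrial code (TAA, TAG, AGA, AGG).
VERTEBRATE_MITO_STOPS = frozenset(unambiguous_dna_by_id[2].stop_codons)

#: All sense (non-stop) codons under the vertebrate mitochondrial code.
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in VERTEBRATE_MITO_STOPS
)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC degeneracy codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def iupac_mismatches(observed: str, pattern: str) -> int:
    """Mismatches of ``observed`` (plain bases) against an IUPAC ``pattern``.

    A position matches when the observed base is in the pattern symbol's
    degeneracy set; unknown observed characters never match.
    """
    if len(observed) != len(pattern):
        raise ValueError(f"length mismatch: {len(observed)} vs {len(pattern)}")
    n = 0
    for obs, pat in zip(observed, pattern):
        allowed = IUPAC.get(pat)
        if allowed is None or obs not in allowed:
            n += 1
    return n


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 97.25 -> 97.3, not banker's 97.2)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def stop_codon_positions(seq: str, frame: int) -> list[int]:
    """0-based codon indices that are stops in the given forward frame (0-2).

    Codons are read from ``frame`` to the last complete triplet; trailing
    bases that do not fill a codon are ignored (the 652-nt Folmer fragment
    is not a codon multiple).
    """
    stops = []
    n_codons = (len(seq) - frame) // 3
    for i in range(n_codons):
        codon = seq[frame + 3 * i : frame + 3 * i + 3]
        if codon in VERTEBRATE_MITO_STOPS:
            stops.append(i)
    return stops


def translatable_frames(seq: str) -> list[int]:
    """Forward frames (0, 1, 2) with no stop codon anywhere in the read."""
    return [f for f in range(3) if not stop_codon_positions(seq, f)]


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
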