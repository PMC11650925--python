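"""Demultiplexing of dual-tagged amplicon reads.

Reads carry a specimen-specific 13-nt tag at the 5' end of each primer, so
a read looks like ``tagF + primerF + insert + revcomp(tagR + primerR)`` in
either orientation. Assignment requires the same specimen's forward tag at
one end and reverse tag at the other (each within ``max_tag_mismatch``
substitutions), with the primer pair determined by which primer sequence
matches behind the tags. Ambiguous or conflicting tag matches leave the
read unassigned rather than guessed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from coipipe.seqs import IUPAC, encode, revcomp

#: Symmetric equality pairs letting IUPAC degeneracy codes in primers
#: match plain bases during alignment.
_IUPAC_PAIRS = [(sym, base) for sym, bases in IUPAC.items()
                for base in bases if sym not in "ACGT"]


@dataclass
class DemuxParams:
    """Tag/primer matching tolerances and the read length filter."""

    max_tag_mismatch: int = 1  # substitutions only
    length_window: tuple[int, int] | None = None  # default: expected span +/- 25%
    search_window: int = 6  # tag start scanned at offsets 0..search_window
    primer_max_mismatch: int = 5
    expected_amplicon: int = 652
    previous_tags: frozenset[str] = frozenset()

    def resolved_length_window(self, scheme=None) -> tuple[int, int]:
        if self.length_window is not None:
            return self.length_window
        overhead = 2 * 13 + 54  # two tags plus the two ~27-nt primers
        expected = self.expected_amplicon + overhead
        return (int(0.75 * expected), int(1.25 * expected))


@dataclass
class TaggedRead:
    """A read with its (possibly null) demultiplexing assignment."""

    read_id: str
    sequence: str
    qualities: str | None = None
    assigned_sample: str | None = None
    assigned_primer_pair: str | None = None
    orientation: str | None = None
    reason: str | None = None  # why unassigned, when unassigned
    insert: str | None = None  # tag/primer-trimmed, forward-oriented amplicon

    @property
    def assigned(self) -> bool:
        return self.assigned_sample is not None


@dataclass
class DemuxStats:
    n_input: int = 0
    n_retained: int = 0
    n_assigned: int = 0
    per_pair: Counter = field(default_factory=Counter)
    unassigned_reasons: Counter = field(default_factory=Counter)

    @property
    def success_rate(self) -> float:
        return 100.0 * self.n_assigned / self.n_retained if self.n_retained else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [("all", self.n_assigned, self.n_retained, self.success_rate)]
        for pair, n in sorted(self.per_pair.items()):
            rows.append((pair, n, self.n_retained,
                         100.0 * n / self.n_retained if self.n_retained else float("nan")))
        return pd.DataFrame(rows, columns=["primer_pair", "n_assigned",
                                           "n_retained", "success_pct"])


def length_filter(reads, params: DemuxParams):
    """Split reads into (retained, rejected) by the accepted length window."""
    lo, hi = params.resolved_length_window()
    if lo > hi:
        raise ValueError(f"invalid length window ({lo}, {hi})")
    retained, rejected = [], []
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else read.sequence
        (retained if lo <= len(seq) <= hi else rejected).append(read)
    return retained, rejected


class _TagMatcher:
    """Vectorised tag lookup over all specimens' tags at small offsets."""

    def __init__(self, scheme, params: DemuxParams):
        self.scheme = scheme
        self.params = params
        self.samples = list(scheme.tags)
        self.tag_len = len(next(iter(scheme.tags.values()))[0])
        self.fwd = np.stack([encode(scheme.tags[s][0]) for s in self.samples])
        self.rev = np.stack([encode(scheme.tags[s][1]) for s in self.samples])
        self.prev = [encode(t) for t in sorted(params.previous_tags)]

    def best_tag(self, seq: str, which: str):
        """Best (sample_index, mismatches, offset) at the 5' end of ``seq``.

        Returns None when no tag is within tolerance, or the string
        "ambiguous"/"previous_tag" for the corresponding failure modes.
        """
        mat = self.fwd if which == "fwd" else self.rev
        best = None  # (mismatches, sample_idx, offset)
        hit_prev = False
        for off in range(self.params.search_window + 1):
            window = seq[off : off + self.tag_len]
            if len(window) < self.tag_len:
                break
            w = encode(window)
            mm = (mat != w).sum(axis=1)
            order = np.argsort(mm, kind="stable")
            i0 = int(order[0])
            m0 = int(mm[i0])
            if m0 <= self.params.max_tag_mismatch:
                if len(order) > 1 and int(mm[order[1]]) == m0:
                    return "ambiguous"
                if best is None or m0 < best[0]:
                    best = (m0, i0, off)
            elif self.prev and not hit_prev:
                hit_prev = any(
                    int((p != w).sum()) <= self.params.max_tag_mismatch for p in self.prev
                )
        if best is not None:
            return best
        return "previous_tag" if hit_prev else None

    def best_primer(self, seq: str, offset: int, end: int):
        """Best primer pair behind a tag match: (pair, distance, span) or None.

        Primers are located by prefix (semi-global) alignment so read
        indels inside the primer do not sink the match; IUPAC degeneracy
        codes in the primer match any compatible base.
        """
        start = offset + self.tag_len
        best = None
        tied = False
        for pair, primers in self.scheme.primer_pairs.items():
            primer = primers[end]
            window = seq[start : start + len(primer) + self.params.primer_max_mismatch]
            if len(window) < len(primer) - self.params.primer_max_mismatch:
                continue
            res = edlib.align(primer, window, mode="SHW", task="locations",
                              additionalEqualities=_IUPAC_PAIRS)
            dist = res["editDistance"]
            if 0 <= dist <= self.params.primer_max_mismatch:
                span = res["locations"][0][1] + 1
                if best is None or dist < best[1]:
                    best = (pair, dist, span)
                    tied = False
                elif dist == best[1]:
                    tied = True
        if best is None:
            return None
        return "ambiguous" if tied else best


def _try_orientation(seq: str, matcher: _TagMatcher):
    """Attempt assignment assuming ``seq`` is forward-oriented."""
    head = matcher.best_tag(seq, "fwd")
    tail_seq = revcomp(seq)
    tail = matcher.best_tag(tail_seq, "rev")
    for res in (head, tail):
        if res in ("ambiguous", "previous_tag"):
            return None, "tag_ambiguous" if res == "ambiguous" else "previous_tag"
    if head is None or tail is None:
        return None, "no_tag"
    mm_f, si_f, off_f = head
    mm_r, si_r, off_r = tail
    if si_f != si_r:
        return None, "tag_conflict"
    pf = matcher.best_primer(seq, off_f, 0)
    pr = matcher.best_primer(tail_seq, off_r, 1)
    if pf == "ambiguous" or pr == "ambiguous":
        return None, "primer_ambiguous"
    if pf is None or pr is None:
        return None, "no_primer"
    if pf[0] != pr[0]:
        return None, "primer_conflict"
    insert_start = off_f + matcher.tag_len + pf[2]
    insert_end = len(seq) - (off_r + matcher.tag_len + pr[2])
    if insert_end <= insert_start:
        return None, "no_insert"
    return (
        matcher.samples[si_f], pf[0], mm_f + mm_r + pf[1] + pr[1],
        seq[insert_start:insert_end],
    ), None


def assign_read(read, scheme, params: DemuxParams | None = None,
                matcher: _TagMatcher | None = None) -> TaggedRead:
    """Assign one read to (specimen, primer pair), or leave it unassigned.

    ``read`` is a ``(read_id, sequence)`` tuple or an object with those
    attributes. Both orientations are tried; the better-scoring one wins
    and exact ties are left unassigned.
    """
    params = params or DemuxParams()
    if matcher is None:
        matcher = _TagMatcher(scheme, params)
    rid, seq = (read if isinstance(read, tuple) else (read.read_id, read.sequence))[:2]
    fwd_hit, fwd_reason = _try_orientation(seq, matcher)
    rev_hit, rev_reason = _try_orientation(revcomp(seq), matcher)
    if fwd_hit and rev_hit:
        if fwd_hit[2] == rev_hit[2]:
            return TaggedRead(rid, seq, reason="orientation_ambiguous")
        hit, orient = (fwd_hit, "+") if fwd_hit[2] < rev_hit[2] else (rev_hit, "-")
    elif fwd_hit:
        hit, orient = fwd_hit, "+"
    elif rev_hit:
        hit, orient = rev_hit, "-"
    else:
        reasons = [r for r in (fwd_reason, rev_reason) if r and r != "no_tag"]
        return TaggedRead(rid, seq, reason=reasons[0] if reasons else "no_tag")
    sample, pair, _score, insert = hit
    return TaggedRead(rid, seq, assigned_sample=sample, assigned_primer_pair=pair,
                      orientation=orient, insert=insert)


def demultiplex(reads, scheme, params: DemuxParams | None = None):
    """Assign all reads; returns (bins, unassigned, stats).

    ``bins`` maps (sample_id, primer_pair) to the list of assigned
    TaggedReads; every retained read lands in exactly one bin or in
    ``unassigned``. Reads failing the length filter are counted but not
    binned.
    """
    params = params or DemuxParams()
    reads = list(reads)
    stats = DemuxStats(n_input=len(reads))
    retained, _rejected = length_filter(reads, params)
    stats.n_retained = len(retained)
    matcher = _TagMatcher(scheme, params)
    bins: dict[tuple[str, str], list[TaggedRead]] = {}
    unassigned: list[TaggedRead] = []
    for i, read in enumerate(retained):
        try:
            tr = assign_read(read, scheme, params, matcher)
        except Exception as exc:  # noqa: BLE001 - annotate the offending record
            raise RuntimeError(f"malformed read record at index {i}") from exc
        if tr.assigned:
            bins.setdefault((tr.assigned_sample, tr.assigned_primer_pair), []).append(tr)
            stats.n_assigned += 1
            stats.per_pair[tr.assigned_primer_pair] += 1
        else:
            unassigned.append(tr)
            stats.unassigned_reasons[tr.reason] += 1
    return bins, unassigned, stats
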