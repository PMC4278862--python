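"""Paired-read merging and amplicon quality control.

The QC regime applied to merged amplicon reads:

* reject any sequence containing an ``N``;
* reject homopolymer runs longer than 7 bp;
* reject reads with more than 2 mismatches against either primer, then trim
  both primer footprints and normalise orientation to the forward strand;
* for the long GH7 product (515 bp, unmergeable from 2x250 chemistry), keep
  the forward read only and truncate it to the first 210 nt after the
  forward primer.

Each filter is a pure predicate on the sequence, so the accept/reject
status of a read is independent of the order the filters run in; rejected
reads carry at least one flag from {contains_N, homopolymer,
primer_mismatch, too_short, unmerged, ambiguous_family}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .primers import DegeneratePrimer, PrimerPair, match_window, revcomp

__all__ = [
    "ReadPair",
    "MergedRead",
    "merge_pair",
    "filter_ns",
    "filter_homopolymer",
    "locate_trim_primers",
    "truncate_forward",
    "assign_family",
]


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: tuple[int, ...]
    rev_qual: tuple[int, ...]
    sample: str = ""

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    sequence: str
    sample: str = ""
    family: Optional[str] = None
    qc_flags: frozenset[str] = frozenset()
    trimmed: bool = False

    def with_flag(self, flag: str) -> "MergedRead":
        return replace(self, qc_flags=self.qc_flags | {flag})

    @property
    def passed(self) -> bool:
        return not self.qc_flags


def merge_pair(
    pair: ReadPair,
    min_overlap: int = 20,
    max_overlap_mismatch_frac: float = 0.25,
) -> MergedRead:
    """Merge a read pair by best ungapped overlap.

    The reverse mate is reverse complemented and slid along the forward
    mate; the overlap with the most matching bases wins (ties: longest
    overlap, then smallest offset). Disagreements in the overlap are
    resolved toward the higher-quality base (ties toward the forward mate).
    Failure to find a qualifying overlap yields an ``unmerged`` flag.
    """
    if not pair.fwd_seq or not pair.rev_seq:
        raise ValueError("both mates must be non-empty")
    fwd = pair.fwd_seq.upper()
    rc = revcomp(pair.rev_seq)
    rq = tuple(reversed(pair.rev_qual))
    best = None  # (matches, overlap_len, -offset)
    for offset in range(len(fwd)):
        overlap = min(len(fwd) - offset, len(rc))
        if overlap < min_overlap:
            continue
        matches = sum(fwd[offset + i] == rc[i] for i in range(overlap))
        if (overlap - matches) / overlap > max_overlap_mismatch_frac:
            continue
        key = (matches, overlap, -offset)
        if best is None or key > best[0]:
            best = (key, offset, overlap)
    if best is None:
        return MergedRead(pair.read_id, "", pair.sample, qc_flags=frozenset({"unmerged"}))
    _, offset, overlap = best
    consensus = []
    for i in range(overlap):
        a, b = fwd[offset + i], rc[i]
        if a == b:
            consensus.append(a)
        else:
            consensus.append(a if pair.fwd_qual[offset + i] >= rq[i] else b)
    if offset + len(rc) >= len(fwd):
        merged = fwd[:offset] + "".join(consensus) + rc[overlap:]
    else:  # reverse mate contained within the forward mate
        merged = fwd[:offset] + "".join(consensus) + fwd[offset + overlap:]
    return MergedRead(pair.read_id, merged, pair.sample)


def filter_ns(read: MergedRead | str) -> bool:
    """Pass iff the sequence contains no ``N``."""
    seq = read.sequence if isinstance(read, MergedRead) else read
    return "N" not in seq.upper()


def filter_homopolymer(read: MergedRead | str, max_run: int = 7) -> bool:
    """Pass iff no single-base run is strictly longer than ``max_run``."""
    seq = read.sequence if isinstance(read, MergedRead) else read
    return re.search(r"(.)\1{%d,}" % max_run, seq.upper()) is None


def _terminal_mismatches(seq: str, pair: PrimerPair) -> Optional[tuple[int, int]]:
    """(fwd_mm, rev_mm) of the primer footprints at the read termini, or
    None if the read is shorter than the two footprints."""
    lf, lr = len(pair.fwd), len(pair.rev)
    if len(seq) < lf + lr:
        return None
    fwd_mm = match_window(pair.fwd, seq[:lf])
    rev_mm = match_window(revcomp(pair.rev.sequence), seq[-lr:])
    return fwd_mm, rev_mm


def locate_trim_primers(
    read: MergedRead,
    pair: PrimerPair,
    max_mm_per_primer: int = 2,
) -> MergedRead:
    """Match both primers at the read termini, normalise orientation and trim.

    The forward primer is expected at the 5' end and the reverse complement
    of the reverse primer at the 3' end; the reverse-complemented read is
    also tried and the better orientation kept. More than
    ``max_mm_per_primer`` mismatches in either footprint flags the read
    ``primer_mismatch``; reads shorter than the two footprints are
    ``too_short``.
    """
    seq = read.sequence.upper()
    candidates = []
    for oriented in (seq, revcomp(seq)):
        mm = _terminal_mismatches(oriented, pair)
        if mm is not None:
            candidates.append((mm[0] + mm[1], mm, oriented))
    if not candidates:
        return read.with_flag("too_short")
    candidates.sort(key=lambda c: c[0])
    _, (fwd_mm, rev_mm), oriented = candidates[0]
    if fwd_mm > max_mm_per_primer or rev_mm > max_mm_per_primer:
        return read.with_flag("primer_mismatch")
    insert = oriented[len(pair.fwd): len(oriented) - len(pair.rev)]
    return replace(read, sequence=insert, trimmed=True, family=pair.family)


def truncate_forward(
    read: MergedRead,
    fwd_primer: DegeneratePrimer,
    length: int = 210,
    max_mm: int = 2,
) -> MergedRead:
    """Keep exactly ``length`` nt immediately after the forward primer.

    Used for products too long to merge (GH7): the unmerged forward read is
    anchored at its 5' primer footprint and truncated. Reads with fewer than
    ``length`` nt after the footprint are flagged ``too_short``.
    """
    seq = read.sequence.upper()
    lf = len(fwd_primer)
    if len(seq) < lf or match_window(fwd_primer, seq[:lf]) > max_mm:
        raise ValueError(f"{read.read_id}: forward primer not found at the 5' terminus")
    insert = seq[lf: lf + length]
    if len(insert) < length:
        return read.with_flag("too_short")
    return replace(read, sequence=insert, trimmed=True, family=fwd_primer.family)


def assign_family(
    fwd_seq: str,
    pairs: Sequence[PrimerPair],
    max_mm: int = 2,
) -> Optional[str]:
    """Assign a raw forward read to a gene family by its 5' primer footprint.

    The best-scoring forward primer wins; ties or no primer within
    ``max_mm`` return None (ambiguous/unassigned). Libraries pool several
    families per run, so assignment happens before merging.
    """
    seq = fwd_seq.upper()
    scores = []
    for pair in pairs:
        lf = len(pair.fwd)
        if len(seq) < lf:
            continue
        scores.append((match_window(pair.fwd, seq[:lf]), pair.family))
    scores.sort()
    if not scores or scores[0][0] > max_mm:
        return None
    if len(scores) > 1 and scores[1][0] == scores[0][0]:
        return None
    return scores[0][1]
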