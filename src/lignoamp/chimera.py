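"""Dereplication and abundance-aware bimera (two-parent chimera) screening.

PCR chimeras arise when an incompletely extended product primes a second,
different template; the resulting read is a two-segment mosaic of two
"parent" sequences that are both more abundant than the chimera itself.
The screen below exploits exactly that signal: for each dereplicated query
it asks whether some breakpoint splits it into a left segment near-identical
to one sufficiently-more-abundant unique and a right segment near-identical
to another, and whether that two-parent model explains the query markedly
better than the best single parent does.

This is a deliberately compact functional substitute for k-mer-chunked
reference-free chimera detectors: the screen is a filter here, not the
object of study. Queries are compared against equal-length candidates only
(the pipeline is substitution-centric and per-family amplicon lengths are
fixed).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["UniqueSequence", "BimeraVerdict", "dereplicate", "detect_bimeras"]


@dataclass(frozen=True)
class UniqueSequence:
    sequence: str
    abundance: int
    sample: str = ""
    ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class BimeraVerdict:
    query: UniqueSequence
    is_chimeric: bool
    parent_a: Optional[str] = None
    parent_b: Optional[str] = None
    breakpoint: Optional[int] = None
    score: float = 0.0


def dereplicate(reads: Iterable[tuple[str, str]], sample: str = "") -> list[UniqueSequence]:
    """Group exact duplicate sequences; sort by descending abundance.

    ``reads`` yields (read_id, sequence). Ties in abundance are broken
    lexicographically by sequence, so the output is invariant to input
    permutation.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for read_id, seq in reads:
        groups[seq.upper()].append(read_id)
    uniques = [
        UniqueSequence(seq, len(ids), sample, tuple(sorted(ids)))
        for seq, ids in groups.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def detect_bimeras(
    uniques: Sequence[UniqueSequence],
    min_parent_skew: float = 2.0,
    min_segment_identity: float = 0.99,
    min_score_margin: int = 2,
) -> list[BimeraVerdict]:
    """Flag uniques explainable as two-parent mosaics of more abundant ones.

    For each query, candidate parents are uniques with abundance >=
    ``min_parent_skew`` x the query's. The query is chimeric iff some
    breakpoint yields left/right segments each >= ``min_segment_identity``
    identical to (possibly different) parents, and the two-parent model
    explains at least ``min_score_margin`` more positions than the best
    single parent. Verdicts are deterministic and invariant to input order
    (uniques are re-sorted defensively).
    """
    uniques = sorted(uniques, key=lambda u: (-u.abundance, u.sequence))
    verdicts: list[BimeraVerdict] = []
    for qi, q in enumerate(uniques):
        candidates = [
            u for u in uniques
            if u.abundance >= min_parent_skew * q.abundance
            and u.sequence != q.sequence
            and len(u.sequence) == len(q.sequence)
        ]
        if len(candidates) < 2:
            verdicts.append(BimeraVerdict(q, False))
            continue
        L = len(q.sequence)
        qarr = np.frombuffer(q.sequence.encode(), dtype=np.uint8)
        # match[i, j] = 1 if candidate i agrees with the query at position j
        match = np.stack([
            qarr == np.frombuffer(c.sequence.encode(), dtype=np.uint8)
            for c in candidates
        ]).astype(np.int32)
        prefix = np.concatenate(
            [np.zeros((len(candidates), 1), dtype=np.int32), np.cumsum(match, axis=1)],
            axis=1,
        )
        totals = prefix[:, -1]
        best_single = int(totals.max())
        best = None  # (two_parent_matches, -breakpoint, ia, ib)
        for k in range(1, L):
            left = prefix[:, k]
            right = totals - left
            ia = int(left.argmax())
            ib = int(right.argmax())
            if ia == ib:
                # force two distinct parents: take the better swap of runner-ups
                order_l = np.argsort(-left, kind="stable")
                order_r = np.argsort(-right, kind="stable")
                alt_a = (int(order_l[1]), ib) if len(order_l) > 1 else None
                alt_b = (ia, int(order_r[1])) if len(order_r) > 1 else None
                options = []
                if alt_a is not None:
                    options.append((left[alt_a[0]] + right[alt_a[1]], alt_a))
                if alt_b is not None:
                    options.append((left[alt_b[0]] + right[alt_b[1]], alt_b))
                if not options:
                    continue
                score, (ia, ib) = max(options, key=lambda o: o[0])
            if left[ia] / k < min_segment_identity or right[ib] / (L - k) < min_segment_identity:
                continue
            key = (int(left[ia] + right[ib]), -k, ia, ib)
            if best is None or key > best:
                best = key
        if best is None:
            verdicts.append(BimeraVerdict(q, False))
            continue
        two_parent, neg_k, ia, ib = best
        gain = two_parent - best_single
        if gain >= min_score_margin:
            verdicts.append(
                BimeraVerdict(
                    q, True,
                    parent_a=candidates[ia].sequence[:12],
                    parent_b=candidates[ib].sequence[:12],
                    breakpoint=-neg_k,
                    score=float(gain),
                )
            )
        else:
            verdicts.append(BimeraVerdict(q, False))
    return verdicts
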