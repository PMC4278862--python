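"""Identity-based greedy clustering and the empirical cutoff-selection rule.

Coding gene families evolve at different rates, so no single identity
cutoff suits them all. The rule implemented here picks the cutoff
empirically from the data: cluster the unique sequences at every
dissimilarity d on a 0-15% grid (1-point steps), plot the cluster count
N(d), and select the first d where the drop between successive steps,
|N(d) - N(d-1)|, falls below a fixed fraction (default 6%) of N(0) - the
"beginning of the plateau" of the cluster-count curve.

Identity between two sequences is computed from a global alignment with
free terminal gaps (match +1, mismatch -1, gap open -2, gap extend -1):
matches divided by aligned columns, excluding terminal-gap columns.
Terminal gaps are excluded because amplicons may be deliberately truncated
(the 210-nt GH7 fragments); internal gaps count as mismatch columns.

Clustering is greedy over abundance-sorted uniques: each sequence joins the
first cluster whose representative it matches at or above the cutoff, else
seeds a new cluster. The representative is the most abundant member (ties:
lexicographically smallest sequence), matching the convention that the most
abundant sequence represents its cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .chimera import UniqueSequence

__all__ = [
    "SequenceCluster",
    "ClusterCountCurve",
    "AbundanceTable",
    "pairwise_identity",
    "cluster_greedy",
    "cluster_count_curve",
    "select_cutoff",
    "SelectedCutoff",
    "build_abundance_table",
    "remove_singletons",
    "shared_cluster_stats",
    "abundance_concentration",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # terminal gaps free
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def _alignment_stats(a: str, b: str) -> tuple[int, int]:
    """(matches, columns) over the aligned span, terminal gaps excluded."""
    aln = _ALIGNER.align(a, b)[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    columns = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            columns += (ts - prev_t_end) + (qs - prev_q_end)  # internal gap columns
        for i in range(te - ts):
            columns += 1
            if a[ts + i] == b[qs + i]:
                matches += 1
        prev_t_end, prev_q_end = te, qe
    return matches, columns


@lru_cache(maxsize=1_000_000)
def _identity_cached(a: str, b: str) -> float:
    matches, columns = _alignment_stats(a, b)
    # Floor the denominator at the shorter sequence length: with free
    # terminal gaps the score-optimal alignment of two unrelated sequences
    # can span a handful of columns, which would inflate identity. A truly
    # contained/truncated sequence still reaches 1.0 (span = its length).
    columns = max(columns, min(len(a), len(b)))
    return matches / columns if columns else 0.0


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions over the aligned span of a and b."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    if a > b:  # symmetric; canonicalise for the cache
        a, b = b, a
    return _identity_cached(a, b)


@dataclass
class SequenceCluster:
    cluster_id: str
    representative: str
    members: list[tuple[str, int, str]]  # (sequence, abundance, sample)

    @property
    def total_abundance(self) -> int:
        return sum(m[1] for m in self.members)

    @property
    def per_sample_abundance(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, abundance, sample in self.members:
            out[sample] = out.get(sample, 0) + abundance
        return out

    def _refresh_representative(self) -> None:
        by_seq: dict[str, int] = {}
        for seq, abundance, _ in self.members:
            by_seq[seq] = by_seq.get(seq, 0) + abundance
        self.representative = min(by_seq, key=lambda s: (-by_seq[s], s))


def cluster_greedy(
    uniques: Sequence[UniqueSequence],
    cutoff_identity: float,
) -> list[SequenceCluster]:
    """Greedy incremental clustering of abundance-sorted uniques.

    Each sequence joins the first existing cluster whose representative has
    identity >= ``cutoff_identity``, else seeds a new cluster. Deterministic
    given the dereplication order (descending abundance, lexicographic
    tie-break).
    """
    ordered = sorted(uniques, key=lambda u: (-u.abundance, u.sequence))
    clusters: list[SequenceCluster] = []
    for u in ordered:
        placed = False
        for cl in clusters:
            if pairwise_identity(u.sequence, cl.representative) >= cutoff_identity:
                cl.members.append((u.sequence, u.abundance, u.sample))
                placed = True
                break
        if not placed:
            clusters.append(
                SequenceCluster(
                    f"cluster_{len(clusters) + 1:04d}",
                    u.sequence,
                    [(u.sequence, u.abundance, u.sample)],
                )
            )
    for cl in clusters:
        cl._refresh_representative()
    return clusters


@dataclass(frozen=True)
class ClusterCountCurve:
    dissimilarity_grid: tuple[int, ...]  # percent dissimilarity
    counts: tuple[int, ...]  # N(d)

    def __post_init__(self) -> None:
        if len(self.dissimilarity_grid) != len(self.counts):
            raise ValueError("grid and counts must have equal length")

    @property
    def deltas(self) -> tuple[int, ...]:
        """Delta(d) = N(d) - N(d - step), one value per grid step."""
        return tuple(
            self.counts[i] - self.counts[i - 1] for i in range(1, len(self.counts))
        )

    def to_frame(self) -> pd.DataFrame:
        deltas = (np.nan,) + self.deltas
        return pd.DataFrame(
            {"dissimilarity_pct": self.dissimilarity_grid, "n_clusters": self.counts, "delta": deltas}
        )


def cluster_count_curve(
    uniques: Sequence[UniqueSequence],
    d_grid: Sequence[int] = tuple(range(0, 16)),
) -> ClusterCountCurve:
    """Cluster counts N(d) across a grid of percent dissimilarities."""
    if not uniques:
        raise ValueError("cluster_count_curve requires at least one sequence")
    counts = tuple(
        len(cluster_greedy(uniques, (100 - d) / 100.0)) for d in d_grid
    )
    return ClusterCountCurve(tuple(int(d) for d in d_grid), counts)


@dataclass(frozen=True)
class SelectedCutoff:
    dissimilarity_pct: int
    identity: float
    plateau_found: bool


def select_cutoff(curve: ClusterCountCurve, plateau_frac: float = 0.06) -> SelectedCutoff:
    """Pick the clustering cutoff at the start of the curve's plateau.

    Returns the smallest grid dissimilarity d >= one step where
    |N(d) - N(d-step)| < plateau_frac * N(0). If no step qualifies, the
    largest grid value is returned flagged ``plateau_found=False``.
    """
    if len(curve.counts) < 2:
        raise ValueError("curve must contain at least two grid points")
    n0 = curve.counts[0]
    for i in range(1, len(curve.counts)):
        if abs(curve.counts[i] - curve.counts[i - 1]) < plateau_frac * n0:
            d = curve.dissimilarity_grid[i]
            return SelectedCutoff(d, (100 - d) / 100.0, True)
    d = curve.dissimilarity_grid[-1]
    return SelectedCutoff(d, (100 - d) / 100.0, False)


class AbundanceTable:
    """Clusters x samples count matrix with per-sample richness summaries."""

    def __init__(self, counts: pd.DataFrame):
        if (counts.values < 0).any():
            raise ValueError("abundance counts must be non-negative")
        self.counts = counts.astype(int)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def sample_vector(self, sample: str) -> np.ndarray:
        if sample not in self.counts.columns:
            raise KeyError(f"unknown sample {sample!r}")
        v = self.counts[sample].to_numpy()
        return v[v > 0]

    def s_obs(self, sample: str) -> int:
        return int((self.counts[sample] > 0).sum())

    def f1(self, sample: str) -> int:
        return int((self.counts[sample] == 1).sum())

    def f2(self, sample: str) -> int:
        return int((self.counts[sample] == 2).sum())

    def total(self, sample: str) -> int:
        return int(self.counts[sample].sum())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="cluster_id")


def build_abundance_table(
    clusters: Sequence[SequenceCluster],
    samples: Optional[Sequence[str]] = None,
) -> AbundanceTable:
    if samples is None:
        seen: list[str] = []
        for cl in clusters:
            for s in cl.per_sample_abundance:
                if s not in seen:
                    seen.append(s)
        samples = seen
    rows = {
        cl.cluster_id: {s: cl.per_sample_abundance.get(s, 0) for s in samples}
        for cl in clusters
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(samples)).fillna(0)
    return AbundanceTable(frame)


def remove_singletons(table: AbundanceTable) -> AbundanceTable:
    """Drop clusters holding a single read overall (necessarily detected in
    only one sample); clusters with one read in each of several samples are
    retained."""
    if not table.samples:
        raise ValueError("abundance table has no sample columns")
    totals = table.counts.sum(axis=1)
    return AbundanceTable(table.counts.loc[totals > 1])


def shared_cluster_stats(
    table: AbundanceTable, sample_a: str, sample_b: str
) -> dict[str, float]:
    """Percent of clusters, and of sequences, shared between two samples."""
    for s in (sample_a, sample_b):
        if s not in table.counts.columns:
            raise KeyError(f"unknown sample {s!r}")
    a = table.counts[sample_a]
    b = table.counts[sample_b]
    present = (a > 0) | (b > 0)
    shared = (a > 0) & (b > 0)
    n_total = int(present.sum())
    total_reads = int(a.sum() + b.sum())
    shared_reads = int(a[shared].sum() + b[shared].sum())
    return {
        "shared_cluster_pct": 100.0 * int(shared.sum()) / n_total if n_total else 0.0,
        "shared_sequence_pct": 100.0 * shared_reads / total_reads if total_reads else 0.0,
    }


def abundance_concentration(table: AbundanceTable, mass_frac: float = 0.75) -> float:
    """Fraction of clusters that jointly hold ``mass_frac`` of all reads.

    Clusters are ranked by descending total abundance; returns k/K where k
    is the minimal number of top clusters whose cumulative share reaches
    ``mass_frac``.
    """
    totals = table.counts.sum(axis=1).sort_values(ascending=False).to_numpy()
    if totals.size == 0 or totals.sum() == 0:
        raise ValueError("abundance_concentration requires a non-empty table")
    cumulative = np.cumsum(totals) / totals.sum()
    k = int(np.searchsorted(cumulative, mass_frac) + 1)
    return k / totals.size
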