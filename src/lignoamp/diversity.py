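"""Equal-depth rarefaction, Shannon and Chao1 diversity estimators.

Sequencing effort differs between samples, so all indices are computed on
random subsamples rarefied to a common depth - the lowest read count among
the samples being compared. Indices are reported as means (with standard
deviations) over repeated rarefactions, both with and without singleton
clusters, so the effect of the singleton policy on diversity is visible.

Conventions: Shannon uses the natural logarithm; Chao1 defaults to the
bias-corrected form S_obs + F1(F1-1)/(2(F2+1)), with the classic form
S_obs + F1^2/(2 F2) available (falling back to bias-corrected when F2 = 0,
where the classic form is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import AbundanceTable, remove_singletons

__all__ = ["rarefy", "shannon", "chao1", "diversity_report"]


def _as_counts(v) -> np.ndarray:
    counts = np.asarray(v, dtype=np.int64)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("abundance vector must be 1-D and non-negative")
    return counts


def rarefy(v, depth: int, rng: np.random.Generator | int) -> np.ndarray:
    """Uniform subsample of ``depth`` individuals without replacement.

    Implemented as a multivariate hypergeometric draw over the cluster
    counts; the result sums to ``depth`` exactly and is reproducible under
    a fixed seed.
    """
    counts = _as_counts(v)
    if depth > counts.sum():
        raise ValueError(f"depth {depth} exceeds total count {counts.sum()}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.multivariate_hypergeometric(counts, depth)


def shannon(v) -> float:
    """Shannon index H = -sum p_i ln p_i (natural log)."""
    counts = _as_counts(v)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("shannon requires a non-empty abundance vector")
    return float(stats.entropy(counts))


def chao1(v, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts."""
    counts = _as_counts(v)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("chao1 requires at least one observed cluster")
    s_obs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if not bias_corrected and f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def diversity_report(
    table: AbundanceTable,
    repetitions: int = 100,
    seed: int = 0,
    bias_corrected: bool = True,
) -> pd.DataFrame:
    """Rarefied Shannon/Chao1 summary per sample, with and without singletons.

    For each variant ({with, without} singletons) every sample is rarefied
    ``repetitions`` times to the minimum total of that variant across
    samples; means and standard deviations of both indices are reported.
    """
    if len(table.samples) < 2:
        raise ValueError("diversity_report requires at least two samples")
    rng = np.random.default_rng(seed)
    rows = []
    for variant, tbl in (
        ("with_singletons", table),
        ("without_singletons", remove_singletons(table)),
    ):
        depth = min(tbl.total(s) for s in tbl.samples)
        for sample in tbl.samples:
            counts = tbl.sample_vector(sample)
            h = np.empty(repetitions)
            c = np.empty(repetitions)
            s_sub = np.empty(repetitions)
            for i in range(repetitions):
                sub = rarefy(counts, depth, rng)
                sub = sub[sub > 0]
                h[i] = shannon(sub)
                c[i] = chao1(sub, bias_corrected=bias_corrected)
                s_sub[i] = sub.size
            rows.append(
                {
                    "sample": sample,
                    "variant": variant,
                    "total_sequences": int(counts.sum()),
                    "s_obs": int(counts.size),
                    "subsample_depth": int(depth),
                    "subsample_clusters_mean": float(s_sub.mean()),
                    "shannon_mean": float(h.mean()),
                    "shannon_sd": float(h.std(ddof=0)),
                    "chao1_mean": float(c.mean()),
                    "chao1_sd": float(c.std(ddof=0)),
                    "repetitions": repetitions,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
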