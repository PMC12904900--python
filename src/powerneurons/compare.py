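"""Nonparametric comparison of centrality distributions between connectomes.

Centralities are first normalized (degree by its maximum possible value
2(n-1) in a simple digraph, betweenness by the directed ordered-pair count
(n-1)(n-2); closeness and eigenvector are already on [0,1] scales), then
log-transformed with log10(1+x). Samples are compared with two-sided
two-sample Kolmogorov–Smirnov and Mann–Whitney U tests, Benjamini–Hochberg
adjustment across the four centralities, Cliff's delta as the effect size,
and medians per sample. A subsampling check guards against sample-size
artifacts when one network is much larger than the other.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .model import ValidationError

NORMALIZATION_MODES = ("theoretical_max", "observed_max", "identity")


def normalize_centrality(
    values: Mapping[str, float] | Sequence[float],
    kind: str,
    n: int,
    mode: str = "theoretical_max",
) -> np.ndarray:
    """Scale centrality values onto comparable [0, ~1] ranges.

    ``theoretical_max`` divides total degree by 2(n-1) and betweenness by
    (n-1)(n-2); closeness and eigenvector pass through unchanged (their
    conventions already bound them). ``observed_max`` divides by the sample
    maximum; ``identity`` passes everything through.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    if kind not in ("degree", "in_degree", "out_degree", "closeness", "betweenness", "eigenvector"):
        raise ValidationError(f"unknown centrality kind {kind!r}")
    if n < 2:
        raise ValidationError("n must be >= 2 for normalization")
    arr = np.asarray(
        list(values.values()) if isinstance(values, Mapping) else values, dtype=float
    )
    if mode == "identity":
        return arr
    if mode == "observed_max":
        maximum = arr.max() if arr.size else 0.0
        return arr / maximum if maximum > 0 else arr
    if kind == "degree":
        return arr / (2.0 * (n - 1))
    if kind in ("in_degree", "out_degree"):
        return arr / (n - 1.0)
    if kind == "betweenness":
        return arr / ((n - 1.0) * (n - 2.0))
    return arr  # closeness / eigenvector: already normalized


def log_transform(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Elementwise log10(1 + x); strictly monotone, so rank statistics survive."""
    arr = np.asarray(values, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValidationError("log transform requires non-negative values")
    return np.log10(1.0 + arr)


@dataclass
class ComparisonResult:
    centrality_name: str
    ks_D: float
    ks_p: float
    mwu_U: float
    mwu_p_raw: float
    mwu_p_adjusted: float
    cliffs_delta: float
    median_a: float
    median_b: float

    def to_dict(self) -> dict:
        return asdict(self)


def cliffs_delta_from_u(u_stat: float, n_a: int, n_b: int) -> float:
    """delta = 2U/(n_a n_b) - 1 with U counting (a>b) + 0.5(a=b) pairs."""
    return 2.0 * u_stat / (n_a * n_b) - 1.0


def compare_distributions(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    name: str = "",
) -> ComparisonResult:
    """Two-sided KS and Mann-Whitney U comparison of two value samples.

    The U statistic reported is for ``sample_a`` (pairs where a exceeds b,
    ties counted half), so a fully dominated ``sample_a`` gives U = 0 and
    Cliff's delta = -1. The exact Mann-Whitney null is used for small
    tie-free samples (both sides <= 50), the tie-corrected normal
    approximation otherwise. ``mwu_p_adjusted`` is filled by the caller
    (see :func:`bh_adjust`); here it equals the raw p.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both samples need at least 2 values")
    ks = scipy.stats.ks_2samp(a, b, alternative="two-sided")
    has_ties = np.intersect1d(a, b).size > 0 or a.size != np.unique(a).size or b.size != np.unique(b).size
    method = "exact" if (max(a.size, b.size) <= 50 and not has_ties) else "asymptotic"
    mwu = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    delta = cliffs_delta_from_u(float(mwu.statistic), a.size, b.size)
    return ComparisonResult(
        centrality_name=name,
        ks_D=float(ks.statistic),
        ks_p=float(ks.pvalue),
        mwu_U=float(mwu.statistic),
        mwu_p_raw=float(mwu.pvalue),
        mwu_p_adjusted=float(mwu.pvalue),
        cliffs_delta=delta,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def compare_centrality_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    normalization: str = "theoretical_max",
    log_scale: bool = True,
) -> list[ComparisonResult]:
    """Full four-centrality comparison pipeline between two networks.

    Normalizes each centrality, applies log10(1+x), compares, then adjusts
    the four Mann-Whitney p-values jointly with Benjamini–Hochberg.
    """
    results = []
    for kind in ("degree", "closeness", "betweenness", "eigenvector"):
        a = normalize_centrality(table_a[kind].to_numpy(), kind, len(table_a), normalization)
        b = normalize_centrality(table_b[kind].to_numpy(), kind, len(table_b), normalization)
        if log_scale:
            a, b = log_transform(a), log_transform(b)
        results.append(compare_distributions(a, b, name=kind))
    adjusted = bh_adjust([r.mwu_p_raw for r in results])
    for res, p_adj in zip(results, adjusted):
        res.mwu_p_adjusted = float(p_adj)
    return results


@dataclass
class SubsampleReport:
    n_sub: int
    reps: int
    ks_D_mean: float
    ks_D_std: float
    frac_p_below: float
    threshold: float
    seed: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def subsample_ks(
    values_large: Sequence[float],
    values_small: Sequence[float],
    n_sub: int,
    reps: int = 500,
    p_threshold: float = 0.001,
    seed: int | None = None,
) -> SubsampleReport:
    """Repeatedly subsample the larger network's values and re-run the KS test.

    Each repetition draws ``n_sub`` values without replacement from
    ``values_large`` (each node keeps its full-network centrality; degrees
    are not recomputed on an induced subgraph) and compares them with
    ``values_small``. Reports the mean and standard deviation of the KS D
    statistic and the fraction of repetitions with p below the threshold.
    """
    large = np.asarray(values_large, dtype=float)
    small = np.asarray(values_small, dtype=float)
    if n_sub > large.size:
        raise ValidationError(
            f"n_sub={n_sub} exceeds the population size {large.size}"
        )
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    d_values = np.empty(reps)
    p_below = 0
    for i in range(reps):
        draw = rng.choice(large, size=n_sub, replace=False)
        ks = scipy.stats.ks_2samp(draw, small, alternative="two-sided")
        d_values[i] = ks.statistic
        if ks.pvalue < p_threshold:
            p_below += 1
    return SubsampleReport(
        n_sub=n_sub,
        reps=reps,
        ks_D_mean=float(d_values.mean()),
        ks_D_std=float(d_values.std()),
        frac_p_below=p_below / reps,
        threshold=p_threshold,
        seed=seed,
    )


def percentile_composition(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    percentile: float = 95.0,
) -> tuple[float, float]:
    """Fractions of each sample strictly above the pooled percentile cutoff.

    The cutoff is the linearly interpolated percentile of the pooled
    sample; exceedance is strict.
    """
    if not 0 < percentile < 100:
        raise ValidationError("percentile must lie in (0, 100)")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    cutoff = np.percentile(np.concatenate([a, b]), percentile)
    return (
        float(np.count_nonzero(a > cutoff) / a.size),
        float(np.count_nonzero(b > cutoff) / b.size),
    )


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
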