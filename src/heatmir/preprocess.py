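"""Data-quality filtering and two-step normalization.

The pipeline mirrors the microarray vendor workflow: probes must be called
present (flag P) in a minimum number of samples; intensities are quantile
normalized so every sample shares one distribution; each probe is then
centered on its median across all samples ("baseline to median"), so
downstream fold changes read directly as deviations from a probe's typical
level.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from heatmir.containers import ExpressionMatrix
from heatmir.errors import ConfigError


def default_min_present(n_samples: int) -> int:
    """The present-call threshold: ceil(0.6 * n_samples).

    Generalizes the study design's "at least 6 of 10 samples" so the rule
    scales to simulated designs of any size.
    """
    return math.ceil(0.6 * n_samples)


def filter_by_flags(m: ExpressionMatrix, min_present: int | None = None) -> ExpressionMatrix:
    """Keep probes with >= ``min_present`` P (present) flags; order preserved."""
    if m.flags is None:
        raise ConfigError("flag filtering requested but the matrix has no flags")
    n = len(m.sample_ids)
    if min_present is None:
        min_present = default_min_present(n)
    if not 0 <= min_present <= n:
        raise ConfigError(f"min_present={min_present} outside [0, {n}]")
    p_counts = (m.flags == "P").sum(axis=1)
    keep = m.probe_ids if min_present == 0 else list(p_counts.index[p_counts >= min_present])
    return m.subset_probes([p for p in m.probe_ids if p in set(keep)])


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples to the mean order-statistic distribution.

    After normalization every sample's sorted value vector equals the
    cross-sample mean of order statistics; within-sample rank order is
    preserved.  Tied values receive the mean of the target quantiles their
    tied block spans, so the result is deterministic and permutation
    invariant (with ties, sorted columns therefore agree only up to the
    tie averaging; on tie-free data they are exactly equal).  Probes with
    any missing value must be removed beforehand.
    """
    values = m.values
    if values.shape[1] < 2:
        raise ConfigError("quantile normalization needs at least 2 samples")
    if values.isna().any().any():
        raise ConfigError("missing values present; drop incomplete probes first")
    arr = values.to_numpy(dtype=float)
    target = np.sort(arr, axis=0).mean(axis=1)  # mean order statistics
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = target
        # average target quantiles within tied blocks
        ranks = rankdata(col, method="dense")
        sums = np.bincount(ranks, weights=assigned)
        counts = np.bincount(ranks)
        out[:, j] = sums[ranks] / counts[ranks]
    return m.with_values(pd.DataFrame(out, index=values.index, columns=values.columns))


def baseline_to_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each probe on its median across all samples (idempotent)."""
    values = m.values
    centered = values.sub(values.median(axis=1), axis=0)
    return m.with_values(centered)


def log2_transform(values: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """log2-transform raw-scale intensities, clipping at ``floor`` first.

    The clip avoids -inf from zero or negative background-subtracted cells.
    """
    if floor <= 0:
        raise ConfigError("log floor must be positive")
    return np.log2(values.clip(lower=floor))
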