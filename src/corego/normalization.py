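"""Library-size and distributional normalization of count matrices.

Implements trimmed-mean-of-M-values (TMM) scaling factors following the
published algorithm: per-gene M (log2 ratio of library-scaled proportions)
and A (average log2 abundance) against a reference sample, double trimming
(30% of the M tails, 5% of the A tails by default), a precision-weighted
mean of the surviving M values with inverse asymptotic binomial variances as
weights, and a final rescaling so the factors' geometric mean is 1. CPM uses
TMM-effective library sizes (raw library x factor) throughout the package.

Percentile/quantile computation everywhere uses linear interpolation between
order statistics (numpy's default), so cross-module conventions cannot
drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .formats_io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "tmm_factors",
    "cpm",
    "log2_plus_one",
    "quantile_normalize",
    "tmm_cpm",
]


@dataclass
class NormalizedMatrix:
    """CPM or log2 values with the scaling metadata that produced them."""

    values: pd.DataFrame
    tmm_factors: pd.Series
    effective_library: pd.Series
    design: pd.DataFrame
    kind: str = "cpm"  # "cpm" or "log2"

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    a_cutoff: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        log_r = np.log2(p_obs / p_ref)
        abs_e = 0.5 * np.log2(p_obs * p_ref)
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    a_cutoff: float = -1e10,
    reference: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile library-scaled
    count is closest to the mean 75th percentile across samples, unless
    ``reference`` names one explicitly. Genes with zero counts in either
    member of a pair are excluded from the M/A computation; ``a_cutoff``
    (default off) drops low-abundance genes by their A-value.
    """
    mat = counts.counts.to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    zero = libs <= 0
    if zero.any():
        bad = counts.sample_ids[zero][0]
        raise ValueError(f"sample {bad!r} has an all-zero library")
    if mat.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")

    f75 = np.quantile(mat / libs, 0.75, axis=0)
    if reference is None:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = int(counts.sample_ids.get_loc(reference))

    factors = np.empty(mat.shape[1])
    for k in range(mat.shape[1]):
        if k == ref_idx:
            factors[k] = 1.0
        else:
            factors[k] = _tmm_pair_factor(
                mat[:, k], mat[:, ref_idx], libs[k], libs[ref_idx],
                trim_m, trim_a, a_cutoff,
            )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def cpm(counts: CountMatrix, factors: pd.Series | None = None) -> NormalizedMatrix:
    """Counts per million on TMM-effective library sizes.

    value = count / (library x factor) x 1e6. With ``factors=None`` the TMM
    factors are computed here.
    """
    if factors is None:
        factors = tmm_factors(counts)
    factors = factors.reindex(counts.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("need one positive factor per sample")
    eff = counts.library_sizes.astype(float) * factors
    values = counts.counts.astype(float).div(eff, axis=1) * 1e6
    return NormalizedMatrix(
        values=values,
        tmm_factors=factors,
        effective_library=eff.rename("effective_library"),
        design=counts.design,
        kind="cpm",
    )


def log2_plus_one(values: pd.DataFrame | np.ndarray):
    """Elementwise log2(value + 1); rejects negative input."""
    arr = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values)
    if (arr < 0).any():
        raise ValueError("log2_plus_one requires non-negative values")
    out = np.log2(arr + 1.0)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def tmm_cpm(counts: CountMatrix, log2: bool = False) -> NormalizedMatrix:
    """Convenience: TMM factors -> CPM, optionally log2(CPM + 1)."""
    norm = cpm(counts)
    if log2:
        norm = NormalizedMatrix(
            values=log2_plus_one(norm.values),
            tmm_factors=norm.tmm_factors,
            effective_library=norm.effective_library,
            design=norm.design,
            kind="log2",
        )
    return norm


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the across-column mean distribution.

    Each column's sorted values are replaced by the mean of the sorted
    columns; original ranks are restored and ties receive the mean of the
    reference values their positions span. Idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization requires >= 2 columns")
    arr = matrix.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col_sorted = arr[order, j]
        assigned = ref.copy()
        # average reference values over runs of tied input values
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    assigned[start:i] = ref[start:i].mean()
                start = i
        out[order, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
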