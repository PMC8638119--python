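"""Between-sample normalization by the trimmed mean of M-values (TMM).

Per-sample scaling factors are computed from gene-wise log-expression
ratios (M-values) against a reference sample, after excluding genes with a
zero in either sample and double-trimming by M and by average log-abundance
(A), weighting the surviving genes by their inverse asymptotic variance.
Factors are rescaled to geometric mean 1 and expression is reported as
factor-corrected counts-per-million.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05


@dataclass(frozen=True)
class NormalizationResult:
    factors: pd.Series          # per-sample TMM factors, geometric mean 1
    normalized: pd.DataFrame    # factor-corrected per-million expression
    reference_sample: str


def _tmm_factor_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    obs, ref = obs[keep], ref[keep]
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M (delta method on binomial counts)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(f) if np.isfinite(f) else 0.0


def tmm_normalize(
    expr: pd.DataFrame,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
) -> NormalizationResult:
    """TMM-normalize a genes x samples nonnegative expression matrix.

    The reference sample is the one whose upper-quartile expression is
    closest to the mean upper-quartile across samples. Raises ValueError
    with fewer than two samples or an all-zero sample.
    """
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError("expression matrix must be nonnegative and finite")
    if expr.shape[1] < 2:
        raise ValueError("TMM normalization requires at least 2 samples")
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        bad = expr.columns[lib <= 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")

    uq = np.array(
        [np.quantile(values[:, j][values[:, j] > 0], 0.75) / lib[j]
         for j in range(values.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.array(
        [
            _tmm_factor_pair(
                values[:, j], values[:, ref_idx], lib[j], lib[ref_idx],
                trim_m, trim_a,
            )
            for j in range(values.shape[1])
        ]
    )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1

    normalized = values / (lib * factors)[np.newaxis, :] * 1e6
    return NormalizationResult(
        factors=pd.Series(factors, index=expr.columns, name="tmm_factor"),
        normalized=pd.DataFrame(
            normalized, index=expr.index, columns=expr.columns
        ),
        reference_sample=str(expr.columns[ref_idx]),
    )


def log_normalized_expression(norm: NormalizationResult) -> pd.DataFrame:
    """log2(normalized-per-million + 1), the scale used for mixture fitting."""
    return np.log2(norm.normalized + 1.0)
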