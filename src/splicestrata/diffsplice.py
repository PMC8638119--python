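"""Differential splicing between high and low expression strata.

Per event, delta-Psi is the difference of group-mean Psi (high minus low)
over non-missing entries; significance comes from a two-sided Mann-Whitney
rank-sum test (normal approximation with tie correction) with
Benjamini-Hochberg adjustment across tested events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import STRATUM_HIGH, STRATUM_LOW, StrataAssignment

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_DPSI = 0.1
DEFAULT_MIN_PER_GROUP = 5


@dataclass(frozen=True)
class DiffSplicingRecord:
    event_id: str
    event_type: str
    delta_psi: float
    p_value: float       # NaN when the event was excluded from testing
    adj_p: float
    n_high: int
    n_low: int
    significant: bool


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _event_types_from_ids(event_ids, catalog=None) -> dict[str, str]:
    if catalog is not None:
        return {ev.event_id: ev.event_type for ev in catalog}
    types = {}
    for eid in event_ids:
        try:
            types[eid] = eid.split(";", 1)[1].split(":", 1)[0]
        except IndexError:
            types[eid] = "NA"
    return types


def diff_psi(
    psi: pd.DataFrame,
    strata: StrataAssignment | pd.Series,
    alpha: float = DEFAULT_ALPHA,
    min_dpsi: float = DEFAULT_MIN_DPSI,
    min_per_group: int = DEFAULT_MIN_PER_GROUP,
    catalog=None,
) -> list[DiffSplicingRecord]:
    """Test every event for differential splicing between high and low strata.

    Events with fewer than ``min_per_group`` non-missing values in either
    group are excluded from testing (p reported as NaN). An event is called
    significant when its BH-adjusted p is below ``alpha`` and |delta-Psi|
    reaches ``min_dpsi``.
    """
    labels = strata.labels if isinstance(strata, StrataAssignment) else strata
    high = [s for s in psi.columns if labels.get(s) == STRATUM_HIGH]
    low = [s for s in psi.columns if labels.get(s) == STRATUM_LOW]
    if not high or not low:
        raise ValueError("both high and low strata must be non-empty")

    types = _event_types_from_ids(psi.index, catalog)
    hi_mat = psi[high].to_numpy(dtype=float)
    lo_mat = psi[low].to_numpy(dtype=float)

    raw_p: list[float] = []
    tested_idx: list[int] = []
    deltas = np.full(psi.shape[0], np.nan)
    n_hi = np.zeros(psi.shape[0], dtype=int)
    n_lo = np.zeros(psi.shape[0], dtype=int)
    for i in range(psi.shape[0]):
        hv = hi_mat[i][~np.isnan(hi_mat[i])]
        lv = lo_mat[i][~np.isnan(lo_mat[i])]
        n_hi[i], n_lo[i] = hv.size, lv.size
        if hv.size and lv.size:
            deltas[i] = hv.mean() - lv.mean()
        if hv.size < min_per_group or lv.size < min_per_group:
            continue
        if np.all(hv == hv[0]) and np.all(lv == lv[0]) and hv[0] == lv[0]:
            p = 1.0  # all observations tied across both groups
        else:
            p = float(
                stats.mannwhitneyu(
                    hv, lv, alternative="two-sided", method="asymptotic"
                ).pvalue
            )
        raw_p.append(min(max(p, np.finfo(float).tiny), 1.0))
        tested_idx.append(i)

    adj = bh_adjust(raw_p) if raw_p else np.array([])
    p_col = np.full(psi.shape[0], np.nan)
    adj_col = np.full(psi.shape[0], np.nan)
    p_col[tested_idx] = raw_p
    adj_col[tested_idx] = adj

    records = []
    for i, eid in enumerate(psi.index):
        sig = (
            np.isfinite(adj_col[i])
            and adj_col[i] < alpha
            and np.isfinite(deltas[i])
            and abs(deltas[i]) >= min_dpsi
        )
        records.append(
            DiffSplicingRecord(
                event_id=eid,
                event_type=types.get(eid, "NA"),
                delta_psi=float(deltas[i]),
                p_value=float(p_col[i]),
                adj_p=float(adj_col[i]),
                n_high=int(n_hi[i]),
                n_low=int(n_lo[i]),
                significant=bool(sig),
            )
        )
    return records


def diff_table(records: list[DiffSplicingRecord]) -> pd.DataFrame:
    """Volcano-ready results table (adds -log10 adjusted p)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if not df.empty:
        with np.errstate(divide="ignore"):
            df["neg_log10_adj_p"] = -np.log10(df["adj_p"])
    return df


def write_diff_tsv(records: list[DiffSplicingRecord], path) -> None:
    diff_table(records).to_csv(path, sep="\t", index=False, na_rep="NA")
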