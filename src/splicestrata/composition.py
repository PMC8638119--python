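"""Per-sample splicing-event composition and group comparison.

The composition statistic of sample s is the relative frequency
rf(event) = Psi(event, s) / sum_events Psi(event, s), computed over
non-missing events, and its aggregation by the seven event types. Type
compositions are compared between high and low strata with two-sided
rank-sum and two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffsplice import bh_adjust
from .events import EVENT_TYPES, SpliceEvent
from .mixture import STRATUM_HIGH, STRATUM_LOW, StrataAssignment

MIN_GROUP_SIZE_FOR_TESTS = 3


@dataclass(frozen=True)
class CompositionComparison:
    event_type: str
    mean_rf_high: float
    mean_rf_low: float
    wilcoxon_p: float
    ks_p: float
    significant: bool


def relative_frequency(
    psi: pd.DataFrame, catalog: Sequence[SpliceEvent]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample relative frequencies of events and of event types.

    Returns ``(rf_by_event, rf_by_type)``: events x samples and the seven
    types x samples. Missing Psi entries are excluded from numerator and
    denominator; samples with zero total Psi get all-NaN profiles.
    """
    if psi.empty:
        raise ValueError("empty Psi matrix")
    type_of = {ev.event_id: ev.event_type for ev in catalog}
    unknown = [eid for eid in psi.index if eid not in type_of]
    if unknown:
        raise KeyError(f"events absent from catalog: {unknown[:5]}")

    totals = psi.sum(axis=0, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rf = psi.div(totals, axis=1)
    rf.loc[:, totals <= 0] = np.nan

    type_index = pd.Index([type_of[eid] for eid in psi.index])
    rf_by_type = rf.groupby(type_index).sum(min_count=1)
    rf_by_type = rf_by_type.reindex(list(EVENT_TYPES)).fillna(0.0)
    rf_by_type.loc[:, totals <= 0] = np.nan
    return rf, rf_by_type


def compare_composition(
    rf_by_type: pd.DataFrame,
    strata: StrataAssignment | pd.Series,
    alpha: float = 0.05,
    require_both_tests: bool = False,
    adjust: bool = False,
) -> list[CompositionComparison]:
    """Compare type compositions between the high and low strata.

    By default a type is significant when its rank-sum (Wilcoxon) p is below
    ``alpha``; ``require_both_tests`` additionally demands the KS p pass.
    ``adjust`` applies BH across the seven types before thresholding.
    Strata with fewer than 3 samples yield NaN tests with a warning.
    """
    labels = strata.labels if isinstance(strata, StrataAssignment) else strata
    high = [s for s in rf_by_type.columns if labels.get(s) == STRATUM_HIGH]
    low = [s for s in rf_by_type.columns if labels.get(s) == STRATUM_LOW]
    if not high or not low:
        raise ValueError("both strata must be non-empty")

    too_small = min(len(high), len(low)) < MIN_GROUP_SIZE_FOR_TESTS
    if too_small:
        warnings.warn(
            "a stratum has fewer than 3 samples; composition tests reported "
            "as missing",
            stacklevel=2,
        )

    rows = []
    for etype in rf_by_type.index:
        hv = rf_by_type.loc[etype, high].dropna().to_numpy(dtype=float)
        lv = rf_by_type.loc[etype, low].dropna().to_numpy(dtype=float)
        mean_hi = float(hv.mean()) if hv.size else np.nan
        mean_lo = float(lv.mean()) if lv.size else np.nan
        if too_small or hv.size < MIN_GROUP_SIZE_FOR_TESTS or lv.size < MIN_GROUP_SIZE_FOR_TESTS:
            rows.append((etype, mean_hi, mean_lo, np.nan, np.nan))
            continue
        if np.all(hv == hv[0]) and np.all(lv == lv[0]) and hv[0] == lv[0]:
            wp, kp = 1.0, 1.0
        else:
            wp = float(
                stats.mannwhitneyu(
                    hv, lv, alternative="two-sided", method="asymptotic"
                ).pvalue
            )
            kp = float(stats.ks_2samp(hv, lv).pvalue)
        rows.append((etype, mean_hi, mean_lo, min(wp, 1.0), min(kp, 1.0)))

    wps = np.array([r[3] for r in rows], dtype=float)
    kps = np.array([r[4] for r in rows], dtype=float)
    if adjust:
        ok = np.isfinite(wps)
        if ok.any():
            wps_adj, kps_adj = wps.copy(), kps.copy()
            wps_adj[ok] = bh_adjust(np.clip(wps[ok], np.finfo(float).tiny, 1.0))
            kps_adj[ok] = bh_adjust(np.clip(kps[ok], np.finfo(float).tiny, 1.0))
            wps, kps = wps_adj, kps_adj

    results = []
    for (etype, mean_hi, mean_lo, _, _), wp, kp in zip(rows, wps, kps):
        if np.isfinite(wp):
            sig = wp < alpha and (kp < alpha if require_both_tests else True)
        else:
            sig = False
        results.append(
            CompositionComparison(
                event_type=etype,
                mean_rf_high=mean_hi,
                mean_rf_low=mean_lo,
                wilcoxon_p=float(wp),
                ks_p=float(kp),
                significant=bool(sig),
            )
        )
    return results


def event_type_spectrum(
    catalog: Sequence[SpliceEvent],
    event_subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Counts and percentages per event type over a designated event set.

    ``event_subset`` selects event ids (must all be in the catalog); None
    uses the full catalog. An empty subset yields zero counts and NaN
    percentages.
    """
    type_of = {ev.event_id: ev.event_type for ev in catalog}
    if event_subset is None:
        ids = list(type_of)
    else:
        ids = list(event_subset)
        unknown = [eid for eid in ids if eid not in type_of]
        if unknown:
            raise KeyError(f"events not in catalog: {unknown[:5]}")
    counts = {t: 0 for t in EVENT_TYPES}
    for eid in ids:
        counts[type_of[eid]] += 1
    total = sum(counts.values())
    spectrum = pd.DataFrame(
        {
            "event_type": list(EVENT_TYPES),
            "count": [counts[t] for t in EVENT_TYPES],
        }
    )
    if total > 0:
        spectrum["percent"] = spectrum["count"] / total * 100.0
    else:
        spectrum["percent"] = np.nan
    return spectrum


def comparison_table(results: list[CompositionComparison]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
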