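"""Gene-gene correlations, gene-set over-representation, and the IHC score."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffsplice import bh_adjust


@dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    rho: float
    p_value: float
    n: int
    method: str = "spearman"


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class OraResult:
    set_name: str
    hits: int
    set_size: int
    gene_ratio: float
    p_value: float
    adj_p: float


def _exact_spearman_p(ra: np.ndarray, rb: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact Spearman p by full permutation enumeration (n <= 9)."""
    n = ra.size
    perms = np.array(list(itertools.permutations(rb)))
    a_c = ra - ra.mean()
    denom = np.sqrt((a_c**2).sum() * ((rb - rb.mean()) ** 2).sum())
    rhos = (perms - rb.mean()) @ a_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlate_genes(
    expr: pd.DataFrame, pairs: list[tuple[str, str]]
) -> list[CorrelationResult]:
    """Spearman rank correlation for gene pairs over pairwise-complete samples.

    P-values use the t-approximation; for n <= 9 an exact permutation
    p-value is computed instead. Requires >= 3 complete samples per pair.
    """
    results = []
    for gene_a, gene_b in pairs:
        for g in (gene_a, gene_b):
            if g not in expr.index:
                raise KeyError(f"gene {g!r} not found in expression matrix")
        sub = expr.loc[[gene_a, gene_b]].T.dropna()
        n = sub.shape[0]
        if n < 3:
            raise ValueError(
                f"pair ({gene_a}, {gene_b}): need >= 3 complete samples, got {n}"
            )
        a = sub[gene_a].to_numpy(dtype=float)
        b = sub[gene_b].to_numpy(dtype=float)
        rho, p = stats.spearmanr(a, b)
        if n <= 9:
            ra = stats.rankdata(a)
            rb = stats.rankdata(b)
            p = _exact_spearman_p(ra, rb, float(rho))
        results.append(
            CorrelationResult(
                gene_a=gene_a,
                gene_b=gene_b,
                rho=float(rho),
                p_value=float(min(max(p, np.finfo(float).tiny), 1.0)),
                n=int(n),
            )
        )
    return results


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} empty")
            sets.append(GeneSet(name=name, genes=frozenset(genes)))
    return sets


def hypergeometric_ora(
    query_genes: set[str],
    sets: list[GeneSet],
    universe: set[str],
) -> list[OraResult]:
    """Upper-tail hypergeometric over-representation test per gene set.

    Sets are intersected with the universe before testing; the query must be
    a subset of the universe. gene_ratio = hits / |set within universe|.
    BH adjustment is applied across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & set(universe)
    if set(query_genes) - set(universe):
        raise ValueError("query genes must be contained in the universe")
    n_universe = len(universe)
    n_query = len(query)

    raw = []
    for gs in sets:
        members = gs.genes & universe
        k = len(query & members)
        m = len(members)
        if m == 0:
            raw.append((gs.name, 0, 0, np.nan, 1.0))
            continue
        # P(X >= k) for X ~ Hypergeom(N=n_universe, K=m, n=n_query)
        p = float(stats.hypergeom.sf(k - 1, n_universe, m, n_query))
        raw.append((gs.name, k, m, k / m, min(max(p, np.finfo(float).tiny), 1.0)))

    adj = bh_adjust([r[4] for r in raw]) if raw else []
    return [
        OraResult(
            set_name=name,
            hits=k,
            set_size=m,
            gene_ratio=ratio,
            p_value=p,
            adj_p=float(a),
        )
        for (name, k, m, ratio, p), a in zip(raw, adj)
    ]


# --- immunohistochemistry combined score ----------------------------------

_PERCENT_BIN_EDGES = (0.0, 25.0, 50.0, 75.0, 100.0)


def percent_positive_bin(percent_positive: float) -> int:
    """Bin a percentage of positive cells: 0 -> 0, (0,25] -> 1, (25,50] -> 2,
    (50,75] -> 3, (75,100] -> 4."""
    if not 0 <= percent_positive <= 100:
        raise ValueError("percent_positive must be in [0, 100]")
    if percent_positive == 0:
        return 0
    for score, upper in enumerate(_PERCENT_BIN_EDGES, start=0):
        if percent_positive <= upper:
            return score
    raise AssertionError("unreachable")


def ihc_combined_score(percent_positive: float, intensity: int) -> int:
    """Combined IHC score: percentage bin (0-4) times staining intensity (0-3).

    The attainable range is 0 to 12.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be one of 0, 1, 2, 3")
    return percent_positive_bin(percent_positive) * intensity


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def ora_table(results: list[OraResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
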