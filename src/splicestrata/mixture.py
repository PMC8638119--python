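"""Univariate equal-variance Gaussian mixtures for expression stratification.

Samples are classified into low/intermediate/high strata of a driver gene's
normalized expression by fitting equal-variance ("E"-model) univariate
Gaussian mixtures over a range of component counts with EM and selecting
the count by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRATUM_LOW = "low"
STRATUM_INTERMEDIATE = "intermediate"
STRATUM_HIGH = "high"

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GmmFit:
    """A fitted univariate equal-variance Gaussian mixture."""

    n_components: int
    means: np.ndarray          # sorted ascending
    shared_sd: float
    weights: np.ndarray        # simplex, aligned with means
    bic: float
    loglik: float
    converged: bool
    n_obs: int

    def __post_init__(self) -> None:
        if self.shared_sd <= 0:
            raise ValueError("shared_sd must be positive")
        if not np.all(np.diff(self.means) > 0):
            raise ValueError("means must be strictly increasing")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def responsibilities(self, values: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, shape (n, n_components)."""
        log_r = self._log_joint(values)
        log_r -= log_r.max(axis=1, keepdims=True)
        r = np.exp(log_r)
        return r / r.sum(axis=1, keepdims=True)

    def _log_joint(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float)[:, None]
        var = self.shared_sd**2
        return (
            np.log(self.weights)[None, :]
            - 0.5 * (_LOG2PI + np.log(var))
            - 0.5 * (x - self.means[None, :]) ** 2 / var
        )


@dataclass(frozen=True)
class StrataAssignment:
    labels: pd.Series          # sample_id -> low/intermediate/high
    posterior: pd.DataFrame    # samples x components responsibilities
    fit: GmmFit


def _em_equal_variance(
    x: np.ndarray,
    mu0: np.ndarray,
    w0: np.ndarray,
    var0: float,
    tol: float,
    max_iter: int,
) -> tuple[float, np.ndarray, np.ndarray, float, bool]:
    """EM for a univariate mixture with one shared variance.

    Returns (loglik, means, weights, var, converged). The observed-data
    log-likelihood is asserted non-decreasing every iteration.
    """
    n = x.size
    mu, w, var = mu0.copy(), w0.copy(), var0
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        log_joint = (
            np.log(w)[None, :]
            - 0.5 * (_LOG2PI + np.log(var))
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var
        )
        m = log_joint.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_joint - m).sum(axis=1))
        ll = float(lse.sum())
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), (
            "EM log-likelihood decreased"
        )
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        r = np.exp(log_joint - lse[:, None])
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = float((r * (x[:, None] - mu[None, :]) ** 2).sum() / n)
        if var < 1e-12:
            var = 1e-12
    return prev_ll, mu, w, var, converged


def fit_gmm_equal_variance(
    values: np.ndarray | pd.Series,
    g_min: int = 1,
    g_max: int = 5,
    n_starts: int = 8,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GmmFit:
    """Fit equal-variance mixtures for G in [g_min, g_max]; pick by BIC.

    Initialization is deterministic: one quantile-based start plus
    ``n_starts - 1`` seeded perturbations of it. BIC = -2*loglik +
    k*log(n) with k = 2G (G means, G-1 free weights, one shared variance).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    n_distinct = np.unique(x).size
    if g_min < 1 or g_max < g_min:
        raise ValueError("need 1 <= g_min <= g_max")
    if n_distinct < 2:
        raise ValueError("degenerate input: all values identical")
    if n_distinct < g_max:
        raise ValueError(
            f"only {n_distinct} distinct values for up to {g_max} components"
        )

    rng = np.random.default_rng(seed)
    overall_sd = float(x.std())
    best: GmmFit | None = None
    for g in range(g_min, g_max + 1):
        q = np.quantile(x, (np.arange(g) + 0.5) / g)
        starts = [q]
        for _ in range(n_starts - 1):
            starts.append(q + rng.normal(0.0, 0.25 * overall_sd + 1e-12, g))
        best_g: tuple[float, np.ndarray, np.ndarray, float, bool] | None = None
        for mu0 in starts:
            mu0 = np.sort(mu0)
            res = _em_equal_variance(
                x, mu0, np.full(g, 1.0 / g), max(overall_sd**2, 1e-12),
                tol, max_iter,
            )
            if best_g is None or res[0] > best_g[0]:
                best_g = res
        ll, mu, w, var, converged = best_g
        order = np.argsort(mu)
        mu, w = mu[order], w[order]
        # collapse of two components onto one mean makes the fit invalid
        if np.any(np.diff(mu) <= 0):
            continue
        k = 2 * g
        bic = -2.0 * ll + k * np.log(x.size)
        fit = GmmFit(
            n_components=g,
            means=mu,
            shared_sd=float(np.sqrt(var)),
            weights=w,
            bic=float(bic),
            loglik=float(ll),
            converged=bool(converged),
            n_obs=int(x.size),
        )
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise RuntimeError("no valid mixture fit obtained")
    return best


def assign_strata(
    fit: GmmFit, values: pd.Series | np.ndarray, sample_ids=None
) -> StrataAssignment:
    """Map each sample to low/intermediate/high by maximum posterior.

    The lowest-mean component is "low", the highest-mean "high", all others
    "intermediate"; posterior ties break toward the lower-mean component.
    """
    if fit.n_components < 2:
        raise ValueError("no strata separable: mixture has a single component")
    if isinstance(values, pd.Series):
        sample_ids = values.index
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        if sample_ids is None:
            sample_ids = [f"sample_{i}" for i in range(x.size)]
    resp = fit.responsibilities(x)
    # argmax returns the first (lower-mean) component on exact ties
    comp = np.argmax(resp, axis=1)
    names = np.array(
        [STRATUM_LOW]
        + [STRATUM_INTERMEDIATE] * (fit.n_components - 2)
        + [STRATUM_HIGH]
    )
    labels = pd.Series(names[comp], index=pd.Index(sample_ids), name="stratum")
    posterior = pd.DataFrame(
        resp,
        index=pd.Index(sample_ids),
        columns=[f"component_{i}" for i in range(fit.n_components)],
    )
    return StrataAssignment(labels=labels, posterior=posterior, fit=fit)


def write_strata_tsv(assignment: StrataAssignment, path) -> None:
    resp = assignment.posterior.to_numpy()
    g = assignment.fit.n_components
    out = pd.DataFrame(
        {
            "sample_id": assignment.labels.index,
            "label": assignment.labels.to_numpy(),
            "posterior_low": resp[:, 0],
            "posterior_mid": resp[:, 1:-1].sum(axis=1) if g > 2 else 0.0,
            "posterior_high": resp[:, -1],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_strata_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(
        df["label"].to_numpy(), index=df["sample_id"].to_numpy(), name="stratum"
    )
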