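"""Convergence assessment and posterior summarization.

Convergence uses the classic split potential-scale-reduction statistic
(split R̂) computed on half-chains; values below 1.1 are taken as converged.
Summaries are posterior medians with equal-tailed central 95% credible
intervals, pooled across chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import PosteriorDraws

#: parameter blocks reported by default (per-event eps draws are omitted)
DEFAULT_REPORT_BLOCKS = (
    "lambda_bar", "alpha", "beta", "sigma_lam", "n1",
    "sigma_gamma", "sigma_eps", "gamma", "lam",
)


@dataclass(frozen=True)
class SummaryRow:
    parameter: str
    median: float
    lower95: float
    upper95: float
    rhat: float

    def __post_init__(self) -> None:
        if not (self.lower95 <= self.median <= self.upper95):
            raise ValueError(f"unordered summary for {self.parameter}")


@dataclass
class ConvergenceReport:
    passed: bool
    threshold: float
    failures: list[str]

    def __str__(self) -> str:
        if self.passed:
            return f"converged: all split R-hat < {self.threshold}"
        listing = ", ".join(self.failures[:20])
        more = "" if len(self.failures) <= 20 else f" (+{len(self.failures)-20} more)"
        return (f"NOT converged: {len(self.failures)} parameter(s) with split "
                f"R-hat >= {self.threshold}: {listing}{more}")


def _rank_normalize(draws: np.ndarray) -> np.ndarray:
    """Map pooled draws to normal scores via fractional ranks (Blom offset)."""
    flat = draws.ravel()
    ranks = np.argsort(np.argsort(flat)) + 1.0
    z = norm.ppf((ranks - 3.0 / 8.0) / (flat.size + 0.25))
    return z.reshape(draws.shape)


def split_rhat(chains, rank_normalized: bool = False) -> float:
    """Split potential-scale-reduction statistic for one scalar parameter.

    ``chains`` is an (M, N) array (or list of equal-length 1-D sequences) of
    post-warmup draws.  Each chain is split into halves; with W the mean
    within-half-chain variance and B/N the between-half-chain variance of
    half-chain means, R̂ = sqrt(((N−1)/N · W + B/N) / W).

    A completely degenerate input (every draw identical) is defined as
    exactly 1.0, with a warning.  ``rank_normalized=True`` applies a normal
    score transform to the pooled draws first (a more robust variant;
    the classic statistic is the default).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_draws)")
    m, n = arr.shape
    if m < 2:
        raise ValueError("split R-hat needs at least 2 chains")
    if n < 4:
        raise ValueError("split R-hat needs at least 4 draws per chain")
    if np.all(arr == arr.flat[0]):
        warnings.warn("all draws identical: split R-hat defined as 1.0 "
                      "(degenerate variance)", stacklevel=2)
        return 1.0
    if rank_normalized:
        arr = _rank_normalize(arr)
    half = (n // 2) * 2
    halves = arr[:, :half].reshape(2 * m, half // 2)
    N = half // 2
    W = float(np.mean(np.var(halves, axis=1, ddof=1)))
    B = N * float(np.var(np.mean(halves, axis=1), ddof=1))
    if W == 0.0:
        return np.inf
    var_plus = (N - 1) / N * W + B / N
    return float(np.sqrt(var_plus / W))


def summarize(
    draws: PosteriorDraws,
    blocks: list[str] | None = None,
    interval: float = 0.95,
    rank_normalized: bool = False,
) -> pd.DataFrame:
    """Per-parameter posterior median, central credible interval and split R̂.

    Quantiles pool all chains (linear interpolation of order statistics);
    R̂ uses the chain structure.  Returns a DataFrame with columns
    parameter, median, lower95, upper95, rhat.
    """
    blocks = list(blocks) if blocks is not None else [
        b for b in DEFAULT_REPORT_BLOCKS if b in draws.draws
    ]
    arr = draws.parameter_array(blocks)          # (C, D, P)
    names = draws.parameter_names(blocks)
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    pooled = arr.reshape(-1, arr.shape[2])
    med = np.median(pooled, axis=0)
    lo = np.quantile(pooled, lo_q, axis=0)
    hi = np.quantile(pooled, hi_q, axis=0)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-variance warnings per param
        for j, name in enumerate(names):
            rhat = (split_rhat(arr[:, :, j], rank_normalized=rank_normalized)
                    if arr.shape[0] >= 2 and arr.shape[1] >= 4 else np.nan)
            rows.append(SummaryRow(name, float(med[j]), float(lo[j]),
                                   float(hi[j]), float(rhat)))
    return pd.DataFrame([r.__dict__ for r in rows])


def check_convergence(summary: pd.DataFrame,
                      threshold: float = 1.1) -> ConvergenceReport:
    """Flag every parameter whose split R̂ meets or exceeds the threshold."""
    if summary.empty:
        raise ValueError("empty summary")
    bad = summary.loc[
        summary["rhat"].notna() & (summary["rhat"] >= threshold), "parameter"
    ].tolist()
    return ConvergenceReport(passed=not bad, threshold=threshold, failures=bad)
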