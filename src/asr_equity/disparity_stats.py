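"""Brunner-Munzel test for comparing WER distributions between groups.

The Brunner-Munzel test addresses the nonparametric Behrens-Fisher problem:
it tests H0: p = P(X < Y) + 0.5 P(X = Y) = 0.5 without assuming equal
variances or similar distribution shapes in the two groups — appropriate for
per-utterance WER, which is bounded below, heavily tied, and skewed.

Ties are handled with midranks.  The statistic is referred to a t
distribution with Satterthwaite-type degrees of freedom; a studentized
permutation p-value is available for very small samples.  The statistic is
oriented so that positive values indicate the second sample tends larger
(relative effect above 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, t as t_dist


@dataclass(frozen=True)
class BMTestResult:
    """Brunner-Munzel test outcome.

    ``relative_effect`` estimates P(X < Y) + 0.5 P(X = Y): values above 0.5
    mean the second sample stochastically dominates.
    """

    statistic: float
    df: float
    p_value: float
    relative_effect: float
    n_x: int
    n_y: int
    method: str = "t"


class DegenerateSamplesError(ValueError):
    """Raised when the pooled rank variance is zero (all values identical)."""


def _bm_core(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Statistic, df, rank-variance total, and relative effect via midranks."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    rc = rankdata(pooled)  # midranks
    rcx, rcy = rc[:nx], rc[nx:]
    rx = rankdata(x)
    ry = rankdata(y)

    # placement-based empirical variances (Brunner & Munzel 2000)
    dev_x = rcx - rx - rcx.mean() + (nx + 1) / 2.0
    dev_y = rcy - ry - rcy.mean() + (ny + 1) / 2.0
    Sx2 = float(dev_x @ dev_x) / (nx - 1)
    Sy2 = float(dev_y @ dev_y) / (ny - 1)

    p_hat = (rcy.mean() - (ny + 1) / 2.0) / nx
    var_total = nx * Sx2 + ny * Sy2
    if var_total <= 0.0:
        if np.all(pooled == pooled[0]):
            raise DegenerateSamplesError(
                "Brunner-Munzel variance is zero: samples are jointly constant"
            )
        # zero placement variance with distinct samples (e.g. complete
        # separation): the statistic diverges but the relative effect stands
        stat = np.sign(rcy.mean() - rcx.mean()) * np.inf
        return float(stat), float("nan"), 0.0, float(p_hat)
    stat = nx * ny * (rcy.mean() - rcx.mean()) / ((nx + ny) * np.sqrt(var_total))
    df = var_total**2 / ((nx * Sx2) ** 2 / (nx - 1) + (ny * Sy2) ** 2 / (ny - 1))
    return float(stat), float(df), float(var_total), float(p_hat)


def relative_effect(x, y) -> float:
    """Midrank estimate of P(X < Y) + 0.5 P(X = Y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    rc = rankdata(np.concatenate([x, y]))
    return float((rc[nx:].mean() - (ny + 1) / 2.0) / nx)


def brunner_munzel(
    x,
    y,
    method: str = "t",
    n_permutations: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> BMTestResult:
    """Two-sided Brunner-Munzel test of P(X < Y) + 0.5 P(X = Y) = 0.5.

    Parameters
    ----------
    x, y
        The two samples (each needs at least 2 observations).
    method
        ``"t"`` (default): t-approximation with Satterthwaite-type df,
        appropriate from moderate sample sizes.  ``"permutation"``:
        studentized permutation of the pooled sample, for tiny samples.
    n_permutations, rng
        Permutation count and random source for ``method="permutation"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    stat, df, _, p_hat = _bm_core(x, y)

    if method == "t":
        if np.isinf(stat):
            p = 0.0
        else:
            p = min(1.0, float(2.0 * t_dist.sf(abs(stat), df)))
    elif method == "permutation":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        pooled = np.concatenate([x, y])
        nx = len(x)
        exceed = 0
        valid = 0
        for _ in range(n_permutations):
            perm = gen.permutation(pooled)
            try:
                s, _, _, _ = _bm_core(perm[:nx], perm[nx:])
            except DegenerateSamplesError:
                continue
            valid += 1
            if abs(s) >= abs(stat) - 1e-12:
                exceed += 1
        p = (exceed + 1) / (valid + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    return BMTestResult(
        statistic=stat,
        df=df,
        p_value=float(p),
        relative_effect=p_hat,
        n_x=len(x),
        n_y=len(y),
        method=method,
    )
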