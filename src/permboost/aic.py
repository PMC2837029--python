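"""Data-driven choice of m_stop by AIC along the boosting path.

The boosting fit after m iterations is treated as a linear smoother on the
working-response scale: each componentwise base fit applies the rank-2 hat
matrix H_j = (1/n) 11' + c_j c_j' / ||c_j||^2 (intercept plus centered column
c_j = x_j - xbar_j), and the aggregated boosting operator obeys the recursion

    B_m = B_{m-1} + nu * H_{j*_m} (I - B_{m-1}),        B_0 = 0.

The effective degrees of freedom after m iterations is df(m) = trace(B_m) —
the classical approximation for binomial boosting, applied on the gradient
scale.  The criterion is AIC(m) = -2 * loglik(m) + 2 * df(m) with
loglik(m) = -n * ell(m); the clinical offset is fixed, not estimated in
step 2, so its q+1 parameters are excluded (only relative AIC across m
matters).  The minimizer over m = 1..m_max is returned; ties go to the
smallest m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boosting import BoostConfig, BoostFit, ColumnStats, fit_boost
from .core import Outcome
from .offset import OffsetModel

#: largest n for which the dense n x n smoother is maintained.
OPERATOR_SIZE_GUARD = 5000


@dataclass
class AICPath:
    """AIC trajectory along the boosting path.

    ``loglik[m]`` is the total binomial log-likelihood after m iterations,
    ``df[m]`` the trace of the aggregated hat operator (df[0] = 0), and
    ``aic[m] = -2 loglik[m] + 2 df[m]``; ``m_opt`` minimizes aic over
    1..m_max.
    """

    m_grid: np.ndarray
    loglik: np.ndarray
    df: np.ndarray
    aic: np.ndarray
    m_opt: int


def _df_path_dense(
    X: np.ndarray,
    selection: list[int],
    nu: float,
    stats: ColumnStats,
) -> np.ndarray:
    """trace(B_m) for m = 0..len(selection), maintaining B densely."""
    n = X.shape[0]
    B = np.zeros((n, n))
    I = np.eye(n)
    df = np.empty(len(selection) + 1)
    df[0] = 0.0
    for m, j in enumerate(selection, start=1):
        c = X[:, j] - stats.mean[j]
        ssq = stats.ssq[j]
        R = I - B
        HR = np.outer(np.ones(n), R.sum(axis=0)) / n  # (1/n) 11' R
        if ssq > 0:
            HR += np.outer(c, c @ R) / ssq
        B += nu * HR
        df[m] = np.trace(B)
    return df


def select_mstop_aic(
    X: np.ndarray,
    outcome: Outcome,
    offset: OffsetModel,
    config: BoostConfig,
    *,
    column_stats: ColumnStats | None = None,
) -> tuple[int, AICPath, BoostFit]:
    """Run the path to m_max and return the AIC-minimizing m_stop.

    Returns ``(m_opt, path, fit)`` where ``fit`` is the full-length boosting
    fit to m_max (its first m_opt iterations are the selected model; a
    fixed-m_stop refit at m_opt reproduces it exactly since the path is
    deterministic).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n > OPERATOR_SIZE_GUARD:
        raise ValueError(
            f"n = {n} exceeds the dense-operator guard ({OPERATOR_SIZE_GUARD}); "
            "use a fixed m_stop instead of AIC selection"
        )
    stats = column_stats if column_stats is not None else ColumnStats.from_matrix(X)
    run_cfg = BoostConfig(
        m_stop=config.m_max, nu=config.nu, m_max=config.m_max, center=config.center
    )
    fit = fit_boost(X, outcome, offset, run_cfg, column_stats=stats)
    df = _df_path_dense(X, fit.selection_path, config.nu, stats)
    loglik = -n * fit.loss_path
    aic = -2.0 * loglik + 2.0 * df
    m_opt = 1 + int(np.argmin(aic[1:]))  # smallest minimizer over 1..m_max
    path = AICPath(
        m_grid=np.arange(config.m_max + 1),
        loglik=loglik,
        df=df,
        aic=aic,
        m_opt=m_opt,
    )
    return m_opt, path, fit
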