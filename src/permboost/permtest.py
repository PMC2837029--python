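"""Permutation test for the additional predictive value of the molecular block.

Null hypothesis: given the clinical covariates (through the fixed offset),
the molecular predictors X_1..X_p carry no additional predictive value — all
their coefficients in the combined logistic model are zero.

Procedure: the two-stage fit is run on the original data, yielding the
average negative binomial log-likelihood ell; then B times on data whose
molecular rows x_1..x_n are replaced by x_sigma(1)..x_sigma(n) for a random
permutation sigma, while the clinical covariates and the outcome stay fixed.
The permutation p-value uses the add-one convention

    p = (1 + #{b : ell_b <= ell}) / (B + 1),

which is strictly positive and exactly discrete-uniform on
{1/(B+1), ..., 1} under the null.  Ties count as <= (conservative).

The offset depends only on (Z, y), which the permutation never touches, so
it is computed once and reused across all B re-runs.  Each permutation draws
its sigma from an independent RNG substream spawned from the master seed, so
results are bit-identical for any worker count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .aic import select_mstop_aic
from .boosting import BoostConfig, ColumnStats, fit_boost
from .core import Outcome
from .offset import (
    OffsetModel,
    fit_logistic_offset,
    intercept_only_offset,
    offset_from_risk_score,
)


@dataclass(frozen=True)
class TestConfig:
    """Configuration of the permutation test.

    Attributes
    ----------
    B
        Number of permutations; the p-value resolution is 1/(B+1).  Set as
        high as computationally feasible (200 is a workable default).
    seed
        Master RNG seed; every permutation uses an independent substream
        spawned from it.
    mstop_mode
        ``"fixed"`` (use ``m_stop``) or ``"aic"`` (minimize AIC along the
        path, capped at ``m_max``).
    m_stop
        Boosting iterations in fixed mode.
    nu
        Boosting step length, default 0.1.
    m_max
        Cap for the AIC search.
    aic_rerun
        In AIC mode, re-run the selection on every permuted dataset so the
        identical procedure is applied to original and permuted data
        (required for exchangeability).  ``False`` reuses the original
        m_opt for all permutations (cheaper).
    threads
        Worker count for the permutation loop; never changes the result.
    center
        Mean-center molecular columns inside the boosting fit.
    allow_nonconverged
        Downgrade a separated/non-converged clinical fit from error to
        warning (study harnesses over many replicates may prefer this).
    """

    B: int = 200
    seed: int = 0
    mstop_mode: str = "fixed"
    m_stop: int = 100
    nu: float = 0.1
    m_max: int = 1000
    aic_rerun: bool = True
    threads: int = 1
    center: bool = True
    allow_nonconverged: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.mstop_mode not in ("fixed", "aic"):
            raise ValueError(f"unknown mstop_mode {self.mstop_mode!r}")

    def boost_config(self, m_stop: int | None = None) -> BoostConfig:
        return BoostConfig(
            m_stop=self.m_stop if m_stop is None else m_stop,
            nu=self.nu,
            m_max=self.m_max,
            center=self.center,
        )


@dataclass
class TestResult:
    """Outcome of the permutation test."""

    p_value: float
    ell_observed: float
    ell_perm: np.ndarray
    mstop_used: list[int]  # original first, then one entry per permutation
    config: TestConfig
    offset: OffsetModel

    @property
    def B(self) -> int:
        return self.ell_perm.shape[0]

    @property
    def resolution(self) -> float:
        """Smallest attainable p-value, 1/(B+1)."""
        return 1.0 / (self.B + 1)

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "p_value_resolution": self.resolution,
            "ell_observed": self.ell_observed,
            "ell_perm": self.ell_perm.tolist(),
            "mstop_used": self.mstop_used,
            "B": self.B,
            "seed": self.config.seed,
            "mstop_mode": self.config.mstop_mode,
            "nu": self.config.nu,
            "offset_mode": self.offset.mode,
            "offset_coefficients": self.offset.coefficients.tolist(),
        }


def permute_molecular(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply one random row permutation sigma jointly to all p columns of X.

    Within-row feature correlation is preserved; the clinical covariates and
    the outcome are untouched by contract.
    """
    X = np.asarray(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to permute")
    sigma = rng.permutation(X.shape[0])
    return X[sigma]


def permutation_pvalue(ell_observed: float, ell_perm: np.ndarray) -> float:
    """Add-one permutation p-value; ties count toward the null."""
    B = len(ell_perm)
    return float((1 + np.sum(np.asarray(ell_perm) <= ell_observed)) / (B + 1))


def _run_one(
    X: np.ndarray,
    outcome: Outcome,
    offset: OffsetModel,
    config: TestConfig,
    stats: ColumnStats,
) -> tuple[float, int]:
    """Two-stage step 2 on one (possibly permuted) dataset -> (ell, m_stop)."""
    if config.mstop_mode == "aic":
        m_opt, _, fit = select_mstop_aic(
            X, outcome, offset, config.boost_config(), column_stats=stats
        )
        return float(fit.loss_path[m_opt]), m_opt
    fit = fit_boost(X, outcome, offset, config.boost_config(), column_stats=stats)
    return fit.final_loss, fit.m_stop


def global_boost_test(
    X: np.ndarray,
    outcome: Outcome,
    config: TestConfig,
    *,
    Z: np.ndarray | None = None,
    risk_score: np.ndarray | None = None,
    score_scale: str = "probability",
    offset: OffsetModel | None = None,
) -> TestResult:
    """Run the full two-stage permutation test.

    The offset is built once from whichever clinical input is given — a
    prebuilt ``offset``, a ``risk_score`` (fixed-score mode), a covariate
    matrix ``Z`` (logistic fit), or none (intercept only) — and held fixed
    across all permutations.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != outcome.n:
        raise ValueError("X and outcome sample counts differ")

    if offset is None:
        if risk_score is not None:
            offset = offset_from_risk_score(risk_score, scale=score_scale)
        elif Z is not None:
            offset = fit_logistic_offset(
                Z, outcome, allow_nonconverged=config.allow_nonconverged
            )
        else:
            offset = intercept_only_offset(outcome)
    if offset.n != outcome.n:
        raise ValueError("offset length does not match sample count")

    stats = ColumnStats.from_matrix(X)
    ell_obs, m_used = _run_one(X, outcome, offset, config, stats)

    # AIC-once variant: freeze the originally selected m for the permutations
    perm_config = config
    if config.mstop_mode == "aic" and not config.aic_rerun:
        perm_config = TestConfig(
            B=config.B, seed=config.seed, mstop_mode="fixed", m_stop=m_used,
            nu=config.nu, m_max=config.m_max, threads=config.threads,
            center=config.center,
        )

    children = np.random.SeedSequence(config.seed).spawn(config.B)

    def one_perm(child: np.random.SeedSequence) -> tuple[float, int]:
        rng = np.random.default_rng(child)
        Xp = permute_molecular(X, rng)
        return _run_one(Xp, outcome, offset, perm_config, stats)

    if config.threads > 1:
        results = Parallel(n_jobs=config.threads, backend="threading")(
            delayed(one_perm)(c) for c in children
        )
    else:
        results = [one_perm(c) for c in children]
    ell_perm = np.array([r[0] for r in results])
    mstops = [m_used] + [r[1] for r in results]

    return TestResult(
        p_value=permutation_pvalue(ell_obs, ell_perm),
        ell_observed=ell_obs,
        ell_perm=ell_perm,
        mstop_used=mstops,
        config=config,
        offset=offset,
    )


def mstop_diagnostic(
    X: np.ndarray,
    outcome: Outcome,
    offset: OffsetModel,
    *,
    m_grid: Sequence[int],
    B: int = 20,
    seed: int = 0,
    nu: float = 0.1,
    center: bool = True,
) -> dict:
    """Training ell versus m_stop for the original and B permuted datasets.

    One boosting run to max(m_grid) per dataset suffices: the path is nested,
    so the loss at every grid point is read off the single run.  Returns a
    dict with ``m_grid``, ``ell_original`` and ``ell_perm`` (B x len(m_grid))
    suitable for the classic diagnostic plot of loss curves under the null
    band.
    """
    m_grid = sorted(set(int(m) for m in m_grid))
    if not m_grid or m_grid[0] < 0:
        raise ValueError("m_grid must contain nonnegative integers")
    cfg = BoostConfig(m_stop=max(m_grid), nu=nu, center=center)
    stats = ColumnStats.from_matrix(np.asarray(X, dtype=float))
    fit = fit_boost(X, outcome, offset, cfg, column_stats=stats)
    ell0 = fit.loss_path[m_grid]
    perm_curves = np.empty((B, len(m_grid)))
    for b, child in enumerate(np.random.SeedSequence(seed).spawn(B)):
        rng = np.random.default_rng(child)
        Xp = permute_molecular(np.asarray(X, dtype=float), rng)
        fb = fit_boost(Xp, outcome, offset, cfg, column_stats=stats)
        perm_curves[b] = fb.loss_path[m_grid]
    return {
        "m_grid": list(m_grid),
        "ell_original": ell0.tolist(),
        "ell_perm": perm_curves.tolist(),
    }
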