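"""Step 1 of the two-stage procedure: the fixed clinical offset.

Three ways to build it:

* ``fit_logistic_offset`` — maximum-likelihood logistic regression of the
  outcome on the clinical covariates Z (IRLS via statsmodels GLM); the fitted
  linear predictor eta_i = b0 + sum_j b_j z_ij becomes the offset.
* ``offset_from_risk_score`` — a published per-sample risk score, taken
  verbatim on the linear (log-odds) scale or logit-transformed from the
  probability scale.  No coefficients are estimated.
* ``intercept_only_offset`` — the constant log(n+/n-), i.e. the clinical
  model reduced to its intercept; used to assess the molecular block without
  any covariate adjustment.

The offset is computed once from (Z, y), never refit, and enters step 2 with
coefficient fixed at 1.  ``OffsetModel`` is frozen to enforce this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .core import Outcome, linear_predictor_from_prob

#: |coefficient| beyond which the clinical fit is treated as separated.
SEPARATION_COEF_BOUND = 15.0
#: IRLS iteration cap for the clinical GLM.
GLM_MAX_ITER = 100
#: IRLS convergence tolerance.
GLM_TOL = 1e-8


class SeparationError(RuntimeError):
    """Raised when the clinical logistic fit shows (quasi-)complete separation."""


@dataclass(frozen=True)
class OffsetModel:
    """Fixed per-sample offset on the logit scale, plus fit metadata.

    Attributes
    ----------
    mode
        One of ``fitted_glm``, ``fixed_risk_score``, ``intercept_only``.
    coefficients
        b0, b1..bq in log-odds units; empty except in ``fitted_glm`` mode
        (``intercept_only`` records the single intercept).
    offset
        Per-sample linear predictor eta_hat, length n.
    converged
        Whether the IRLS fit converged (True for the non-fitted modes).
    n_iter
        IRLS iterations used (0 for the non-fitted modes).
    """

    mode: str
    coefficients: np.ndarray
    offset: np.ndarray
    converged: bool = True
    n_iter: int = 0

    @property
    def n(self) -> int:
        return self.offset.shape[0]


def fit_logistic_offset(
    Z: np.ndarray,
    outcome: Outcome,
    *,
    allow_nonconverged: bool = False,
) -> OffsetModel:
    """Fit the clinical logistic regression and return its linear predictor.

    Parameters
    ----------
    Z
        n x q numeric covariate matrix (q may be 0 for an intercept-only fit).
        Constant columns are dropped with a warning (they duplicate the
        intercept).
    outcome
        Coded outcome; both classes must be present.
    allow_nonconverged
        Downgrade the separation/non-convergence error to a warning.

    Raises
    ------
    SeparationError
        On (quasi-)complete separation — diagnosed as any |coefficient|
        exceeding 15 or IRLS not converging in 100 iterations — unless
        ``allow_nonconverged`` is set.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.size and Z.shape[0] != outcome.n:
        raise ValueError(f"Z has {Z.shape[0]} rows but outcome has {outcome.n}")
    if Z.size and not np.all(np.isfinite(Z)):
        raise ValueError("missing or non-finite values in clinical covariates")
    n, q = (Z.shape if Z.size else (outcome.n, 0))
    if n <= q + 1:
        raise ValueError(f"need n > q+1 (got n={n}, q={q})")
    if outcome.n_pos == 0 or outcome.n_neg == 0:
        raise ValueError("degenerate outcome: only one class present")

    keep = np.ones(q, dtype=bool)
    if q:
        keep = Z.std(axis=0) > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant clinical column(s) "
                "(duplicate the intercept)",
                stacklevel=2,
            )
    Zk = Z[:, keep] if q else np.empty((n, 0))
    design = sm.add_constant(Zk, has_constant="add")

    ybin = outcome.binary
    model = sm.GLM(ybin, design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-separation warnings handled below
        res = model.fit(maxiter=GLM_MAX_ITER, tol=GLM_TOL)
    converged = bool(res.converged)
    params = np.asarray(res.params, dtype=float)

    bad = (not converged) or (np.max(np.abs(params)) > SEPARATION_COEF_BOUND)
    if bad:
        msg = (
            "separation detected in the clinical logistic fit "
            f"(max|coef| = {np.max(np.abs(params)):.2f}, converged={converged}); "
            "the offset model is degenerate"
        )
        if allow_nonconverged:
            warnings.warn(msg, stacklevel=2)
        else:
            raise SeparationError(msg)

    # re-insert zero coefficients for dropped constant columns
    coef = np.zeros(q + 1)
    coef[0] = params[0]
    if q:
        coef[1:][keep] = params[1:]
    eta = design @ params
    return OffsetModel(
        mode="fitted_glm",
        coefficients=coef,
        offset=np.asarray(eta, dtype=float),
        converged=converged,
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
    )


def offset_from_risk_score(scores: np.ndarray, scale: str = "probability") -> OffsetModel:
    """Build the offset from a previously published per-sample risk score.

    ``scale='probability'`` applies the logit transform (scores must lie
    strictly inside (0, 1)); ``scale='linear'`` takes the scores verbatim as
    log-odds.  Step 1 is skipped entirely: no coefficients are estimated.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1:
        s = s.ravel()
    if scale == "probability":
        bad = ~((s > 0.0) & (s < 1.0))
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"risk score outside (0,1) at index {idx}: {s[idx]!r}"
            )
        offset = linear_predictor_from_prob(s)
    elif scale == "linear":
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite linear risk score")
        offset = s.copy()
    else:
        raise ValueError(f"unknown risk-score scale {scale!r}")
    return OffsetModel(mode="fixed_risk_score", coefficients=np.empty(0), offset=offset)


def intercept_only_offset(outcome: Outcome) -> OffsetModel:
    """Constant offset log(n+/n-): the clinical model reduced to its intercept."""
    if outcome.n_pos == 0 or outcome.n_neg == 0:
        raise ValueError("degenerate outcome: only one class present")
    b0 = float(np.log(outcome.n_pos / outcome.n_neg))
    return OffsetModel(
        mode="intercept_only",
        coefficients=np.array([b0]),
        offset=np.full(outcome.n, b0),
    )
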