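"""Shared numeric primitives.

Outcome coding, logit-scale transforms, and the average negative binomial
log-likelihood that serves as the test statistic throughout the package.

Conventions
-----------
* The binary outcome is coded internally as y in {-1, +1}; the lower of the
  two sorted source levels maps to -1, so results are invariant to row order.
* All likelihood quantities are in natural log units (nats), matching the
  logistic-regression deviance convention.  With this choice the boosting fit
  at zero iterations reproduces the clinical GLM's maximized average negative
  log-likelihood exactly.
* Probabilities are clipped into [PROB_EPS, 1 - PROB_EPS] before logs are
  taken, so permutation statistics stay finite when a fit saturates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.special import expit, logit as _logit

#: Probability clipping bound applied before any log; configurable here once.
PROB_EPS: float = 1e-10


@dataclass(frozen=True)
class Outcome:
    """Binary outcome coded as -1/+1 with the original level mapping retained.

    Attributes
    ----------
    labels
        Array of length n with values in {-1.0, +1.0}.
    original_levels
        The two source labels in sorted order; ``original_levels[0]`` mapped
        to -1 and ``original_levels[1]`` to +1.
    """

    labels: np.ndarray
    original_levels: tuple[Any, Any]

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def binary(self) -> np.ndarray:
        """0/1 indicator y' = 1(y = +1), the working response scale."""
        return (self.labels > 0).astype(float)

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels > 0))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels < 0))


def encode_outcome(raw_labels: Sequence[Any]) -> Outcome:
    """Map a two-level label vector onto {-1, +1}.

    The two distinct levels are sorted and the lower one becomes -1, so the
    coding does not depend on the order in which samples appear.

    Raises
    ------
    ValueError
        If the labels contain missing values, are not exactly two-level, or
        one class is absent.
    """
    arr = np.asarray(raw_labels)
    if arr.size == 0:
        raise ValueError("empty outcome vector")
    if arr.dtype.kind == "f" and np.isnan(arr.astype(float)).any():
        raise ValueError("missing values in outcome")
    if arr.dtype == object and any(x is None or x != x for x in arr):
        raise ValueError("missing values in outcome")
    levels = sorted(set(arr.tolist()))
    if len(levels) == 1:
        raise ValueError("degenerate outcome: only one class present")
    if len(levels) > 2:
        raise ValueError(f"outcome has {len(levels)} levels; exactly 2 required")
    labels = np.where(arr == levels[1], 1.0, -1.0)
    return Outcome(labels=labels, original_levels=(levels[0], levels[1]))


@dataclass(frozen=True)
class LinearPredictor:
    """Per-sample values on the logit (log-odds) scale."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite linear predictor")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def clip_probabilities(p: np.ndarray) -> np.ndarray:
    """Clip probabilities into [PROB_EPS, 1 - PROB_EPS]."""
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def prob_from_linear_predictor(eta: LinearPredictor | np.ndarray) -> np.ndarray:
    """Inverse-logit transform pi = 1 / (1 + exp(-eta)), clipped away from 0/1."""
    v = eta.values if isinstance(eta, LinearPredictor) else np.asarray(eta, dtype=float)
    return clip_probabilities(expit(v))


def linear_predictor_from_prob(p: np.ndarray) -> np.ndarray:
    """Logit transform; inverse of :func:`prob_from_linear_predictor` on (eps, 1-eps)."""
    return _logit(clip_probabilities(np.asarray(p, dtype=float)))


def neg_binomial_loglik(probs: np.ndarray, outcome: Outcome) -> float:
    """Average negative binomial log-likelihood, the test statistic.

    ell = -(1/n) * sum_i [ 1(y_i=+1) log pi_i + 1(y_i=-1) log(1 - pi_i) ]

    Small values indicate good fit; an uninformative model (pi = 1/2
    throughout) gives exactly log 2.
    """
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if p.shape[0] != outcome.n:
        raise ValueError(
            f"length mismatch: {p.shape[0]} probabilities vs {outcome.n} outcomes"
        )
    p = clip_probabilities(p)
    ybin = outcome.binary
    return float(-np.mean(ybin * np.log(p) + (1.0 - ybin) * np.log1p(-p)))
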