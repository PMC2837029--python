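"""Synthetic data generator: Gaussian two-group shift design.

The generator emulates the standard benchmark for "additional predictive
value" testing.  The outcome Y is a fair coin; informative molecular columns
are N(mu_X, 1) in the Y = +1 group and N(0, 1) in the Y = -1 group, the
remaining columns are N(0, 1) regardless of class; clinical covariates
follow the same scheme with shift mu_Z.  A duplication switch makes the
informative molecular columns exact copies of the clinical columns, the
degenerate case in which the molecular block is fully redundant with the
clinical block and a test of *additional* value must not reject.

Named settings (n = 100, p = 1000, q = 5 unless overridden):

========  ====  =====  =====  ==============================================
name      p*    mu_X   mu_Z   description
========  ====  =====  =====  ==============================================
null      0     --     0      no informative molecular variables
a         5     0.5    0      few relevant variables, weak shift
b         5     0.8    0      few relevant variables, strong shift
c         50    0.3    0      many relevant variables, very weak shift
d         50    0.5    0      many relevant variables, weak shift
e         200   0.3    0      very many relevant variables, very weak shift
f1        5     1.0    1.0    clinical and molecular both informative,
                              mutually independent
f2        5     1.0    1.0    as f1 but X_1 = Z_1, ..., X_5 = Z_5 (redundant)
========  ====  =====  =====  ==============================================

All draws come from one ``numpy`` Generator seeded per dataset, so output is
bit-identical across runs and worker counts.  Noise is drawn first and the
group shift added afterwards, so a shared seed across settings yields common
random numbers — the right harness for power comparisons along a shift grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .core import encode_outcome
from .io import Dataset
from .offset import fit_logistic_offset
from .permtest import (
    TestConfig,
    global_boost_test,
    mstop_diagnostic,
    permutation_pvalue,
)

#: Reduced-scale profile for interactive/desk runs vs. full-scale benchmark.
#: "desk" reduces the molecular dimension and permutation count only; the
#: sample size stays at the design's n = 100.
PROFILES: Mapping[str, Mapping[str, int]] = {
    "desk": {"n": 100, "p": 200, "B": 99, "n_reps": 50},
    "paper": {"n": 100, "p": 1000, "B": 200, "n_reps": 100},
}

_NAMED: Mapping[str, dict] = {
    "null": {"p_star": 0, "mu_X": 0.0, "mu_Z": 0.0},
    "a": {"p_star": 5, "mu_X": 0.5, "mu_Z": 0.0},
    "b": {"p_star": 5, "mu_X": 0.8, "mu_Z": 0.0},
    "c": {"p_star": 50, "mu_X": 0.3, "mu_Z": 0.0},
    "d": {"p_star": 50, "mu_X": 0.5, "mu_Z": 0.0},
    "e": {"p_star": 200, "mu_X": 0.3, "mu_Z": 0.0},
    "f1": {"p_star": 5, "mu_X": 1.0, "mu_Z": 1.0},
    "f2": {"p_star": 5, "mu_X": 1.0, "mu_Z": 1.0, "duplicate_xz": True},
}


@dataclass(frozen=True)
class SimSetting:
    """Parameter bundle for one simulation scenario."""

    name: str = "custom"
    n: int = 100
    p: int = 1000
    q: int = 5
    p_star: int = 0
    mu_X: float = 0.0
    mu_Z: float = 0.0
    duplicate_xz: bool = False
    shuffle_columns: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p_star <= self.p):
            raise ValueError(f"p_star must be in [0, p], got {self.p_star}")
        if self.duplicate_xz and self.p_star != self.q:
            raise ValueError(
                "duplication requires p_star == q (informative molecular "
                "columns are copied from the clinical columns)"
            )
        if self.n < 4:
            raise ValueError("need n >= 4")

    @classmethod
    def named(cls, name: str, **overrides) -> "SimSetting":
        """Look up a named scenario, optionally overriding sizes."""
        if name == "custom":
            return cls(name="custom", **overrides)
        if name not in _NAMED:
            raise ValueError(
                f"unknown setting {name!r}; choose from {sorted(_NAMED)} or 'custom'"
            )
        params = dict(_NAMED[name])
        params.update(overrides)
        return cls(name=name, **params)


def simulate_dataset(setting: SimSetting, seed: int) -> Dataset:
    """Draw one dataset (Z, X, y) from the two-group shift design.

    Noise for y, Z and X is drawn in a fixed order before any shift is
    applied, so datasets simulated with the same seed but different shifts
    share their noise realizations exactly.
    """
    rng = np.random.default_rng(seed)
    n, p, q = setting.n, setting.p, setting.q
    y_raw = np.where(rng.random(n) < 0.5, 1, -1)
    Z = rng.standard_normal((n, q))
    X = rng.standard_normal((n, p))
    pos = y_raw == 1
    if q and setting.mu_Z != 0.0:
        Z[pos, :] += setting.mu_Z
    if setting.p_star and not setting.duplicate_xz:
        X[pos, : setting.p_star] += setting.mu_X
    if setting.duplicate_xz:
        X[:, : setting.q] = Z  # exact elementwise copies, after Z is final
    feature_order = np.arange(p)
    if setting.shuffle_columns:
        feature_order = rng.permutation(p)
        X = X[:, feature_order]
    outcome = encode_outcome(y_raw)
    return Dataset(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        Z=Z,
        X=X,
        y=outcome,
        covariate_ids=[f"z{j + 1}" for j in range(q)],
        feature_ids=[f"x{j + 1}" for j in feature_order],
    )


@dataclass
class PowerStudyResult:
    """Rejection rate and p-value distribution over replicate datasets."""

    setting: SimSetting
    alpha: float
    p_values: np.ndarray
    mstop_used: list[int]  # original-data m_stop per replicate

    @property
    def n_reps(self) -> int:
        return self.p_values.shape[0]

    @property
    def rejection_rate(self) -> float:
        return float(np.mean(self.p_values <= self.alpha))

    def quantiles(self, qs=(0.1, 0.25, 0.5, 0.75, 0.9)) -> dict[float, float]:
        vals = np.quantile(self.p_values, qs)
        return {float(q): float(v) for q, v in zip(qs, vals)}

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))

    def to_dict(self) -> dict:
        return {
            "setting": self.setting.name,
            "n": self.setting.n,
            "p": self.setting.p,
            "q": self.setting.q,
            "p_star": self.setting.p_star,
            "mu_X": self.setting.mu_X,
            "mu_Z": self.setting.mu_Z,
            "duplicate_xz": self.setting.duplicate_xz,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "rejection_rate": self.rejection_rate,
            "median_p": self.median_p,
            "p_value_quantiles": {str(k): v for k, v in self.quantiles().items()},
        }


def run_power_study(
    setting: SimSetting,
    n_reps: int,
    test_config: TestConfig,
    alpha: float = 0.05,
) -> PowerStudyResult:
    """Run the full test on ``n_reps`` independent datasets.

    Replicate r draws its dataset with seed ``master + r`` and runs the test
    with the same derived seed, so the whole study is reproducible from
    ``test_config.seed`` alone and replicates are directly comparable across
    settings (common random numbers).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    p_values = np.empty(n_reps)
    mstops: list[int] = []
    for r in range(n_reps):
        rep_seed = int((test_config.seed + 1_000_003 * (r + 1)) % (2**31 - 1))
        ds = simulate_dataset(setting, rep_seed)
        cfg = replace(test_config, seed=rep_seed)
        res = global_boost_test(ds.X, ds.y, cfg, Z=ds.Z)
        p_values[r] = res.p_value
        mstops.append(res.mstop_used[0])
    return PowerStudyResult(
        setting=setting, alpha=alpha, p_values=p_values, mstop_used=mstops
    )


def run_mstop_study(
    setting: SimSetting,
    n_reps: int,
    m_grid: list[int],
    *,
    B: int = 99,
    seed: int = 0,
    nu: float = 0.1,
    allow_nonconverged: bool = False,
) -> np.ndarray:
    """P-values over replicates for several m_stop values at once.

    The boosting path is nested, so one run to max(m_grid) per dataset (and
    per permutation) yields the loss — and hence the p-value — at every grid
    point; this is exactly equivalent to running the fixed-m test separately
    for each m with the same seed.  Returns an (n_reps, len(m_grid)) array
    of p-values; the per-replicate seeding matches :func:`run_power_study`.
    """
    m_grid = [int(m) for m in m_grid]
    pvals = np.empty((n_reps, len(m_grid)))
    for r in range(n_reps):
        rep_seed = int((seed + 1_000_003 * (r + 1)) % (2**31 - 1))
        ds = simulate_dataset(setting, rep_seed)
        off = fit_logistic_offset(ds.Z, ds.y, allow_nonconverged=allow_nonconverged)
        diag = mstop_diagnostic(
            ds.X, ds.y, off, m_grid=m_grid, B=B, seed=rep_seed, nu=nu
        )
        perm = np.asarray(diag["ell_perm"])
        for k in range(len(m_grid)):
            pvals[r, k] = permutation_pvalue(diag["ell_original"][k], perm[:, k])
    return pvals
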