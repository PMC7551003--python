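"""Score-weighted regression and the one-sided non-inferiority contrast test.

For one benefit category we observe triplets (b_i, g_i, s_i): the bioassay
count, the group indicator (0 = black ginseng, 1 = red ginseng) and the
literature-quality score used as a precision weight.  The model is

    b_i = mu + Delta * g_i + eps_i,   eps_i ~ N(0, sigma^2 / s_i), independent,

so mu and mu + Delta are the weighted mean bioassay counts of the black and
red groups.  Non-inferiority of black relative to red at margin gamma (0.8 by
convention here) is the one-sided test

    H0: mu = gamma * (mu + Delta)   vs   H1: mu > gamma * (mu + Delta),

i.e. the linear contrast (1 - gamma) * mu - gamma * Delta tested with a
Student-t statistic on n - 2 degrees of freedom.  Because the design is a
binary indicator, the weighted least-squares fit has a closed form (per-group
weighted means), and the contrast variance is
sigma^2 * (1 / S_black + gamma^2 / S_red) with S_g the group weight sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import FUNCTIONS, StudyRecord
from .scaling import SCORE_FLOOR

__all__ = [
    "UntestableFunctionError",
    "NonInferiorityInput",
    "WLSFit",
    "NonInferiorityResult",
    "fit_weighted_regression",
    "test_noninferiority",
    "run_function_battery",
    "simulate_type1_power",
    "SimulationResult",
]


class UntestableFunctionError(ValueError):
    """One group has no usable records; the regression cannot be estimated."""


@dataclass(frozen=True)
class NonInferiorityInput:
    """Triplets (b_i, g_i, s_i) for one benefit category."""

    b: np.ndarray
    g: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        g = np.asarray(self.g, dtype=int)
        s = np.asarray(self.s, dtype=float)
        if not (b.shape == g.shape == s.shape) or b.ndim != 1:
            raise ValueError("b, g, s must be 1-D arrays of equal length")
        if b.size < 3:
            raise ValueError("need n >= 3 observations (df = n - 2 >= 1)")
        if np.any((g != 0) & (g != 1)):
            raise ValueError("group indicator must be 0 (black) or 1 (red)")
        if np.any(s <= 0):
            raise ValueError("weights must be strictly positive")
        if not (np.any(g == 0) and np.any(g == 1)):
            raise UntestableFunctionError("both groups must be represented")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "s", s)

    @classmethod
    def from_records(cls, records: Sequence[StudyRecord]) -> "NonInferiorityInput":
        """Build the triplets from scored black/red extract records.

        A score of 0 means infinite assumed variance: the record carries no
        information under the weighted model, so it is excluded.  This is the
        exact s -> 0 limit of the WLS fit *including its degrees of freedom*
        (flooring the weight at a tiny epsilon instead would leave the record
        in df while contributing nothing to the residual sum, biasing the
        variance estimate downward).  Scores below :data:`SCORE_FLOOR` are
        treated as zero.
        """
        b, g, s = [], [], []
        for rec in records:
            if rec.group is None:
                continue
            if rec.score is None:
                raise ValueError(f"record {rec.record_id!r} has no score assigned")
            if rec.score < SCORE_FLOOR:
                continue
            b.append(rec.n_bioassays)
            g.append(rec.group)
            s.append(rec.score)
        if not b or not (0 in g and 1 in g):
            raise UntestableFunctionError(
                "need positively scored records from both black and red ginseng"
            )
        return cls(b=np.array(b, float), g=np.array(g), s=np.array(s, float))


@dataclass(frozen=True)
class WLSFit:
    """Closed-form weighted least-squares fit of the two-group model."""

    mu_hat: float
    delta_hat: float
    sigma2_hat: float
    sw_black: float
    sw_red: float
    n_black: int
    n_red: int

    @property
    def n(self) -> int:
        return self.n_black + self.n_red

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass(frozen=True)
class NonInferiorityResult:
    """Estimates, contrast t statistic and one-sided p-value."""

    mu_hat: float
    delta_hat: float
    sigma2_hat: float
    gamma: float
    t_stat: float
    df: int
    p_value: float
    n_black: int
    n_red: int

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def fit_weighted_regression(inp: NonInferiorityInput) -> WLSFit:
    """Exact WLS fit with weight s_i on observation i.

    Because the design is (1, g_i), mu_hat is the s-weighted mean of the
    black-group counts and mu_hat + delta_hat the s-weighted mean of the
    red-group counts; sigma2_hat is the weighted residual sum of squares over
    n - 2.
    """
    black = inp.g == 0
    red = ~black
    sw_black = float(inp.s[black].sum())
    sw_red = float(inp.s[red].sum())
    mu_hat = float((inp.s[black] * inp.b[black]).sum() / sw_black)
    red_mean = float((inp.s[red] * inp.b[red]).sum() / sw_red)
    fitted = np.where(black, mu_hat, red_mean)
    wrss = float((inp.s * (inp.b - fitted) ** 2).sum())
    n = inp.b.size
    return WLSFit(
        mu_hat=mu_hat,
        delta_hat=red_mean - mu_hat,
        sigma2_hat=wrss / (n - 2),
        sw_black=sw_black,
        sw_red=sw_red,
        n_black=int(black.sum()),
        n_red=int(red.sum()),
    )


def test_noninferiority(fit: WLSFit, gamma: float = 0.8) -> NonInferiorityResult:
    """One-sided t test of H0: mu = gamma (mu + Delta) vs H1: mu > gamma (mu + Delta).

    The contrast is (1 - gamma) mu_hat - gamma delta_hat; a positive value
    favors non-inferiority.  With a degenerate variance estimate
    (sigma2_hat = 0, a perfect fit) the p-value is the continuous limit of the
    t statistic: 0 when the contrast is positive, 1 when negative, 0.5 at 0.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    contrast = (1.0 - gamma) * fit.mu_hat - gamma * fit.delta_hat
    var_scale = 1.0 / fit.sw_black + gamma**2 / fit.sw_red
    if fit.sigma2_hat == 0.0:
        if contrast > 0:
            t_stat, p = np.inf, 0.0
        elif contrast < 0:
            t_stat, p = -np.inf, 1.0
        else:
            t_stat, p = 0.0, 0.5
    else:
        se = float(np.sqrt(fit.sigma2_hat * var_scale))
        t_stat = contrast / se
        p = float(stats.t.sf(t_stat, fit.df))
    return NonInferiorityResult(
        mu_hat=fit.mu_hat,
        delta_hat=fit.delta_hat,
        sigma2_hat=fit.sigma2_hat,
        gamma=gamma,
        t_stat=float(t_stat),
        df=fit.df,
        p_value=p,
        n_black=fit.n_black,
        n_red=fit.n_red,
    )


test_noninferiority.__test__ = False  # not a pytest test despite the name


def run_function_battery(
    records: Sequence[StudyRecord],
    gamma: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-function non-inferiority tests on scored black/red extract records.

    Returns one row per benefit category with the estimates, t, one-sided p
    and the decision at level ``alpha``; categories where a group is absent
    (or too small) are flagged ``untestable`` rather than failing.  P-values
    are reported raw, without multiplicity adjustment.
    """
    rows = []
    for function in FUNCTIONS:
        subset = [r for r in records if r.function == function and r.group is not None]
        row = {
            "function": function,
            "n_black": sum(1 for r in subset if r.group == 0),
            "n_red": sum(1 for r in subset if r.group == 1),
            "mu_hat": np.nan,
            "delta_hat": np.nan,
            "t": np.nan,
            "p": np.nan,
            "decision": "untestable",
        }
        try:
            inp = NonInferiorityInput.from_records(subset)
            res = test_noninferiority(fit_weighted_regression(inp), gamma=gamma)
        except (UntestableFunctionError, ValueError):
            rows.append(row)
            continue
        row.update(
            mu_hat=res.mu_hat,
            delta_hat=res.delta_hat,
            t=res.t_stat,
            p=res.p_value,
            decision="reject" if res.reject(alpha) else "fail to reject",
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulationResult:
    rejection_rate: float
    mc_se: float
    n_reps: int
    n_rejected: int
    warning: str | None = None


def simulate_type1_power(
    mu: float,
    delta: float,
    gamma: float = 0.8,
    sigma: float = 1.0,
    weight_dist: tuple[float, float] | Callable = (0.25, 1.0),
    n_per_group: int = 20,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SimulationResult:
    """Monte-Carlo operating characteristics of the non-inferiority test.

    Each replicate draws weights s_i from ``weight_dist`` (a (low, high)
    uniform range, or a callable ``f(rng, size)``), errors from
    N(0, sigma^2 / s_i), fits the weighted regression and applies the test at
    level ``alpha``.  At the boundary null mu = gamma (mu + delta) the
    rejection rate estimates the type-I error; away from it, power.
    """
    if sigma <= 0 or n_per_group < 2 or n_reps < 1:
        raise ValueError("sigma > 0, n_per_group >= 2 and n_reps >= 1 required")
    warning = None
    if n_reps < 100:
        warning = f"n_reps={n_reps} is small; Monte-Carlo error will be large"
        warnings.warn(warning, stacklevel=2)
    rng = np.random.default_rng(seed)
    if callable(weight_dist):
        draw_weights = weight_dist
    else:
        lo, hi = weight_dist
        if not (0 < lo <= hi):
            raise ValueError("weight bounds must satisfy 0 < low <= high")
        draw_weights = lambda r, size: r.uniform(lo, hi, size=size)  # noqa: E731

    g = np.repeat([0, 1], n_per_group)
    n_rejected = 0
    for _ in range(n_reps):
        s = np.asarray(draw_weights(rng, 2 * n_per_group), dtype=float)
        eps = rng.normal(0.0, sigma / np.sqrt(s))
        b = mu + delta * g + eps
        res = test_noninferiority(
            fit_weighted_regression(NonInferiorityInput(b=b, g=g, s=s)), gamma=gamma
        )
        n_rejected += res.p_value < alpha
    rate = n_rejected / n_reps
    return SimulationResult(
        rejection_rate=rate,
        mc_se=float(np.sqrt(rate * (1 - rate) / n_reps)),
        n_reps=n_reps,
        n_rejected=int(n_rejected),
        warning=warning,
    )
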