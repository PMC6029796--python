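"""Monte Carlo probabilistic sensitivity analysis (PSA) over the cost model.

Every uncertain parameter of the :class:`~hinhcost.costs.ParameterSet` is
assigned a :class:`DistributionSpec` (Poisson for monthly counts, gamma fitted
by method of moments for skewed length-of-stay means, normal for model-derived
differences, uniform or symmetric triangular for prices and assumptions).  A
trial samples all varied parameters independently, re-evaluates the net-cost
ledger, and the resulting draw vector is summarised and decomposed into
per-parameter variance contributions via signed squared rank correlations —
the convention of spreadsheet simulation tools' "sensitivity charts".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .costs import CostBreakdown, ParameterSet, net_cost

__all__ = [
    "DistributionSpec",
    "PsaResult",
    "sample_parameter",
    "run_psa",
    "variance_contributions",
    "summarize_draws",
]

KINDS = ("poisson", "gamma_mom", "normal", "uniform", "triangular", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling rule for one parameter.

    Parameters
    ----------
    name : ParameterSet field the draws replace.
    kind : one of ``poisson``, ``gamma_mom``, ``normal``, ``uniform``,
        ``triangular``, ``fixed``.
    base : central value.  ``poisson`` uses it as the mean, ``gamma_mom`` and
        ``normal`` as the mean with spread ``se``, ``fixed`` returns it as is.
    se : standard error for ``gamma_mom`` / ``normal``.
    lo, hi : explicit range for ``uniform`` / ``triangular``.
    rel : relative half-width; ``uniform``/``triangular`` with ``rel=0.25``
        span ``base*(1 -/+ 0.25)`` (triangular mode at ``base``).
    """

    name: str
    kind: str
    base: float
    se: float | None = None
    lo: float | None = None
    hi: float | None = None
    rel: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind in ("gamma_mom", "normal"):
            if self.se is None or self.se <= 0:
                raise ValueError(f"{self.kind} spec for {self.name!r} needs se > 0")
            if self.kind == "gamma_mom" and self.base <= 0:
                raise ValueError("gamma_mom needs a positive mean")
        if self.kind in ("uniform", "triangular"):
            lo, hi = self.bounds()
            if not lo < hi:
                raise ValueError(f"{self.kind} spec for {self.name!r} needs lo < hi")
            if self.kind == "triangular" and not (lo <= self.base <= hi):
                raise ValueError("triangular mode must lie inside [lo, hi]")
        if self.kind == "poisson" and self.base < 0:
            raise ValueError("poisson mean must be non-negative")

    def bounds(self):
        if self.lo is not None and self.hi is not None:
            return float(self.lo), float(self.hi)
        if self.rel is None:
            raise ValueError(f"spec for {self.name!r} needs lo/hi or rel")
        return self.base * (1.0 - self.rel), self.base * (1.0 + self.rel)


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator, size=None):
    """Draw ``size`` values (or one scalar) for a parameter."""
    if spec.kind == "fixed":
        return spec.base if size is None else np.full(size, spec.base, dtype=float)
    if spec.kind == "poisson":
        return rng.poisson(spec.base, size=size)
    if spec.kind == "normal":
        return rng.normal(spec.base, spec.se, size=size)
    if spec.kind == "gamma_mom":
        # method of moments: match the stated mean and standard error
        shape = (spec.base / spec.se) ** 2
        scale = spec.se**2 / spec.base
        return rng.gamma(shape, scale, size=size)
    lo, hi = spec.bounds()
    if spec.kind == "uniform":
        return rng.uniform(lo, hi, size=size)
    return rng.triangular(lo, spec.base, hi, size=size)


@dataclass
class PsaResult:
    """Output of :func:`run_psa`.

    ``draws`` holds the simulated net costs (AU$/year); ``inputs`` the aligned
    per-trial parameter draws (one column per varied parameter);
    ``contributions`` the signed percentage of output variance attributed to
    each input.
    """

    draws: np.ndarray
    inputs: pd.DataFrame
    summary: dict
    contributions: pd.Series
    breakdown: CostBreakdown
    n_trials: int
    seed: int | None = None
    percentiles: tuple = (2.5, 97.5)

    def prob_cost_saving(self) -> float:
        return float(np.mean(self.draws < 0))


def summarize_draws(draws, percentiles=(2.5, 97.5)) -> dict:
    """Mean, median, sd (n-1), min, max and requested percentiles.

    Percentiles use linear interpolation between order statistics (NumPy's
    default), so the reported 95% interval is reproducible elsewhere.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarize an empty draw vector")
    constant = bool(np.all(draws == draws.flat[0]))
    out = {
        "n": int(draws.size),
        "mean": float(draws.flat[0]) if constant else float(np.mean(draws)),
        "median": float(np.median(draws)),
        "sd": 0.0 if constant or draws.size == 1 else float(np.std(draws, ddof=1)),
        "min": float(np.min(draws)),
        "max": float(np.max(draws)),
    }
    for p in percentiles:
        out[f"p{p:g}"] = float(np.percentile(draws, p))
    return out


def variance_contributions(draws, inputs: pd.DataFrame) -> pd.Series:
    """Signed contribution-to-variance of each sampled input, in percent.

    ``contribution_i = sign(rho_i) * rho_i**2 / sum_j rho_j**2 * 100`` where
    ``rho_i`` is the Spearman rank correlation between the draws of input
    ``i`` and the output draws.  Inputs held constant contribute 0 by
    convention.  Absolute contributions sum to 100 over the varied inputs.
    """
    draws = np.asarray(draws, dtype=float)
    if len(draws) != len(inputs):
        raise ValueError("draws and inputs must be aligned by trial")
    rho = {}
    for col in inputs.columns:
        x = inputs[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            rho[col] = 0.0
        else:
            rho[col] = float(stats.spearmanr(x, draws).statistic)
    total = sum(r * r for r in rho.values())
    if total == 0:
        return pd.Series({c: 0.0 for c in rho}, name="contribution_pct")
    contrib = {c: np.sign(r) * r * r / total * 100.0 for c, r in rho.items()}
    out = pd.Series(contrib, name="contribution_pct")
    return out.loc[out.abs().sort_values(ascending=False).index]


def run_psa(
    params: ParameterSet,
    specs: list[DistributionSpec],
    n_trials: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    percentiles=(2.5, 97.5),
) -> PsaResult:
    """Run the Monte Carlo sensitivity analysis.

    Parameters are sampled mutually independently in the (fixed) order of
    ``specs``, so results are fully reproducible for a given seed.  Any trial
    yielding a non-finite net cost aborts the run with the offending draw
    reported.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = {}
    for spec in specs:
        if not hasattr(params, spec.name):
            raise ValueError(f"unknown parameter {spec.name!r}")
        samples[spec.name] = np.asarray(
            sample_parameter(spec, rng, size=n_trials), dtype=float
        )
    inputs = pd.DataFrame(samples)
    trial_params = params.replace(**samples)
    breakdown = net_cost(trial_params)
    draws = np.asarray(breakdown.C, dtype=float)
    if draws.ndim == 0:
        draws = np.full(n_trials, float(draws))
    bad = np.flatnonzero(~np.isfinite(draws))
    if bad.size:
        t = int(bad[0])
        raise RuntimeError(
            f"trial {t} produced a non-finite net cost; parameter draw: "
            f"{inputs.iloc[t].to_dict()}"
        )
    varied = inputs.loc[:, inputs.nunique() > 1]
    return PsaResult(
        draws=draws,
        inputs=inputs,
        summary=summarize_draws(draws, percentiles),
        contributions=variance_contributions(draws, varied if varied.shape[1] else inputs),
        breakdown=breakdown,
        n_trials=n_trials,
        seed=seed,
        percentiles=tuple(percentiles),
    )
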