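"""Monte Carlo uncertainty propagation and standardized-regression sensitivity.

Parameter uncertainty is propagated by sampling every model parameter
independently from a normal distribution with the registry mean and SD
(structural constants — the diel hour budget and the activity multiplier —
are held fixed), evaluating the deterministic consumption pipeline per draw,
and fitting a log-normal to the resulting consumption distribution by
maximum likelihood (mean and SD of the log draws).

The sensitivity analysis perturbs each parameter independently to one of
{mean, mean*(1-p), mean*(1+p)} per iteration, z-scores inputs and output,
and regresses standardized consumption on the standardized inputs; the
coefficients measure each parameter's relative influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bioenergetics as be
from .parameters import FIXED_PARAMETERS, ParameterRegistry

__all__ = [
    "ConsumptionDraws", "SensitivityReport",
    "sample_parameters", "evaluate_model", "run_monte_carlo",
    "sensitivity_analysis",
]

#: hard domain constraints; offending draws are rejected and redrawn
_CONSTRAINTS = {
    "A": lambda v: (v > 0) & (v <= 1),
    "W": lambda v: v > 0,
    "AR": lambda v: v > 0,
    "SL": lambda v: v > 0,
    "Q10": lambda v: v > 0,
    "Fj": lambda v: v > 0,
}

_MAX_REDRAWS = 100


@dataclass
class ConsumptionDraws:
    """Simulated consumption-rate distribution for one model."""

    model: str
    draws: np.ndarray              # J g-1 day-1, all > 0
    n_iterations: int
    seed: int | None
    lognormal_mu: float            # mean of log draws
    lognormal_sigma: float         # SD of log draws
    mean: float                    # arithmetic mean of draws
    median: float                  # empirical median of draws
    n_rejected: int
    running_sd: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def mc_se_mean(self) -> float:
        """Monte Carlo standard error of the arithmetic mean."""
        return float(self.draws.std(ddof=1) / np.sqrt(len(self.draws)))

    @property
    def lognormal_mean(self) -> float:
        """Mean implied by the fitted log-normal, exp(mu + sigma^2/2).

        Comparing this with the arithmetic :attr:`mean` is a quick
        distributional-adequacy diagnostic.
        """
        return float(np.exp(self.lognormal_mu + 0.5 * self.lognormal_sigma**2))

    def summary(self) -> dict:
        return {
            "model": self.model, "n": self.n_iterations, "seed": self.seed,
            "mean": self.mean, "median": self.median,
            "lognormal_mu": self.lognormal_mu,
            "lognormal_sigma": self.lognormal_sigma,
            "lognormal_mean": self.lognormal_mean,
            "mc_se_mean": self.mc_se_mean, "n_rejected": self.n_rejected,
        }


@dataclass
class SensitivityReport:
    """Standardized regression coefficients per parameter for one model."""

    model: str
    coefficients: dict[str, float]
    r_squared: float
    n_iterations: int
    seed: int | None
    perturbation: float = 0.10
    dropped: list[str] = field(default_factory=list)

    def ranked(self) -> list[tuple[str, float]]:
        """Parameters sorted by decreasing absolute coefficient."""
        return sorted(self.coefficients.items(), key=lambda kv: -abs(kv[1]))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_parameters(registry: ParameterRegistry, model: str, n: int,
                      seed=None) -> tuple[pd.DataFrame, int]:
    """Draw n independent normal samples of every parameter of *model*.

    Symbols with zero SD (including the structural constants) yield constant
    columns.  Draws violating hard domain constraints (e.g. non-positive
    mass, assimilated fraction outside (0, 1]) are rejected and redrawn;
    the redraw count is returned alongside the samples.
    """
    registry.require_model(model)
    rng = _rng(seed)
    symbols = registry.symbols_for(model)
    n_rejected = 0
    columns = {}
    for sym in symbols:
        spec = registry[sym]
        if spec.sd == 0 or sym in FIXED_PARAMETERS:
            columns[sym] = np.full(n, spec.mean)
            continue
        values = rng.normal(spec.mean, spec.sd, n)
        check = _CONSTRAINTS.get(sym)
        if check is not None:
            bad = ~check(values)
            tries = 0
            while bad.any():
                n_rejected += int(bad.sum())
                values[bad] = rng.normal(spec.mean, spec.sd, int(bad.sum()))
                bad = ~check(values)
                tries += 1
                if tries > _MAX_REDRAWS:
                    raise RuntimeError(
                        f"parameter {sym!r}: could not draw values satisfying "
                        "its domain constraint (distribution mass almost "
                        "entirely outside the valid range)"
                    )
        columns[sym] = values
    return pd.DataFrame(columns), n_rejected


def evaluate_model(model: str, params: pd.DataFrame, max_speed=None) -> np.ndarray:
    """Evaluate one consumption model at a table of parameter vectors."""
    p = {c: params[c].to_numpy() for c in params.columns}
    if model == "accel":
        amr = be.amr_accelerometry(p["log_s"], p["b"], p["Act_day"], p["Act_night"],
                                   p["h_d"], p["h_n"], p["Oxy"])
    elif model == "morph":
        amr = be.amr_morphometric(p["Int"], p["Lc"], p["Ac"], p["SL"], p["AR"],
                                  p["log_r"], p["z"], p["Oxy"], max_speed=max_speed)
    elif model == "physio":
        amr = be.amr_physiological(p["R_a"], p["R_b"], p["Q10"], p["T"],
                                   p["AM"], p["W"], p["Oxy"])
    else:
        raise KeyError(f"unknown model {model!r}")
    growth = be.growth_energy(p["Gv"], p["W"], p["Fj"])
    return be.consumption(amr, growth, p["A"])


def run_monte_carlo(registry: ParameterRegistry, model: str, n: int = 10_000,
                    seed=None, max_speed=None,
                    n_sd_checkpoints: int = 100) -> ConsumptionDraws:
    """Propagate parameter uncertainty through one model.

    Samples parameters with :func:`sample_parameters`, evaluates consumption
    per draw, and summarises the distribution: arithmetic mean, empirical
    median, and a log-normal fitted by maximum likelihood (``mu``/``sigma``
    are the mean/SD of the log draws).  A running-SD trace at
    ``n_sd_checkpoints`` points is kept as a variance-stabilisation
    diagnostic.  Non-finite or non-positive consumption draws are rejected
    and redrawn; more than 1 % of them is an error.
    """
    rng = _rng(seed)
    params, n_rejected = sample_parameters(registry, model, n, rng)
    draws = evaluate_model(model, params, max_speed=max_speed)

    bad = ~np.isfinite(draws) | (draws <= 0)
    n_bad = 0
    tries = 0
    while bad.any():
        n_bad += int(bad.sum())
        redraw, extra = sample_parameters(registry, model, int(bad.sum()), rng)
        n_rejected += extra
        draws[bad] = evaluate_model(model, redraw, max_speed=max_speed)
        bad = ~np.isfinite(draws) | (draws <= 0)
        tries += 1
        if tries > _MAX_REDRAWS:
            raise RuntimeError(f"model {model!r}: could not obtain finite positive draws")
    if n_bad > 0.01 * n:
        raise RuntimeError(
            f"model {model!r}: {n_bad} of {n} draws were non-finite or "
            "non-positive (> 1 %); check the parameter table"
        )
    n_rejected += n_bad

    log_draws = np.log(draws)
    checkpoints = np.unique(
        np.linspace(max(2, n // n_sd_checkpoints), n, num=min(n_sd_checkpoints, n),
                    dtype=int))
    running_sd = np.array([draws[:c].std(ddof=1) for c in checkpoints])

    return ConsumptionDraws(
        model=model, draws=draws, n_iterations=n,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        lognormal_mu=float(log_draws.mean()),
        lognormal_sigma=float(log_draws.std(ddof=1)),
        mean=float(draws.mean()), median=float(np.median(draws)),
        n_rejected=n_rejected, running_sd=running_sd,
    )


def sensitivity_analysis(registry: ParameterRegistry, model: str,
                         n: int = 10_000, perturbation: float = 0.10,
                         levels: int = 3, seed=None,
                         max_speed=None) -> SensitivityReport:
    """Randomised ±perturbation standardized-regression sensitivity analysis.

    Per iteration each parameter independently takes one of
    ``{mean*(1-p), mean, mean*(1+p)}`` with equal probability
    (``levels=2`` drops the unperturbed level).  Consumption is evaluated
    per iteration, inputs and output are z-scored, and an ordinary multiple
    linear regression of standardized output on standardized inputs yields
    the coefficients.  The diel hour budget (h_d, h_n) is never perturbed
    (doing so would break the 24-h day); constant columns are dropped from
    the regression and reported.
    """
    if levels not in (2, 3):
        raise ValueError("levels must be 2 or 3")
    registry.require_model(model)
    rng = _rng(seed)
    symbols = [s for s in registry.symbols_for(model) if s not in ("h_d", "h_n")]

    factor_levels = (np.array([1.0 - perturbation, 1.0, 1.0 + perturbation])
                     if levels == 3 else
                     np.array([1.0 - perturbation, 1.0 + perturbation]))
    table = {}
    for sym in registry.symbols_for(model):
        mean = registry.mean(sym)
        if sym in symbols:
            table[sym] = mean * rng.choice(factor_levels, size=n)
        else:
            table[sym] = np.full(n, mean)
    params = pd.DataFrame(table)
    draws = evaluate_model(model, params, max_speed=max_speed)

    dropped, kept = [], []
    design = []
    for sym in symbols:
        col = params[sym].to_numpy()
        sd = col.std(ddof=1)
        if sd == 0:
            dropped.append(sym)
            continue
        design.append((col - col.mean()) / sd)
        kept.append(sym)
    X = np.column_stack(design)
    y = (draws - draws.mean()) / draws.std(ddof=1)

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    r_squared = 1.0 - float(resid @ resid) / float(y @ y)

    return SensitivityReport(
        model=model, coefficients=dict(zip(kept, coef.tolist())),
        r_squared=r_squared, n_iterations=n,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        perturbation=perturbation, dropped=dropped,
    )
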