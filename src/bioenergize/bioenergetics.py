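"""Deterministic evaluation of the three consumption models.

All functions are plain NumPy ufunc-style: they accept scalars or arrays and
broadcast.  The energy balance is

    C = (AMR + G) / A      [J g-1 day-1]

where ``AMR`` is active metabolic rate, ``G`` the energy allocated to somatic
growth and ``A`` the net assimilated fraction of consumed energy.  The three
models differ only in how ``AMR`` is obtained:

* accelerometry — field activity converted through the laboratory-calibrated
  exponential activity→metabolic-rate relationship, split into day and night
  periods;
* morphometric — routine swimming speed predicted from body morphology, then
  converted through the calibrated speed→metabolic-rate relationship;
* physiological — an allometric standard metabolic rate with a Q10
  temperature function, scaled by a fixed activity multiplier
  (Wisconsin-style).

Unit conversions are centralised here as module constants.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterRegistry

__all__ = [
    "mr_from_activity", "mr_from_speed", "amr_accelerometry",
    "routine_speed_morphometric", "amr_morphometric", "temperature_factor",
    "amr_physiological", "growth_energy", "vb_length", "vb_growth_rate",
    "consumption", "point_estimate",
]

# --- unit conversion constants (bit-exact) -------------------------------
KMH_TO_MS = 1.0 / 3.6       # km h-1  ->  m s-1
J_PER_KG_TO_J_PER_G = 1e-3  # J kg-1  ->  J g-1
GO2_TO_MGO2 = 1e3           # gO2     ->  mgO2
DAYS_PER_YEAR = 365.25


def mr_from_activity(log_s, b, activity):
    """Mass-specific metabolic rate (mgO2 kg-1 h-1) from activity (m s-2).

    Exponential form ``MR = s * exp(b * Act)`` with ``log_s = ln(s)``; the
    extrapolated rate at zero activity, ``exp(log_s)``, is always positive.
    """
    activity = np.asarray(activity, dtype=float)
    if np.any(activity < 0):
        raise ValueError("activity must be >= 0")
    return np.exp(np.asarray(log_s, dtype=float) + np.asarray(b, dtype=float) * activity)


def mr_from_speed(log_r, z, speed):
    """Mass-specific metabolic rate (mgO2 kg-1 h-1) from swimming speed (m s-1)."""
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be >= 0")
    return np.exp(np.asarray(log_r, dtype=float) + np.asarray(z, dtype=float) * speed)


def amr_accelerometry(log_s, b, act_day, act_night, h_d=12.0, h_n=12.0, oxy=14.14):
    """Daily active metabolic rate (J g-1 day-1) from diel-partitioned activity.

    Day and night mean hourly activities are converted to metabolic rate,
    weighted by the hours in each period, summed, and converted to energy via
    the oxycalorific coefficient ``oxy`` (J mgO2-1).
    """
    daily_mgO2_per_kg = (mr_from_activity(log_s, b, act_day) * h_d
                         + mr_from_activity(log_s, b, act_night) * h_n)
    return daily_mgO2_per_kg * oxy * J_PER_KG_TO_J_PER_G


def routine_speed_morphometric(intercept, lc, ac, sl, ar):
    """Routine swimming speed (m s-1) from a log10-linear morphometric regression.

    ``log10(speed_kmh) = intercept + lc*log10(SL) + ac*log10(AR)`` with
    standard length ``sl`` in cm and caudal-fin aspect ratio ``ar``; the
    regression predicts km h-1 and the result is converted to m s-1.
    """
    sl = np.asarray(sl, dtype=float)
    ar = np.asarray(ar, dtype=float)
    if np.any(sl <= 0) or np.any(ar <= 0):
        raise ValueError("SL and AR must be > 0")
    log10_kmh = (np.asarray(intercept, dtype=float)
                 + np.asarray(lc, dtype=float) * np.log10(sl)
                 + np.asarray(ac, dtype=float) * np.log10(ar))
    return 10.0 ** log10_kmh * KMH_TO_MS


def amr_morphometric(intercept, lc, ac, sl, ar, log_r, z, oxy=14.14,
                     max_speed=None):
    """Daily active metabolic rate (J g-1 day-1) via derived routine speed.

    ``max_speed`` (m s-1) optionally clips the derived speed at the upper end
    of the calibrated swim-tunnel range to guard against extrapolating the
    exponential speed→metabolic-rate relationship; the default (``None``)
    applies no guard.
    """
    speed = routine_speed_morphometric(intercept, lc, ac, sl, ar)
    if max_speed is not None:
        speed = np.minimum(speed, max_speed)
    return mr_from_speed(log_r, z, speed) * 24.0 * oxy * J_PER_KG_TO_J_PER_G


def temperature_factor(q10, temperature_c):
    """Q10 temperature dependence factor ``exp(ln(Q10)/10 * T)``."""
    q10 = np.asarray(q10, dtype=float)
    if np.any(q10 <= 0):
        raise ValueError("Q10 must be > 0")
    return np.exp(np.log(q10) / 10.0 * np.asarray(temperature_c, dtype=float))


def amr_physiological(r_a, r_b, q10, temperature_c, am, mass_g, oxy=14.14):
    """Daily active metabolic rate (J g-1 day-1), Wisconsin-style.

    ``R = R_a * W**R_b * Temp * AM`` in gO2 g-1 day-1, with ``Temp`` the Q10
    factor and ``AM`` the activity multiplier; converted to energy through the
    oxycalorific coefficient.
    """
    mass_g = np.asarray(mass_g, dtype=float)
    if np.any(mass_g <= 0):
        raise ValueError("mass must be > 0")
    r = (np.asarray(r_a, dtype=float) * mass_g ** np.asarray(r_b, dtype=float)
         * temperature_factor(q10, temperature_c) * np.asarray(am, dtype=float))
    return r * GO2_TO_MGO2 * oxy


def growth_energy(gv, mass_g, fj):
    """Energy allocated to somatic growth (J g-1 day-1): ``(Gv / W) * Fj``."""
    mass_g = np.asarray(mass_g, dtype=float)
    if np.any(mass_g <= 0):
        raise ValueError("mass must be > 0")
    return np.asarray(gv, dtype=float) / mass_g * np.asarray(fj, dtype=float)


def vb_length(t0, k, l_inf, age_years):
    """von Bertalanffy length at age: ``L(t) = L_inf * (1 - exp(-k (t - t0)))``."""
    return np.asarray(l_inf, dtype=float) * (
        1.0 - np.exp(-np.asarray(k, dtype=float)
                     * (np.asarray(age_years, dtype=float) - np.asarray(t0, dtype=float))))


def vb_growth_rate(t0, k, l_inf, age_years, lw_coeff_a=None, lw_coeff_b=None):
    """Daily mass growth rate (g day-1) from von Bertalanffy growth.

    Differentiates the mass-at-age curve ``M(t) = a * L(t)**b`` analytically,
    with length in cm from :func:`vb_length` and the length–weight
    coefficients supplied by the caller.  Raises if the length–weight
    coefficients are missing (use a literature growth-rate value instead).
    """
    if lw_coeff_a is None or lw_coeff_b is None:
        raise ValueError(
            "length-weight coefficients lw_coeff_a/lw_coeff_b are required to "
            "convert length growth to mass growth; without them supply a "
            "literature Gv value directly"
        )
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("von Bertalanffy k must be > 0")
    length = vb_length(t0, k, l_inf, age_years)
    dldt_per_year = np.asarray(l_inf, dtype=float) * k * np.exp(
        -k * (np.asarray(age_years, dtype=float) - np.asarray(t0, dtype=float)))
    dmdt_per_year = lw_coeff_a * lw_coeff_b * length ** (lw_coeff_b - 1.0) * dldt_per_year
    return dmdt_per_year / DAYS_PER_YEAR


def consumption(amr, growth, assimilated_fraction, reproduction=0.0):
    """Daily consumption rate (J g-1 day-1): ``C = (AMR + G + Rep) / A``.

    ``assimilated_fraction`` is the share of consumed energy retained after
    egestion, excretion and digestion costs, so the energy budget is divided
    by it to recover gross consumption.  Reproduction defaults to zero
    (juvenile fish).
    """
    a = np.asarray(assimilated_fraction, dtype=float)
    if np.any(a <= 0) or np.any(a > 1):
        raise ValueError("assimilated fraction must lie in (0, 1]")
    return (np.asarray(amr, dtype=float) + np.asarray(growth, dtype=float)
            + np.asarray(reproduction, dtype=float)) / a


def point_estimate(registry: ParameterRegistry, model: str,
                   max_speed=None) -> dict:
    """Evaluate one consumption model at the registry means.

    Returns a dict with ``amr``, ``growth`` and ``consumption`` (all
    J g-1 day-1) plus, for the morphometric model, the derived routine
    ``speed`` in m s-1.
    """
    registry.require_model(model)
    m = registry.mean
    out: dict = {"model": model}
    if model == "accel":
        amr = amr_accelerometry(m("log_s"), m("b"), m("Act_day"), m("Act_night"),
                                m("h_d"), m("h_n"), m("Oxy"))
    elif model == "morph":
        out["speed"] = float(routine_speed_morphometric(
            m("Int"), m("Lc"), m("Ac"), m("SL"), m("AR")))
        amr = amr_morphometric(m("Int"), m("Lc"), m("Ac"), m("SL"), m("AR"),
                               m("log_r"), m("z"), m("Oxy"), max_speed=max_speed)
    elif model == "physio":
        amr = amr_physiological(m("R_a"), m("R_b"), m("Q10"), m("T"),
                                m("AM"), m("W"), m("Oxy"))
    else:
        raise KeyError(f"unknown model {model!r}")
    growth = growth_energy(m("Gv"), m("W"), m("Fj"))
    out["amr"] = float(amr)
    out["growth"] = float(growth)
    out["consumption"] = float(consumption(amr, growth, m("A")))
    return out
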