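"""Seasonal site temperatures and temperature-dependent ontogenetic growth.

A site's climate is summarised by its winter minimum and summer maximum mean
ocean temperature; the intra-annual course is a sinusoid between the two.
Individuals grow along the West universal growth trajectory

    dm/dt = a(T) · m^(3/4) · (1 − (m/M)^(1/4)),

from newborn mass ``m0`` toward the asymptotic mass ``M``.  Ectotherm
temperature dependence enters through the growth coefficient via a Q10 factor,

    a(T) = a_ref · Q10^((T − T_ref)/10),

so sharks grow faster, and reach any given mass younger, in warm water.  At
constant temperature the trajectory has the closed form

    1 − (m(t)/M)^(1/4) = (1 − (m0/M)^(1/4)) · exp(−a t / (4 M^(1/4))),

which this module also inverts (:func:`age_at_mass`) and which the test suite
uses as the oracle for the numerically integrated dynamics.

Units: time in days, mass in grams, temperature in °C; the growth coefficient
``a_ref`` is in g^(1/4)·day^(−1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SiteEnvironment",
    "GrowthParams",
    "temperature_at",
    "growth_coefficient",
    "growth_rate",
    "mass_at_age",
    "age_at_mass",
]

logger = logging.getLogger("dentdist.environment")


@dataclass(frozen=True)
class SiteEnvironment:
    """Seasonal temperature envelope of one site.

    ``t_winter_min`` / ``t_summer_max`` are the winter minimum and summer
    maximum mean ocean temperatures (°C); ``peak_day`` is the day-of-year at
    which the maximum occurs.
    """

    t_winter_min: float
    t_summer_max: float
    peak_day: float = 210.0
    period: float = 365.0
    label: str = "site"

    def __post_init__(self) -> None:
        if self.t_summer_max < self.t_winter_min:
            raise ValueError("t_summer_max must be >= t_winter_min")
        if not (0 <= self.peak_day < self.period):
            raise ValueError("peak_day must lie in [0, period)")
        if self.period <= 0:
            raise ValueError("period must be positive")


@dataclass(frozen=True)
class GrowthParams:
    """West growth-law parameters with Q10 temperature scaling.

    ``m0``: newborn mass (g); ``M``: asymptotic mass (g); ``a_ref``: growth
    coefficient (g^(1/4)/day) at reference temperature ``t_ref`` (°C);
    ``activation``: Q10 factor (≥ 1).  ``t_viable`` bounds the physiological
    temperature range — temperatures outside it are clamped with a warning.
    """

    m0: float = 6.2e3
    M: float = 1.608e5
    a_ref: float = 0.06
    t_ref: float = 15.0
    activation: float = 2.0
    t_viable: tuple[float, float] = (-2.0, 40.0)

    def __post_init__(self) -> None:
        if not (0 < self.m0 < self.M):
            raise ValueError("need 0 < m0 < M")
        if self.a_ref <= 0:
            raise ValueError("a_ref must be positive")
        if self.activation < 1:
            raise ValueError("activation (Q10) must be >= 1")


def temperature_at(t, env: SiteEnvironment):
    """Sea temperature (°C) on day ``t`` of the simulation.

    Sinusoid peaking at ``env.peak_day`` with the summer maximum and reaching
    the winter minimum half a period later; period-periodic in ``t``.
    """
    t = np.asarray(t, dtype=float)
    mid = 0.5 * (env.t_summer_max + env.t_winter_min)
    amp = 0.5 * (env.t_summer_max - env.t_winter_min)
    out = mid + amp * np.cos(2.0 * np.pi * (t - env.peak_day) / env.period)
    return float(out) if out.ndim == 0 else out


def growth_coefficient(T, params: GrowthParams):
    """Temperature-adjusted West growth coefficient a(T) = a_ref·Q10^((T−T_ref)/10)."""
    T = np.asarray(T, dtype=float)
    lo, hi = params.t_viable
    if np.any(T < lo) or np.any(T > hi):
        logger.warning(
            "temperature outside viable range [%s, %s] C; clamping", lo, hi
        )
        T = np.clip(T, lo, hi)
    out = params.a_ref * params.activation ** ((T - params.t_ref) / 10.0)
    return float(out) if out.ndim == 0 else out


def growth_rate(m, T, params: GrowthParams):
    """West growth rate dm/dt (g/day) at mass ``m`` and temperature ``T``.

    Zero at the asymptotic mass ``M``, positive below it.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0) or np.any(m > params.M * (1 + 1e-12)):
        raise ValueError("mass must lie in (0, M]")
    a = growth_coefficient(T, params)
    out = a * m**0.75 * (1.0 - (np.minimum(m, params.M) / params.M) ** 0.25)
    return float(out) if out.ndim == 0 else out


def mass_at_age(t, T, params: GrowthParams):
    """Closed-form constant-temperature mass trajectory m(t), m(0) = m0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    a = growth_coefficient(T, params)
    mu0 = (params.m0 / params.M) ** 0.25
    mu = 1.0 - (1.0 - mu0) * np.exp(-a * t / (4.0 * params.M**0.25))
    out = params.M * mu**4
    return float(out) if out.ndim == 0 else out


def age_at_mass(m_target, T, params: GrowthParams):
    """Age (days) at which the constant-temperature trajectory reaches ``m_target``.

    Inverts :func:`mass_at_age`; strictly decreasing in ``T`` (warm water,
    younger age).  ``m_target`` must lie strictly between ``m0`` and ``M``.
    """
    m = np.asarray(m_target, dtype=float)
    if np.any(m <= params.m0) or np.any(m >= params.M):
        raise ValueError("m_target must lie strictly within (m0, M)")
    a = growth_coefficient(T, params)
    mu0 = (params.m0 / params.M) ** 0.25
    mut = (m / params.M) ** 0.25
    out = (4.0 * params.M**0.25 / a) * np.log((1.0 - mu0) / (1.0 - mut))
    return float(out) if out.ndim == 0 else out
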