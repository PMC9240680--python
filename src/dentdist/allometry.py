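"""Tooth–length–mass allometry for sand tiger sharks.

The metapopulation simulator evolves body *mass*, while the empirical unit of
measurement is the anterior tooth crown height (ATCH, mm).  This module closes
the loop with three monotone transforms:

    total length (cm)  <->  crown height (mm)     (odontometric relation)
    total length (cm)  <->  body mass (g)         (length–mass power law)

and their composition ``mass  <->  crown height`` used to bin simulated teeth.

The default coefficient set is calibrated to the two printed anchors for
*Carcharias taurus*: a 295 cm shark bears a 26.11 mm anterior crown, and the
asymptotic total length of the species is 296 cm.  The tooth–length relation is
proportional by default (a log–log power form is available via ``tooth_form``);
the length–mass law defaults to isometric (exponent 3) with a coefficient that
yields ~161 kg at the asymptotic length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AllometryParams",
    "AllometryDomainError",
    "length_to_tooth",
    "tooth_to_length",
    "length_to_mass",
    "mass_to_length",
    "mass_to_tooth",
    "tooth_to_mass",
]


class AllometryDomainError(ValueError):
    """Input outside the valid (invertible) range of an allometric transform."""


#: crown height gained per cm of total length, calibrated to 295 cm -> 26.11 mm
_DEFAULT_SLOPE = 26.11 / 295.0


@dataclass(frozen=True)
class AllometryParams:
    """Coefficients of the tooth–length and length–mass relations.

    Parameters
    ----------
    tooth_length_slope:
        mm of crown height per cm of total length (linear form) or the
        multiplicative coefficient (power form).
    tooth_length_intercept:
        mm; additive offset of the tooth–length relation (0 keeps the relation
        proportional and invertible down to zero length).
    tooth_power:
        exponent of the power form; 1.0 reduces it to the linear form.
    mass_coeff:
        g · cm^(-mass_exp) coefficient of the length–mass power law.
    mass_exp:
        length–mass exponent (3.0 = isometry).
    length_range:
        (cm, cm) validity window of the tooth–length relation; lengths outside
        it are rejected by :func:`length_to_tooth` / :func:`tooth_to_length`.
    """

    tooth_length_slope: float = _DEFAULT_SLOPE
    tooth_length_intercept: float = 0.0
    tooth_form: str = "linear"  # "linear" | "power"
    tooth_power: float = 1.0
    mass_coeff: float = 6.2e-3
    mass_exp: float = 3.0
    species_label: str = "Carcharias taurus"
    length_range: tuple[float, float] = (10.0, 500.0)

    def __post_init__(self) -> None:
        if self.tooth_length_slope <= 0:
            raise ValueError("tooth_length_slope must be positive")
        if self.mass_coeff <= 0 or self.mass_exp <= 0:
            raise ValueError("mass_coeff and mass_exp must be positive")
        if self.tooth_form not in ("linear", "power"):
            raise ValueError(f"unknown tooth_form {self.tooth_form!r}")
        if self.tooth_power <= 0:
            raise ValueError("tooth_power must be positive")
        lo, hi = self.length_range
        if not (0 <= lo < hi):
            raise ValueError("length_range must satisfy 0 <= lo < hi")


def _as_array(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _ret(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def length_to_tooth(total_length, params: AllometryParams | None = None):
    """Anterior crown height (mm) of a shark of given total length (cm)."""
    params = params or AllometryParams()
    L, scalar = _as_array(total_length)
    lo, hi = params.length_range
    if np.any(L <= 0) or np.any(L < lo) or np.any(L > hi):
        raise AllometryDomainError(
            f"total length outside valid range [{lo}, {hi}] cm"
        )
    return _ret(_tooth_of_length(L, params), scalar)


def _tooth_of_length(L: np.ndarray, params: AllometryParams) -> np.ndarray:
    if params.tooth_form == "linear":
        return params.tooth_length_slope * L + params.tooth_length_intercept
    return params.tooth_length_slope * L**params.tooth_power + params.tooth_length_intercept


def _length_of_tooth(h: np.ndarray, params: AllometryParams) -> np.ndarray:
    core = (h - params.tooth_length_intercept) / params.tooth_length_slope
    if params.tooth_form == "linear":
        return core
    return core ** (1.0 / params.tooth_power)


def tooth_to_length(crown_height, params: AllometryParams | None = None):
    """Total length (cm) from anterior crown height (mm); inverse of
    :func:`length_to_tooth` on the valid range."""
    params = params or AllometryParams()
    h, scalar = _as_array(crown_height)
    if np.any(h <= 0):
        raise AllometryDomainError("crown height must be positive")
    lo, hi = params.length_range
    hlo, hhi = _tooth_of_length(np.array(lo), params), _tooth_of_length(np.array(hi), params)
    if np.any(h < hlo) or np.any(h > hhi):
        raise AllometryDomainError(
            f"crown height outside invertible range [{hlo:.3f}, {hhi:.3f}] mm"
        )
    return _ret(_length_of_tooth(h, params), scalar)


def length_to_mass(total_length, params: AllometryParams | None = None):
    """Body mass (g) from total length (cm) via the power law m = c·L^b."""
    params = params or AllometryParams()
    L, scalar = _as_array(total_length)
    if np.any(L < 0):
        raise AllometryDomainError("total length must be non-negative")
    return _ret(params.mass_coeff * L**params.mass_exp, scalar)


def mass_to_length(mass, params: AllometryParams | None = None):
    """Total length (cm) from body mass (g); inverse of :func:`length_to_mass`."""
    params = params or AllometryParams()
    m, scalar = _as_array(mass)
    if np.any(m < 0):
        raise AllometryDomainError("mass must be non-negative")
    return _ret((m / params.mass_coeff) ** (1.0 / params.mass_exp), scalar)


def mass_to_tooth(mass, params: AllometryParams | None = None):
    """Anterior crown height (mm) of a shark of given body mass (g).

    Composition of :func:`mass_to_length` and the tooth–length relation.  Used
    to map simulator mass bins onto crown-height bins, so it accepts the full
    non-negative mass range without the measurement-validity gate.
    """
    params = params or AllometryParams()
    m, scalar = _as_array(mass)
    if np.any(m < 0):
        raise AllometryDomainError("mass must be non-negative")
    return _ret(_tooth_of_length(mass_to_length(m, params), params), scalar)


def tooth_to_mass(crown_height, params: AllometryParams | None = None):
    """Body mass (g) from anterior crown height (mm)."""
    params = params or AllometryParams()
    h, scalar = _as_array(crown_height)
    if np.any(h <= 0):
        raise AllometryDomainError("crown height must be positive")
    return _ret(length_to_mass(_length_of_tooth(h, params), params), scalar)
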