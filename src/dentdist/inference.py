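"""Dispersal-window inference by grid search over (ξ_j, ξ_a).

For each combination of the juvenile dispersal window ξ_j (grams) and the
adult dispersal window ξ_a (days), the two-site simulator is run and both
sites' dental distributions are summarised by their shape vectors.  Comparing
an observed assemblage against the simulated juvenile and adult sites yields
two error surfaces ε_j(ξ_j, ξ_a) and ε_a(ξ_j, ξ_a); the hypothesis (site
identity) and grid point attaining the lower minimum give the best-fit
dispersal strategy.  Surfaces are displayed as 10%-of-minimum error bands;
near-equal minima are flagged ambiguous.  A seeded recovery harness checks
that samples generated at a known grid node are classified and located
correctly.

Simulations and their shape vectors are memoised by config hash, so the two
hypotheses and repeated fits against the same grid reuse runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .shapes import ShapeVector, compute_shape_vector, DentalDistribution, error_epsilon
from .simulate import ADULT, JUVENILE, RunConfig, run_cached

__all__ = [
    "DispersalGrid",
    "ErrorSurface",
    "FitResult",
    "compute_error_surface",
    "classify_from_minima",
    "classify_site",
    "error_contours",
    "fit_observed",
    "recover_parameters",
    "clear_shape_cache",
]

logger = logging.getLogger("dentdist.inference")


@dataclass(frozen=True)
class DispersalGrid:
    """Grid of candidate dispersal windows: ξ_j in grams, ξ_a in days."""

    xi_j_values: tuple[float, ...]
    xi_a_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals in (("xi_j_values", self.xi_j_values),
                           ("xi_a_values", self.xi_a_values)):
            arr = np.asarray(vals, dtype=float)
            if arr.size < 3:
                raise ValueError(f"{name} needs at least 3 values")
            if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be positive and ascending")

    @staticmethod
    def log_spaced(xi_j_range: tuple[float, float] = (2e2, 5e4),
                   xi_a_range: tuple[float, float] = (1.0, 120.0),
                   n: int = 10) -> "DispersalGrid":
        return DispersalGrid(tuple(np.geomspace(*xi_j_range, n)),
                             tuple(np.geomspace(*xi_a_range, n)))

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.xi_j_values), len(self.xi_a_values)


@dataclass
class ErrorSurface:
    """ε over the grid for both site-identity hypotheses (NaN = failed run)."""

    grid: DispersalGrid
    epsilon_j: np.ndarray  # (n_xi_j, n_xi_a)
    epsilon_a: np.ndarray
    failures: list = None

    def __post_init__(self) -> None:
        if self.failures is None:
            self.failures = []
        for eps in (self.epsilon_j, self.epsilon_a):
            valid = eps[np.isfinite(eps)]
            if np.any(valid < 0):
                raise ValueError("epsilon values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        band_j = error_contours(self.epsilon_j)
        band_a = error_contours(self.epsilon_a)
        rows = []
        for i, xj in enumerate(self.grid.xi_j_values):
            for j, xa in enumerate(self.grid.xi_a_values):
                rows.append((xj, xa, self.epsilon_j[i, j], self.epsilon_a[i, j],
                             band_j[i, j], band_a[i, j]))
        return pd.DataFrame(rows, columns=["xi_j", "xi_a", "eps_j", "eps_a",
                                           "band_j", "band_a"])


@dataclass
class FitResult:
    """Best-fit site identity and dispersal windows."""

    site_identity: str  # "juvenile" | "adult" | "ambiguous"
    ambiguous: bool
    best_xi_j: float
    best_xi_a: float
    best_index: tuple[int, int]
    eps_j_min: float
    eps_a_min: float
    within10_mask: np.ndarray

    def as_dict(self) -> dict:
        return {
            "site_identity": self.site_identity,
            "ambiguous": self.ambiguous,
            "best_xi_j": self.best_xi_j,
            "best_xi_a": self.best_xi_a,
            "eps_j_min": self.eps_j_min,
            "eps_a_min": self.eps_a_min,
        }


# shape vectors of simulated sites, keyed by config hash
_SHAPE_CACHE: dict[str, tuple[ShapeVector, ShapeVector]] = {}


def clear_shape_cache() -> None:
    _SHAPE_CACHE.clear()


def simulated_site_shapes(config: RunConfig, xi_j: float, xi_a: float,
                          prominence_frac: float = 0.05
                          ) -> tuple[ShapeVector, ShapeVector]:
    """Shape vectors of the simulated (juvenile, adult) dental distributions."""
    cfg = config.with_dispersal(xi_j=xi_j, xi_a=xi_a)
    key = cfg.config_hash()
    if key not in _SHAPE_CACHE:
        acc = run_cached(cfg).accumulator
        shapes = []
        for s in (JUVENILE, ADULT):
            edges, counts = acc.site_histogram(s)
            dist = DentalDistribution(bin_edges=edges, counts=counts)
            shapes.append(compute_shape_vector(dist, prominence_frac=prominence_frac))
        _SHAPE_CACHE[key] = tuple(shapes)
    return _SHAPE_CACHE[key]


def compute_error_surface(obs: ShapeVector, config: RunConfig,
                          grid: DispersalGrid) -> ErrorSurface:
    """Evaluate ε against both simulated sites at every grid point.

    A grid point whose simulation fails is recorded in ``failures`` and left
    NaN; the search continues over the remaining points.
    """
    nj, na = grid.shape
    eps_j = np.full((nj, na), np.nan)
    eps_a = np.full((nj, na), np.nan)
    failures = []
    for i, xj in enumerate(grid.xi_j_values):
        for j, xa in enumerate(grid.xi_a_values):
            try:
                sj, sa = simulated_site_shapes(config, xj, xa)
                eps_j[i, j] = error_epsilon(sj, obs)
                eps_a[i, j] = error_epsilon(sa, obs)
            except Exception as exc:  # noqa: BLE001 - flagged, not fatal
                failures.append(((i, j), repr(exc)))
                logger.warning("grid point (xi_j=%.3g, xi_a=%.3g) failed: %s",
                               xj, xa, exc)
    if failures:
        logger.warning("%d/%d grid points failed", len(failures), nj * na)
    return ErrorSurface(grid, eps_j, eps_a, failures)


def _argmin_prefer_small(eps: np.ndarray) -> tuple[int, int]:
    """Index of the minimum; ε ties break toward smaller (stricter) windows."""
    m = np.nanmin(eps)
    cand = np.argwhere(eps == m)
    i, j = min(map(tuple, cand))
    if len(cand) > 1:
        logger.info("epsilon tie at %d grid points; choosing strictest windows", len(cand))
    return int(i), int(j)


def classify_from_minima(eps_j_min: float, eps_a_min: float,
                         ambiguity_threshold: float = 0.15) -> tuple[str, bool]:
    """Site identity and ambiguity flag from the two minimal ε values.

    The hypothesis with the lower minimum wins; the result is flagged
    ambiguous when the relative gap |ε_j − ε_a| / min(ε_j, ε_a) falls below
    the threshold (and the identity is ``"ambiguous"`` on an exact tie).
    """
    lo = min(eps_j_min, eps_a_min)
    gap = abs(eps_j_min - eps_a_min) / lo if lo > 0 else 0.0
    ambiguous = gap < ambiguity_threshold
    if eps_j_min == eps_a_min:
        return "ambiguous", True
    return ("juvenile" if eps_j_min < eps_a_min else "adult"), ambiguous


def classify_site(surface: ErrorSurface,
                  ambiguity_threshold: float = 0.15) -> FitResult:
    """Pick the site-identity hypothesis and dispersal windows with lowest ε.

    The identity with the lower minimum wins; when the relative gap
    |ε_j − ε_a| / min(ε_j, ε_a) between the two minima falls below
    ``ambiguity_threshold`` the result is flagged ambiguous (identity is
    reported as ``"ambiguous"`` only on an exact tie).
    """
    if not (np.any(np.isfinite(surface.epsilon_j))
            and np.any(np.isfinite(surface.epsilon_a))):
        raise ValueError("error surface has no valid entries for a hypothesis")
    ej = float(np.nanmin(surface.epsilon_j))
    ea = float(np.nanmin(surface.epsilon_a))
    identity, ambiguous = classify_from_minima(ej, ea, ambiguity_threshold)
    winning = surface.epsilon_a if identity == "adult" else surface.epsilon_j
    i, j = _argmin_prefer_small(winning)
    return FitResult(
        site_identity=identity,
        ambiguous=ambiguous,
        best_xi_j=float(surface.grid.xi_j_values[i]),
        best_xi_a=float(surface.grid.xi_a_values[j]),
        best_index=(i, j),
        eps_j_min=ej,
        eps_a_min=ea,
        within10_mask=error_contours(winning) == 0,
    )


def error_contours(eps: np.ndarray) -> np.ndarray:
    """Band index per cell in 10% steps above the surface minimum.

    Band b covers ε in [ε_min·(1 + 0.1 b), ε_min·(1 + 0.1 (b+1))); band 0 is
    within 10% of the minimum.  NaN cells get band −1.
    """
    eps = np.asarray(eps, dtype=float)
    m = float(np.nanmin(eps))
    band = np.full(eps.shape, -1.0)
    finite = np.isfinite(eps)
    if m == 0.0:
        big = float(np.iinfo(np.int64).max)
        band[finite] = np.where(eps[finite] == 0.0, 0.0, big)
    else:
        band[finite] = np.floor((eps[finite] / m - 1.0) / 0.1)
    return band.astype(np.int64)


def fit_observed(obs_dist: DentalDistribution, config: RunConfig,
                 grid: Optional[DispersalGrid] = None,
                 ambiguity_threshold: float = 0.15,
                 prominence_frac: float = 0.05
                 ) -> tuple[FitResult, ErrorSurface]:
    """End-to-end fit of an observed dental distribution."""
    grid = grid or DispersalGrid.log_spaced()
    obs = compute_shape_vector(obs_dist, prominence_frac=prominence_frac)
    surface = compute_error_surface(obs, config, grid)
    return classify_site(surface, ambiguity_threshold), surface


def recover_parameters(true_xi_j: float, true_xi_a: float, true_site: str,
                       config: RunConfig, grid: DispersalGrid,
                       n_teeth: int = 5000, seed: int = 0) -> dict:
    """Self-consistency check: sample at a known grid node, fit, and score.

    Returns the fitted result plus ``identity_correct`` and
    ``grid_distance`` — the Chebyshev distance (in grid cells) between the
    recovered and true (ξ_j, ξ_a) node.
    """
    from .synthetic import generate_synthetic_observed

    if n_teeth < 100:
        raise ValueError("n_teeth must be at least 100")
    obs_dist = generate_synthetic_observed(config, true_xi_j, true_xi_a,
                                           true_site, n_teeth, seed)
    fit, surface = fit_observed(obs_dist, config, grid)
    ti = int(np.argmin(np.abs(np.asarray(grid.xi_j_values) - true_xi_j)))
    tj = int(np.argmin(np.abs(np.asarray(grid.xi_a_values) - true_xi_a)))
    bi, bj = fit.best_index
    dist_cells = max(abs(bi - ti), abs(bj - tj))
    identity_correct = fit.site_identity == true_site
    return {
        "fit": fit,
        "surface": surface,
        "true_index": (ti, tj),
        "identity_correct": bool(identity_correct),
        "grid_distance": int(dist_cells),
        "seed": seed,
        "n_teeth": n_teeth,
    }
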