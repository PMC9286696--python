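"""Parameterization of simulated metacommunities.

Every simulation is fully described by a :class:`ParamSet`: the species pool,
the landscape, the climate process, species' environmental and demographic
sensitivities, Lotka-Volterra competition coefficients, and the dispersal
rate.  :func:`sample_params` draws one such parameterization from the study's
sampling distributions, so an ensemble of simulations explores the joint
parameter space rather than a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

import numpy as np

__all__ = ["ParamSet", "sample_params", "LOCAL_PATCH_CHOICES"]

#: Perfect-square patch counts admissible for the nearest-neighbour lattice,
#: spanning the same 9-49 range used for global dispersal.
LOCAL_PATCH_CHOICES = (9, 16, 25, 36, 49)

# Scalar fields a caller may override; drawn before the per-species vectors so
# that overriding S, P or a spread parameter reshapes the dependent draws.
_SCALAR_FIELDS = ("S", "P", "h", "a", "env_sd", "r_avg", "beta_max", "d")
_VECTOR_FIELDS = ("sigma_e", "sigma_d", "r", "beta", "K")
_OTHER_FIELDS = ("dispersal_mode", "extinction_threshold")
_DERIVED_FIELDS = ("b",)


@dataclass(frozen=True)
class ParamSet:
    """One simulated metacommunity's full parameterization.

    Attributes
    ----------
    S, P : int
        Regional species-pool size and number of patches.
    h : float
        Spatial heterogeneity: sd of patch-level environmental conditions
        around the regional climate value.
    a : float
        Temporal autocorrelation of the regional climate (AR(1) coefficient).
    b : float
        Climate noise magnitude, ``sqrt(1 - a**2)``; derived, keeps the
        stationary climate variance at 1 for every ``a``.
    env_sd : float
        Sd of species' responses to environmental variation.
    sigma_e, sigma_d : ndarray, shape (S,)
        Per-species environmental response and demographic-stochasticity
        susceptibility.
    r_avg : float
        Half-width of the growth-rate distribution around 0.5.
    r : ndarray, shape (S,)
        Intrinsic growth rates.
    beta_max : float
        Upper bound of competition coefficients.
    beta : ndarray, shape (S, S)
        Competition coefficient of species j (column) on species s (row);
        the diagonal is zero and unused (intraspecific competition enters
        through N/K).
    d : float
        Dispersal probability, shared across species.
    K : ndarray, shape (S,)
        Carrying capacities.
    seed : int
        RNG seed the set was drawn with; also seeds the simulation.
    dispersal_mode : str
        ``"global"`` or ``"local"`` (square lattice, wrap-around boundaries).
    extinction_threshold : float
        Abundance below which a local population is set to zero after each
        growth step ("less than one individual").
    """

    S: int
    P: int
    h: float
    a: float
    b: float
    env_sd: float
    sigma_e: np.ndarray
    sigma_d: np.ndarray
    r_avg: float
    r: np.ndarray
    beta_max: float
    beta: np.ndarray
    d: float
    K: np.ndarray
    seed: int
    dispersal_mode: str = "global"
    extinction_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.dispersal_mode not in ("global", "local"):
            raise ValueError(
                f"dispersal_mode must be 'global' or 'local', got {self.dispersal_mode!r}"
            )
        if not np.isclose(self.a**2 + self.b**2, 1.0):
            raise ValueError("climate parameters must satisfy a**2 + b**2 == 1")
        if self.dispersal_mode == "local" and not _is_perfect_square(self.P):
            raise ValueError(
                f"local dispersal requires a perfect-square patch count "
                f"(square lattice with wrap-around boundaries); got P={self.P}"
            )
        for name, vec in (("sigma_e", self.sigma_e), ("sigma_d", self.sigma_d),
                          ("r", self.r), ("K", self.K)):
            if np.asarray(vec).shape != (self.S,):
                raise ValueError(f"{name} must have shape ({self.S},)")
        if np.asarray(self.beta).shape != (self.S, self.S):
            raise ValueError(f"beta must have shape ({self.S}, {self.S})")
        if np.any(np.asarray(self.K) <= 0):
            raise ValueError("all carrying capacities K must be positive")
        if not 0 <= self.d <= 1:
            raise ValueError("dispersal probability d must lie in [0, 1]")

    def scalars(self) -> dict[str, float]:
        """The scalar parameters recorded per-run in ensemble tables."""
        return {name: getattr(self, name) for name in _SCALAR_FIELDS}


def _is_perfect_square(n: int) -> bool:
    root = int(np.sqrt(n) + 0.5)
    return root * root == n


def sample_params(
    seed: int,
    overrides: Mapping[str, Any] | None = None,
    dispersal_mode: str = "global",
    extinction_threshold: float = 0.5,
) -> ParamSet:
    """Draw one :class:`ParamSet` from the study's sampling distributions.

    Scalars: S ~ discrete-uniform{15..55}, P ~ discrete-uniform{9..49}
    (restricted to perfect squares in local mode), h ~ U(0, 0.5),
    a ~ U(0, 0.75), env_sd ~ U(0.05, 0.5), r_avg ~ U(0, 0.25),
    beta_max ~ U(0, 0.5), d ~ U(0, 0.2).  Vectors (length S):
    sigma_e ~ N(0, env_sd), sigma_d ~ U(0, 0.75),
    r ~ U(0.5 - r_avg, 0.5 + r_avg), beta entries ~ U(0, beta_max)
    (diagonal zeroed), K ~ lognormal(logmean=3, logsd=1).
    b = sqrt(1 - a**2) is derived, never drawn.

    Parameters
    ----------
    seed : int
        RNG seed; the same (seed, overrides) always yields an identical set.
    overrides : mapping, optional
        Field values replacing the sampled ones.  Scalar overrides (incl. S
        and P) are applied *before* the per-species vectors are drawn so the
        dependent draws use the overridden values; vector overrides replace
        the drawn arrays.  Overriding the derived field ``b`` is an error.

    Examples
    --------
    >>> p = sample_params(1, overrides={"a": 0.6})
    >>> round(p.b, 10)
    0.8
    """
    overrides = dict(overrides or {})
    for name in _DERIVED_FIELDS:
        if name in overrides:
            raise ValueError(
                f"{name!r} is derived (b = sqrt(1 - a**2)) and cannot be overridden; "
                f"override 'a' instead"
            )
    valid = set(_SCALAR_FIELDS) | set(_VECTOR_FIELDS) | set(_OTHER_FIELDS) | {"seed"}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown ParamSet field(s) in overrides: {sorted(unknown)}")

    dispersal_mode = overrides.pop("dispersal_mode", dispersal_mode)
    extinction_threshold = overrides.pop("extinction_threshold", extinction_threshold)
    stored_seed = overrides.pop("seed", seed)

    # Dedicated sub-stream so parameter draws never alias simulation noise.
    rng = np.random.default_rng([0, seed])

    draws: dict[str, Any] = {}
    draws["S"] = int(rng.integers(15, 56))
    if dispersal_mode == "local":
        draws["P"] = int(rng.choice(LOCAL_PATCH_CHOICES))
    else:
        draws["P"] = int(rng.integers(9, 50))
    draws["h"] = rng.uniform(0.0, 0.5)
    draws["a"] = rng.uniform(0.0, 0.75)
    draws["env_sd"] = rng.uniform(0.05, 0.5)
    draws["r_avg"] = rng.uniform(0.0, 0.25)
    draws["beta_max"] = rng.uniform(0.0, 0.5)
    draws["d"] = rng.uniform(0.0, 0.2)
    for name in _SCALAR_FIELDS:
        if name in overrides:
            draws[name] = overrides.pop(name)
    draws["S"] = int(draws["S"])
    draws["P"] = int(draws["P"])

    S = draws["S"]
    draws["sigma_e"] = rng.normal(0.0, draws["env_sd"], size=S)
    draws["sigma_d"] = rng.uniform(0.0, 0.75, size=S)
    draws["r"] = rng.uniform(0.5 - draws["r_avg"], 0.5 + draws["r_avg"], size=S)
    beta = rng.uniform(0.0, draws["beta_max"], size=(S, S))
    np.fill_diagonal(beta, 0.0)
    draws["beta"] = beta
    draws["K"] = rng.lognormal(mean=3.0, sigma=1.0, size=S)
    for name in _VECTOR_FIELDS:
        if name in overrides:
            draws[name] = np.asarray(overrides.pop(name), dtype=float)

    draws["b"] = float(np.sqrt(1.0 - draws["a"] ** 2))
    return ParamSet(
        seed=stored_seed,
        dispersal_mode=dispersal_mode,
        extinction_threshold=extinction_threshold,
        **draws,
    )
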