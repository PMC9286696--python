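"""Stochastic metacommunity dynamics.

The model couples patch-level discrete-time Lotka-Volterra competition with
demographic and environmental stochasticity, regional climate forcing, and
between-patch dispersal.  Each time step applies dispersal first, then local
population growth:

    N[s,p,t+d]  = N[s,p,t] - E[s,p,t] + I[s,p,t]                 (dispersal)
    N[s,p,t+1]  = N[s,p,t+d] * exp( r_s (1 - N[s,p,t+d]/K_s
                    - sum_{j!=s} beta_sj N[j,p,t+d]/K_j)
                    + sigma_e_s * mu_e[p,t]
                    + sigma_d_s * mu_d[s,p,t] / sqrt(N[s,p,t+d]) )  (growth)

with emigrants E binomially distributed and the regional climate an AR(1)
process c[t+1] = a*c[t] + b*phi[t], b = sqrt(1 - a^2), so the stationary
climate variance is 1 for every autocorrelation level.  Patch conditions are
mu_e[p,t] ~ Normal(c[t], h).  Local populations falling below an extinction
threshold are set to zero, which is what lets species richness fluctuate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParamSet

__all__ = [
    "ClimateSeries",
    "AbundanceCube",
    "generate_climate",
    "environment_draw",
    "disperse_global",
    "disperse_local",
    "growth_step",
    "run_simulation",
]


@dataclass(frozen=True)
class ClimateSeries:
    """Regional climate c_t: an AR(1) series with stationary variance 1."""

    c: np.ndarray
    a: float
    b: float

    def __len__(self) -> int:
        return len(self.c)


@dataclass
class AbundanceCube:
    """Species x patch x time abundances from one simulation.

    ``N[s, p, t]`` is the (continuous) abundance of species ``s`` in patch
    ``p`` at step ``t``.  ``burn_in`` marks the boundary of the analysis
    window: steps ``burn_in:`` reflect the model's stationary behaviour.
    """

    N: np.ndarray
    burn_in: int
    params: ParamSet | None = None

    def __post_init__(self) -> None:
        N = np.asarray(self.N, dtype=float)
        if N.ndim != 3:
            raise ValueError("N must be a 3-d (species, patch, time) array")
        if np.any(N < 0):
            raise ValueError("abundances must be nonnegative")
        if not 0 <= self.burn_in < N.shape[2]:
            raise ValueError("burn_in must lie inside the time axis")
        self.N = N

    @property
    def n_species(self) -> int:
        return self.N.shape[0]

    @property
    def n_patches(self) -> int:
        return self.N.shape[1]

    @property
    def n_steps(self) -> int:
        return self.N.shape[2]

    def analysis_window(self) -> np.ndarray:
        """The post-burn-in portion of the cube (a view)."""
        return self.N[:, :, self.burn_in:]


def generate_climate(a: float, T: int, seed=None, rng: np.random.Generator | None = None) -> ClimateSeries:
    """Generate the regional climate series c of length ``T``.

    c_0 = 0 and c_{t+1} = a*c_t + b*phi_t with phi_t iid standard normal and
    b = sqrt(1 - a^2), so var(c) -> 1 regardless of ``a``.

    Raises
    ------
    ValueError
        If ``a`` is outside [0, 1) (the process would be nonstationary) or
        ``T < 1``.
    """
    if not 0.0 <= a < 1.0:
        raise ValueError(f"climate autocorrelation a must lie in [0, 1); got {a}")
    if T < 1:
        raise ValueError("T must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    b = float(np.sqrt(1.0 - a * a))
    phi = rng.standard_normal(T - 1)
    c = np.empty(T)
    c[0] = 0.0
    for t in range(T - 1):
        c[t + 1] = a * c[t] + b * phi[t]
    return ClimateSeries(c=c, a=float(a), b=b)


def environment_draw(
    climate: ClimateSeries, h: float, P: int, seed=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Patch-level environmental conditions mu_e, shape (P, T).

    Each column t holds P independent Normal(c_t, h) draws; h = 0 gives all
    patches identical forcing (a pure Moran driver).
    """
    if h < 0:
        raise ValueError("patch heterogeneity h must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    T = len(climate)
    return climate.c[None, :] + h * rng.standard_normal((P, T))


def _draw_emigrants(N_t: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Binomial emigrant draw, clipped so emigration never exceeds stock.

    Propagule emigration is Binomial(round(N), d) per population; because
    round(N) can exceed a fractional N by up to 0.5, the draw is capped at N
    to keep post-dispersal abundances nonnegative.
    """
    n_trials = np.rint(N_t).astype(np.int64)
    E = rng.binomial(n_trials, d).astype(float)
    return np.minimum(E, N_t)


def disperse_global(
    N_t: np.ndarray, d: float, seed=None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One global-dispersal step: emigrants redistribute evenly to all other patches.

    Per species, emigrants E[s,p] ~ Binomial(round(N[s,p]), d) leave patch p
    and every other patch receives the equal fractional share E[s,p]/(P-1),
    so per-species metacommunity totals are conserved exactly.
    """
    N_t = np.asarray(N_t, dtype=float)
    if np.any(N_t < 0):
        raise ValueError("abundances must be nonnegative")
    if not 0.0 <= d <= 1.0:
        raise ValueError("dispersal probability d must lie in [0, 1]")
    if d == 0.0:
        return N_t.copy()
    P = N_t.shape[-1]
    if P < 2:
        raise ValueError("global dispersal needs at least 2 patches when d > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    E = _draw_emigrants(N_t, d, rng)
    # Immigrants to p: equal share of all other patches' emigrants.
    total_E = E.sum(axis=-1, keepdims=True)
    I = (total_E - E) / (P - 1)
    return N_t - E + I


def disperse_local(
    N_t: np.ndarray, d: float, seed=None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One local-dispersal step on a square lattice with wrap-around boundaries.

    Patches are the row-major cells of an L x L torus (P = L**2); emigrants
    from a patch split equally among its 4 von-Neumann neighbours.
    """
    N_t = np.asarray(N_t, dtype=float)
    if np.any(N_t < 0):
        raise ValueError("abundances must be nonnegative")
    if not 0.0 <= d <= 1.0:
        raise ValueError("dispersal probability d must lie in [0, 1]")
    P = N_t.shape[-1]
    L = int(np.sqrt(P) + 0.5)
    if L * L != P:
        raise ValueError(
            f"local dispersal requires a perfect-square patch count "
            f"(square lattice with wrap-around boundaries); got P={P}"
        )
    if d == 0.0:
        return N_t.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    E = _draw_emigrants(N_t, d, rng)
    grid = E.reshape(N_t.shape[:-1] + (L, L))
    share = grid / 4.0
    I = (
        np.roll(share, 1, axis=-1) + np.roll(share, -1, axis=-1)
        + np.roll(share, 1, axis=-2) + np.roll(share, -1, axis=-2)
    )
    return N_t - E + I.reshape(N_t.shape)


def growth_step(
    N_disp: np.ndarray,
    params: ParamSet,
    mu_e_col: np.ndarray,
    seed=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One local growth step applied to post-dispersal abundances.

    Implements discrete-time Lotka-Volterra competition with environmental
    forcing (sigma_e_s * mu_e[p]) and demographic stochasticity
    (sigma_d_s * mu_d / sqrt(N), the first-order normal approximation of
    individual-level birth-death variability).  Extinct populations (N = 0)
    stay extinct; populations falling below ``params.extinction_threshold``
    after growth are set to zero.
    """
    N_disp = np.asarray(N_disp, dtype=float)
    if np.any(N_disp < 0):
        raise ValueError("abundances must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    K = params.K[:, None]
    r = params.r[:, None]
    alive = N_disp > 0

    # Competition term: sum_{j != s} beta[s, j] * N[j, p] / K[j]; the beta
    # diagonal is zero so a plain matmul excludes self-competition.
    comp = params.beta @ (N_disp / K)
    mu_d = rng.standard_normal(N_disp.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        # 1/sqrt(N) is the first-order normal approximation of demographic
        # stochasticity, derived for N counted in whole individuals; below one
        # individual it diverges, so the divisor is floored at 1 (fractional
        # immigrant shares would otherwise receive unbounded noise).
        demo = np.where(
            alive,
            params.sigma_d[:, None] * mu_d / np.sqrt(np.maximum(N_disp, 1.0)),
            0.0,
        )
        exponent = (
            r * (1.0 - N_disp / K - comp)
            + params.sigma_e[:, None] * mu_e_col[None, :]
            + demo
        )
        N_next = np.where(alive, N_disp * np.exp(exponent), 0.0)
    if not np.all(np.isfinite(N_next)):
        s, p = np.argwhere(~np.isfinite(N_next))[0]
        raise FloatingPointError(
            f"non-finite abundance produced for species {s}, patch {p}"
        )
    N_next[N_next < params.extinction_threshold] = 0.0
    return N_next


def run_simulation(
    params: ParamSet, T_total: int = 100, burn_in: int = 50
) -> AbundanceCube:
    """Simulate the metacommunity for ``T_total`` steps.

    All species start at their carrying capacities (N[s,p,0] = K_s); each
    step applies dispersal then growth.  The first ``burn_in`` steps remove
    the influence of initial conditions; analyses use the remaining window.
    Fully deterministic given ``params`` (the RNG sub-streams are derived
    from ``params.seed``), so the same seed reproduces the cube bit-for-bit.
    """
    if T_total <= burn_in:
        raise ValueError("T_total must exceed burn_in")
    # Independent sub-streams per noise source, all derived from params.seed,
    # so each component is independently reproducible.
    rng_climate = np.random.default_rng([1, params.seed])
    rng_env = np.random.default_rng([2, params.seed])
    rng_disp = np.random.default_rng([3, params.seed])
    rng_growth = np.random.default_rng([4, params.seed])

    climate = generate_climate(params.a, T_total, rng=rng_climate)
    mu_e = environment_draw(climate, params.h, params.P, rng=rng_env)

    disperse = disperse_global if params.dispersal_mode == "global" else disperse_local
    N = np.empty((params.S, params.P, T_total))
    N[:, :, 0] = params.K[:, None]
    for t in range(T_total - 1):
        N_disp = disperse(N[:, :, t], params.d, rng=rng_disp)
        N[:, :, t + 1] = growth_step(N_disp, params, mu_e[:, t], rng=rng_growth)
    return AbundanceCube(N=N, burn_in=burn_in, params=params)
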