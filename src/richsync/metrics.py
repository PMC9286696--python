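"""Community-structure metrics and ecosystem stability.

These are the emergent covariates of richness synchrony and the stability
response used in the regression analyses: mean patch richness, evenness,
beta diversity (mean pairwise Jaccard similarity of pooled patch species
lists, plus its turnover/nestedness partition), temporal turnover rate, and
ecosystem stability measured as -1 x the coefficient of variation of
metacommunity total abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import AbundanceCube
from .synchrony import RichnessMatrix

__all__ = [
    "CommunityMetrics",
    "filter_rare",
    "filter_rare_cube",
    "mean_patch_richness",
    "evenness",
    "evar",
    "pielou",
    "jaccard_beta",
    "baselga_decompose",
    "turnover_rate",
    "stability",
    "community_metrics",
]

logger = logging.getLogger(__name__)


@dataclass
class CommunityMetrics:
    """Emergent community structure of one metacommunity."""

    mean_richness: float
    evenness: float
    beta_jaccard: float
    beta_turnover_component: float
    beta_nestedness_component: float
    turnover_rate: float
    stability: float
    extent_km: float | None = None


# ---------------------------------------------------------------------------
# rare-species occupancy filter

def filter_rare(table: pd.DataFrame, min_occupancy: float = 0.05) -> pd.DataFrame:
    """Drop species present in fewer than ``min_occupancy`` of patch-time cells.

    A species is retained iff its count of (patch, time) cells with abundance
    strictly greater than zero is at least ``min_occupancy * P * T``, where P
    and T are the numbers of distinct patches and times in the table.  This
    minimizes the influence of observational error on richness fluctuations;
    a threshold of 0 keeps every species.
    """
    if not 0.0 <= min_occupancy <= 0.10:
        raise ValueError("min_occupancy must lie in [0, 0.10]")
    required = {"patch", "time", "species", "abundance"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    if min_occupancy == 0.0:
        return table.copy()
    P = table["patch"].nunique()
    T = table["time"].nunique()
    present = table[table["abundance"] > 0]
    occupancy = present.groupby("species")[["patch", "time"]].apply(
        lambda g: len(g[["patch", "time"]].drop_duplicates())
    )
    keep = occupancy[occupancy >= min_occupancy * P * T].index
    out = table[table["species"].isin(keep)]
    if out.empty:
        raise ValueError("occupancy filter removed every species")
    return out.copy()


def filter_rare_cube(N: np.ndarray, min_occupancy: float = 0.05) -> np.ndarray:
    """Cube-native occupancy filter: zero out species occupying fewer than
    ``min_occupancy`` of the P x T cells of a (species, patch, time) array."""
    if not 0.0 <= min_occupancy <= 0.10:
        raise ValueError("min_occupancy must lie in [0, 0.10]")
    S, P, T = N.shape
    occupancy = (N > 0).reshape(S, -1).sum(axis=1)
    keep = occupancy >= min_occupancy * P * T
    if not keep.any():
        raise ValueError("occupancy filter removed every species")
    return N * keep[:, None, None]


# ---------------------------------------------------------------------------
# richness and evenness

def mean_patch_richness(R: RichnessMatrix | np.ndarray) -> float:
    """Mean species richness over all patches and time steps."""
    mat = R.R if isinstance(R, RichnessMatrix) else np.asarray(R)
    return float(np.mean(mat))


def evar(abundances: np.ndarray) -> float:
    """Smith & Wilson's Evar evenness of one community sample.

    ``1 - (2/pi) * arctan(var(ln n))`` with the population variance of log
    abundances; 1 for perfectly even communities, approaching 0 for extreme
    dominance.  Requires at least 2 species with positive abundance.
    """
    v = np.asarray(abundances, dtype=float)
    v = v[v > 0]
    if len(v) < 2:
        raise ValueError("Evar needs at least 2 species with positive abundance")
    ln = np.log(v)
    return float(1.0 - (2.0 / np.pi) * np.arctan(np.var(ln)))


def pielou(abundances: np.ndarray) -> float:
    """Pielou's J evenness: Shannon entropy over its maximum, ln(S)."""
    v = np.asarray(abundances, dtype=float)
    v = v[v > 0]
    if len(v) < 2:
        raise ValueError("Pielou's J needs at least 2 species with positive abundance")
    p = v / v.sum()
    return float(-(p * np.log(p)).sum() / np.log(len(v)))


def evenness(
    cube: AbundanceCube | np.ndarray,
    window: slice | None = None,
    method: str = "evar",
) -> float:
    """Mean patch-level evenness over time.

    Evenness is computed per patch-time cell on the species with positive
    abundance and averaged over cells; cells with fewer than 2 species carry
    no evenness information and are skipped (their count is logged).
    """
    if method not in ("evar", "pielou"):
        raise ValueError("method must be 'evar' or 'pielou'")
    N = _window_array(cube, window)
    mask = N > 0
    counts = mask.sum(axis=0)
    valid = counts >= 2
    if not valid.any():
        raise ValueError("no patch-time cell has 2 or more species present")
    skipped = int((~valid).sum())
    if skipped:
        logger.debug("evenness: skipped %d patch-time cells with <2 species", skipped)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "evar":
            ln = np.where(mask, np.log(np.where(mask, N, 1.0)), 0.0)
            mean_ln = ln.sum(axis=0) / counts
            var_ln = (np.where(mask, (ln - mean_ln) ** 2, 0.0)).sum(axis=0) / counts
            vals = 1.0 - (2.0 / np.pi) * np.arctan(var_ln)
        else:
            tot = N.sum(axis=0)
            p = np.where(mask, N / np.where(tot > 0, tot, 1.0), 1.0)
            H = -(np.where(mask, p * np.log(p), 0.0)).sum(axis=0)
            vals = H / np.log(counts.astype(float))
    return float(vals[valid].mean())


# ---------------------------------------------------------------------------
# beta diversity

def _pooled_presence(arg) -> np.ndarray:
    """Species x patch boolean presence, pooled over all time steps."""
    if isinstance(arg, AbundanceCube):
        return (arg.analysis_window() > 0).any(axis=2)
    arr = np.asarray(arg)
    if arr.ndim == 3:
        return (arr > 0).any(axis=2)
    if arr.ndim == 2:
        return arr.astype(bool)
    raise ValueError("expected a cube (S,P,T) or presence matrix (S,P)")


def jaccard_beta(presence) -> float:
    """Mean pairwise Jaccard similarity among patches' pooled species lists.

    ``|A & B| / |A | B|`` per patch pair, averaged over all pairs.  Pairs in
    which both pooled lists are empty contribute 0 and are logged.
    """
    pres = _pooled_presence(presence)
    S, P = pres.shape
    if P < 2:
        raise ValueError("beta diversity needs at least 2 patches")
    pres_f = pres.astype(float)
    shared = pres_f.T @ pres_f                    # |A & B|
    sizes = pres.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - shared
    ii, jj = np.tril_indices(P, k=-1)
    sims = np.zeros(len(ii))
    nonempty = union[ii, jj] > 0
    sims[nonempty] = shared[ii, jj][nonempty] / union[ii, jj][nonempty]
    if (~nonempty).any():
        logger.debug("jaccard_beta: %d pairs with empty pooled lists", (~nonempty).sum())
    return float(sims.mean())


def baselga_decompose(presence, method: str = "pairwise") -> tuple[float, float]:
    """Partition Jaccard dissimilarity into turnover and nestedness components.

    ``method="pairwise"`` returns the means over patch pairs of the pairwise
    partition: with a shared species, b and c exclusive to each patch, total
    dissimilarity (b+c)/(a+b+c) splits into a species-replacement (turnover)
    component 2*min(b,c)/(a+2*min(b,c)) and a richness-difference
    (nestedness-resultant) remainder.  ``method="multisite"`` returns the
    multiple-site analogue computed from summed pairwise mismatches.  Either
    way the two components are nonnegative and sum to the corresponding total
    dissimilarity.

    Returns
    -------
    (turnover_component, nestedness_component)
    """
    pres = _pooled_presence(presence)
    S, P = pres.shape
    if P < 2:
        raise ValueError("beta diversity needs at least 2 patches")
    pres_f = pres.astype(float)
    a = pres_f.T @ pres_f
    sizes = pres.sum(axis=0).astype(float)
    b = sizes[:, None] - a        # exclusive to patch i
    c = sizes[None, :] - a        # exclusive to patch j
    ii, jj = np.tril_indices(P, k=-1)
    A, B, C = a[ii, jj], b[ii, jj], c[ii, jj]
    m = np.minimum(B, C)
    if method == "pairwise":
        with np.errstate(invalid="ignore", divide="ignore"):
            jac = np.where(A + B + C > 0, (B + C) / (A + B + C), 0.0)
            jtu = np.where(A + m > 0, 2 * m / (A + 2 * m), 0.0)
        jne = jac - jtu
        return float(jtu.mean()), float(jne.mean())
    if method == "multisite":
        pooled_total = pres.any(axis=1).sum()
        core = sizes.sum() - pooled_total         # Sum S_i - S_T
        sum_min = m.sum()
        sum_max = np.maximum(B, C).sum()
        denom_tot = core + sum_min + sum_max
        jac_m = (sum_min + sum_max) / denom_tot if denom_tot > 0 else 0.0
        denom_tu = core + 2 * sum_min
        jtu_m = 2 * sum_min / denom_tu if denom_tu > 0 else 0.0
        return float(jtu_m), float(jac_m - jtu_m)
    raise ValueError("method must be 'pairwise' or 'multisite'")


# ---------------------------------------------------------------------------
# temporal turnover

def turnover_rate(cube_or_presence) -> float:
    """Mean patch-level temporal turnover in species composition.

    Per patch and consecutive time pair: (gains + losses) / (number of
    species observed at either time); averaged over time pairs within a
    patch, then over patches.  Time pairs in which both censuses are empty
    are skipped (logged); patches with no usable pair are skipped.
    """
    if isinstance(cube_or_presence, AbundanceCube):
        pres = cube_or_presence.analysis_window() > 0
    else:
        pres = np.asarray(cube_or_presence) > 0
    if pres.ndim != 3:
        raise ValueError("expected a (species, patch, time) array")
    S, P, T = pres.shape
    if T < 2:
        raise ValueError("turnover needs at least 2 time steps")
    changed = (pres[:, :, 1:] != pres[:, :, :-1]).sum(axis=0).astype(float)
    observed = (pres[:, :, 1:] | pres[:, :, :-1]).sum(axis=0).astype(float)
    usable = observed > 0
    n_empty = int((~usable).sum())
    if n_empty:
        logger.debug("turnover_rate: skipped %d both-empty time pairs", n_empty)
    patch_means = []
    for p in range(P):
        u = usable[p]
        if u.any():
            patch_means.append((changed[p, u] / observed[p, u]).mean())
    if not patch_means:
        raise ValueError("no patch has a usable consecutive time pair")
    return float(np.mean(patch_means))


# ---------------------------------------------------------------------------
# ecosystem stability

def stability(cube: AbundanceCube | np.ndarray, window: slice | None = None) -> float:
    """Ecosystem stability: -1 x CV of metacommunity total abundance.

    The total over species and patches is computed per time step over the
    analysis window; stability is ``-sd(total)/mean(total)`` with the sample
    standard deviation (ddof=1).  Larger (less negative) values mean more
    stable aggregate function; the statistic is invariant to rescaling all
    abundances.
    """
    N = _window_array(cube, window)
    if N.shape[2] < 3:
        raise ValueError("stability needs a window of at least 3 time steps")
    totals = N.sum(axis=(0, 1))
    mean = totals.mean()
    if mean == 0:
        raise ValueError("mean total abundance is zero")
    return float(-totals.std(ddof=1) / mean)


def _window_array(cube, window: slice | None) -> np.ndarray:
    if isinstance(cube, AbundanceCube):
        if window is None:
            return cube.analysis_window()
        return cube.N[:, :, window]
    arr = np.asarray(cube, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a (species, patch, time) array")
    return arr if window is None else arr[:, :, window]


# ---------------------------------------------------------------------------
# one-stop aggregation (ensemble pipeline)

def community_metrics(
    cube: AbundanceCube,
    window: slice | None = None,
    min_occupancy: float = 0.05,
    evenness_method: str = "evar",
) -> CommunityMetrics:
    """All emergent community metrics of one simulated metacommunity.

    The occupancy filter is applied before computing the community-structure
    metrics (richness, evenness, beta diversity, turnover), mirroring the
    observational workflow; stability is computed from the unfiltered totals
    since aggregate biomass includes every individual.
    """
    N = _window_array(cube, window)
    filtered = filter_rare_cube(N, min_occupancy)
    R = (filtered > 0).sum(axis=0)
    jtu, jne = baselga_decompose(filtered)
    return CommunityMetrics(
        mean_richness=float(R.mean()),
        evenness=evenness(filtered, method=evenness_method),
        beta_jaccard=jaccard_beta(filtered),
        beta_turnover_component=jtu,
        beta_nestedness_component=jne,
        turnover_rate=turnover_rate(filtered),
        stability=stability(N),
    )
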