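"""Thermodynamic and kinetic read-outs of transition matrices and models.

Stationary distributions are computed on the largest closed communicating
class (states outside it get probability zero).  Eigenvalues of the
non-reversible maximum-likelihood estimator may come in complex pairs;
relaxation and implied timescales use the eigenvalue modulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from ._constants import KB_KCAL_PER_MOL_K

__all__ = [
    "AnalysisResult",
    "ContactFeatureSpec",
    "stationary_distribution",
    "relaxation_time",
    "implied_timescales",
    "one_step_transition_time",
    "free_energy_profile",
    "state_free_energy",
    "map_states_to_basins",
    "fraction_native_contacts",
    "analyze_level",
]


@dataclass
class AnalysisResult:
    """Per-state read-outs of one level of a multiscale model."""

    level: int
    state_ids: list
    pi: np.ndarray
    relaxation_times: dict
    free_energy: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "level": self.level,
            "id": self.state_ids,
            "pi": self.pi,
            "free_energy": self.free_energy,
            "relaxation_time": [self.relaxation_times.get(s, float("nan"))
                                for s in self.state_ids],
        })


@dataclass(frozen=True)
class ContactFeatureSpec:
    """Native-contact definition: distance pairs and a formation threshold (A)."""

    pairs: tuple
    threshold: float = 4.5

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("pairs must be nonempty")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


# --------------------------------------------------------------------------
# stationary distribution
# --------------------------------------------------------------------------

def _validate_stochastic(T: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    rows = T.sum(axis=1)
    bad = np.flatnonzero(np.abs(rows - 1.0) > tol)
    if bad.size:
        raise ValueError(f"row {int(bad[0])} sums to {rows[bad[0]]!r}, not 1")
    if np.any(T < -tol):
        i, j = np.unravel_index(int(np.argmin(T)), T.shape)
        raise ValueError(f"negative entry at ({i},{j})")
    return T

def largest_closed_class(T: np.ndarray) -> np.ndarray:
    """Indices of the largest closed communicating class of ``T``.

    Closed means no probability flows out of the class; among closed
    classes the largest (ties: the one containing the lowest index) wins.
    """
    n = T.shape[0]
    support = sp.csr_matrix((T > 0).astype(np.int8))
    n_comp, labels = connected_components(support, directed=True, connection="strong")
    out_mass = np.zeros(n_comp)
    np.add.at(out_mass, labels, _outflow_per_state(T, labels))
    closed = np.flatnonzero(out_mass <= 1e-12)
    if closed.size == 0:  # numerically leaky; fall back to all states
        return np.arange(n)
    sizes = np.bincount(labels, minlength=n_comp)
    best = max(closed, key=lambda c: (sizes[c], -int(np.flatnonzero(labels == c)[0])))
    return np.flatnonzero(labels == best)


def _outflow_per_state(T: np.ndarray, labels: np.ndarray) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    return np.where(same, 0.0, T).sum(axis=1)


def stationary_distribution(T: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Left eigenvector of ``T`` for eigenvalue 1, normalized to sum 1.

    Solved as a sparse linear system on the largest closed communicating
    class; entries outside that class are zero.
    """
    T = _validate_stochastic(T, tol)
    n = T.shape[0]
    if n == 1:
        return np.ones(1)
    cls = largest_closed_class(T)
    sub = T[np.ix_(cls, cls)]
    k = len(cls)
    pi_sub = _solve_stationary(sub) if k > 1 else np.ones(1)
    pi = np.zeros(n)
    pi[cls] = pi_sub
    return pi


def _solve_stationary(T: np.ndarray) -> np.ndarray:
    # pi (T - I) = 0 with sum(pi) = 1: replace one balance equation by the
    # normalization row and solve the (dense) linear system.
    n = T.shape[0]
    A = T.T - np.eye(n)
    A[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        pi = np.linalg.lstsq(A, b, rcond=None)[0]
    pi = np.maximum(np.real(pi), 0.0)
    s = pi.sum()
    if not np.isfinite(s) or s <= 0:
        # degenerate system (e.g. exactly periodic chains): eig fallback
        w, v = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.maximum(np.real(v[:, i]), 0.0)
        s = pi.sum()
    return pi / s


# --------------------------------------------------------------------------
# timescales
# --------------------------------------------------------------------------

def _sorted_eig_moduli(T: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvals(T)
    return np.sort(np.abs(lam))[::-1]


def relaxation_time(T: np.ndarray, tau: float) -> float:
    """Relaxation time -tau/ln|lambda_2| of a row-stochastic matrix.

    Returns ``inf`` when |lambda_2| >= 1 (within 1e-12) and 0 when
    lambda_2 vanishes.
    """
    T = np.asarray(T, dtype=float)
    if T.shape[0] < 2:
        raise ValueError("relaxation time needs at least 2 states")
    lam2 = _sorted_eig_moduli(T)[1]
    if lam2 >= 1.0 - 1e-12:
        return math.inf
    if lam2 <= 1e-12:
        return 0.0
    return -tau / math.log(lam2)


def implied_timescales(sequence, lags, tau0: float, n_processes: int = 1) -> np.ndarray:
    """Implied timescales t_i(l) = -l*tau0/ln|lambda_{i+1}(T(l))| per lag.

    ``sequence`` is a discrete state trajectory; counting is sliding-window
    at stride 1.  Returns an array of shape (len(lags), n_processes) with
    ``inf`` where |lambda| >= 1 and 0 where the mode count is exhausted.
    """
    seq = np.asarray(sequence)
    out = np.full((len(lags), n_processes), np.nan)
    states = np.unique(seq)
    idx = {s: i for i, s in enumerate(states)}
    coded = np.vectorize(idx.get, otypes=[np.int64])(seq)
    n = len(states)
    for li, lag in enumerate(lags):
        lag = int(lag)
        if lag < 1 or lag >= len(seq):
            raise ValueError(f"lag {lag} invalid for a sequence of length {len(seq)}")
        C = np.zeros((n, n))
        np.add.at(C, (coded[:-lag], coded[lag:]), 1.0)
        rows = C.sum(axis=1)
        zero = rows == 0
        T = C.copy()
        T[zero, np.flatnonzero(zero)] = 1.0
        T /= np.maximum(T.sum(axis=1), 1e-300)[:, None]
        mods = _sorted_eig_moduli(T)
        for p in range(n_processes):
            if p + 1 >= n:
                out[li, p] = 0.0
                continue
            lam = mods[p + 1]
            if lam >= 1.0 - 1e-12:
                out[li, p] = math.inf
            elif lam <= 1e-12:
                out[li, p] = 0.0
            else:
                out[li, p] = -lag * tau0 / math.log(lam)
    return out


def one_step_transition_time(tij: float, tau0: float) -> float:
    """tau0 / T_ij; infinity for a vanishing transition probability."""
    if not 0.0 <= tij <= 1.0:
        raise ValueError("transition probability must lie in [0, 1]")
    if tij == 0.0:
        return math.inf
    return tau0 / tij


# --------------------------------------------------------------------------
# free energies
# --------------------------------------------------------------------------

def free_energy_profile(samples, bin_width: float, temperature: float,
                        range_: tuple | None = None):
    """Boltzmann inversion of a 1-D sample histogram.

    Returns ``(bin_centers, F)`` with F = -kB*T*ln(count/N) shifted so the
    minimum is 0; empty bins carry NaN (missing, not infinite).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = (x.min(), x.max()) if range_ is None else range_
    nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    F = np.full(nbins, np.nan)
    occ = counts > 0
    F[occ] = -KB_KCAL_PER_MOL_K * temperature * np.log(counts[occ] / x.size)
    if occ.any():
        F -= np.nanmin(F)
    return centers, F


def state_free_energy(pi, temperature: float) -> np.ndarray:
    """F_i = -kB*T*ln(pi_i), shifted so the minimum is 0; NaN where pi_i = 0."""
    pi = np.asarray(pi, dtype=float)
    F = np.full(pi.shape, np.nan)
    pos = pi > 0
    F[pos] = -KB_KCAL_PER_MOL_K * temperature * np.log(pi[pos])
    if pos.any():
        F -= np.nanmin(F)
    return F


# --------------------------------------------------------------------------
# basin mapping and contacts
# --------------------------------------------------------------------------

def map_states_to_basins(model, basin_of, basin_names=None):
    """Assign microstates to basins by center and aggregate pi and T.

    ``basin_of`` maps a center vector to a basin label (or None for the
    "unassigned" bucket).  Aggregation of the base transition matrix uses
    the same stationary-weighted lumping operator as the hierarchy update.

    Returns ``(assignment, pi_by_basin, T_by_basin, labels)`` where
    ``assignment`` maps microstate id -> label.
    """
    from .core import transition_matrix
    from .update import lump_matrix

    lvl = model.levels[0]
    T0 = transition_matrix(model, 0)
    pi0 = stationary_distribution(T0)
    assignment = {}
    for sid in lvl.states:
        lab = basin_of(model.microstates[sid].center)
        assignment[sid] = "unassigned" if lab is None else lab
    labels = basin_names if basin_names is not None else sorted(
        set(assignment.values()), key=str)
    lab_index = {l: i for i, l in enumerate(labels)}
    membership = np.array([lab_index[assignment[s]] for s in lvl.states])
    pi_by = np.zeros(len(labels))
    np.add.at(pi_by, membership, pi0)
    visits = np.array([model.microstates[s].visit_count for s in lvl.states], float)
    T_by = lump_matrix(T0, membership, len(labels), pi0, fallback_weights=visits)
    return assignment, pi_by, T_by, list(labels)


def fraction_native_contacts(distances, spec: ContactFeatureSpec):
    """Per-frame fraction of native contacts formed (distance < threshold)."""
    D = np.atleast_2d(np.asarray(distances, dtype=float))
    if D.shape[1] != len(spec.pairs):
        raise ValueError(
            f"got {D.shape[1]} distances per frame, expected {len(spec.pairs)} pairs")
    return (D < spec.threshold).sum(axis=1) / len(spec.pairs)


def mean_fraction_native_contacts(distances, spec: ContactFeatureSpec,
                                  frame_groups: dict) -> dict:
    """Frame-weighted mean Q per named group of frame indices."""
    q = fraction_native_contacts(distances, spec)
    return {name: float(np.mean(q[np.asarray(idx, dtype=int)]))
            for name, idx in frame_groups.items()}


# --------------------------------------------------------------------------
# level summaries
# --------------------------------------------------------------------------

def analyze_level(model, h: int, temperature: float = 300.0) -> AnalysisResult:
    """Stationary probabilities, free energies, and per-macrostate local
    relaxation times (among children) for level ``h`` of a model."""
    from .core import transition_matrix

    T = transition_matrix(model, h)
    pi = stationary_distribution(T) if T.shape[0] > 1 else np.ones(1)
    lvl = model.levels[h]
    relax = {}
    if h >= 1:
        # each macrostate's relaxation among its children, from the level
        # below (restricted rows renormalized to a stochastic submatrix)
        Tb = transition_matrix(model, h - 1)
        idx = {s: i for i, s in enumerate(model.levels[h - 1].states)}
        for sid in lvl.states:
            children = model.children_of(sid)
            if len(children) < 2:
                continue
            rows = [idx[c] for c in children]
            sub = np.array(Tb[np.ix_(rows, rows)], copy=True)
            s = sub.sum(axis=1)
            for r in range(sub.shape[0]):
                if s[r] > 0:
                    sub[r] /= s[r]
                else:
                    sub[r, r] = 1.0
            relax[sid] = relaxation_time(sub, model.levels[h - 1].lag)
    return AnalysisResult(level=h, state_ids=list(lvl.states), pi=pi,
                          relaxation_times=relax,
                          free_energy=state_free_energy(pi, temperature))
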