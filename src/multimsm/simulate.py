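"""Synthetic dynamical systems with known ground truth.

Two families: (i) overdamped Langevin (Brownian) dynamics on a parametrized
1-D nested multi-minimum potential with a Boltzmann quadrature oracle, and
(ii) nested-block discrete Markov chains with analytically known stationary
distributions and designed tier partitions.  Both expose simulators that
satisfy the exploration driver's ``sim(x, k, m, seed)`` contract.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from ._constants import KB_KCAL_PER_MOL_K, stokes_einstein_diffusion
from .update import Trajectory

__all__ = [
    "PotentialSpec",
    "BDParams",
    "NestedChainSpec",
    "potential_energy",
    "potential_force",
    "bd_simulate",
    "BrownianSimulator",
    "two_spheres_fixture",
    "basin_ground_truth",
    "nested_chain",
    "ChainSimulator",
    "stream_chunks",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is preinstalled
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


# --------------------------------------------------------------------------
# potential
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialSpec:
    """An openly parametrized nested 1-D landscape on ``domain`` (A).

    U(d) = tilt*(d - mid)/span
         + sum_s A_s * cos(2*pi*(d - barrier_anchor)/lambda_s + phi_s)
         + harmonic walls of stiffness ``wall_k`` outside the domain.

    With phases 0 the largest-wavelength cosine peaks at ``barrier_anchor``,
    producing the top-level barrier; shorter wavelengths superimpose nested
    intermediate and fine minima.
    """

    domain: tuple = (22.0, 56.0)
    tilt: float = -0.3
    scales: tuple = ()
    wall_k: float = 1.0
    barrier_anchor: float = 39.0

    def __post_init__(self):
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("domain must satisfy d_lo < d_hi")
        for amp, wav, _ in self.scales:
            if amp < 0:
                raise ValueError("amplitudes must be >= 0")
            if wav <= 0:
                raise ValueError("wavelengths must be > 0")

    @property
    def span(self) -> float:
        return self.domain[1] - self.domain[0]

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.domain[0] + self.domain[1])


def potential_energy(d, spec: PotentialSpec):
    """U(d) in kcal/mol (vectorized over d)."""
    d = np.asarray(d, dtype=float)
    lo, hi = spec.domain
    u = spec.tilt * (d - spec.midpoint) / spec.span
    for amp, wav, phase in spec.scales:
        u = u + amp * np.cos(2.0 * np.pi * (d - spec.barrier_anchor) / wav + phase)
    u = u + 0.5 * spec.wall_k * (np.maximum(0.0, lo - d) ** 2 +
                                 np.maximum(0.0, d - hi) ** 2)
    return u if u.shape else float(u)


def potential_force(d, spec: PotentialSpec):
    """F(d) = -dU/dd, analytic, kcal/mol/A (vectorized over d)."""
    d = np.asarray(d, dtype=float)
    lo, hi = spec.domain
    f = -spec.tilt / spec.span * np.ones_like(d)
    for amp, wav, phase in spec.scales:
        w = 2.0 * np.pi / wav
        f = f + amp * w * np.sin(w * (d - spec.barrier_anchor) + phase)
    f = f + spec.wall_k * np.maximum(0.0, lo - d) - spec.wall_k * np.maximum(0.0, d - hi)
    return f if f.shape else float(f)


# --------------------------------------------------------------------------
# Brownian dynamics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BDParams:
    """Overdamped-Langevin integration settings.

    The diffusion coefficient follows Stokes-Einstein for a sphere of
    ``stokes_radius`` in water at ``temperature``.
    """

    temperature: float = 300.0
    dt: float = 0.03
    stokes_radius: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0 or self.dt <= 0 or self.stokes_radius <= 0:
            raise ValueError("temperature, dt and stokes_radius must be positive")

    @property
    def diffusion(self) -> float:
        """D in A^2/ps."""
        return stokes_einstein_diffusion(self.temperature, self.stokes_radius)

    @property
    def kbt(self) -> float:
        return KB_KCAL_PER_MOL_K * self.temperature


@njit(cache=False)
def _bd_kernel(x0, n_steps, noise, out, mob_dt, sig, tilt_f, amps, omegas,
               phases, anchor, lo, hi, wall_k, record_stride):  # pragma: no cover
    x = x0
    out[0] = x
    j = 1
    for t in range(n_steps):
        f = tilt_f
        for s in range(amps.shape[0]):
            f += amps[s] * omegas[s] * math.sin(omegas[s] * (x - anchor) + phases[s])
        if x < lo:
            f += wall_k * (lo - x)
        elif x > hi:
            f -= wall_k * (x - hi)
        x = x + mob_dt * f + sig * noise[t]
        if (t + 1) % record_stride == 0:
            out[j] = x
            j += 1
    return x


def _kernel_args(spec: PotentialSpec, params: BDParams):
    amps = np.array([s[0] for s in spec.scales], dtype=float)
    omegas = np.array([2.0 * np.pi / s[1] for s in spec.scales], dtype=float)
    phases = np.array([s[2] for s in spec.scales], dtype=float)
    mob_dt = params.diffusion / params.kbt * params.dt
    sig = math.sqrt(2.0 * params.diffusion * params.dt)
    return (mob_dt, sig, -spec.tilt / spec.span, amps, omegas, phases,
            spec.barrier_anchor, spec.domain[0], spec.domain[1], spec.wall_k)


def bd_simulate(x0, k: int, m: int, params: BDParams, spec: PotentialSpec,
                seed: int | None = None, frame_stride: int = 1) -> list[Trajectory]:
    """Euler-Maruyama integration: k independent trajectories of m frames.

    x_{t+1} = x_t + (D/kBT) F(x_t) dt + sqrt(2 D dt) eta, eta ~ N(0,1).
    Frames are recorded every ``frame_stride`` steps, so the frame interval
    is ``dt * frame_stride``.  Deterministic given ``seed``.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    x0 = float(np.atleast_1d(np.asarray(x0, dtype=float))[0])
    rng = np.random.default_rng(params.seed if seed is None else seed)
    args = _kernel_args(spec, params)
    n_steps = (m - 1) * frame_stride
    trajs = []
    for _ in range(k):
        noise = rng.standard_normal(n_steps)
        out = np.empty(m)
        _bd_kernel(x0, n_steps, noise, out, *args, frame_stride)
        trajs.append(Trajectory(frames=out[:, None],
                                frame_interval=params.dt * frame_stride))
    return trajs


class BrownianSimulator:
    """Simulator-contract adapter around :func:`bd_simulate`."""

    def __init__(self, spec: PotentialSpec, params: BDParams, frame_stride: int = 1):
        self.spec = spec
        self.params = params
        self.frame_stride = frame_stride

    @property
    def tau0(self) -> float:
        return self.params.dt * self.frame_stride

    def __call__(self, x, k, m, seed):
        return bd_simulate(x, k, m, self.params, self.spec, seed=seed,
                           frame_stride=self.frame_stride)


# --------------------------------------------------------------------------
# the two-spheres surrogate fixture
# --------------------------------------------------------------------------

def two_spheres_fixture():
    """Default surrogate landscape, BD parameters, and start configuration.

    Domain [22, 56] A.  Three cosine scales: the coarsest (wavelength equal
    to the span) peaks at 39 A and splits the domain into two main basins;
    a 5.67 A scale superimposes ~6 intermediate minima and a 1.9 A scale
    ~18 fine minima.  The negative tilt makes the long-distance basin (B,
    d > 39) the heavier one.  BD at 300 K, dt 0.03 ps, Stokes radius 5 A;
    start at d = 55.25 A.
    """
    spec = PotentialSpec(
        domain=(22.0, 56.0),
        tilt=-0.1,
        scales=((0.6, 34.0, 0.0), (0.5, 5.67, 0.0), (0.1, 1.9, 0.0)),
        wall_k=1.0,
        barrier_anchor=39.0,
    )
    params = BDParams(temperature=300.0, dt=0.03, stokes_radius=5.0)
    xinit = np.array([55.25])
    return spec, params, xinit


def basin_ground_truth(spec: PotentialSpec, temperature: float, basin_edges):
    """Boltzmann probabilities and free energies per basin, by quadrature.

    ``basin_edges`` are sorted interior cut points; basins are the segments
    of the domain they delimit.  Relative quadrature error < 1e-8.
    """
    lo, hi = spec.domain
    edges = [lo] + list(basin_edges) + [hi]
    if any(not lo <= e <= hi for e in basin_edges) or sorted(edges) != edges:
        raise ValueError("basin edges must be sorted and inside the domain")
    kbt = KB_KCAL_PER_MOL_K * temperature
    umin = float(np.min(potential_energy(np.linspace(lo, hi, 20001), spec)))

    def boltz(d):
        return np.exp(-(potential_energy(d, spec) - umin) / kbt)

    weights = []
    for a, b in zip(edges[:-1], edges[1:]):
        w, _ = integrate.quad(boltz, a, b, epsrel=1e-10, epsabs=1e-13, limit=500)
        weights.append(w)
    weights = np.asarray(weights)
    pi = weights / weights.sum()
    F = np.full(pi.shape, np.nan)
    pos = pi > 0
    F[pos] = -kbt * np.log(pi[pos])
    F -= np.nanmin(F)
    return pi, F


# --------------------------------------------------------------------------
# nested-block chains
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NestedChainSpec:
    """Nested-block chain: ``tiers`` lists (branching factor, escape
    probability per step) from the coarsest tier down; escape probabilities
    must increase strictly with depth (finer structure relaxes faster)."""

    tiers: tuple

    def __post_init__(self):
        if len(self.tiers) < 2:
            raise ValueError("need at least 2 tiers")
        probs = [p for _, p in self.tiers]
        if any(p <= 0 or p >= 1 for p in probs):
            raise ValueError("escape probabilities must lie in (0, 1)")
        if any(b < 2 for b, _ in self.tiers):
            raise ValueError("branching factors must be >= 2")
        if any(p2 <= p1 for p1, p2 in zip(probs[:-1], probs[1:])):
            raise ValueError(
                "escape probabilities must increase strictly from coarse to fine "
                "(timescale separation)")
        if sum(probs) >= 1:
            raise ValueError("escape probabilities must sum to < 1")

    @property
    def n_states(self) -> int:
        n = 1
        for b, _ in self.tiers:
            n *= b
        return n


def nested_chain(spec: NestedChainSpec):
    """Exact transition matrix, stationary distribution, and tier partitions.

    T = (1 - sum_t p_t) I + sum_t p_t U_t where U_t jumps uniformly within
    the enclosing tier-(t-1) block (the whole state set for the coarsest
    tier).  Every U_t is symmetric, so T is doubly stochastic and the
    stationary distribution is uniform.  Designed partitions: for tier t,
    the blocks of size prod_{s>t} b_s.
    """
    n = spec.n_states
    T = np.zeros((n, n))
    stay = 1.0 - sum(p for _, p in spec.tiers)
    np.fill_diagonal(T, stay)
    block = n
    for (b, p) in spec.tiers:
        # U_t: uniform over the enclosing block of size `block`
        for start in range(0, n, block):
            T[start:start + block, start:start + block] += p / block
        block //= b
    pi = np.full(n, 1.0 / n)
    partitions = []
    block = n
    for (b, _) in spec.tiers:
        block //= b
        partitions.append([list(range(s, s + block)) for s in range(0, n, block)])
    # partitions[t] groups states into blocks at the granularity below tier t;
    # the designed tiers coarse-to-fine: sizes n/b1, n/(b1 b2), ...
    return T, pi, partitions


class ChainSimulator:
    """Discrete-chain simulator satisfying the ``sim(x, k, m, seed)`` contract.

    States are embedded in a 1-D feature space at integer coordinates, so a
    K-centers diameter below 1 maps each chain state to its own microstate.
    """

    def __init__(self, T: np.ndarray, tau0: float = 1.0):
        self.T = np.asarray(T, dtype=float)
        self.cum = np.cumsum(self.T, axis=1)
        self.tau0 = tau0

    def __call__(self, x, k, m, seed):
        s0 = int(round(float(np.atleast_1d(x)[0])))
        if not 0 <= s0 < self.T.shape[0]:
            raise ValueError(f"start state {s0} out of range")
        rng = np.random.default_rng(seed)
        trajs = []
        for _ in range(k):
            u = rng.random(m - 1)
            path = np.empty(m, dtype=np.int64)
            _chain_kernel(self.cum, s0, u, path)
            trajs.append(Trajectory(frames=path.astype(float)[:, None],
                                    frame_interval=self.tau0))
        return trajs


@njit(cache=False)
def _chain_kernel(cum, s0, u, path):  # pragma: no cover
    s = s0
    path[0] = s
    for t in range(u.shape[0]):
        r = u[t]
        row = cum[s]
        lo = 0
        hi = row.shape[0] - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if row[mid] >= r:
                hi = mid
            else:
                lo = mid + 1
        s = lo
        path[t + 1] = s
    return s


# --------------------------------------------------------------------------
# streamed feature trajectories
# --------------------------------------------------------------------------

def stream_chunks(source, chunk_frames: int, tau0: float, stride: int | None = None):
    """Yield consecutive Trajectory batches from a delimited text file.

    The last frame of each chunk is carried into the next so that counting
    pairs per batch reproduces exactly the counts of monolithic ingestion.
    An optional JSON sidecar ``<source>.json`` may declare
    ``frame_interval_ps``; its interval must equal tau0 or divide it by an
    integer stride (subsampling).  Malformed rows raise with their line
    number.
    """
    if chunk_frames < 2:
        raise ValueError("chunk_frames must be >= 2")
    if stride is None:
        stride = 1
        sidecar = f"{source}.json"
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                meta = json.load(fh)
            interval = float(meta.get("frame_interval_ps", tau0))
            ratio = tau0 / interval
            if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
                raise ValueError(
                    f"file frame interval {interval} does not divide tau0 {tau0}")
            stride = int(round(ratio))

    frames = _read_frames(source)[::stride]
    n = frames.shape[0]
    carry = None
    pos = 0
    while pos < n:
        end = min(pos + chunk_frames, n)
        block = frames[pos:end]
        if carry is not None:
            block = np.vstack([carry, block])
        yield Trajectory(frames=block, frame_interval=tau0)
        carry = frames[end - 1:end]
        pos = end


def _read_frames(source) -> np.ndarray:
    rows = []
    width = None
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ValueError(f"{source}: malformed row at line {lineno}")
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(
                    f"{source}: line {lineno} has {len(vals)} fields, expected {width}")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{source}: no data rows")
    return np.asarray(rows, dtype=float)
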