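"""Adaptive exploration: the multiscale driver loop and its baselines.

The driver repeatedly (i) simulates ``k`` short trajectories of ``m`` steps
from every pending start configuration, accumulating simulation time by
``tau0 * k * (m - 1)`` per start, (ii) updates the multiscale model once on
the whole batch, and (iii) draws ``ninit`` new starts by descending the
hierarchy from the root, sampling one child per level from ``Padap``.

The simulator contract: a callable ``sim(x, k, m, seed)`` returning ``k``
Trajectory objects of ``m`` frames at interval tau0, starting at ``x``.
External engines plug in through this interface; the built-in Brownian
dynamics and discrete-chain simulators implement it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import Configuration, FeatureSpace, MultiscaleModel, as_values, new_multiscale_msm
from .discretize import DiscretizerParams, representative
from .update import CommunityParams, Trajectory, update_base_counts, update_multiscale_msm

logger = logging.getLogger(__name__)

__all__ = [
    "ExploreParams",
    "AdaptivePolicy",
    "padap_weights",
    "multiscale_adaptive_sampling",
    "mmsm_explore",
    "flat_msm_explore",
    "naive_explore",
    "exploration_curve",
    "coverage_time",
    "VisitLog",
]


@dataclass(frozen=True)
class ExploreParams:
    """Driver-loop parameters (see module docstring for the accounting)."""

    tmax: float
    ninit: int = 10
    k: int = 1
    m: int = 11
    adaptive_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.tmax <= 0:
            raise ValueError("tmax must be positive")
        if self.ninit < 1 or self.k < 1:
            raise ValueError("ninit and k must be >= 1")
        if self.m < 2:
            raise ValueError("m must be >= 2")


@dataclass(frozen=True)
class AdaptivePolicy:
    """Restart-weight family over the children of a state.

    ``exp_inverse_visits`` (default) weights child i by
    exp(-rate * v_i / mean(v)); ``inverse_visits`` by 1/(1 + v_i);
    ``uniform`` ignores visits.
    """

    kind: str = "exp_inverse_visits"
    rate: float = 1.0

    def __post_init__(self):
        if self.kind not in ("exp_inverse_visits", "uniform", "inverse_visits"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "exp_inverse_visits" and self.rate <= 0:
            raise ValueError("rate must be positive for exp_inverse_visits")


def padap_weights(visit_counts, policy: AdaptivePolicy) -> np.ndarray:
    """Normalized restart probabilities over children given visit counts."""
    v = np.asarray(visit_counts, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one child")
    if policy.kind == "uniform":
        w = np.ones_like(v)
    elif policy.kind == "inverse_visits":
        w = 1.0 / (1.0 + v)
    else:
        vbar = v.mean()
        if vbar == 0:
            w = np.ones_like(v)
        else:
            w = np.exp(-policy.rate * v / vbar)
    return w / w.sum()


def multiscale_adaptive_sampling(model: MultiscaleModel, policy: AdaptivePolicy,
                                 rng: np.random.Generator) -> Configuration:
    """Descend from the root sampling one child per level via Padap; return a
    representative configuration of the microstate reached."""
    cur = model.root_id
    while cur not in model.microstates:
        children = model.children_of(cur)
        visits = [model.state(c).visit_count for c in children]
        p = padap_weights(visits, policy)
        cur = children[int(rng.choice(len(children), p=p))]
    return representative(model.microstates[cur], rng)


# --------------------------------------------------------------------------
# visit logging
# --------------------------------------------------------------------------

@dataclass
class VisitLog:
    """First-visit times per microstate, keyed by accumulated simulation time.

    Each entry maps microstate id -> (tsim at first visit, center vector).
    ``tsim_final`` records the accumulated simulation time at the end of the
    run (exactly tau0*k*(m-1) per completed start for the batch drivers).
    """

    first_visit: dict = field(default_factory=dict)
    tsim_final: float = 0.0

    def record_new(self, model: MultiscaleModel, known: set, tsim: float) -> None:
        for sid in model.levels[0].states:
            if sid not in known:
                known.add(sid)
                self.first_visit[sid] = (tsim, model.microstates[sid].center.copy())

    def items(self):
        return [(sid, t) for sid, (t, _) in self.first_visit.items()]

    def centers(self):
        return {sid: c for sid, (_, c) in self.first_visit.items()}


# --------------------------------------------------------------------------
# drivers
# --------------------------------------------------------------------------

def mmsm_explore(sim, xinit, space: FeatureSpace, params: ExploreParams,
                 cparams: CommunityParams, dparams: DiscretizerParams,
                 kappa: int = 2, tau0: float = 1.0,
                 policy: AdaptivePolicy | None = None,
                 stop_condition=None, report_sink=None):
    """Build a multiscale model by adaptive exploration from ``xinit``.

    Returns ``(model, visit_log)``; final accumulated time equals
    ``tau0 * k * (m - 1) * completed_starts`` exactly.  ``stop_condition``
    (model -> bool), when given, ends the loop early after an update
    (used e.g. to stop once a reference region is fully covered).
    ``report_sink`` (dict -> None) receives one structured update report
    per iteration (tsim plus created/merged/split counts per level).
    """
    policy = policy or AdaptivePolicy(rate=params.adaptive_rate)
    rng = np.random.default_rng(params.seed)
    sim_rng = np.random.default_rng(rng.integers(2 ** 63 - 1))
    samp_rng = np.random.default_rng(rng.integers(2 ** 63 - 1))
    clust_rng = np.random.default_rng(rng.integers(2 ** 63 - 1))

    model = new_multiscale_msm(xinit, space, dparams.diameter, kappa=kappa, tau0=tau0)
    log = VisitLog()
    known: set = set()
    tsim = 0.0
    log.record_new(model, known, tsim)
    starts = [as_values(xinit)]
    per_start = tau0 * params.k * (params.m - 1)
    completed = 0
    while tsim < params.tmax:
        batch = []
        for x in starts:
            try:
                trajs = sim(x, params.k, params.m, int(sim_rng.integers(2 ** 63 - 1)))
            except Exception as exc:  # pragma: no cover - simulator failure path
                logger.warning("simulator failed at start %s: %s", x, exc)
                continue
            completed += 1
            tsim = per_start * completed  # exact: tau0*k*(m-1)*completed starts
            batch.extend(trajs)
        starts = []
        if not batch:
            logger.warning("no trajectories produced this iteration; stopping")
            break
        report = update_multiscale_msm(model, batch, cparams, dparams, clust_rng)
        if report_sink is not None:
            report_sink({"tsim": tsim, **report.to_dict()})
        log.record_new(model, known, tsim)
        if stop_condition is not None and stop_condition(model):
            break
        for _ in range(params.ninit):
            starts.append(multiscale_adaptive_sampling(model, policy, samp_rng).values)
    log.tsim_final = tsim
    return model, log


def flat_msm_explore(sim, xinit, space: FeatureSpace, params: ExploreParams,
                     dparams: DiscretizerParams, tau0: float = 1.0,
                     policy: AdaptivePolicy | None = None,
                     stop_condition=None):
    """Single-level baseline: same loop, restarts drawn from Padap directly
    over all microstates."""
    policy = policy or AdaptivePolicy(rate=params.adaptive_rate)
    rng = np.random.default_rng(params.seed)
    sim_rng = np.random.default_rng(rng.integers(2 ** 63 - 1))
    samp_rng = np.random.default_rng(rng.integers(2 ** 63 - 1))

    model = new_multiscale_msm(xinit, space, dparams.diameter, kappa=2, tau0=tau0)
    log = VisitLog()
    known: set = set()
    tsim = 0.0
    log.record_new(model, known, tsim)
    starts = [as_values(xinit)]
    per_start = tau0 * params.k * (params.m - 1)
    completed = 0
    while tsim < params.tmax:
        batch = []
        for x in starts:
            try:
                trajs = sim(x, params.k, params.m, int(sim_rng.integers(2 ** 63 - 1)))
            except Exception as exc:  # pragma: no cover
                logger.warning("simulator failed at start %s: %s", x, exc)
                continue
            completed += 1
            tsim = per_start * completed
            batch.extend(trajs)
        starts = []
        update_base_counts(model, batch, dparams, rng=samp_rng)
        model.refresh_visit_counts()
        # keep the singleton root covering every microstate (flat hierarchy)
        root = model.macrostates[model.root_id]
        root.children = set(model.levels[0].states)
        root.visit_count = sum(ms.visit_count for ms in model.microstates.values())
        log.record_new(model, known, tsim)
        if stop_condition is not None and stop_condition(model):
            break
        ids = model.levels[0].states
        visits = [model.microstates[s].visit_count for s in ids]
        p = padap_weights(visits, policy)
        for _ in range(params.ninit):
            sid = ids[int(samp_rng.choice(len(ids), p=p))]
            starts.append(representative(model.microstates[sid], samp_rng).values)
    log.tsim_final = tsim
    return model, log


def naive_explore(sim, xinit, total_time: float, space: FeatureSpace,
                  dparams: DiscretizerParams, tau0: float = 1.0, seed: int = 0,
                  chunk_frames: int = 100_000, stop_condition=None):
    """One continuous trajectory from ``xinit``; first-visit log under the
    same discretizer.  Total frames = total_time / tau0 + 1."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    rng = np.random.default_rng(seed)
    model = new_multiscale_msm(xinit, space, dparams.diameter, kappa=2, tau0=tau0)
    log = VisitLog()
    known: set = set()
    log.record_new(model, known, 0.0)
    n_steps = int(round(total_time / tau0))
    x = as_values(xinit)
    done = 0
    counts = model.levels[0].counts
    prev_last_id = None
    while done < n_steps:
        m = min(chunk_frames, n_steps - done) + 1
        traj = sim(x, 1, m, int(rng.integers(2 ** 63 - 1)))[0]
        frames = traj.frames if done == 0 else traj.frames[1:]
        t = Trajectory(frames=frames, frame_interval=tau0)
        from .discretize import assign_frames
        ids = assign_frames(t.frames, model, dparams, rng=rng)
        if prev_last_id is not None and len(ids):
            pair = (int(prev_last_id), int(ids[0]))
            counts[pair] = counts.get(pair, 0.0) + 1.0
        if len(ids) >= 2:
            key = ids[:-1].astype(np.int64) * (2 ** 32) + ids[1:]
            uk, uc = np.unique(key, return_counts=True)
            for kk, cc in zip(uk, uc):
                pair = (int(kk >> 32), int(kk & 0xFFFFFFFF))
                counts[pair] = counts.get(pair, 0.0) + float(cc)
        prev_last_id = ids[-1] if len(ids) else prev_last_id
        done += m - 1
        # first-visit time: end of this chunk (resolution = chunk length)
        _record_chunk_visits(model, known, log, ids, done, tau0, t.frames)
        x = traj.frames[-1]
        if stop_condition is not None and stop_condition(model):
            break
    log.tsim_final = done * tau0
    model.refresh_visit_counts()
    root = model.macrostates[model.root_id]
    root.children = set(model.levels[0].states)
    root.visit_count = sum(ms.visit_count for ms in model.microstates.values())
    return model, log


def _record_chunk_visits(model, known, log, ids, done, tau0, frames) -> None:
    """Record first visits inside a chunk at frame resolution."""
    base = (done - (len(ids))) * tau0  # time of the first frame in this chunk
    for offset, sid in enumerate(ids):
        sid = int(sid)
        if sid not in known:
            known.add(sid)
            log.first_visit[sid] = (base + (offset + 1) * tau0,
                                    model.microstates[sid].center.copy())


# --------------------------------------------------------------------------
# exploration curves
# --------------------------------------------------------------------------

def exploration_curve(visit_log, reference_states):
    """Fraction of reference states visited as a step function of time.

    ``visit_log`` is an iterable of ``(key, time)``; ``reference_states``
    the keys that count.  Returns ``(times, fractions)`` with a leading
    (0, f0) point; the curve is non-decreasing in [0, 1].
    """
    refs = set(reference_states)
    if not refs:
        raise ValueError("reference_states must be nonempty")
    hits = sorted((t for k, t in visit_log if k in refs))
    times = [0.0]
    fracs = [0.0]
    n = len(refs)
    seen = 0
    for t in hits:
        seen += 1
        if t == times[-1]:
            fracs[-1] = seen / n
        else:
            times.append(t)
            fracs.append(seen / n)
    return np.asarray(times), np.asarray(fracs)


def coverage_time(visit_log, reference_states) -> float:
    """First time the curve reaches 1 (inf if full coverage is never reached)."""
    times, fracs = exploration_curve(visit_log, reference_states)
    full = np.flatnonzero(fracs >= 1.0)
    return float(times[full[0]]) if full.size else math.inf
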