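"""Hierarchy maintenance: ingesting trajectories and rebuilding the levels.

New trajectories first update the base count matrix.  Transition matrices of
the coarser levels are then derived bottom-up: the level-(h-1) matrix is
taken to the power ``kappa`` (moving to the level-h lag) and lumped over the
parent partition with stationary weights.  When enough new transitions have
accumulated, modularity-based community detection re-partitions each level
at its own timescale, realizing merges and splits of macrostates; the
hierarchy is extended (or shrunk) at the top until the root is a single
community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (Macrostate, MultiscaleModel, LevelModel, as_values,
                   check_hierarchy, transition_matrix)
from .discretize import DiscretizerParams, assign_frames
from .analysis import stationary_distribution

__all__ = [
    "Trajectory",
    "CommunityParams",
    "update_base_counts",
    "lump_matrix",
    "coarse_grain_level",
    "detect_temporal_communities",
    "update_multiscale_msm",
]

#: hard cap on hierarchy depth (kappa=2 spans ~7 decades of timescale)
HMAX = 25


@dataclass
class Trajectory:
    """An ordered block of feature-space frames at fixed interval tau0."""

    frames: np.ndarray
    frame_interval: float
    state_ids: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")

    def __len__(self):
        return self.frames.shape[0]


@dataclass(frozen=True)
class CommunityParams:
    """Temporal-community detection knobs.

    ``min_update_frames`` new transitions must accumulate before the
    partitions are re-detected (transition matrices are refreshed on every
    update regardless); ``overlap_match_threshold`` is the visit-weighted
    overlap fraction above which a re-detected community inherits the id of
    an existing macrostate.
    """

    resolution: float = 1.0
    min_update_frames: int = 100
    overlap_match_threshold: float = 0.5

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not 0 < self.overlap_match_threshold <= 1:
            raise ValueError("overlap_match_threshold must lie in (0, 1]")


# --------------------------------------------------------------------------
# base-level counting
# --------------------------------------------------------------------------

def update_base_counts(model: MultiscaleModel, trajs, params: DiscretizerParams,
                       rng: np.random.Generator | None = None,
                       created: list | None = None) -> int:
    """Discretize trajectories and add sliding-window pair counts at lag tau0.

    Counting never crosses trajectory boundaries.  Returns the number of
    transitions added, i.e. sum(m_i - 1).
    """
    counts = model.levels[0].counts
    added = 0
    for traj in trajs:
        if traj.frame_interval != model.tau0:
            raise ValueError(
                f"trajectory frame interval {traj.frame_interval} != tau0 {model.tau0}")
        ids = assign_frames(traj.frames, model, params, rng=rng, created=created)
        traj.state_ids = ids
        if len(ids) < 2:
            continue
        key = ids[:-1].astype(np.int64) * (2 ** 32) + ids[1:]
        uk, uc = np.unique(key, return_counts=True)
        for k, c in zip(uk, uc):
            pair = (int(k >> 32), int(k & 0xFFFFFFFF))
            counts[pair] = counts.get(pair, 0.0) + float(c)
        added += len(ids) - 1
    return added


# --------------------------------------------------------------------------
# coarse graining
# --------------------------------------------------------------------------

def lump_matrix(P: np.ndarray, membership: np.ndarray, n_groups: int,
                pi: np.ndarray, fallback_weights: np.ndarray | None = None) -> np.ndarray:
    """Stationary-weighted lumping of a row-stochastic matrix.

    ``T[K, L] = sum_{i in K} (w_i / w_K) * sum_{j in L} P[i, j]`` where the
    weights are the stationary probabilities restricted and renormalized
    within each group.  Groups whose members all carry zero stationary mass
    fall back to ``fallback_weights`` (visit counts) or uniform weights.
    """
    w = np.array(pi, dtype=float, copy=True)
    group_mass = np.zeros(n_groups)
    np.add.at(group_mass, membership, w)
    for g in np.flatnonzero(group_mass <= 0):
        members = membership == g
        if fallback_weights is not None and fallback_weights[members].sum() > 0:
            w[members] = fallback_weights[members]
        else:
            w[members] = 1.0
        group_mass[g] = w[members].sum()
    w = w / group_mass[membership]
    # T = A P M with A[g, i] = w_i [i in g], M[j, g] = [j in g]
    n = P.shape[0]
    M = np.zeros((n, n_groups))
    M[np.arange(n), membership] = 1.0
    A = (M * w[:, None]).T
    return A @ P @ M


def coarse_grain_level(model: MultiscaleModel, h: int) -> np.ndarray:
    """Recompute level h's transition matrix from level h-1.

    T_h = Lump_pi((T_{h-1})**kappa) over the parent partition; the result is
    cached on the level and returned.
    """
    if not 1 <= h <= model.H:
        raise IndexError(f"level {h} out of range 1..{model.H}")
    T = transition_matrix(model, h - 1)
    pi = stationary_distribution(T)
    P = np.linalg.matrix_power(T, model.kappa)
    below = model.levels[h - 1]
    lvl = model.levels[h]
    gidx = {s: g for g, s in enumerate(lvl.states)}
    membership = np.array([gidx[model.state(s).parent] for s in below.states])
    visits = np.array([model.state(s).visit_count for s in below.states], dtype=float)
    Th = lump_matrix(P, membership, lvl.n_states, pi, fallback_weights=visits)
    lvl.tmatrix = Th
    return Th


# --------------------------------------------------------------------------
# temporal communities
# --------------------------------------------------------------------------

def detect_temporal_communities(states, T: np.ndarray, pi: np.ndarray,
                                params: CommunityParams,
                                rng: np.random.Generator) -> list[list]:
    """Partition ``states`` into temporal communities.

    Builds the undirected stationary-flux graph w_ij = pi_i T_ij + pi_j T_ji
    (self-loops dropped) and maximizes modularity at the configured
    resolution with a seed drawn from ``rng``.  Every returned community is
    internally connected; a single community is legal output.
    """
    states = list(states)
    n = len(states)
    if n == 1:
        return [states]
    import igraph
    import leidenalg

    W = pi[:, None] * T
    W = W + W.T
    np.fill_diagonal(W, 0.0)
    ii, jj = np.nonzero(np.triu(W, k=1))
    if ii.size == 0:
        return [[s] for s in states]
    g = igraph.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())))
    weights = W[ii, jj]
    seed = int(rng.integers(2 ** 31 - 1))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights=list(weights),
        resolution_parameter=params.resolution, seed=seed, n_iterations=-1)
    return [[states[i] for i in sorted(community)] for community in
            sorted(part, key=min)]


# --------------------------------------------------------------------------
# the full update
# --------------------------------------------------------------------------

@dataclass
class UpdateReport:
    """What one update call did, per level."""

    transitions_added: int = 0
    microstates_created: int = 0
    reclustered: bool = False
    created: dict = field(default_factory=dict)
    removed: dict = field(default_factory=dict)
    matched: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "transitions_added": self.transitions_added,
            "microstates_created": self.microstates_created,
            "reclustered": self.reclustered,
            "created": self.created,
            "removed": self.removed,
            "matched": self.matched,
        }


def update_multiscale_msm(model: MultiscaleModel, trajs, cparams: CommunityParams,
                          dparams: DiscretizerParams,
                          rng: np.random.Generator) -> UpdateReport:
    """Ingest a batch of trajectories and restore the multiscale invariants.

    Steps: (1) base counts and microstate creation, with new microstates
    provisionally attached under the parent of their nearest pre-existing
    neighbor; (2) if enough new transitions accumulated, re-detect the
    temporal communities of every level bottom-up at that level's timescale
    (matrix power kappa), matching re-detected communities to existing
    macrostate ids by visit-weighted overlap; the pass keeps adding levels
    until a detection returns a single community (the root) or the depth cap
    is reached; (3) otherwise only the per-level transition matrices are
    refreshed.  Structural validity is asserted on entry and exit.
    """
    issues = check_hierarchy(model)
    if issues:
        raise ValueError(f"refusing to update an invalid model: {issues[0]}")

    report = UpdateReport()
    created: list[int] = []
    added = update_base_counts(model, trajs, dparams, rng=rng, created=created)
    report.transitions_added = added
    report.microstates_created = len(created)
    model.refresh_visit_counts()
    if added == 0 and not created:
        return report

    model.pending_transitions += added
    if model.pending_transitions >= cparams.min_update_frames or created:
        _rebuild_hierarchy(model, cparams, rng, report)
        model.pending_transitions = 0
        report.reclustered = True
    else:
        for h in range(1, model.H + 1):
            coarse_grain_level(model, h)
    model.refresh_visit_counts()
    issues = check_hierarchy(model)
    if issues:
        raise AssertionError(f"update left the model invalid: {issues}")
    return report


def _rebuild_hierarchy(model: MultiscaleModel, cparams: CommunityParams,
                       rng: np.random.Generator, report: UpdateReport) -> None:
    """Re-detect communities level by level and install the new hierarchy.

    The pass is planned on plain data first (communities, matched ids and
    lumped matrices per level), then installed atomically on the model.
    """
    old_levels = model.levels[1:]
    old_macrostates = model.macrostates
    used_ids: set[int] = set()

    prev_states = list(model.levels[0].states)
    prev_T = transition_matrix(model, 0)
    prev_pi = stationary_distribution(prev_T)
    prev_visits = np.array(
        [model.microstates[s].visit_count for s in prev_states], dtype=float)
    visits_of = dict(zip(prev_states, prev_visits))

    plan: list[tuple[list[int], list[list], np.ndarray | None]] = []
    h = 1
    while True:
        P = np.linalg.matrix_power(prev_T, model.kappa)
        if h >= HMAX:
            comms = [list(prev_states)]
        else:
            comms = detect_temporal_communities(prev_states, P, prev_pi, cparams, rng)
        old_here = old_levels[h - 1].states if h - 1 < len(old_levels) else []
        ids = _match_ids(model, comms, visits_of, old_here, old_macrostates,
                         used_ids, cparams, report, h)
        # keep states sorted by id; reorder communities jointly
        order = np.argsort(ids, kind="stable")
        ids = [ids[i] for i in order]
        comms = [comms[i] for i in order]
        if len(comms) == 1:
            plan.append((ids, comms, None))
            break
        sidx = {s: i for i, s in enumerate(prev_states)}
        membership = np.empty(len(prev_states), dtype=np.int64)
        for g, comm in enumerate(comms):
            for c in comm:
                membership[sidx[c]] = g
        Th = lump_matrix(P, membership, len(comms), prev_pi,
                         fallback_weights=prev_visits)
        plan.append((ids, comms, Th))
        group_pi = np.zeros(len(comms))
        np.add.at(group_pi, membership, prev_pi)
        s = group_pi.sum()
        prev_pi = group_pi / s if s > 0 else np.full(len(comms), 1.0 / len(comms))
        group_visits = np.zeros(len(comms))
        np.add.at(group_visits, membership, prev_visits)
        prev_visits = group_visits
        prev_states = ids
        visits_of = dict(zip(ids, group_visits))
        prev_T = Th
        h += 1

    # install
    model.levels = model.levels[:1]
    model.macrostates = {}
    for h, (ids, comms, Th) in enumerate(plan, start=1):
        lvl = LevelModel(level=h, kappa=model.kappa, tau0=model.tau0,
                         states=list(ids), tmatrix=Th)
        model.levels.append(lvl)
        for sid, comm in zip(ids, comms):
            mac = Macrostate(id=sid, level=h, children=set(comm))
            model.macrostates[sid] = mac
            for c in comm:
                if c in model.microstates:
                    model.microstates[c].parent = sid
                else:
                    model.macrostates[c].parent = sid
    model.macrostates[model.root_id].parent = None
    if model.levels[-1].n_states == 1 and model.levels[-1].tmatrix is None:
        model.levels[-1].tmatrix = np.ones((1, 1))


def _match_ids(model, comms, visits_of, old_state_ids, old_macrostates,
               used_ids, cparams, report, h) -> list[int]:
    """Assign ids to detected communities by maximal visit-weighted overlap
    with the old macrostates of the same level (threshold-gated), allocating
    fresh ids otherwise."""
    ids: list[int] = []
    claimed: set[int] = set()
    n_created = n_matched = 0
    for comm in comms:
        total = sum(visits_of.get(c, 0.0) for c in comm)
        best_id, best_overlap = None, 0.0
        for old_id in old_state_ids:
            if old_id in claimed or old_id in used_ids:
                continue
            old_children = old_macrostates[old_id].children
            overlap = sum(visits_of.get(c, 0.0) for c in comm if c in old_children)
            if overlap > best_overlap:
                best_id, best_overlap = old_id, overlap
        if (best_id is not None and total > 0 and
                best_overlap / total >= cparams.overlap_match_threshold):
            sid = best_id
            claimed.add(sid)
            n_matched += 1
        else:
            sid = model.allocate_id()
            n_created += 1
        ids.append(sid)
        used_ids.add(sid)
    report.created[h] = n_created
    report.removed[h] = len([s for s in old_state_ids if s not in claimed])
    report.matched[h] = n_matched
    return ids
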