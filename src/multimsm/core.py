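"""Core data structures for multiscale Markov state models.

A multiscale model is a nested hierarchy of Markov state models sharing one
trajectory source.  Level 0 holds the microstates produced by online
K-centers discretization together with their transition-count matrix at the
base lag time ``tau0``.  Every level ``h >= 1`` partitions the states of
level ``h - 1`` into macrostates and carries a transition matrix at lag
``kappa**h * tau0``.  The top level always contains exactly one macrostate,
the root of the nesting tree.

Counts are stored, probabilities are derived on demand; state ids are
global and never reused after deletion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FeatureSpace",
    "Configuration",
    "Microstate",
    "Macrostate",
    "LevelModel",
    "MultiscaleModel",
    "new_multiscale_msm",
    "transition_matrix",
    "check_hierarchy",
    "save_model_json",
    "load_model_json",
    "export_graphml",
]


# --------------------------------------------------------------------------
# feature space and configurations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpace:
    """Declares the geometry of the feature vectors fed to the model.

    Parameters
    ----------
    n_features : int
        Dimensionality of each configuration.
    periodic : sequence of bool, optional
        Per-feature periodicity flag. Defaults to all aperiodic.
    period : sequence of float, optional
        Per-feature period span (e.g. 360 for angles in degrees).  Must be
        positive for every periodic feature.
    bounds : pair of sequences, optional
        Per-feature closed interval ``(lower, upper)``; configurations
        outside the bounds are rejected on ingestion.
    """

    n_features: int
    periodic: tuple = None
    period: tuple = None
    bounds: tuple = None

    def __post_init__(self):
        n = self.n_features
        if n < 1:
            raise ValueError("n_features must be a positive integer")
        periodic = self.periodic
        if periodic is None:
            periodic = (False,) * n
        else:
            periodic = tuple(bool(p) for p in periodic)
            if len(periodic) != n:
                raise ValueError("periodic flags must have length n_features")
        object.__setattr__(self, "periodic", periodic)

        period = self.period
        if period is None:
            period = tuple(360.0 if p else 0.0 for p in periodic)
        else:
            period = tuple(float(p) for p in period)
            if len(period) != n:
                raise ValueError("period must have length n_features")
        for flag, p in zip(periodic, period):
            if flag and p <= 0:
                raise ValueError("period must be > 0 for every periodic feature")
        object.__setattr__(self, "period", period)

        if self.bounds is not None:
            lo, hi = self.bounds
            lo = tuple(float(v) for v in lo)
            hi = tuple(float(v) for v in hi)
            if len(lo) != n or len(hi) != n:
                raise ValueError("bounds must have length n_features")
            for a, b in zip(lo, hi):
                if not a < b:
                    raise ValueError("bounds must satisfy lower < upper")
            object.__setattr__(self, "bounds", (lo, hi))

    @property
    def any_periodic(self) -> bool:
        return any(self.periodic)

    def wrap(self, values: np.ndarray) -> np.ndarray:
        """Reduce periodic coordinates to the canonical interval [0, period)."""
        values = np.asarray(values, dtype=float)
        if not self.any_periodic:
            return values
        out = np.array(values, dtype=float, copy=True)
        per = np.asarray(self.period)
        mask = np.asarray(self.periodic)
        out[..., mask] = np.mod(out[..., mask], per[mask])
        return out

    def contains(self, values: np.ndarray) -> bool:
        """True if ``values`` respects the declared bounds (if any)."""
        if self.bounds is None:
            return True
        values = np.asarray(values, dtype=float)
        lo, hi = self.bounds
        return bool(np.all(values >= np.asarray(lo)) and np.all(values <= np.asarray(hi)))

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "periodic": list(self.periodic),
            "period": list(self.period),
            "bounds": None if self.bounds is None else [list(self.bounds[0]), list(self.bounds[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpace":
        bounds = d.get("bounds")
        return cls(
            n_features=d["n_features"],
            periodic=d.get("periodic"),
            period=d.get("period"),
            bounds=None if bounds is None else (bounds[0], bounds[1]),
        )


class Configuration:
    """A single point in feature space (thin wrapper around a float vector)."""

    __slots__ = ("values",)

    def __init__(self, values):
        self.values = np.atleast_1d(np.asarray(values, dtype=float))

    def __len__(self):
        return self.values.shape[0]

    def __repr__(self):
        return f"Configuration({self.values.tolist()})"

    def __eq__(self, other):
        if isinstance(other, Configuration):
            return np.array_equal(self.values, other.values)
        return NotImplemented


def as_values(x) -> np.ndarray:
    """Coerce a Configuration or array-like to a 1-D float array."""
    if isinstance(x, Configuration):
        return x.values
    return np.atleast_1d(np.asarray(x, dtype=float))


# --------------------------------------------------------------------------
# states
# --------------------------------------------------------------------------

@dataclass
class Microstate:
    """A finest-grained state: a compact volume of feature space.

    ``representatives`` is a bounded uniform reservoir of configurations
    observed inside the state; ``rep_seen`` counts every configuration ever
    offered to the reservoir so that replacement stays uniform.
    """

    id: int
    center: np.ndarray
    radius: float
    visit_count: int = 0
    parent: int | None = None
    representatives: list = field(default_factory=list)
    rep_seen: int = 0

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("microstate radius must be > 0")


@dataclass
class Macrostate:
    """A union of states one level down; nodes of the nesting tree."""

    id: int
    level: int
    children: set = field(default_factory=set)
    parent: int | None = None
    visit_count: int = 0


@dataclass
class LevelModel:
    """One level of the hierarchy: an ordered state set plus transition data.

    Level 0 accumulates raw transition counts (sparse, keyed by id pairs).
    Levels >= 1 carry a coarse-grained transition matrix derived by the
    update procedure; their ``counts`` dict stays None.
    """

    level: int
    kappa: int
    tau0: float
    states: list = field(default_factory=list)
    counts: dict | None = None
    tmatrix: np.ndarray | None = None

    @property
    def lag(self) -> float:
        """Lag time tau_h = kappa**h * tau0, computed exactly on demand."""
        return (self.kappa ** self.level) * self.tau0

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index_of(self) -> dict:
        return {s: i for i, s in enumerate(self.states)}

    def count_matrix(self) -> np.ndarray:
        """Dense count matrix indexed consistently with ``states``."""
        n = len(self.states)
        C = np.zeros((n, n), dtype=float)
        if self.counts:
            idx = self.index_of()
            for (i, j), c in self.counts.items():
                C[idx[i], idx[j]] = c
        return C


# --------------------------------------------------------------------------
# the multiscale model
# --------------------------------------------------------------------------

class MultiscaleModel:
    """The multiscale MSM: nested partitions plus per-level transition data.

    Attributes
    ----------
    feature_space : FeatureSpace
    kappa : int
        Uniform temporal coarse-graining factor between adjacent levels.
    tau0 : float
        Base lag time (also the frame interval of ingested trajectories).
    levels : list of LevelModel
        ``levels[0]`` is the base (microstate) level; the last entry always
        holds exactly one state, the root.
    """

    def __init__(self, feature_space: FeatureSpace, kappa: int, tau0: float):
        if kappa < 2:
            raise ValueError("kappa must be an integer >= 2")
        if tau0 <= 0:
            raise ValueError("tau0 must be positive")
        self.feature_space = feature_space
        self.kappa = int(kappa)
        self.tau0 = float(tau0)
        self.microstates: dict[int, Microstate] = {}
        self.macrostates: dict[int, Macrostate] = {}
        self.levels: list[LevelModel] = []
        self._next_id = 0
        # id-aligned caches for fast nearest-center queries
        self._center_ids: list[int] = []
        self._center_rows: list[np.ndarray] = []
        self._center_arr: np.ndarray | None = None
        # transitions ingested since the last community re-detection
        self.pending_transitions = 0

    # -- ids ---------------------------------------------------------------

    def allocate_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    # -- structure queries -------------------------------------------------

    @property
    def H(self) -> int:
        """Number of levels above the base."""
        return len(self.levels) - 1

    @property
    def root_id(self) -> int:
        return self.levels[-1].states[0]

    @property
    def n_microstates(self) -> int:
        return len(self.microstates)

    def state(self, sid: int):
        if sid in self.microstates:
            return self.microstates[sid]
        return self.macrostates[sid]

    def level_of(self, sid: int) -> int:
        if sid in self.microstates:
            return 0
        return self.macrostates[sid].level

    def children_of(self, sid: int) -> list:
        """Children ids sorted ascending (deterministic iteration order)."""
        st = self.state(sid)
        if isinstance(st, Microstate):
            return []
        return sorted(st.children)

    # -- centers cache -----------------------------------------------------

    def center_matrix(self) -> np.ndarray:
        """(n_microstates, n_features) array of centers in insertion order."""
        if self._center_arr is None or self._center_arr.shape[0] != len(self._center_rows):
            if self._center_rows:
                self._center_arr = np.vstack(self._center_rows)
            else:
                self._center_arr = np.empty((0, self.feature_space.n_features))
        return self._center_arr

    def center_ids(self) -> np.ndarray:
        return np.asarray(self._center_ids, dtype=np.int64)

    # -- mutation ----------------------------------------------------------

    def add_microstate(self, center: np.ndarray, radius: float,
                       parent: int | None = None) -> Microstate:
        center = self.feature_space.wrap(as_values(center))
        ms = Microstate(id=self.allocate_id(), center=center, radius=radius, parent=parent)
        self.microstates[ms.id] = ms
        self.levels[0].states.append(ms.id)
        self._center_ids.append(ms.id)
        self._center_rows.append(center)
        self._center_arr = None
        if parent is not None:
            self.macrostates[parent].children.add(ms.id)
        return ms

    def refresh_visit_counts(self) -> None:
        """Recompute every macrostate's visit count as the sum over children."""
        for lvl in self.levels[1:]:
            for sid in lvl.states:
                mac = self.macrostates[sid]
                mac.visit_count = sum(self.state(c).visit_count for c in mac.children)

    def total_base_count(self) -> float:
        counts = self.levels[0].counts or {}
        return float(sum(counts.values()))


def new_multiscale_msm(xinit, space: FeatureSpace, diameter: float,
                       kappa: int = 2, tau0: float = 1.0) -> MultiscaleModel:
    """Create a model holding one microstate centered at ``xinit`` plus a root.

    The initial configuration counts as one visit; the hierarchy starts with
    H = 1 (a base level and the singleton root above it).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    x = as_values(xinit)
    if x.shape[0] != space.n_features:
        raise ValueError(f"xinit has {x.shape[0]} features, expected {space.n_features}")
    if not space.contains(x):
        raise ValueError(f"xinit {x.tolist()} lies outside the declared feature bounds")
    model = MultiscaleModel(space, kappa, tau0)
    model.levels = [
        LevelModel(level=0, kappa=model.kappa, tau0=model.tau0, counts={}),
        LevelModel(level=1, kappa=model.kappa, tau0=model.tau0),
    ]
    ms = model.add_microstate(x, radius=diameter / 2.0)
    ms.visit_count = 1
    ms.representatives.append(model.feature_space.wrap(x))
    ms.rep_seen = 1
    root = Macrostate(id=model.allocate_id(), level=1, children={ms.id}, visit_count=1)
    model.macrostates[root.id] = root
    model.levels[1].states.append(root.id)
    ms.parent = root.id
    return model


# --------------------------------------------------------------------------
# transition matrices
# --------------------------------------------------------------------------

def transition_matrix(model: MultiscaleModel, h: int) -> np.ndarray:
    """Row-stochastic transition matrix of level ``h``.

    Level 0 (and any level storing raw counts) uses the maximum-likelihood
    row-normalized estimator; a state with zero outgoing counts receives a
    unit self-transition so the matrix stays stochastic.  Levels >= 1 return
    the coarse-grained matrix cached by the update procedure, computing it
    on demand if absent.
    """
    if not 0 <= h <= model.H:
        raise IndexError(f"level {h} out of range 0..{model.H}")
    lvl = model.levels[h]
    if lvl.counts is not None:
        return _normalize_counts(lvl.count_matrix())
    if lvl.n_states == 1:
        return np.ones((1, 1))
    if lvl.tmatrix is None:
        from .update import coarse_grain_level  # deferred: avoids cycle
        coarse_grain_level(model, h)
    return lvl.tmatrix


def _normalize_counts(C: np.ndarray) -> np.ndarray:
    rows = C.sum(axis=1)
    T = np.array(C, dtype=float, copy=True)
    zero = rows == 0
    T[zero] = 0.0
    T[zero, np.flatnonzero(zero)] = 1.0
    nz = ~zero
    T[nz] = T[nz] / rows[nz, None]
    return T


# --------------------------------------------------------------------------
# structural validation
# --------------------------------------------------------------------------

def check_hierarchy(model: MultiscaleModel) -> list[str]:
    """Verify every structural invariant; return the list of violations.

    Checks nesting (each level partitions the one below), the singleton
    root, non-increasing state counts, visit-count conservation, and lag
    geometry.  Reports, never raises: an empty list means the model is
    structurally valid.
    """
    issues: list[str] = []
    if not model.levels:
        return ["model has no levels"]

    if set(model.levels[0].states) != set(model.microstates):
        issues.append("level 0 state list does not match the microstate table")

    if model.levels[-1].n_states != 1:
        issues.append(
            f"top level has {model.levels[-1].n_states} states, expected a single root")

    prev_n = None
    for h, lvl in enumerate(model.levels):
        if lvl.level != h:
            issues.append(f"level {h} is labeled {lvl.level}")
        expected_lag = (model.kappa ** h) * model.tau0
        if lvl.lag != expected_lag:
            issues.append(f"level {h} lag {lvl.lag} != kappa^h*tau0 {expected_lag}")
        if prev_n is not None and lvl.n_states > prev_n:
            issues.append(
                f"level {h} has {lvl.n_states} states, more than level {h-1} ({prev_n})")
        prev_n = lvl.n_states

    # partition-nesting: each level's children disjointly cover the one below
    for h in range(1, len(model.levels)):
        below = set(model.levels[h - 1].states)
        seen: dict[int, int] = {}
        for sid in model.levels[h].states:
            mac = model.macrostates.get(sid)
            if mac is None:
                issues.append(f"level {h} lists unknown macrostate {sid}")
                continue
            if not mac.children:
                issues.append(f"macrostate {sid} at level {h} has no children")
            for c in mac.children:
                if c not in below:
                    issues.append(
                        f"macrostate {sid} at level {h} has child {c} not present at level {h-1}")
                if c in seen:
                    issues.append(
                        f"state {c} at level {h-1} has two parents: {seen[c]} and {sid}")
                seen[c] = sid
        orphans = below - set(seen)
        for c in sorted(orphans):
            issues.append(f"state {c} at level {h-1} has no parent at level {h}")
        # parent pointers must agree with children sets
        for c, p in seen.items():
            actual = model.state(c).parent
            if actual != p:
                issues.append(
                    f"state {c} records parent {actual} but is a child of {p}")

    # visit-count conservation
    for h in range(1, len(model.levels)):
        for sid in model.levels[h].states:
            mac = model.macrostates.get(sid)
            if mac is None:
                continue
            child_sum = sum(
                model.state(c).visit_count for c in mac.children if
                (c in model.microstates or c in model.macrostates))
            if mac.visit_count != child_sum:
                issues.append(
                    f"macrostate {sid} visit_count {mac.visit_count} != sum over children {child_sum}")

    for ms in model.microstates.values():
        if ms.radius <= 0:
            issues.append(f"microstate {ms.id} has non-positive radius")
    return issues


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

SCHEMA_VERSION = 1


def model_to_dict(model: MultiscaleModel) -> dict:
    counts = model.levels[0].counts or {}
    return {
        "schema_version": SCHEMA_VERSION,
        "feature_space": model.feature_space.to_dict(),
        "kappa": model.kappa,
        "tau0": model.tau0,
        "next_id": model._next_id,
        "pending_transitions": model.pending_transitions,
        "levels": [
            {
                "level": lvl.level,
                "states": list(lvl.states),
                "tmatrix": None if lvl.tmatrix is None else [list(map(float, r)) for r in lvl.tmatrix],
            }
            for lvl in model.levels
        ],
        "microstates": [
            {
                "id": ms.id,
                "center": [float(v) for v in ms.center],
                "radius": ms.radius,
                "visit_count": int(ms.visit_count),
                "parent": ms.parent,
                "representatives": [[float(v) for v in r] for r in ms.representatives],
                "rep_seen": int(ms.rep_seen),
            }
            for ms in (model.microstates[i] for i in sorted(model.microstates))
        ],
        "macrostates": [
            {
                "id": mac.id,
                "level": mac.level,
                "children": sorted(mac.children),
                "parent": mac.parent,
                "visit_count": int(mac.visit_count),
            }
            for mac in (model.macrostates[i] for i in sorted(model.macrostates))
        ],
        "base_counts": [[int(i), int(j), float(c)] for (i, j), c in sorted(counts.items())],
    }


def model_from_dict(d: dict) -> MultiscaleModel:
    space = FeatureSpace.from_dict(d["feature_space"])
    model = MultiscaleModel(space, d["kappa"], d["tau0"])
    model.levels = []
    for lv in d["levels"]:
        lvl = LevelModel(level=lv["level"], kappa=model.kappa, tau0=model.tau0,
                         states=list(lv["states"]))
        if lv.get("tmatrix") is not None:
            lvl.tmatrix = np.asarray(lv["tmatrix"], dtype=float)
        model.levels.append(lvl)
    model.levels[0].counts = {(i, j): c for i, j, c in d["base_counts"]}
    for m in d["microstates"]:
        ms = Microstate(id=m["id"], center=np.asarray(m["center"]), radius=m["radius"],
                        visit_count=m["visit_count"], parent=m["parent"],
                        representatives=[np.asarray(r) for r in m["representatives"]],
                        rep_seen=m["rep_seen"])
        model.microstates[ms.id] = ms
        model._center_ids.append(ms.id)
        model._center_rows.append(ms.center)
    for m in d["macrostates"]:
        model.macrostates[m["id"]] = Macrostate(
            id=m["id"], level=m["level"], children=set(m["children"]),
            parent=m["parent"], visit_count=m["visit_count"])
    model._next_id = d["next_id"]
    model.pending_transitions = d.get("pending_transitions", 0)
    return model


def save_model_json(model: MultiscaleModel, path) -> None:
    """Write the model as a single human-diffable JSON document."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_model_json(path) -> MultiscaleModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def export_graphml(model: MultiscaleModel, h: int, path) -> None:
    """Export level ``h``'s transition graph as GraphML.

    Node attributes: id, level, stationary probability, visit_count.
    Edge attribute: transition probability.
    """
    import networkx as nx

    from .analysis import stationary_distribution

    T = transition_matrix(model, h)
    pi = stationary_distribution(T)
    lvl = model.levels[h]
    g = nx.DiGraph()
    for i, sid in enumerate(lvl.states):
        g.add_node(sid, level=h, stationary_probability=float(pi[i]),
                   visit_count=int(model.state(sid).visit_count))
    for i, si in enumerate(lvl.states):
        for j, sj in enumerate(lvl.states):
            if T[i, j] > 0:
                g.add_edge(si, sj, probability=float(T[i, j]))
    nx.write_graphml(g, path)
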