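"""Online K-centers discretization of configurations into microstates.

A frame within ``diameter/2`` of an existing center joins that microstate;
otherwise it founds a new one centered at the frame.  Centers therefore
stay more than ``diameter/2`` apart, and every ingested frame lies within
``diameter/2`` of its assigned center (or created it).  Assignment is
deterministic: nearest center wins, ties break toward the lowest state id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Configuration, FeatureSpace, Microstate, MultiscaleModel, as_values

__all__ = [
    "DiscretizerParams",
    "feature_distance",
    "assign_microstate",
    "assign_frames",
    "representative",
]


@dataclass(frozen=True)
class DiscretizerParams:
    """K-centers settings: cluster ``diameter`` and the per-microstate
    representative-reservoir capacity."""

    diameter: float
    max_representatives: int = 10

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.max_representatives < 1:
            raise ValueError("max_representatives must be >= 1")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


# --------------------------------------------------------------------------
# metric
# --------------------------------------------------------------------------

def feature_distance(a, b, space: FeatureSpace) -> float:
    """Euclidean distance with minimal wrapped differences on periodic axes."""
    av, bv = as_values(a), as_values(b)
    if av.shape != bv.shape or av.shape[0] != space.n_features:
        raise ValueError("configurations must share the feature space dimension")
    return float(np.sqrt(_sq_distances(av[None, :], bv[None, :], space)[0, 0]))


def _sq_distances(X: np.ndarray, C: np.ndarray, space: FeatureSpace) -> np.ndarray:
    """Pairwise squared distances (frames x centers), periodic-aware."""
    diff = np.abs(X[:, None, :] - C[None, :, :])
    if space.any_periodic:
        per = np.asarray(space.period)
        mask = np.asarray(space.periodic)
        d = diff[:, :, mask]
        diff[:, :, mask] = np.minimum(d, per[mask] - d)
    return np.einsum("ijk,ijk->ij", diff, diff)


# --------------------------------------------------------------------------
# nearest-center queries
# --------------------------------------------------------------------------

def _nearest_center(X: np.ndarray, model: MultiscaleModel) -> tuple[np.ndarray, np.ndarray]:
    """For each frame, the insertion-order index of its nearest center and
    the distance to it.  Ties go to the earliest-inserted (lowest id) center."""
    C = model.center_matrix()
    space = model.feature_space
    n = C.shape[0]
    if n == 0:
        raise ValueError("model has no microstates")
    if space.n_features == 1 and not space.any_periodic and n > 8:
        return _nearest_center_1d(X[:, 0], C[:, 0])
    # brute force, chunked to bound the frames x centers distance matrix;
    # argmin returns the first (lowest-id) minimizer
    m = X.shape[0]
    idx = np.empty(m, dtype=np.int64)
    dist = np.empty(m, dtype=float)
    step = max(1, 4_000_000 // max(1, n * C.shape[1]))
    for a in range(0, m, step):
        b = min(a + step, m)
        d2 = _sq_distances(X[a:b], C, space)
        ii = np.argmin(d2, axis=1)
        idx[a:b] = ii
        dist[a:b] = np.sqrt(d2[np.arange(b - a), ii])
    return idx, dist

def _nearest_center_1d(x: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(c, kind="stable")
    cs = c[order]
    pos = np.searchsorted(cs, x)
    lo = np.clip(pos - 1, 0, len(cs) - 1)
    hi = np.clip(pos, 0, len(cs) - 1)
    dlo = np.abs(x - cs[lo])
    dhi = np.abs(x - cs[hi])
    lo_ids = order[lo]
    hi_ids = order[hi]
    # strict comparison keeps the earlier-inserted center on exact ties
    pick_hi = (dhi < dlo) | ((dhi == dlo) & (hi_ids < lo_ids))
    idx = np.where(pick_hi, hi_ids, lo_ids)
    return idx, np.where(pick_hi, dhi, dlo)


# --------------------------------------------------------------------------
# assignment
# --------------------------------------------------------------------------

def assign_microstate(x, model: MultiscaleModel, params: DiscretizerParams,
                      rng: np.random.Generator | None = None) -> int:
    """Assign one configuration, creating a microstate when none is close.

    Returns the microstate id; increments its visit count and offers the
    configuration to its representative reservoir.
    """
    ids = assign_frames(as_values(x)[None, :], model, params, rng=rng)
    return int(ids[0])


def assign_frames(frames: np.ndarray, model: MultiscaleModel, params: DiscretizerParams,
                  rng: np.random.Generator | None = None,
                  created: list | None = None) -> np.ndarray:
    """Assign a block of frames in order; vectorized between center creations.

    ``created`` (optional) collects the ids of newly founded microstates.
    New microstates are provisionally attached under the parent of their
    nearest pre-existing microstate.
    """
    space = model.feature_space
    X = np.asarray(frames, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != space.n_features:
        raise ValueError(
            f"frames have {X.shape[1]} features, expected {space.n_features}")
    if space.bounds is not None:
        lo, hi = np.asarray(space.bounds[0]), np.asarray(space.bounds[1])
        if np.any(X < lo) or np.any(X > hi):
            bad = int(np.flatnonzero(np.any((X < lo) | (X > hi), axis=1))[0])
            raise ValueError(f"frame {bad} lies outside the declared feature bounds")
    X = space.wrap(X)

    m = X.shape[0]
    ids = np.empty(m, dtype=np.int64)
    radius = params.radius
    # process in blocks so a center created early in a long stream does not
    # force re-scans of millions of remaining frames
    block = 65536
    for b0 in range(0, m, block):
        b1 = min(b0 + block, m)
        pos = b0
        while pos < b1:
            if model.n_microstates == 0:
                ids[pos] = _found_microstate(X[pos], model, radius, created)
                pos += 1
                continue
            idx, dist = _nearest_center(X[pos:b1], model)
            far = np.flatnonzero(dist > radius)
            stop = int(far[0]) if far.size else b1 - pos
            cid = model.center_ids()
            ids[pos:pos + stop] = cid[idx[:stop]]
            if far.size:
                ids[pos + stop] = _found_microstate(X[pos + stop], model, radius, created)
                pos += stop + 1
            else:
                pos = b1

    _record_visits(ids, X, model, params, rng)
    return ids


def _found_microstate(x: np.ndarray, model: MultiscaleModel, radius: float,
                      created: list | None) -> int:
    parent = None
    if model.n_microstates > 0:
        idx, _ = _nearest_center(x[None, :], model)
        nearest_id = int(model.center_ids()[idx[0]])
        parent = model.microstates[nearest_id].parent
    ms = model.add_microstate(x, radius=radius, parent=parent)
    if created is not None:
        created.append(ms.id)
    return ms.id


def _record_visits(ids: np.ndarray, X: np.ndarray, model: MultiscaleModel,
                   params: DiscretizerParams, rng: np.random.Generator | None) -> None:
    if rng is None:
        rng = np.random.default_rng(0)
    uniq, inv = np.unique(ids, return_inverse=True)
    counts = np.bincount(inv)
    cap = params.max_representatives
    for k, sid in enumerate(uniq):
        ms = model.microstates[int(sid)]
        ms.visit_count += int(counts[k])
        block = X[inv == k]
        _reservoir_merge(ms, block, cap, rng)


def _reservoir_merge(ms: Microstate, block: np.ndarray, cap: int,
                     rng: np.random.Generator) -> None:
    """Merge a block of observations into the state's uniform reservoir.

    Equivalent to running reservoir sampling item by item: after the merge
    the stored set is a uniform size-``cap`` subset of everything seen.  The
    number of survivors from the old reservoir is hypergeometric in
    (old seen, block size).
    """
    b = block.shape[0]
    n_old = ms.rep_seen
    n_total = n_old + b
    ms.rep_seen = n_total
    if n_total <= cap:
        ms.representatives.extend(block[i] for i in range(b))
        return
    # survivors from the new block in a uniform size-cap subset of n_total
    k_new = int(rng.hypergeometric(b, n_old, cap)) if n_old > 0 else cap
    k_new = min(k_new, b, cap)
    k_old = cap - k_new
    old = ms.representatives
    if k_old > 0 and len(old) > 0:
        keep_idx = rng.choice(len(old), size=min(k_old, len(old)), replace=False)
        kept = [old[i] for i in sorted(keep_idx)]
    else:
        kept = []
    if k_new > 0:
        new_idx = rng.choice(b, size=k_new, replace=False)
        kept.extend(block[i] for i in sorted(new_idx))
    ms.representatives = kept


# --------------------------------------------------------------------------
# restart configurations
# --------------------------------------------------------------------------

def representative(s: Microstate, rng: np.random.Generator) -> Configuration:
    """A uniformly sampled stored representative (center if storage is empty)."""
    if not s.representatives:
        return Configuration(s.center)
    i = int(rng.integers(len(s.representatives)))
    return Configuration(s.representatives[i])
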