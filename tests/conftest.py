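import numpy as np
import pytest

from multimsm import (DiscretizerParams, FeatureSpace, Macrostate,
                      new_multiscale_msm)
from multimsm.core import LevelModel


@pytest.fixture
def space1d():
    return FeatureSpace(n_features=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dparams():
    return DiscretizerParams(diameter=0.05)


def build_model_from_chain(centers, counts, blocks, kappa=2, tau0=1.0, diameter=0.5):
    """Hand-build a 3-level model: microstates at ``centers``, base counts,
    macrostates grouping microstate indices per ``blocks``, and a root.

    Microstate ids are 0..n-1 in center order; returns the model.
    """
    centers = np.asarray(centers, dtype=float).reshape(len(centers), -1)
    space = FeatureSpace(n_features=centers.shape[1])
    model = new_multiscale_msm(centers[0], space, diameter, kappa=kappa, tau0=tau0)
    for c in centers[1:]:
        model.add_microstate(c, radius=diameter / 2.0)
    # drop the auto-created root; rebuild levels explicitly
    model.macrostates.clear()
    model.levels = [model.levels[0]]
    model.levels[0].counts = {}
    ids = list(model.levels[0].states)  # actual microstate ids, center order
    C = np.asarray(counts, dtype=float)
    for i in range(C.shape[0]):
        for j in range(C.shape[1]):
            if C[i, j]:
                model.levels[0].counts[(ids[i], ids[j])] = float(C[i, j])
        model.microstates[ids[i]].visit_count = max(1, int(C[i].sum()))
        model.microstates[ids[i]].representatives = [centers[i]]
        model.microstates[ids[i]].rep_seen = 1
    lvl1 = LevelModel(level=1, kappa=model.kappa, tau0=model.tau0)
    for block in blocks:
        mac = Macrostate(id=model.allocate_id(), level=1,
                         children={ids[i] for i in block})
        mac.visit_count = sum(model.microstates[ids[i]].visit_count for i in block)
        model.macrostates[mac.id] = mac
        lvl1.states.append(mac.id)
        for i in block:
            model.microstates[ids[i]].parent = mac.id
    model.levels.append(lvl1)
    if len(blocks) > 1:
        root = Macrostate(id=model.allocate_id(), level=2,
                          children=set(lvl1.states))
        root.visit_count = sum(model.macrostates[s].visit_count for s in lvl1.states)
        model.macrostates[root.id] = root
        lvl2 = LevelModel(level=2, kappa=model.kappa, tau0=model.tau0,
                          states=[root.id])
        for s in lvl1.states:
            model.macrostates[s].parent = root.id
        model.levels.append(lvl2)
    return model


def sample_chain(T, n_steps, seed, s0=0):
    """Plain-numpy Markov chain sampler (independent oracle for tests)."""
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    path = np.empty(n_steps + 1, dtype=np.int64)
    path[0] = s0
    u = rng.random(n_steps)
    s = s0
    for t in range(n_steps):
        s = int(np.searchsorted(cum[s], u[t]))
        path[t + 1] = s
    return path
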