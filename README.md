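# multimsm

Multiscale Markov state models: a nested hierarchy of MSMs over one
trajectory source, built incrementally by adaptive exploration with
on-the-fly detection of temporal communities at every scale.

A multiscale model consists of levels `M0 .. MH`. Level 0 holds microstates
produced by online K-centers discretization together with transition counts
at the base lag time `tau0`; every level `h >= 1` partitions the level below
into macrostates and carries a transition matrix at lag `kappa**h * tau0`
(default `kappa = 2`). The top level is always a single root macrostate.
The exploration driver alternates short simulations, hierarchy updates
(bottom-up coarse-graining by stationary-weighted lumping plus
modularity-based community re-detection), and adaptive restarts that descend
the hierarchy from the root sampling children with probabilities weighted
against their visit counts.

## Layout

| module | contents |
| --- | --- |
| `multimsm.core` | model data structures, transition matrices, structural validation, JSON/GraphML serialization |
| `multimsm.discretize` | online K-centers, periodic-aware metric, representative reservoirs |
| `multimsm.update` | base-count ingestion, coarse-graining, temporal-community detection, merge/split hierarchy maintenance |
| `multimsm.adaptive` | the exploration driver, multiscale adaptive sampling, flat-MSM and naive baselines, exploration curves |
| `multimsm.analysis` | stationary distributions, relaxation/implied timescales, free energies, basin mapping, native-contact fractions |
| `multimsm.simulate` | Brownian-dynamics engine on a parametrized nested 1-D landscape, nested-block chains with exact ground truth, chunked trajectory streaming |
| `multimsm.config` / `multimsm.cli` | YAML run configuration and the `multimsm` command |

## CLI

```sh
multimsm fixtures --system two_spheres --out out/       # landscape + ground truth
multimsm explore run.yaml --out out/                    # adaptive construction
multimsm baseline run.yaml --method naive --out out/    # baselines
multimsm analyze out/model.json --out out/              # pi / F / timescale tables
multimsm build traj.txt --config run.yaml --out out/    # stream an external trajectory
```

A minimal config:

```yaml
system: two_spheres
seed: 1
tau0: 0.03        # ps
diameter: 0.05    # angstrom, K-centers cluster diameter
explore: {tmax: 1000.0, ninit: 10, k: 1, m: 101}
```

Units everywhere: angstroms, picoseconds, kcal/mol, kelvin; angles in
degrees (period 360). Every run records its config hash and seed for exact
replay; model JSON round-trips byte-identically.

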