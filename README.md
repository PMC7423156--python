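# tractoprint

Comparative tractography of temporal-lobe-style white matter, desk-scale:
connectivity-based parcellation of white-matter ROIs, protocol-constrained
probabilistic tract reconstruction, vertex × tract **connectivity
blueprints**, and cross-brain **KL-divergence** matching — exercised end to
end on synthetic fiber-orientation phantoms with known ground truth.

The package is for methods work on comparative diffusion-MRI analyses:
every stage of the chain (tracking, clustering, blueprint algebra, vertex
matching) is a tested library function, and the phantom generator provides
two "species" whose differences — a bundle that splits into lateral/medial
subcomponents, and a curved arcuate-like bundle present in only one brain —
are known exactly, so the sensitivity and direction of the comparisons can
be verified rather than assumed.

## The core quantities

- **Tractogram.** Streamlines are propagated from every seed voxel through
  a per-voxel orientation field (Euler steps, curvature threshold 0.2 as a
  minimum cosine, exclusion masks delete, termination masks stop without
  deleting) and kept only if they cross a waypoint. With visitation counted
  once per streamline per voxel, the normalized map is
  `n(v) = counts(v) / n_retained` — the probability that a retained
  streamline visits v.
- **Connectivity-based parcellation.** For ROI voxels with whole-brain
  connectivity rows `c_i`, the similarity matrix `S_ij = corr(c_i, c_j)`
  is clustered by k-means; clusters localize tract bodies and yield
  seed/waypoint masks.
- **Connectivity blueprint.** With vertexwise connectivity `V` (vertices ×
  voxels) and tract matrix `T` (voxels × tracts), the blueprint is the
  row-normalized product `B = norm(V·T)`; row `B_v` is vertex v's
  connectivity fingerprint, a probability distribution over tracts.
- **Divergence matching.** Across brains,
  `KL(p‖q) = Σ_i p_i ln((p_i+ε)/(q_i+ε))` (nats, ε = 1e-8) is computed
  between every fingerprint pair; each vertex's minimum over the other
  brain's vertices forms the min-KL map. Low = a matching profile exists;
  high = a species-unique profile. Distribution shifts are tested with the
  two-sample Kolmogorov–Smirnov test at p < 0.01.

## Worked example

The numbered scripts under `analysis/` run the study in order:
`01_build_phantoms.py` → `02_reconstruct_tracts.py` → `03_parcellate.py`
→ `04_blueprints.py` → `05_divergence.py`, writing tables and maps under
`results/`. The final comparison prints:

```
$ python analysis/05_divergence.py
min-KL medians: A->B 0.0000, B->A 0.0007 nats
arcuate effect: KS D=0.698, p=8.73e-118; 729 elevated vertices, 84.8% in the arcuate's territory
ILF swap: mean (lat - med) difference over the ILF territory = +0.0303 nats (n=25); positive = the medial assumption fits better
outputs under results/divergence/
```

Reading: the two brains' shared tracts match almost perfectly (median
min-KL near zero). Adding the arcuate-like bundle — present in brain B
only — shifts B's min-KL distribution decisively (KS rejects far below
0.01), and the elevated vertices sit overwhelmingly in the arcuate's own
territory: the machinery attributes the divergence to the right bundle.
Swapping which ILF subcomponent stands in for brain A's single ILF gives a
positive (lateral − medial) difference, i.e. the temporal lobes are more
similar under the medial-equivalence assumption — and the phantom's ILF
was indeed built congruent to the medial child.

A minimal library-level session:

```python
import numpy as np
from tractoprint import blueprint, divergence

V = np.array([[1., 0., 1.], [0., 2., 0.]])      # vertices x voxels
T = np.array([[1., 0.], [0., 1.], [1., 1.]])    # voxels x tracts
bp = blueprint.build_blueprint(V, T, ["ILF", "MdLF"])
print(bp.matrix)           # [[0.667 0.333], [0. 1.]] — fingerprints
print(divergence.kl_divergence([0.5, 0.5], [0.25, 0.75]))  # 0.1438 nats
```

## Layout

```
src/tractoprint/     phantom | tracking | parcellation | blueprint |
                     divergence | study (canonical conditions) | io
analysis/            numbered narrative drivers writing results/
tests/               unit + property tests and end-to-end checks
scripts/acceptance.py
docs/methods.md
```
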