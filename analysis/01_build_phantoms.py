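#!/usr/bin/env python
"""Build the two synthetic species brains and write their ground truth.

Species A (three-bundle brain) carries straight MdLF, IFOF and ILF tubes;
species B (split brain) splits the ILF into medial + lateral subcomponents
and adds an arcuate-like curved dorsal bundle.  Both share the same grid and
gray/white surface, so vertex homology is the identity - the ground truth
every later comparison relies on.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tractoprint import io, study
from tractoprint.phantom import matched_pair

SEED = 1
OUT = Path("results/phantoms")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec_a = study.three_bundle_spec(seed=study.derive_seed(SEED, "phantom_a"))
    spec_b = study.split_bundle_spec(seed=study.derive_seed(SEED, "phantom_b"))
    label_map = {"MdLF": "MdLF", "IFOF": "IFOF", "ILF": ("ILFlat", "ILFmed")}
    pa, pb, corr = matched_pair(spec_a, spec_b, label_map)

    rows = []
    for tag, ph in (("A", pa), ("B", pb)):
        vs = ph.spec.voxel_size
        io.save_volume(OUT / f"species_{tag}_labels.nii.gz",
                       ph.bundle_labels, vs)
        io.save_volume(OUT / f"species_{tag}_wm.nii.gz", ph.wm_mask, vs)
        io.save_volume(OUT / f"species_{tag}_gm.nii.gz", ph.gm_mask, vs)
        io.save_surface(OUT / f"species_{tag}.surf.gii", ph.surface)
        io.save_vertex_scalars(OUT / f"species_{tag}_truth.func.gii",
                               ph.vertex_truth)
        io.save_vertex_scalars(OUT / f"species_{tag}_homology.func.gii",
                               ph.homology_id)
        io.save_orientation_field(OUT / f"species_{tag}", ph.orientation_field)
        names = ph.truth_names()
        for bundle in ph.label_names:
            rows.append({
                "species": tag, "bundle": bundle,
                "tube_voxels": int(ph.bundle_mask(bundle).sum()),
                "labeled_vertices": int((names == bundle).sum()),
            })
    summary = pd.DataFrame(rows)
    io.save_table(OUT / "bundle_summary.tsv", summary)

    print(summary.to_string(index=False))
    shared = np.array_equal(pa.homology_id, pb.homology_id)
    print(f"\nshared surface: {pa.surface.n_vertices} vertices; homology ids "
          f"{'shared (identity on vertex indices)' if shared else 'DIFFER'}; "
          f"{len(corr.a_labeled)} (A) / {len(corr.b_labeled)} (B) labeled "
          "vertices")
    af = pb.truth_names()[corr.b_labeled] == "AF"
    print(f"arcuate-only vertices without a counterpart in A: "
          f"{int((~corr.b_has_counterpart[af]).sum() + 0) if af.any() else 0}"
          f" of {int(af.sum())}")
    print(f"artifacts written under {OUT}/")


if __name__ == "__main__":
    main()
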