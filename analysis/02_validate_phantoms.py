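#!/usr/bin/env python
"""Validate thickness recovery on phantoms of known ground truth.

Measures slab, cut cylindrical shell and graded folded-C phantoms across
1.5-4 mm sheet thicknesses with the full chain (layer growth, landmark MDS
flattening, EDT thickness on the flat map) and writes
results/phantom_recovery.csv.  The finding this table supports: under the
boundary-corrected convention every subregion mean lands within one voxel
spacing (0.4 mm here) of truth, and the literal convention exceeds truth by
one spacing on odd-voxel slabs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hippoflat.layering import grow_layers
from hippoflat.synthetic import PhantomSpec, generate_phantom
from hippoflat.volume_io import SUBREGION_NAMES, derive_gray_matter
from hippoflat import thickness as th, unfolding as uf

OUT = Path(__file__).resolve().parent.parent / "results"
ISO = (0.4, 0.4, 0.4)
SEED = 1


def measure(vol, convention):
    gm = derive_gray_matter(vol)
    la = grow_layers(gm, vol.wm_mask())
    fm = uf.unfold(gm, la, vol.spacing_mm, n_landmarks=300,
                   pixel_size_mm=min(vol.spacing_mm), seed=SEED)
    dist = th.distance_to_nongray(gm, vol.spacing_mm)
    per_pixel = th.flatmap_thickness(fm, dist, convention)
    labels2d = uf.project_subregion_labels(vol.labels, fm)
    return th.subregion_mean_thickness(per_pixel, labels2d, convention), fm


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    cases = [("flat_slab", t, (24, 40, 40)) for t in (1.5, 2.0, 2.75, 3.5, 4.0)]
    cases += [("cylindrical_shell", t, (52, 52, 22)) for t in (1.5, 2.0, 2.75, 3.5, 4.0)]
    for shape, t_true, grid in cases:
        spec = PhantomSpec(shape, t_true, ISO, grid, 2, 0.0, SEED)
        vol, gt = generate_phantom(spec)
        truth = float(np.unique(gt[gt > 0])[0])
        for conv in ("boundary_corrected", "literal"):
            res, fm = measure(vol, conv)
            for name in ("CA23DG", "CA1"):
                rows.append({
                    "shape": shape, "nominal_mm": t_true, "truth_mm": truth,
                    "band": name, "convention": conv,
                    "measured_mm": round(res.subregion_mean_mm[name], 3),
                    "error_mm": round(res.subregion_mean_mm[name] - truth, 3),
                    "stress1": round(fm.stress1, 4),
                })
    # graded folded C: all seven bands in one phantom
    truth7 = [1.6, 2.0, 2.4, 2.8, 3.2, 3.6, 4.0]
    vol, _ = generate_phantom(
        PhantomSpec("folded_c_sheet", truth7, ISO, (48, 48, 30), 7, 0.0, SEED))
    res, fm = measure(vol, "boundary_corrected")
    for name, t in zip(SUBREGION_NAMES, truth7):
        rows.append({
            "shape": "folded_c_sheet", "nominal_mm": t, "truth_mm": t,
            "band": name, "convention": "boundary_corrected",
            "measured_mm": round(res.subregion_mean_mm[name], 3),
            "error_mm": round(res.subregion_mean_mm[name] - t, 3),
            "stress1": round(fm.stress1, 4),
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "phantom_recovery.csv", index=False)
    bc = df[df.convention == "boundary_corrected"]
    print(df.to_string(index=False))
    print(f"\nworst boundary-corrected error: {bc['error_mm'].abs().max():.3f} mm "
          f"(tolerance: one voxel spacing = 0.4 mm)")


if __name__ == "__main__":
    main()
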