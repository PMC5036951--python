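import numpy as np
import pytest

from hippoflat.layering import grow_layers
from hippoflat.synthetic import CohortSpec, PhantomSpec, generate_phantom
from hippoflat.volume_io import derive_gray_matter
from hippoflat import thickness as th, unfolding as uf

ISO = (0.4, 0.4, 0.4)


@pytest.fixture(scope="session")
def slab_phantom():
    """Uniform 2 mm slab, isotropic 0.4 mm grid, 3 bands."""
    spec = PhantomSpec("flat_slab", 2.0, ISO, (24, 40, 40), 3, 0.0, 1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def c_sheet_phantom():
    """Uniform 2 mm folded C-sheet with all 7 subregion bands."""
    spec = PhantomSpec("folded_c_sheet", 2.0, ISO, (48, 48, 30), 7, 0.0, 1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_cohort():
    from hippoflat.synthetic import generate_cohort_table

    return generate_cohort_table(CohortSpec(seed=11))


def measure_phantom(vol, convention="boundary_corrected", pixel_size=0.4,
                    n_landmarks=300, seed=0, capture=2):
    """Full measurement chain phantom -> per-subregion thickness."""
    gm = derive_gray_matter(vol)
    la = grow_layers(gm, vol.wm_mask())
    fm = uf.unfold(gm, la, vol.spacing_mm, n_landmarks=n_landmarks,
                   pixel_size_mm=pixel_size, seed=seed)
    dist = th.distance_to_nongray(gm, vol.spacing_mm)
    per_pixel = th.flatmap_thickness(fm, dist, convention, capture_radius_px=capture)
    labels2d = uf.project_subregion_labels(vol.labels, fm)
    return th.subregion_mean_thickness(per_pixel, labels2d, convention), fm
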