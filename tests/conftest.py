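import numpy as np
import pytest

from cmr_remodel.geometry import SliceContours
from cmr_remodel.phantom import PhantomParams, LesionSpec, generate_subject


def make_annulus_contours(grid=96, endo_r=20.0, epi_r=30.0, spacing=1.0,
                          level="mid", thickness=8.0,
                          endo_center=None) -> SliceContours:
    """Concentric (or eccentric) annulus with insertion points on the
    epicardial rim at math angles 135 (anterior) and 255 (inferior) deg."""
    c = (grid - 1) / 2.0
    ii, jj = np.indices((grid, grid))
    ec = endo_center or (c, c)
    r_endo = np.hypot(ii - ec[0], jj - ec[1]) * spacing
    r_epi = np.hypot(ii - c, jj - c) * spacing
    endo = r_endo < endo_r
    epi = (r_epi < epi_r) | endo
    def pt(theta_deg, r_mm):
        th = np.radians(theta_deg)
        return (c - r_mm / spacing * np.sin(th),
                c + r_mm / spacing * np.cos(th))
    return SliceContours(endo, epi, level, spacing, thickness,
                         rv_insertion_anterior=pt(135.0, epi_r),
                         rv_insertion_inferior=pt(255.0, epi_r))


@pytest.fixture(scope="session")
def noise_free_subject():
    """Rendered noise-free phantom with two septal lesions."""
    params = PhantomParams(
        noise_sd=0.0, seed=11,
        lesion_spec=[LesionSpec(1, 250.0, 40.0, 0.5),
                     LesionSpec(4, 260.0, 30.0, 0.6)])
    return generate_subject(params)


@pytest.fixture(scope="session")
def clean_subject_no_lesions():
    params = PhantomParams(noise_sd=0.0, seed=12)
    return generate_subject(params)
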