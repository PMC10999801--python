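"""Shared fixtures: one small synthetic biopsy and a trained segmenter.

Session-scoped so the expensive pieces (rendering, random-forest training)
happen once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import ielquant as iq
from ielquant.synthetic import get_render_profile


@pytest.fixture(scope="session")
def small_params() -> iq.GenerationParams:
    return iq.GenerationParams(
        image_height_px=256, image_width_px=384, n_crypts=2, seed=42,
        surface_iel_rate=8.0, crypt_iel_rate=8.0, lp_cd3_density=400.0,
    )


@pytest.fixture(scope="session")
def ground_truth(small_params) -> iq.GroundTruth:
    return iq.generate_biopsy(small_params)


@pytest.fixture(scope="session")
def cd3_image(ground_truth) -> iq.CalibratedImage:
    return iq.render(ground_truth, "ihc_cd3")


@pytest.fixture(scope="session")
def cd3_concentrations(cd3_image) -> np.ndarray:
    profile = get_render_profile("ihc_cd3").stain_profile
    return iq.unmix(iq.rgb_to_od(cd3_image), profile)


@pytest.fixture(scope="session")
def trained_model() -> iq.SegmentationModel:
    from ielquant.experiments import train_reference_model

    return train_reference_model(seed=1, n_images=4, width=512, height=256)
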