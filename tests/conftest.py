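import numpy as np
import pytest

from wmhtex.masking import MaskSet
from wmhtex.synthetic import CohortConfig, PhantomSpec, generate_clinical_cohort, synthesize_phantom
from wmhtex.volume import VolumeImage


@pytest.fixture(scope="session")
def small_phantom():
    """One small phantom (48x48x12 at 1x1x6 mm) with ~3 mL of lesions."""
    spec = PhantomSpec(
        shape=(48, 48, 12),
        brain_halfaxes_mm=(21.0, 19.0, 30.0),
        ventricle_halfaxes_mm=(4.0, 8.0, 10.0),
        ventricle_offset_mm=5.0,
    )
    cfg = CohortConfig(n_subjects=1, seed=42)
    row = generate_clinical_cohort(cfg).iloc[0]
    img, masks = synthesize_phantom(row, 3.0, spec, cfg, seed=7)
    return img, MaskSet(masks["brain"], masks["ventricles"], masks["wmh"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_discretized(rng, max_shape=(8, 8, 3), max_levels=5, p_mask=0.75):
    """Random small discretized volume (levels 0..max_levels, 0 = background)."""
    from wmhtex.radiomics.preprocess import DiscretizedImage

    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    ng = int(rng.integers(1, max_levels + 1))
    lev = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    lev[rng.random(shape) > p_mask] = 0
    if not (lev > 0).any():
        lev[0, 0, 0] = 1
    d = DiscretizedImage(lev, lev > 0, int(lev.max()), 1.0)
    return d


@pytest.fixture
def solid_block_masks():
    """Brain = solid 20x20x3 block, no ventricles, no lesions."""
    brain = np.zeros((26, 26, 3), dtype=bool)
    brain[3:23, 3:23, :] = True
    z = np.zeros_like(brain)
    return MaskSet(
        VolumeImage(brain, (1, 1, 6)), VolumeImage(z, (1, 1, 6)), VolumeImage(z, (1, 1, 6))
    )
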