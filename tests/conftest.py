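import numpy as np
import pytest
from scipy import ndimage

from nashmri.clustering import DCNConfig, extract_patches, train_dcn
from nashmri.cohort import CohortConfig, generate_cohort
from nashmri.segmentation import SegmenterSpec, train_segmenter


@pytest.fixture(scope="session")
def small_cohort():
    """12 noisy subjects at defaults; shared read-only across tests."""
    return generate_cohort(CohortConfig(n_subjects=12, rng_seed=42))


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return generate_cohort(CohortConfig(n_subjects=3, rng_seed=7, noise_sd=0.0))


@pytest.fixture(scope="session")
def tiny_dcn(small_cohort):
    """Quickly trained k=10 model; adequate wherever cluster quality is
    irrelevant (shapes, normalization, determinism of use)."""
    stream = np.random.default_rng(0)
    patches = extract_patches(small_cohort, "t1_hbp", 200, stream=stream)
    cfg = DCNConfig(k=10, pretrain_epochs=2, joint_epochs=1, seed=0)
    return train_dcn(patches, k=10, config=cfg)


@pytest.fixture(scope="session")
def trained_unet(zero_noise_cohort):
    cohort = generate_cohort(CohortConfig(n_subjects=8, rng_seed=4))
    studies = [s for _, s in cohort]
    return studies, train_segmenter(studies, SegmenterSpec(rng_seed=0))


def texture_family_patches(rng, kinds=(0, 1, 2), n_per=300, patch_size=16):
    """Three visually distinct texture families: fine grain, coarse blobs,
    horizontal streaks; unit-variance, zero-mean patches."""
    patches, labels = [], []
    big = patch_size + 16
    for kind in kinds:
        for _ in range(n_per):
            if kind == 0:
                f = rng.standard_normal((patch_size, patch_size))
            elif kind == 1:
                f = ndimage.gaussian_filter(rng.standard_normal((big, big)), 2.5)
                f = f[8 : 8 + patch_size, 8 : 8 + patch_size]
            else:
                f = ndimage.gaussian_filter(rng.standard_normal((big, big)), (0.5, 4.0))
                f = f[8 : 8 + patch_size, 8 : 8 + patch_size]
            patches.append((f - f.mean()) / f.std())
            labels.append(kind)
    order = rng.permutation(len(patches))
    return np.stack(patches)[order], np.asarray(labels)[order]
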