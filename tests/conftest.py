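import numpy as np
import pytest

from retica import (gen_sparse_gabor_images, gen_ica_patches, extract_patches,
                    whiten, PatchDataset)


@pytest.fixture(scope="session")
def sparse_images():
    """Small naturalistic ensemble shared across tests."""
    return gen_sparse_gabor_images(n_images=40, size=64, density=30,
                                   fs=25.0, seed=101)


@pytest.fixture(scope="session")
def gaussian_images():
    """Pure 1/f background control (no oriented structure)."""
    return gen_sparse_gabor_images(n_images=40, size=64, density=0,
                                   fs=25.0, seed=102)


@pytest.fixture(scope="session")
def ica_problem():
    """Laplacian-source ICA ground truth plus its whitening."""
    X, A = gen_ica_patches(16, 20000, seed=7)
    Z, wm = whiten(PatchDataset(X, 4, 1.0), 16)
    return X, A, Z, wm


@pytest.fixture(scope="session")
def whitened_patches(sparse_images):
    """Whitened 16x16 patches on a 36-dim (6x6 torus) retained subspace."""
    data = extract_patches(sparse_images, 16, 4000, seed=5)
    Z, wm = whiten(data, 36)
    return data, Z, wm
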