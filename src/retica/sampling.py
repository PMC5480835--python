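"""Scale-controlled patch extraction and PCA whitening.

The visual angle subtended by a training patch is set jointly by the patch
side N (pixels) and the assumed sampling frequency fs (cpd): angle = N/fs.
Coarser scales are reached by antialiased undersampling (which halves fs per
factor-of-two decimation), so that the same pixel count covers a larger
piece of the visual field.  Patches are DC-removed per patch and whitened by
PCA before training; the whitening transform is exposed as an sklearn-style
transformer so it composes with pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import ImageEnsemble


@dataclass
class PatchDataset:
    """T patches of side N flattened row-major, with scale metadata."""

    X: np.ndarray            # (T, N*N)
    N: int
    fs: float
    offsets: np.ndarray | None = None   # (T, 3): image index, row, col

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[1] != self.N ** 2:
            raise ValueError("X columns must equal N^2")

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def visual_angle(self) -> float:
        return self.N / self.fs

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X)
            if self.offsets is not None:
                f.create_dataset("offsets", data=self.offsets)
            f.attrs["N"] = self.N
            f.attrs["fs"] = self.fs

    @classmethod
    def from_hdf5(cls, path) -> "PatchDataset":
        import h5py
        with h5py.File(path, "r") as f:
            off = f["offsets"][...] if "offsets" in f else None
            return cls(f["X"][...], int(f.attrs["N"]), float(f.attrs["fs"]), off)


@dataclass
class WhiteningModel:
    """PCA whitening map: mean, leading eigvecs and eigvals of the data."""

    mean: np.ndarray        # (d,)
    eigvecs: np.ndarray     # (d, d_r)
    eigvals: np.ndarray     # (d_r,) strictly positive, descending
    d_r: int

    def whiten(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.eigvecs / np.sqrt(self.eigvals)

    def dewhiten(self, Z: np.ndarray) -> np.ndarray:
        return Z * np.sqrt(self.eigvals) @ self.eigvecs.T + self.mean

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("mean", data=self.mean)
            f.create_dataset("eigvecs", data=self.eigvecs)
            f.create_dataset("eigvals", data=self.eigvals)
            f.attrs["d_r"] = self.d_r

    @classmethod
    def from_hdf5(cls, path) -> "WhiteningModel":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(f["mean"][...], f["eigvecs"][...], f["eigvals"][...],
                       int(f.attrs["d_r"]))


def default_retained_dim(d: int, fraction: float = 0.4) -> int:
    """Largest perfect square not exceeding ``fraction * d``.

    A square retained dimension lets the pooled topology be a square torus
    (e.g. d = 1024 -> 400 -> a 20 x 20 grid).
    """
    m = int(np.floor(fraction * d))
    return int(np.floor(np.sqrt(m))) ** 2


def undersample(ensemble: ImageEnsemble, factor: int) -> ImageEnsemble:
    """Antialiased decimation by an integer factor; fs drops by the factor.

    A separable windowed-sinc FIR with cutoff at 0.9x the new Nyquist is
    applied along both axes (circular boundary, so the pass/stop band is
    exact in the DFT sense) before keeping every ``factor``-th sample.
    """
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise ValueError("factor must be an integer >= 1")
    h, w = ensemble.shape
    if h % factor or w % factor:
        raise ValueError(f"factor {factor} must divide image dims {h}x{w}")
    if factor == 1:
        return ImageEnsemble(ensemble.images.copy(), ensemble.fs,
                             ensemble.provenance)
    numtaps = 33 * factor + (1 - (33 * factor) % 2)   # odd, ~33 taps/factor
    kernel = signal.firwin(numtaps, cutoff=0.9 / factor)  # Nyquist = 1
    out = np.empty((ensemble.n_images, h // factor, w // factor))
    for k, im in enumerate(ensemble.images):
        lp = ndimage.convolve1d(im, kernel, axis=0, mode="wrap")
        lp = ndimage.convolve1d(lp, kernel, axis=1, mode="wrap")
        out[k] = lp[::factor, ::factor]
    return ImageEnsemble(out, ensemble.fs / factor, ensemble.provenance)


def extract_patches(ensemble: ImageEnsemble, N: int, T: int,
                    seed=None) -> PatchDataset:
    """T random N x N patches, DC-removed, offsets logged.

    Source image and top-left offset are drawn uniformly (with replacement
    across images); each patch has its own mean subtracted so the DC
    component never reaches PCA.
    """
    h, w = ensemble.shape
    if N > min(h, w):
        raise ValueError(f"patch side {N} exceeds image dims {h}x{w}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ensemble.n_images, T)
    rows = rng.integers(0, h - N + 1, T)
    cols = rng.integers(0, w - N + 1, T)
    X = np.empty((T, N * N))
    for t in range(T):
        patch = ensemble.images[idx[t], rows[t]:rows[t] + N, cols[t]:cols[t] + N]
        X[t] = patch.ravel()
    X -= X.mean(axis=1, keepdims=True)
    offsets = np.column_stack([idx, rows, cols])
    return PatchDataset(X, N, ensemble.fs, offsets)


class PCAWhitener(BaseEstimator, TransformerMixin):
    """PCA whitening transformer with a configurable retained dimension.

    Parameters
    ----------
    d_r : int or None
        Retained dimension.  ``None`` uses the largest perfect square not
        exceeding ``fraction * d`` so downstream topologies are square tori.
    fraction : float
        Retention fraction used when ``d_r`` is None.

    Attributes (after fit)
    ----------------------
    mean_, eigvecs_, eigvals_ : the whitening map; eigvals strictly
        positive and descending.  Transformed training data has identity
        covariance (1/T normalization) on the retained components.
    """

    def __init__(self, d_r: int | None = None, fraction: float = 0.4):
        self.d_r = d_r
        self.fraction = fraction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        T, d = X.shape
        d_r = self.d_r if self.d_r is not None else default_retained_dim(d, self.fraction)
        if not 2 <= d_r <= d:
            raise ValueError("need 2 <= d_r <= d")
        if T <= d_r:
            raise ValueError("need more samples than retained dimensions")
        mean = X.mean(axis=0)
        _, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
        eigvals = s ** 2 / T
        rank = int(np.sum(eigvals > eigvals[0] * 1e-12))
        if rank < d_r:
            raise ValueError(
                f"data rank {rank} below requested dimension {d_r}")
        self.mean_ = mean
        self.eigvecs_ = Vt[:d_r].T
        self.eigvals_ = eigvals[:d_r]
        self.n_features_in_ = d
        self.d_r_ = d_r
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.eigvecs_ / np.sqrt(self.eigvals_)

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        return Z * np.sqrt(self.eigvals_) @ self.eigvecs_.T + self.mean_

    @property
    def model_(self) -> WhiteningModel:
        return WhiteningModel(self.mean_, self.eigvecs_, self.eigvals_, self.d_r_)


def whiten(data: PatchDataset, d_r: int | None = None
           ) -> tuple[np.ndarray, WhiteningModel]:
    """Whiten a patch dataset; returns (Z, whitening model)."""
    w = PCAWhitener(d_r=d_r).fit(data.X)
    return w.transform(data.X), w.model_
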