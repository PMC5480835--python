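"""Synthetic inputs for every pipeline stage.

Four generators, all pure functions of their arguments including the seed:

* naturalistic images — sparse superpositions of oriented Gabor
  micro-patterns over a weak 1/f background.  Linear ICA is degenerate on
  Gaussian inputs, so the higher-order (super-Gaussian) structure injected
  by the sparse occurrences is what lets the model learn oriented,
  localized filters;
* ground-truth ICA data — unit-variance Laplacian sources through a random
  well-conditioned mixing, the recovery oracle for the trainer;
* planted unit ensembles — oriented units whose orientations either form
  locally continuous iso-orientation domains (the standard pinwheel-map
  construction: half the argument of a bandpass-filtered complex Gaussian
  field) or are salt-and-pepper (i.i.d. uniform), the positive and negative
  controls for the retinal-space analysis;
* reference 2-D point sets — uniform, Cartesian, or Neyman-Scott clustered,
  for calibrating the uniformity test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gabor import GaborFit, UnitAtlas
from .maps import PointSet
from .uniformity import cartesian_grid


@dataclass
class ImageEnsemble:
    """A stack of same-size grayscale images with a sampling frequency.

    ``fs`` is the assumed sampling frequency in samples per degree of visual
    angle (cpd), so an N-pixel patch cut from these images subtends N/fs
    degrees.
    """

    images: np.ndarray  # (n, H, W) luminance, arbitrary linear units
    fs: float
    provenance: str = "synthetic"

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, H, W) stack")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("images contain non-finite values")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images)
            f.attrs["fs"] = self.fs
            f.attrs["provenance"] = self.provenance

    @classmethod
    def from_hdf5(cls, path) -> "ImageEnsemble":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(f["images"][...], float(f.attrs["fs"]),
                       str(f.attrs.get("provenance", "file")))

    def to_png_dir(self, outdir) -> list[Path]:
        """Write the stack as 16-bit PNGs (each image scaled to full range)."""
        import imageio.v3 as iio
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for k, im in enumerate(self.images):
            lo, hi = im.min(), im.max()
            scaled = np.zeros_like(im) if hi == lo else (im - lo) / (hi - lo)
            p = outdir / f"img_{k:05d}.png"
            iio.imwrite(p, (scaled * 65535).astype(np.uint16))
            paths.append(p)
        return paths


def load_image_dir(path, fs: float) -> ImageEnsemble:
    """Adapter: read a directory of grayscale PNG/TIFF/PGM images."""
    import imageio.v3 as iio
    files = sorted(p for p in Path(path).iterdir()
                   if p.suffix.lower() in {".png", ".tif", ".tiff", ".pgm"})
    if not files:
        raise FileNotFoundError(f"no images found in {path}")
    imgs = [np.asarray(iio.imread(p), dtype=float) for p in files]
    imgs = [im.mean(axis=-1) if im.ndim == 3 else im for im in imgs]
    return ImageEnsemble(np.stack(imgs), fs, provenance="file")


@dataclass
class PlantedMapSpec:
    """Ground-truth oriented-unit ensemble: domains or salt-and-pepper.

    ``map_scale`` is the correlation length (degrees) of the orientation
    field for ``map_kind='domains'``; ``jitter`` is the SD (degrees) of the
    center-placement noise around the underlying grid.
    """

    map_kind: str            # 'domains' | 'salt_pepper'
    n_units: int = 400
    domain: float = 1.0
    map_scale: float = 0.3
    jitter: float = 0.02
    seed: int | None = 0

    def __post_init__(self):
        if self.map_kind not in ("domains", "salt_pepper"):
            raise ValueError(f"unknown map_kind {self.map_kind!r}")
        if self.n_units < 1:
            raise ValueError("need n_units >= 1")
        if self.map_kind == "domains" and not self.map_scale > 0:
            raise ValueError("map_scale must be > 0 for domains")


def _one_over_f_background(size: int, rng: np.random.Generator,
                           amplitude: float = 0.15) -> np.ndarray:
    white = rng.standard_normal((size, size))
    F = np.fft.fft2(white)
    fr = np.fft.fftfreq(size)
    fx, fy = np.meshgrid(fr, fr)
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0
    im = np.real(np.fft.ifft2(F / radius))
    im[...] -= im.mean()
    s = im.std()
    return im * (amplitude / s) if s > 0 else im


def gen_sparse_gabor_images(n_images: int, size: int = 64, density: int = 40,
                            f_range: tuple[float, float] | None = None,
                            fs: float = 25.0, seed=None) -> ImageEnsemble:
    """Naturalistic ensemble: sparse oriented Gabor occurrences plus 1/f.

    Each image is a sum of ``density`` randomly placed, oriented, phased
    Gabor micro-patterns with Laplacian (heavy-tailed) amplitudes over a
    low-amplitude 1/f background.  ``density=0`` yields the pure-background
    (approximately Gaussian) control ensemble.
    """
    if size < 16:
        raise ValueError("need size >= 16")
    if density < 0:
        raise ValueError("density must be >= 0")
    nyq = fs / 2.0
    if f_range is None:
        f_range = (fs / 16.0, 0.8 * nyq)
    if not (0.0 < f_range[0] <= f_range[1] < nyq):
        raise ValueError(
            f"f_range {f_range} must lie within (0, Nyquist={nyq} cpd)")
    rng = np.random.default_rng(seed)
    cols = np.arange(size)
    xg, yg = np.meshgrid(cols, cols)
    images = np.empty((n_images, size, size))
    for k in range(n_images):
        im = _one_over_f_background(size, rng)
        for _ in range(density):
            cx, cy = rng.uniform(0, size, 2)
            theta = rng.uniform(0, np.pi)
            f_cpd = rng.uniform(*f_range)
            f_px = f_cpd / fs                       # cycles per pixel
            lam = 1.0 / f_px
            sigma = lam * rng.uniform(0.3, 0.6)
            phi = rng.uniform(0, 2 * np.pi)
            amp = rng.laplace(0.0, 1.0)
            psi = theta + np.pi / 2.0               # carrier direction
            u = (xg - cx) * np.cos(psi) + (yg - cy) * np.sin(psi)
            v = -(xg - cx) * np.sin(psi) + (yg - cy) * np.cos(psi)
            im += amp * np.exp(-(u ** 2 + v ** 2) / (2 * sigma ** 2)) \
                * np.cos(2 * np.pi * f_px * u + phi)
        images[k] = im
    return ImageEnsemble(images, fs, provenance="synthetic")


def gen_ica_patches(d_r: int, T: int, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Laplacian-source ICA ground truth: (data T x d_r, mixing d_r x d_r).

    Sources are independent unit-variance Laplacian (excess kurtosis 3,
    which makes the sparsity check exact); the mixing matrix is random with
    singular values in [1, 2], hence well conditioned.
    """
    if d_r < 2:
        raise ValueError("need d_r >= 2")
    if T < 10 * d_r:
        raise ValueError("need T >= 10 * d_r")
    rng = np.random.default_rng(seed)
    sources = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(T, d_r))
    q1, _ = np.linalg.qr(rng.standard_normal((d_r, d_r)))
    q2, _ = np.linalg.qr(rng.standard_normal((d_r, d_r)))
    mixing = q1 @ np.diag(rng.uniform(1.0, 2.0, d_r)) @ q2
    return sources @ mixing.T, mixing


def _orientation_field(spec: PlantedMapSpec, rng: np.random.Generator,
                       grid: int = 128) -> np.ndarray:
    """Pinwheel orientation field on a grid covering the domain (degrees)."""
    if not np.isfinite(spec.map_scale):
        return np.full((grid, grid), rng.uniform(0.0, 180.0))
    z = rng.standard_normal((grid, grid)) + 1j * rng.standard_normal((grid, grid))
    fr = np.fft.fftfreq(grid, d=spec.domain / grid)   # cycles per degree
    fx, fy = np.meshgrid(fr, fr)
    radius = np.hypot(fx, fy)
    k0 = 1.0 / spec.map_scale
    bp = np.exp(-((radius - k0) ** 2) / (2.0 * (0.25 * k0) ** 2))
    field = np.fft.ifft2(np.fft.fft2(z) * bp)
    return (np.degrees(np.angle(field)) / 2.0) % 180.0


def gen_unit_ensemble(spec: PlantedMapSpec) -> UnitAtlas:
    """Planted ensemble of oriented units with known spatial organization.

    Centers sit on a jittered grid covering the domain.  For
    ``map_kind='domains'`` orientation is sampled from a locally continuous
    pinwheel field with correlation length ``map_scale``; for
    ``'salt_pepper'`` orientations are i.i.d. uniform on [0, 180).  The
    result is packaged as a synthetic :class:`UnitAtlas` so it flows through
    the same partition/test machinery as fitted models.
    """
    rng = np.random.default_rng(spec.seed)
    g = int(np.ceil(np.sqrt(spec.n_units)))
    cells = rng.permutation(g * g)[: spec.n_units]
    rows, colz = cells // g, cells % g
    spacing = spec.domain / g
    x = (colz + 0.5) * spacing + rng.normal(0.0, spec.jitter, spec.n_units)
    y = (rows + 0.5) * spacing + rng.normal(0.0, spec.jitter, spec.n_units)
    # reflect jittered centers back into the domain
    x = np.abs(x) % (2 * spec.domain)
    x = np.where(x > spec.domain, 2 * spec.domain - x, x)
    y = np.abs(y) % (2 * spec.domain)
    y = np.where(y > spec.domain, 2 * spec.domain - y, y)

    if spec.map_kind == "salt_pepper":
        thetas = rng.uniform(0.0, 180.0, spec.n_units)
    else:
        field_grid = 128
        field = _orientation_field(spec, rng, field_grid)
        ix = np.minimum((x / spec.domain * field_grid).astype(int), field_grid - 1)
        iy = np.minimum((y / spec.domain * field_grid).astype(int), field_grid - 1)
        thetas = field[iy, ix]

    N = 32
    fs = N / spec.domain
    f_mid = fs / 8.0
    units = []
    for k in range(spec.n_units):
        gf = GaborFit(float(x[k]), float(y[k]), f_mid, float(thetas[k]),
                      0.0, 0.1 * spec.domain, 0.1 * spec.domain, 1.0, nmae=0.0)
        units.append(((k // g, k % g), gf))
    return UnitAtlas(units, fs, N, mae_threshold=0.125,
                     all_fits=list(units), excluded_fraction=0.0)


def gen_point_set(kind: str, M: int, domain: float = 1.0,
                  params: dict | None = None, seed=None) -> PointSet:
    """Reference point sets for the uniformity test.

    ``uniform`` draws M i.i.d. points on the square; ``cartesian`` returns
    the S_cart grid; ``clustered`` is a Neyman-Scott process (Poisson-like
    parents, Gaussian-offset offspring) truncated to M in-domain points.
    Defaults: about M/10 parents and offspring SD domain/20.
    """
    if M < 4:
        raise ValueError("need M >= 4")
    params = params or {}
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        return PointSet(rng.uniform(0.0, domain, (M, 2)), domain, label="S_rand")
    if kind == "cartesian":
        ps, _, _ = cartesian_grid(M, domain)
        return ps
    if kind == "clustered":
        n_parents = int(params.get("n_parents", max(1, round(M / 10))))
        sigma = float(params.get("sigma", domain / 20.0))
        parents = rng.uniform(0.0, domain, (n_parents, 2))
        pts = np.empty((0, 2))
        while pts.shape[0] < M:
            idx = rng.integers(0, n_parents, 4 * M)
            cand = parents[idx] + rng.normal(0.0, sigma, (4 * M, 2))
            ok = np.all((cand >= 0.0) & (cand <= domain), axis=1)
            pts = np.vstack([pts, cand[ok]])
        return PointSet(pts[:M], domain, label="S_clustered")
    raise ValueError(f"unknown point-set kind {kind!r}")
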