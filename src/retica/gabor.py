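"""Gabor characterization of learned receptive fields.

Each unit of a fitted topographic ICA model is summarized by a 2-D Gabor
function — an oriented sinusoidal carrier under an elliptical Gaussian
envelope — fitted by nonlinear least squares.  The fitted center (in degrees
of visual angle), carrier frequency (cycles/degree) and stripe orientation
are the bridge from the model's abstract topology back to retinal space.

Conventions used repo-wide
--------------------------
* Pixel centers sit at ``(k + 0.5) / fs`` degrees; the origin is the patch's
  lower-left corner, and row index ``iy`` of a receptive-field array
  increases with ``y``.
* ``theta`` is the orientation of the stripes, measured counterclockwise
  from the positive x-axis and reduced modulo 180 degrees.  The carrier wave
  vector points along ``theta + 90``.
* Fit quality is the mean absolute error between the unit and its rendered
  Gabor, normalized by the unit's value range ("normalized MAE", in [0, 1]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class DegenerateUnitError(ValueError):
    """Raised when a receptive field is constant and cannot be fitted."""


@dataclass
class GaborFit:
    """Parameters of a fitted 2-D Gabor, in degrees / cycles-per-degree.

    ``theta`` is the stripe orientation in [0, 180); ``phi`` the carrier
    phase in [0, 360); ``sigma_x`` is the envelope SD along the carrier
    direction and ``sigma_y`` across it.  ``nmae`` is the normalized mean
    absolute error of the fit; a sentinel value of 1.0 with
    ``converged=False`` marks an optimizer failure.
    """

    x0: float
    y0: float
    f: float
    theta: float
    phi: float
    sigma_x: float
    sigma_y: float
    amplitude: float
    nmae: float = 0.0
    converged: bool = True


@dataclass
class UnitAtlas:
    """Retained units of a model: topology index plus fitted Gabor.

    ``units`` holds ``((i, j), GaborFit)`` for every unit that passed the
    quality filter (``nmae <= mae_threshold`` and fitted center inside the
    patch extent ``[0, N/fs]^2``); ``all_fits`` keeps every fit for
    diagnostics.  ``excluded_fraction`` is the fraction of units dropped.
    """

    units: list[tuple[tuple[int, int], GaborFit]]
    fs: float
    N: int
    mae_threshold: float = 0.125
    all_fits: list[tuple[tuple[int, int], GaborFit]] = field(default_factory=list)
    excluded_fraction: float = 0.0

    @property
    def visual_angle(self) -> float:
        return self.N / self.fs

    def __len__(self) -> int:
        return len(self.units)

    def centers(self) -> np.ndarray:
        """(M, 2) array of retained unit centers in degrees."""
        return np.array([[g.x0, g.y0] for _, g in self.units]).reshape(-1, 2)

    def orientations(self) -> np.ndarray:
        return np.array([g.theta for _, g in self.units])

    def to_frame(self) -> pd.DataFrame:
        kept = {(i, j) for (i, j), _ in self.units}
        rows = []
        for (i, j), g in (self.all_fits or self.units):
            rows.append(
                dict(topo_i=i, topo_j=j, x0_deg=g.x0, y0_deg=g.y0, f_cpd=g.f,
                     theta_deg=g.theta, phi_deg=g.phi, sigma_x_deg=g.sigma_x,
                     sigma_y_deg=g.sigma_y, amplitude=g.amplitude,
                     nmae=g.nmae, kept=(i, j) in kept))
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float, N: int, mae_threshold: float = 0.125) -> "UnitAtlas":
        df = pd.read_csv(path)
        all_fits, units = [], []
        for _, r in df.iterrows():
            g = GaborFit(r.x0_deg, r.y0_deg, r.f_cpd, r.theta_deg, r.phi_deg,
                         r.sigma_x_deg, r.sigma_y_deg, r.amplitude, r.nmae)
            all_fits.append(((int(r.topo_i), int(r.topo_j)), g))
            if bool(r.kept):
                units.append(all_fits[-1])
        excl = 1.0 - len(units) / max(len(all_fits), 1)
        return cls(units, fs, N, mae_threshold, all_fits, excl)


def pixel_grid(N: int, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate arrays (x, y) in degrees for an N x N patch."""
    coords = (np.arange(N) + 0.5) / fs
    x, y = np.meshgrid(coords, coords)  # row index <-> y
    return x, y


def render_gabor(g: GaborFit, N: int, fs: float) -> np.ndarray:
    """Evaluate the Gabor on the patch's pixel grid."""
    x, y = pixel_grid(N, fs)
    return _gabor_eval(
        [g.x0, g.y0, g.f, math.radians(g.theta + 90.0), math.radians(g.phi),
         g.sigma_x, g.sigma_y, g.amplitude], x, y)


def _gabor_eval(p: Sequence[float], x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x0, y0, f, psi, phi, sx, sy, a = p
    dx, dy = x - x0, y - y0
    u = dx * math.cos(psi) + dy * math.sin(psi)
    v = -dx * math.sin(psi) + dy * math.cos(psi)
    env = np.exp(-(u ** 2 / (2.0 * sx ** 2) + v ** 2 / (2.0 * sy ** 2)))
    return a * env * np.cos(2.0 * math.pi * f * u + phi)


def normalized_mae(rf: np.ndarray, gabor, fs: float | None = None) -> float:
    """Mean |rf - g| over pixels divided by the range max(rf) - min(rf).

    ``gabor`` may be a rendered array of the same shape or a :class:`GaborFit`
    (then ``fs`` is required to render it on rf's grid).
    """
    rf = np.asarray(rf, dtype=float)
    rng = float(np.max(rf) - np.min(rf))
    if rng == 0.0:
        raise DegenerateUnitError("receptive field has zero range")
    if isinstance(gabor, GaborFit):
        if fs is None:
            raise ValueError("fs required to render a GaborFit")
        gabor = render_gabor(gabor, rf.shape[0], fs)
    return float(np.mean(np.abs(rf - np.asarray(gabor, dtype=float))) / rng)


def _fft_init(rf: np.ndarray, fs: float) -> tuple[float, float]:
    """Carrier (frequency cpd, direction rad) from the spectral peak."""
    N = rf.shape[0]
    F = np.fft.fft2(rf)
    fr = np.fft.fftfreq(N, d=1.0 / fs)
    fx, fy = np.meshgrid(fr, fr)
    mag = np.abs(F)
    # keep one half-plane (spectrum is conjugate-symmetric); kill DC
    mag[(fy < 0) | ((fy == 0) & (fx <= 0))] = 0.0
    iy, ix = np.unravel_index(np.argmax(mag), mag.shape)
    f0 = float(np.hypot(fx[iy, ix], fy[iy, ix]))
    psi0 = float(math.atan2(fy[iy, ix], fx[iy, ix]))
    return f0, psi0


def _canonicalize(p: np.ndarray) -> GaborFit:
    x0, y0, f, psi, phi, sx, sy, a = [float(v) for v in p]
    if a < 0:
        a, phi = -a, phi + math.pi
    psi = psi % (2.0 * math.pi)
    theta = math.degrees(psi - math.pi / 2.0) % 180.0
    # flipping the carrier direction by 180 deg conjugates the phase
    if math.degrees(psi) % 360.0 >= 90.0 + 180.0 or math.degrees(psi) % 360.0 < 90.0:
        phi = -phi
    phi = math.degrees(phi) % 360.0
    return GaborFit(x0, y0, f, theta, phi, abs(sx), abs(sy), a)


def fit_gabor(rf: np.ndarray, fs: float, n_restarts: int = 4,
              max_nfev: int = 400) -> GaborFit:
    """Fit a 2-D Gabor to a receptive field by bounded least squares.

    Initialization takes the carrier (f, direction) from the FFT peak and
    the center from the energy centroid; ``n_restarts`` phase offsets spaced
    by 90 degrees guard against the phase local minimum.  The best restart by
    normalized MAE wins, ties broken by lower carrier frequency.
    """
    rf = np.asarray(rf, dtype=float)
    if rf.ndim != 2 or rf.shape[0] != rf.shape[1]:
        raise ValueError("rf must be a square 2-D array")
    rng_rf = float(np.max(rf) - np.min(rf))
    if rng_rf == 0.0:
        raise DegenerateUnitError("constant receptive field")

    N = rf.shape[0]
    va = N / fs
    x, y = pixel_grid(N, fs)
    w = rf ** 2
    w = w / w.sum()
    x0_init = float((w * x).sum())
    y0_init = float((w * y).sum())
    var = float((w * ((x - x0_init) ** 2 + (y - y0_init) ** 2)).sum() / 2.0)
    f0, psi0 = _fft_init(rf, fs)

    f_lo, f_hi = 0.5 / va, fs / 2.0
    s_lo, s_hi = 0.25 / fs, va
    f0 = min(max(f0, f_lo), f_hi)
    s0 = min(max(math.sqrt(max(var, 1e-12)), s_lo), s_hi)
    a0 = rng_rf / 2.0

    lower = [-0.5 * va, -0.5 * va, f_lo, -np.inf, -np.inf, s_lo, s_lo, -np.inf]
    upper = [1.5 * va, 1.5 * va, f_hi, np.inf, np.inf, s_hi, s_hi, np.inf]

    def residuals(p):
        return (_gabor_eval(p, x, y) - rf).ravel()

    best: GaborFit | None = None
    for k in range(n_restarts):
        phi0 = k * math.pi / 2.0
        p0 = np.array([x0_init, y0_init, f0, psi0, phi0, s0, s0, a0])
        try:
            sol = least_squares(residuals, p0, bounds=(lower, upper),
                                max_nfev=max_nfev, method="trf")
            if not np.all(np.isfinite(sol.x)):
                continue
            cand = _canonicalize(sol.x)
            cand.nmae = normalized_mae(rf, render_gabor(cand, N, fs))
        except Exception:
            continue
        if best is None or cand.nmae < best.nmae - 1e-12 or (
                abs(cand.nmae - best.nmae) <= 1e-12 and cand.f < best.f):
            best = cand
    if best is None:
        return GaborFit(x0_init, y0_init, f0, 0.0, 0.0, s0, s0, a0,
                        nmae=1.0, converged=False)
    return best


def build_atlas(rfs: np.ndarray, topology, fs: float,
                mae_threshold: float = 0.125) -> UnitAtlas:
    """Fit every unit of a receptive-field matrix and keep the good ones.

    ``rfs`` is d x d_r with columns reshaping to N x N patches (row-major,
    row index increasing with y).  Units are retained iff their normalized
    MAE is at or below ``mae_threshold`` and the fitted center falls inside
    the patch extent [0, N/fs]^2; the excluded fraction is recorded.
    """
    rfs = np.asarray(rfs, dtype=float)
    d, d_r = rfs.shape
    N = int(round(math.sqrt(d)))
    if N * N != d:
        raise ValueError("rfs columns do not reshape to a square patch")
    n2 = getattr(topology, "n2", None) or int(round(math.sqrt(d_r)))
    va = N / fs
    all_fits, units = [], []
    for k in range(d_r):
        ij = (k // n2, k % n2)
        col = rfs[:, k].reshape(N, N)
        try:
            g = fit_gabor(col, fs)
        except DegenerateUnitError:
            g = GaborFit(0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 0.0,
                         nmae=1.0, converged=False)
        all_fits.append((ij, g))
        if g.nmae <= mae_threshold and 0.0 <= g.x0 <= va and 0.0 <= g.y0 <= va:
            units.append((ij, g))
    excl = 1.0 - len(units) / d_r
    return UnitAtlas(units, fs, N, mae_threshold, all_fits, excl)
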