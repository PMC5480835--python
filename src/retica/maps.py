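"""Retinal-space and Fourier-space projections of a unit atlas.

A patch of ``N`` pixels sampled at ``fs`` cycles/degree subtends a visual
angle of ``N / fs`` degrees; the fitted unit centers therefore live in the
square retinal domain ``[0, N/fs]^2``.  Partitioning the retained units by
preferred orientation into K equal bins of ``180/K`` degrees yields, per
bin, the point set of same-orientation unit centers that the uniformity
test consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gabor import UnitAtlas


@dataclass
class PointSet:
    """M labeled points in the square retinal domain [0, domain]^2."""

    points: np.ndarray  # (M, 2) in degrees
    domain: float
    label: str = ""
    bin_id: int | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 2:
            raise ValueError("points must be (M, 2)")
        if self.points.size and (
                self.points.min() < -1e-9 or self.points.max() > self.domain + 1e-9):
            raise ValueError("points fall outside [0, domain]^2")

    @property
    def M(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.M

    def to_csv(self, path) -> None:
        pd.DataFrame(self.points, columns=["x_deg", "y_deg"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, domain: float | None = None, label: str = "") -> "PointSet":
        df = pd.read_csv(path)
        pts = df[["x_deg", "y_deg"]].to_numpy()
        if domain is None:
            domain = float(pts.max()) if pts.size else 1.0
        return cls(pts, domain, label)


@dataclass
class OrientationPartition:
    """Exhaustive, exclusive split of units into K orientation bins."""

    K: int
    edges: np.ndarray          # K+1 edges of the (possibly offset) bins, deg
    centers: np.ndarray        # K bin centers in [0, 180), deg
    members: list[PointSet] = field(default_factory=list)
    bin_offset: float = 0.0

    @property
    def bandwidth(self) -> float:
        return 180.0 / self.K


def visual_angle(N: int, fs: float) -> float:
    """Visual angle in degrees subtended by an N-pixel patch at fs cpd."""
    if N < 1 or fs <= 0:
        raise ValueError("need N >= 1 and fs > 0")
    return N / fs


def orientation_bandwidth(K: int) -> float:
    """Width in degrees of one of K equal orientation bins on [0, 180)."""
    if K < 1:
        raise ValueError("need K >= 1")
    return 180.0 / K


def orientation_bin(theta, K: int, bin_offset: float | None = None):
    """Half-open bin index of orientation(s) ``theta`` (degrees mod 180).

    ``bin_offset=None`` centers bin b on ``b * 180/K`` (so for K=4 the last
    bin is 135 +/- 22.5 degrees); ``bin_offset=0`` anchors bin edges at 0.
    """
    if bin_offset is None:
        bin_offset = 180.0 / (2 * K)
    t = (np.asarray(theta, dtype=float) + bin_offset) % 180.0
    return np.minimum((t // (180.0 / K)).astype(int), K - 1)


def orientation_partition(atlas: UnitAtlas, K: int,
                          bin_offset: float | None = None) -> OrientationPartition:
    """Split the retained units of an atlas into K orientation bins.

    Each retained unit falls in exactly one half-open bin; the member point
    sets carry the unit centers on the retinal domain [0, N/fs]^2.
    """
    if len(atlas) == 0:
        raise ValueError("atlas has no retained units")
    if bin_offset is None:
        bin_offset = 180.0 / (2 * K)
    width = 180.0 / K
    thetas = atlas.orientations()
    centers_xy = atlas.centers()
    bins = orientation_bin(thetas, K, bin_offset)
    domain = atlas.visual_angle
    bin_centers = (np.arange(K) * width - bin_offset + width / 2.0) % 180.0
    members = []
    for b in range(K):
        pts = centers_xy[bins == b]
        members.append(PointSet(pts.reshape(-1, 2), domain,
                                label=f"S_ori_K{K}_bin{b}", bin_id=b))
    edges = np.arange(K + 1) * width - bin_offset
    return OrientationPartition(K, edges, bin_centers, members, bin_offset)


def fourier_centers(atlas: UnitAtlas) -> tuple[np.ndarray, np.ndarray]:
    """Carrier wave vectors (fx, fy) in cpd plus orientation labels.

    The wave vector points along ``theta + 90`` degrees with magnitude equal
    to the unit's carrier frequency, so every point lies within the Nyquist
    disc of radius fs/2.
    """
    if len(atlas) == 0:
        raise ValueError("atlas has no retained units")
    f = np.array([g.f for _, g in atlas.units])
    psi = np.radians(atlas.orientations() + 90.0)
    pts = np.column_stack([f * np.cos(psi), f * np.sin(psi)])
    return pts, atlas.orientations()


def render_maps(atlas: UnitAtlas, partition: OrientationPartition,
                outdir, prefix: str = "maps", topology=None) -> list[Path]:
    """Write the three diagnostic figures for one fitted model.

    (a) retinal scatter of unit centers colored by orientation bin,
    (b) Fourier scatter of carrier wave vectors, and (c) the topology grid
    colored by orientation (excluded units gray).  Returns the file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cmap = plt.get_cmap("hsv")
    colors = [cmap(b / partition.K) for b in range(partition.K)]
    paths = []

    fig, ax = plt.subplots(figsize=(5, 5))
    for b, ps in enumerate(partition.members):
        if ps.M:
            ax.scatter(ps.points[:, 0], ps.points[:, 1], s=14, color=colors[b],
                       label=f"{partition.centers[b]:.0f} deg")
    ax.set_xlim(0, atlas.visual_angle)
    ax.set_ylim(0, atlas.visual_angle)
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    ax.set_title("Unit centers in retinal space")
    ax.legend(fontsize=7)
    p = outdir / f"{prefix}_retinal.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 5))
    pts, thetas = fourier_centers(atlas)
    bins = orientation_bin(thetas, partition.K, partition.bin_offset)
    for b in range(partition.K):
        sel = bins == b
        if sel.any():
            ax.scatter(pts[sel, 0], pts[sel, 1], s=14, color=colors[b])
    lim = atlas.fs / 2.0
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("fx (cpd)")
    ax.set_ylabel("fy (cpd)")
    ax.set_title("Carrier frequencies in the Fourier domain")
    p = outdir / f"{prefix}_fourier.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    if topology is not None:
        n1, n2 = topology.n1, topology.n2
    else:
        n = int(round(np.sqrt(len(atlas.all_fits) or len(atlas))))
        n1 = n2 = n
    grid = np.full((n1, n2), np.nan)
    for (i, j), g in atlas.units:
        grid[i, j] = g.theta
    fig, ax = plt.subplots(figsize=(5, 5))
    masked = np.ma.masked_invalid(grid)
    cmap_t = plt.get_cmap("hsv").copy()
    cmap_t.set_bad("0.6")
    im = ax.imshow(masked, cmap=cmap_t, vmin=0, vmax=180, origin="lower")
    fig.colorbar(im, ax=ax, label="theta (deg)")
    ax.set_title("Orientation on the model topology")
    p = outdir / f"{prefix}_topology.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
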