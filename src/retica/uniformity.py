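"""KLD-based Monte-Carlo test of spatial uniformity for point sets.

The question asked of a set ``S_ori`` of M same-orientation unit centers is
whether it is more similar to a Cartesian grid ``S_cart`` (the least
clustered arrangement possible) than finite uniform samples ``S_rand`` are.
Similarity is the Kullback-Leibler divergence between the set's occupancy
histogram on the ``N1 x N2`` tiling of the domain and the flat histogram of
the grid, with ``N1 * N2`` the best integer approximation to M.  The null
distribution of the divergence is estimated by Monte-Carlo over i.i.d.
uniform sets of the same size, and the decision has three outcomes:

* ``more_regular_than_uniform`` — observed KLD below the 5% left tail of
  the null: the set tiles the domain more evenly than chance; clustered
  structure is firmly rejected.
* ``consistent_with_uniform`` — observed KLD inside the central 90% of the
  null: indistinguishable from a finite uniform sample, again incompatible
  with locally continuous iso-orientation domains.
* ``inconclusive_possible_structure`` — observed KLD above the 95% tail:
  the set is less uniform than chance, as clustering would produce.

The divergence is taken as D(h(S) || h(S_cart)); the reference histogram is
strictly positive so the statistic is always finite, and it vanishes only
when the set occupies every bin as evenly as the grid itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import PointSet

OUTCOME_REGULAR = "more_regular_than_uniform"
OUTCOME_UNIFORM = "consistent_with_uniform"
OUTCOME_STRUCTURE = "inconclusive_possible_structure"

_LN2 = float(np.log(2.0))


@dataclass
class HistogramGrid:
    """Bin-occupancy counts of a point set on an N1 x N2 tiling."""

    counts: np.ndarray  # (N1, N2) nonnegative ints; row index along y
    domain: float

    @property
    def N1(self) -> int:
        return self.counts.shape[0]

    @property
    def N2(self) -> int:
        return self.counts.shape[1]

    @property
    def B(self) -> int:
        return self.counts.size

    @property
    def M(self) -> int:
        return int(self.counts.sum())


@dataclass
class NullDistribution:
    sample: np.ndarray
    mu: float
    sem: float


@dataclass
class UniformityTestResult:
    """Observed KLD, Monte-Carlo null and the three-outcome decision."""

    kld_obs: float
    null_sample: np.ndarray
    p_left: float
    null_mean: float
    null_sem: float
    ci: tuple[float, float]           # mean +/- 2.576 * SEM
    outcome: str
    M: int = 0
    N1: int = 0
    N2: int = 0
    label: str = ""

    def to_dict(self) -> dict:
        return dict(label=self.label, M=self.M, N1=self.N1, N2=self.N2,
                    kld_obs=self.kld_obs, p_left=self.p_left,
                    mu=self.null_mean, sem=self.null_sem,
                    ci=list(self.ci), outcome=self.outcome)


def cartesian_grid(M: int, domain: float) -> tuple[PointSet, int, int]:
    """The S_cart reference: an N1 x N2 grid with N1*N2 ~ M points.

    N1 = round(sqrt(M)) and N2 = round(M / N1); points sit at the centers of
    the N1 x N2 tiling of [0, domain]^2 (N1 rows along y, N2 columns along x).
    """
    if M < 4:
        raise ValueError("need M >= 4")
    N1 = int(np.floor(np.sqrt(M) + 0.5))
    N2 = int(np.floor(M / N1 + 0.5))
    ys = (np.arange(N1) + 0.5) * domain / N1
    xs = (np.arange(N2) + 0.5) * domain / N2
    xg, yg = np.meshgrid(xs, ys)
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    return PointSet(pts, domain, label="S_cart"), N1, N2


def occupancy_histogram(points: PointSet, N1: int, N2: int) -> HistogramGrid:
    """Count points per bin of the N1 x N2 tiling (half-open bins).

    Points exactly on the upper domain boundary go to the last bin; points
    outside the domain are an error.
    """
    pts = points.points
    d = points.domain
    if pts.size and (pts.min() < -1e-9 or pts.max() > d + 1e-9):
        raise ValueError("point outside the domain")
    ix = np.minimum((pts[:, 0] / d * N2).astype(int), N2 - 1)
    iy = np.minimum((pts[:, 1] / d * N1).astype(int), N1 - 1)
    counts = np.zeros((N1, N2), dtype=int)
    np.add.at(counts, (iy, ix), 1)
    return HistogramGrid(counts, d)


def kld_to_uniform(h: HistogramGrid, bits: bool = False) -> float:
    """KLD of the histogram from the flat reference, in nats (or bits).

    With p = counts/M and q = 1/B this is sum_b p_b ln(p_b / q_b), equal to
    ln(B) - H(p); it is zero exactly when the counts are all equal.
    """
    M = h.M
    if M < 1:
        raise ValueError("empty histogram")
    p = h.counts.ravel() / M
    nz = p > 0
    kld = float(np.log(h.B) + np.sum(p[nz] * np.log(p[nz])))
    if kld < 1e-12:      # rounding either side of the exact lower bound
        kld = 0.0
    return kld / _LN2 if bits else kld


def _kld_from_counts(counts: np.ndarray, M: int, B: int) -> np.ndarray:
    p = counts / M
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(p), 0.0)
    return np.maximum(np.log(B) + t.sum(axis=-1), 0.0)


def null_kld_distribution(M: int, domain: float, N1: int, N2: int,
                          n_real: int = 10000, seed=None,
                          bits: bool = False) -> NullDistribution:
    """Monte-Carlo null: KLD of i.i.d. uniform M-point sets on the tiling.

    Because uniform binning makes the counts multinomial(M, 1/B), the null
    depends only on (M, N1, N2), not on the domain size.
    """
    if n_real < 100:
        raise ValueError("need n_real >= 100")
    rng = np.random.default_rng(seed)
    B = N1 * N2
    u = rng.random((n_real, M, 2))
    ix = np.minimum((u[:, :, 0] * N2).astype(int), N2 - 1)
    iy = np.minimum((u[:, :, 1] * N1).astype(int), N1 - 1)
    flat = iy * N2 + ix + np.arange(n_real)[:, None] * B
    counts = np.bincount(flat.ravel(), minlength=n_real * B).reshape(n_real, B)
    sample = _kld_from_counts(counts, M, B)
    if bits:
        sample = sample / _LN2
    mu = float(sample.mean())
    sem = float(sample.std(ddof=1) / np.sqrt(n_real))
    return NullDistribution(sample, mu, sem)


def uniformity_test(S: PointSet, n_real: int = 10000, seed=None,
                    bits: bool = False) -> UniformityTestResult:
    """Run the full KLD uniformity test on one point set.

    Builds the Cartesian tiling from M, computes the observed divergence and
    the Monte-Carlo null, and applies the left/right 5% tail rule.  The
    reported p is the left-tail fraction with a +1 correction so it is never
    exactly zero.
    """
    M = S.M
    if M < 4:
        raise ValueError("need at least 4 points")
    _, N1, N2 = cartesian_grid(M, S.domain)
    h = occupancy_histogram(S, N1, N2)
    kld_obs = kld_to_uniform(h, bits=bits)
    null = null_kld_distribution(M, S.domain, N1, N2, n_real=n_real,
                                 seed=seed, bits=bits)
    p_left = (1 + int(np.sum(null.sample <= kld_obs))) / (1 + n_real)
    q05, q95 = np.quantile(null.sample, [0.05, 0.95])
    if kld_obs < q05:
        outcome = OUTCOME_REGULAR
    elif kld_obs > q95:
        outcome = OUTCOME_STRUCTURE
    else:
        outcome = OUTCOME_UNIFORM
    ci = (null.mu - 2.576 * null.sem, null.mu + 2.576 * null.sem)
    return UniformityTestResult(kld_obs, null.sample, p_left, null.mu,
                                null.sem, ci, outcome, M, N1, N2,
                                label=S.label)
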