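"""Topographic ICA: linear filters on a cyclic 2-D grid with energy pooling.

The model has two stages.  First-stage linear filters ``w_i`` act on
whitened patches ``z`` giving responses ``s_i = w_i^T z``; the squared
responses are pooled over an L x L toroidal neighborhood of a 2-D grid,

    e_j(t) = sum_i h(i, j) s_i(t)^2,

and training maximizes the sparsity of the pooled energies,

    L(W) = (1/T) sum_t sum_j G(e_j(t)),

over orthonormal W in whitened space, with G a saturating (concave)
function — by default the square root, G(u) = -(eps + u)^p with p = 0.5.
Residual energy correlations that plain ICA cannot remove thus pull
statistically dependent filters close together on the grid, which is what
makes orientation cluster in the model's topology.

Optimization is monotone-safeguarded gradient ascent: the natural gradient
step is followed by symmetric orthogonalization W <- (W W^T)^{-1/2} W, and
the step size is halved whenever the objective would decrease.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .sampling import WhiteningModel


@dataclass
class Topology:
    """Toroidal 2-D pooling topology with an L x L binary window."""

    n1: int
    n2: int
    L: int
    H: np.ndarray   # (d_r, d_r) binary pooling matrix, symmetric

    @property
    def d_r(self) -> int:
        return self.n1 * self.n2

    def window_indices(self, i: int, j: int) -> np.ndarray:
        """Flat indices of units inside the window centered on (i, j)."""
        half = self.L // 2
        rows = (np.arange(i - half, i + half + 1)) % self.n1
        cols = (np.arange(j - half, j + half + 1)) % self.n2
        return (rows[:, None] * self.n2 + cols[None, :]).ravel()


@dataclass
class NonlinearitySpec:
    """Saturating energy nonlinearity G and its derivative.

    ``power``: G(u) = -(eps + u)^p, the default square root at p = 0.5;
    ``arctan``: G(u) = -atan(sqrt(eps + u)), a more strongly saturating
    alternative.  ``eps`` > 0 keeps G' finite at zero energy.
    """

    family: str = "power"
    p: float = 0.5
    eps: float = 1e-3

    def __post_init__(self):
        if self.family not in ("power", "arctan"):
            raise ValueError(f"unknown nonlinearity family {self.family!r}")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")

    def G(self, u: np.ndarray) -> np.ndarray:
        if self.family == "power":
            return -np.power(self.eps + u, self.p)
        return -np.arctan(np.sqrt(self.eps + u))

    def Gprime(self, u: np.ndarray) -> np.ndarray:
        if self.family == "power":
            return -self.p * np.power(self.eps + u, self.p - 1.0)
        r = np.sqrt(self.eps + u)
        return -1.0 / (2.0 * r * (1.0 + self.eps + u))


@dataclass
class TICAModel:
    """A fitted model: filters in whitened space plus topology and trace."""

    W: np.ndarray
    topology: Topology
    nonlinearity: NonlinearitySpec
    objective_trace: np.ndarray
    n_iter: int
    seed: int | None = None

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W)
            f.create_dataset("H", data=self.topology.H.astype(np.uint8))
            f.create_dataset("objective_trace", data=self.objective_trace)
            f.attrs.update(n1=self.topology.n1, n2=self.topology.n2,
                           L=self.topology.L, family=self.nonlinearity.family,
                           p=self.nonlinearity.p, eps=self.nonlinearity.eps,
                           n_iter=self.n_iter,
                           seed=-1 if self.seed is None else self.seed)

    @classmethod
    def from_hdf5(cls, path) -> "TICAModel":
        import h5py
        with h5py.File(path, "r") as f:
            topo = Topology(int(f.attrs["n1"]), int(f.attrs["n2"]),
                            int(f.attrs["L"]), f["H"][...].astype(float))
            nl = NonlinearitySpec(str(f.attrs["family"]), float(f.attrs["p"]),
                                  float(f.attrs["eps"]))
            seed = int(f.attrs["seed"])
            return cls(f["W"][...], topo, nl, f["objective_trace"][...],
                       int(f.attrs["n_iter"]), None if seed < 0 else seed)


def build_topology(n1: int, n2: int, L: int) -> Topology:
    """Binary pooling matrix of an L x L window on the (n1, n2) torus.

    h(i, j) = 1 iff unit j lies in the L x L neighborhood of unit i with
    toroidal wraparound; H is symmetric with all row sums equal to L^2.
    """
    if L % 2 == 0:
        raise ValueError("L must be odd (window needs a center)")
    if L > min(n1, n2):
        raise ValueError("L must not exceed the torus dimensions")
    idx = np.arange(n1 * n2)
    r, c = idx // n2, idx % n2
    dr = (r[:, None] - r[None, :]) % n1
    dc = (c[:, None] - c[None, :]) % n2
    half = L // 2
    near_r = (dr <= half) | (dr >= n1 - half)
    near_c = (dc <= half) | (dc >= n2 - half)
    return Topology(n1, n2, L, (near_r & near_c).astype(float))


def tica_objective(W: np.ndarray, Z: np.ndarray, topology: Topology,
                   nonlinearity: NonlinearitySpec) -> float:
    """Mean pooled-energy sparsity (1/T) sum_t sum_j G(e_j(t))."""
    W = np.asarray(W, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(Z))):
        raise ValueError("non-finite input")
    S = Z @ W.T
    E = (S ** 2) @ topology.H      # H symmetric: e_j = sum_i h(i,j) s_i^2
    return float(nonlinearity.G(E).sum(axis=1).mean())


def _sym_orth(W: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(W, full_matrices=False)
    return U @ Vt


class TopographicICA(BaseEstimator, TransformerMixin):
    """Sklearn-style estimator for the topographic ICA model.

    Parameters
    ----------
    n1, n2 : torus grid dimensions (their product must equal the input
        dimension).  ``None`` infers a square grid from the data.
    pool_size : odd side L of the pooling window (L=1 gives plain ICA).
    nonlinearity, exponent, eps : energy nonlinearity G; see
        :class:`NonlinearitySpec`.
    n_iter : gradient-ascent iterations (the objective trace records
        ``n_iter_ + 1`` values including the initial one).
    step : initial step size; backtracking halves it on any objective
        decrease, so the trace is non-decreasing.
    random_state : seed of the random orthonormal initialization.

    Attributes (after fit)
    ----------------------
    components_ : (d_r, d_r) orthonormal filter matrix W, rows = filters.
    topology_, nonlinearity_, objective_trace_, n_iter_.
    """

    def __init__(self, n1: int | None = None, n2: int | None = None,
                 pool_size: int = 5, nonlinearity: str = "power",
                 exponent: float = 0.5, eps: float = 1e-3,
                 n_iter: int = 2000, step: float = 0.1,
                 random_state: int | None = None):
        self.n1 = n1
        self.n2 = n2
        self.pool_size = pool_size
        self.nonlinearity = nonlinearity
        self.exponent = exponent
        self.eps = eps
        self.n_iter = n_iter
        self.step = step
        self.random_state = random_state

    def fit(self, Z, y=None):
        Z = np.asarray(Z, dtype=float)
        T, d_r = Z.shape
        n1, n2 = self.n1, self.n2
        if n1 is None or n2 is None:
            n = int(round(math.sqrt(d_r)))
            if n * n != d_r:
                raise ValueError("cannot infer a square torus; pass n1, n2")
            n1 = n2 = n
        if n1 * n2 != d_r:
            raise ValueError(f"n1*n2 = {n1 * n2} != data dimension {d_r}")
        cov_dev = np.max(np.abs(Z.T @ Z / T - np.eye(d_r)))
        if cov_dev > 1e-2:
            warnings.warn(f"input does not look whitened "
                          f"(covariance deviates by {cov_dev:.3g})")
        topo = build_topology(n1, n2, self.pool_size)
        nl = NonlinearitySpec(self.nonlinearity, self.exponent, self.eps)
        rng = np.random.default_rng(self.random_state)
        W, _ = np.linalg.qr(rng.standard_normal((d_r, d_r)))

        H = topo.H
        step = float(self.step)

        def objective(Wm, S=None):
            S = Z @ Wm.T if S is None else S
            E = (S ** 2) @ H
            return float(nl.G(E).sum(axis=1).mean()), S, E

        obj, S, E = objective(W)
        trace = [obj]
        n_done = 0
        for it in range(self.n_iter):
            if not np.isfinite(obj):
                raise FloatingPointError(f"objective diverged at iteration {it}")
            R = nl.Gprime(E) @ H             # r_i = sum_j h(i,j) G'(e_j)
            grad = (2.0 / T) * (S * R).T @ Z
            improved = False
            trial = step
            for _ in range(30):
                W_new = _sym_orth(W + trial * grad)
                obj_new, S_new, E_new = objective(W_new)
                if obj_new >= obj:
                    improved = True
                    break
                trial /= 2.0
            if not improved:
                # no ascent direction at machine precision: converged
                trace.extend([obj] * (self.n_iter - it))
                n_done = self.n_iter
                break
            W, obj, S, E = W_new, obj_new, S_new, E_new
            step = trial * 1.5   # grow on success; backtracking bounds it
            trace.append(obj)
            n_done = it + 1
        else:
            n_done = self.n_iter

        self.components_ = W
        self.topology_ = topo
        self.nonlinearity_ = nl
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = n_done
        self.n_features_in_ = d_r
        return self

    def transform(self, Z):
        """First-stage linear responses s = Z W^T."""
        return np.asarray(Z, dtype=float) @ self.components_.T

    def pooled_energies(self, Z):
        S = self.transform(Z)
        return (S ** 2) @ self.topology_.H

    @property
    def model_(self) -> TICAModel:
        return TICAModel(self.components_, self.topology_, self.nonlinearity_,
                         self.objective_trace_, self.n_iter_, self.random_state)


def fit_tica(Z: np.ndarray, topology: Topology,
             nonlinearity: NonlinearitySpec | None = None,
             n_iter: int = 2000, step: float = 0.1, seed=None) -> TICAModel:
    """Functional wrapper over :class:`TopographicICA`."""
    nl = nonlinearity or NonlinearitySpec()
    est = TopographicICA(n1=topology.n1, n2=topology.n2, pool_size=topology.L,
                         nonlinearity=nl.family, exponent=nl.p, eps=nl.eps,
                         n_iter=n_iter, step=step, random_state=seed)
    est.fit(Z)
    return est.model_


def receptive_fields(model: TICAModel, whitening: WhiteningModel) -> np.ndarray:
    """Dewhitened basis vectors, one column per unit.

    Column i is a_i = eigvecs diag(sqrt(eigvals)) w_i — the image-space
    feature of unit i, reshapeable to N x N on demand.
    """
    if model.W.shape[0] != whitening.d_r:
        raise ValueError("model and whitening dimensions disagree")
    return whitening.eigvecs @ (np.sqrt(whitening.eigvals)[:, None] * model.W.T)


def amari_index(P: np.ndarray) -> float:
    """Permutation/scale-invariant distance of P = W_est A from identity.

    0 means perfect source recovery up to permutation and sign; values
    below ~0.1 are conventionally called recovered.
    """
    P = np.abs(np.asarray(P, dtype=float))
    d = P.shape[0]
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * d * (d - 1)))
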