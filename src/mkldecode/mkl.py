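"""Sparse multiple kernel learning (SimpleMKL) for region-based decoding.

Learns a convex combination K(d) = sum_m d_m K_m of region kernels
jointly with a kernel machine: an L1 simplex constraint on d (d >= 0,
sum d = 1) makes the combination sparse, so uninformative regions end
with weight exactly zero.  Optimisation alternates an inner dual solve
of the kernel machine on K(d) — a soft-margin SVM for classification, an
epsilon-insensitive SVR for regression — with reduced-gradient descent
on the simplex, following the SimpleMKL scheme: the objective

    J(d) = max_alpha  dual(alpha; K(d))

is differentiable with dJ/dd_m = -1/2 u' K_m u, where u is the signed
dual vector of the inner solution, and the stopping rule is the duality
gap  max_m 1/2 u'K_m u - 1/2 u'K(d) u  <= tol.

No randomness anywhere: d starts uniform, the inner solver is
deterministic, and the line search is Armijo backtracking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC, SVR

from .kernels import KernelSet, RegionFeatureBlock, transform_block

__all__ = ["MKLModel", "WeightMap", "train_mkl", "predict", "extract_weights"]

#: kernel weights below this are reported as exactly zero
SPARSITY_EPS = 1e-6


@dataclass
class MKLModel:
    """Fitted simplex-weighted kernel machine.

    ``dual_coef`` is the signed dual vector over all training samples
    (y_i alpha_i for classification, alpha_i - alpha*_i for regression);
    ``kernel_weights`` lives on the probability simplex with entries
    below 1e-6 snapped to exactly zero.
    """

    region_ids: list[int]
    kernel_weights: np.ndarray
    dual_coef: np.ndarray
    bias: float
    task: str                      # "classification" | "regression"
    C: float
    epsilon: float | None = None
    target_mean: float = 0.0       # restored at prediction (regression)
    n_iter: int = 0
    duality_gap: float = np.inf
    converged: bool = True
    objective: float = np.nan
    objective_path: list = None    # J after each accepted outer step

    def __post_init__(self) -> None:
        d = self.kernel_weights
        if (d < -1e-8).any() or abs(d.sum() - 1.0) > 1e-8:
            raise ValueError("kernel weights must lie on the unit simplex")


@dataclass
class WeightMap:
    """Back-projected model weights for interpretation.

    ``region_percent`` maps region id -> 100 * d_m; ``voxel_weights``
    maps region id -> per-voxel primal weight vector (zero array for
    regions with d_m = 0).
    """

    region_percent: dict[int, float]
    voxel_weights: dict[int, np.ndarray]
    voxel_coords: dict[int, np.ndarray]
    note: str = ("voxel weights are primal weights in the centred, "
                 "trace-normalised feature space, scaled by the region's "
                 "kernel weight")

    def volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Assemble voxel weights onto the atlas grid (zero background)."""
        vol = np.zeros(shape)
        for rid, w in self.voxel_weights.items():
            vol[tuple(self.voxel_coords[rid].T)] = w
        return vol


def _inner_solve(K: np.ndarray, y: np.ndarray, task: str, C: float,
                 epsilon: float | None, inner_tol: float
                 ) -> tuple[np.ndarray, float, float]:
    """Exact dual solve of the kernel machine on one combined kernel.

    Returns (signed dual vector u over all samples, bias, objective J)
    where J is the optimal dual objective being minimised over d:
      classification: J = sum_i alpha_i - 1/2 u'Ku
      regression:     J = y'u - eps * ||u||_1 - 1/2 u'Ku
    """
    n = len(y)
    if task == "classification":
        est = SVC(C=C, kernel="precomputed", tol=inner_tol, shrinking=False,
                  cache_size=64)
        est.fit(K, y)
        u = np.zeros(n)
        u[est.support_] = est.dual_coef_[0]
        J = np.abs(u).sum() - 0.5 * u @ K @ u
    else:
        est = SVR(C=C, epsilon=epsilon, kernel="precomputed", tol=inner_tol,
                  shrinking=False, cache_size=64)
        est.fit(K, y)
        u = np.zeros(n)
        u[est.support_] = est.dual_coef_[0]
        J = y @ u - epsilon * np.abs(u).sum() - 0.5 * u @ K @ u
    return u, float(est.intercept_[0]), float(J)


def _descent_direction(d: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Reduced-gradient descent direction on the simplex.

    The reduced gradient is taken relative to the largest component mu;
    coordinates at zero whose reduced gradient is positive are frozen,
    and the mu component absorbs the rest so the direction sums to zero.
    """
    mu = int(np.argmax(d))
    red = grad - grad[mu]
    D = -red
    D[(d <= 0) & (red > 0)] = 0.0
    D[mu] = -(np.sum(D) - D[mu])
    return D


def _descend(d: np.ndarray, u: np.ndarray, b: float, J: float,
             grad: np.ndarray, solve) -> tuple | None:
    """One reduced-gradient descent pass with boundary crossing.

    Walks along the descent direction to the nearest simplex face while
    the objective keeps decreasing there (zeroing the blocking
    coordinate and re-absorbing the direction each time), then finishes
    with an Armijo backtracking search inside the last interval.
    Returns the new iterate, or None if no descent was possible.
    """
    tiny = 1e-9
    d = d.copy()
    d[d < tiny] = 0.0               # exact zeros so faces are real boundaries
    d /= d.sum()
    D = _descent_direction(d, grad)
    improved = False
    for _ in range(len(d)):  # at most one boundary hit per coordinate
        if np.abs(D).max() < 1e-12:
            break
        neg = D < -1e-15
        if not neg.any():
            break
        ratios = -d[neg] / D[neg]
        step_max = float(ratios.min())
        d_max = np.clip(d + step_max * D, 0.0, None)
        d_max[d_max < tiny] = 0.0
        d_max /= d_max.sum()
        u2, b2, J2 = solve(d_max)
        if J2 < J - 1e-10 * max(1.0, abs(J)):
            d, u, b, J = d_max, u2, b2, J2
            improved = True
            D[d <= 0] = 0.0          # freeze coordinates on the boundary
            mu = int(np.argmax(d))
            D[mu] = 0.0
            D[mu] = -np.sum(D)
            continue
        # line search inside (0, step_max]: quadratic interpolation from
        # J(0), J'(0) and J(step_max), safeguarded by Armijo backtracking
        slope = float(grad @ D)
        if slope >= 0:
            break
        denom = J2 - J - slope * step_max
        step = (-slope * step_max ** 2 / (2.0 * denom)
                if denom > 0 else 0.5 * step_max)
        step = float(np.clip(step, 0.05 * step_max, 0.95 * step_max))
        for _ in range(15):
            d_try = np.clip(d + step * D, 0.0, None)
            d_try[d_try < tiny] = 0.0
            d_try /= d_try.sum()
            u3, b3, J3 = solve(d_try)
            if J3 <= J + 1e-4 * step * slope:
                return d_try, u3, b3, J3
            step *= 0.5
        break
    return (d, u, b, J) if improved else None


def _sqp_polish(d0: np.ndarray, solve, mats, max_iter: int):
    """Refine the kernel weights with SLSQP on the simplex.

    The objective and its envelope gradient come from the same inner
    dual solve, so this is the identical convex problem the reduced
    gradient descends — just with a quasi-Newton model of its curvature,
    which avoids the zigzag of first-order steps near the optimum.
    Deterministic (no randomness in SLSQP).
    """
    from scipy.optimize import minimize

    R = len(d0)

    def fun(dv):
        dvc = np.clip(dv, 0.0, None)
        s = dvc.sum()
        dvc = dvc / s if s > 0 else np.full(R, 1.0 / R)
        u, _, J = solve(dvc)
        quad = np.array([u @ Km @ u for Km in mats])
        return J, -0.5 * quad

    res = minimize(fun, d0, jac=True, method="SLSQP",
                   bounds=[(0.0, 1.0)] * R,
                   constraints=[{"type": "eq",
                                 "fun": lambda dv: dv.sum() - 1.0,
                                 "jac": lambda dv: np.ones(R)}],
                   options={"maxiter": max_iter, "ftol": 1e-10})
    d = np.clip(res.x, 0.0, None)
    d /= d.sum()
    u, b, J = solve(d)
    u0, b0, J0 = solve(d0)
    if J0 < J:                      # keep the better iterate
        return d0, u0, b0, J0, int(res.nit)
    return d, u, b, J, int(res.nit)


def train_mkl(kernels: KernelSet, targets: np.ndarray, task: str,
              C: float = 1.0, epsilon: float | None = None,
              tol: float = 1e-4, max_iter: int = 500,
              inner_tol: float = 1e-6) -> MKLModel:
    """Fit a SimpleMKL model on (already centred/normalised) kernels.

    Parameters
    ----------
    kernels : KernelSet whose matrices cover the training samples, in
        the same row order as ``targets``.
    targets : class labels in {-1, +1} (classification) or continuous
        values (regression; mean-centred internally, the mean is
        restored at prediction).
    C : soft-margin / regularisation trade-off of the inner machine.
    epsilon : insensitive-tube half-width for regression; defaults to
        0.1 x SD of the training targets.
    tol : duality-gap stopping threshold (relative to |J|).
    """
    if task not in ("classification", "regression"):
        raise ValueError("task must be 'classification' or 'regression'")
    y = np.asarray(targets, dtype=float)
    if len(y) != kernels.n_samples:
        raise ValueError("targets length does not match kernel sample count")
    if len(y) < 2:
        raise ValueError("need at least two samples")
    target_mean = 0.0
    if task == "classification":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("both classes must be present")
        if not set(classes) <= {-1.0, 1.0}:
            raise ValueError("classification targets must be -1/+1")
    else:
        target_mean = float(y.mean())
        y = y - target_mean
        if epsilon is None:
            epsilon = 0.1 * float(y.std(ddof=0))
        epsilon = max(epsilon, 1e-12)

    R = kernels.n_regions
    mats = kernels.matrices
    # PSD sanity on the combined starting kernel
    d = np.full(R, 1.0 / R)
    K0 = kernels.combined(d)
    w_min = float(np.linalg.eigvalsh(K0).min())
    if w_min < -1e-6 * max(1.0, np.trace(K0)):
        raise ValueError("combined kernel is not positive semidefinite")

    def solve(dvec: np.ndarray):
        return _inner_solve(kernels.combined(dvec), y, task, C, epsilon,
                            inner_tol)

    u, b, J = solve(d)
    best = (d.copy(), u, b, J)
    path = [J]
    gap = np.inf
    it = 0
    converged = False
    # phase 1: reduced-gradient descent on the simplex (a handful of
    # passes finds the active face and is already optimal for sparse
    # solutions); phase 2 below polishes the tail, where the reduced
    # gradient is known to zigzag
    for it in range(1, min(max_iter, 12) + 1):
        quad = np.array([u @ Km @ u for Km in mats])  # u'K_m u per region
        grad = -0.5 * quad
        gap = 0.5 * quad.max() - 0.5 * float(quad @ d)
        if gap <= tol * max(1.0, abs(J)):
            converged = True
            break
        moved = _descend(d, u, b, J, grad, solve)
        if moved is None:
            break
        d, u, b, J = moved
        path.append(J)
        if J < best[3]:
            best = (d.copy(), u, b, J)
    if J > best[3]:
        d, u, b, J = best
    if not converged:
        # phase 2: sequential quadratic refinement of min_d J(d) on the
        # simplex, using the same analytic gradient -1/2 u'K_m u
        d, u, b, J, n2 = _sqp_polish(d, solve, mats, max_iter)
        it += n2
        path.append(J)
        quad = np.array([u @ Km @ u for Km in mats])
        gap = 0.5 * quad.max() - 0.5 * float(quad @ d)
        converged = gap <= tol * max(1.0, abs(J))
    if not converged:
        warnings.warn("MKL solver did not reach the duality-gap tolerance; "
                      "returning best iterate", stacklevel=2)

    d = d.copy()
    d[d < SPARSITY_EPS] = 0.0
    d /= d.sum()
    u, b, J = solve(d)  # consistent duals for the sparsified weights

    return MKLModel(region_ids=list(kernels.region_ids), kernel_weights=d,
                    dual_coef=u, bias=b, task=task, C=C,
                    epsilon=epsilon if task == "regression" else None,
                    target_mean=target_mean, n_iter=it, duality_gap=float(gap),
                    converged=converged, objective=float(J),
                    objective_path=path)


def predict(model: MKLModel, kernels_test_vs_train: list[np.ndarray]
            ) -> np.ndarray:
    """Decision values (classification) or predicted targets (regression).

    ``kernels_test_vs_train`` holds, per region (model order), the
    n_test x n_train kernel block between test and training samples,
    centred/normalised with the model's training statistics.
    """
    if len(kernels_test_vs_train) != len(model.region_ids):
        raise ValueError("one test kernel block required per model region")
    n_train = len(model.dual_coef)
    Kd = np.zeros_like(kernels_test_vs_train[0], dtype=float)
    for w, Km in zip(model.kernel_weights, kernels_test_vs_train):
        if Km.shape[1] != n_train:
            raise ValueError("test kernel block column count must equal the "
                             "number of training samples")
        if w != 0:
            Kd += w * Km
    f = Kd @ model.dual_coef + model.bias
    if model.task == "regression":
        f = f + model.target_mean
    return f


def predict_from_set(model: MKLModel, processed: KernelSet,
                     train_rows: np.ndarray, test_rows: np.ndarray) -> np.ndarray:
    """Convenience: slice test-vs-train blocks out of full processed kernels."""
    id_to_mat = dict(zip(processed.region_ids, processed.matrices))
    blocks = [id_to_mat[rid][np.ix_(test_rows, train_rows)]
              for rid in model.region_ids]
    return predict(model, blocks)


def extract_weights(model: MKLModel, blocks: list[RegionFeatureBlock],
                    training_rows: np.ndarray) -> WeightMap:
    """Back-project the dual solution to region and voxel weights.

    For linear kernels the primal weight of region m is
    w_m = d_m * sum_i u_i phi(x_i^(m)) with phi the centring/scaling
    transform the kernels were built with; regions with d_m = 0 get
    all-zero voxel weights.  Region percentages are 100 * d_m.
    """
    by_id = {b.region_id: b for b in blocks}
    missing = [rid for rid in model.region_ids if rid not in by_id]
    if missing:
        raise ValueError(f"feature blocks missing for regions {missing}")
    tr = np.asarray(training_rows)
    if tr.dtype == bool:
        tr = np.flatnonzero(tr)
    if len(model.dual_coef) != len(tr):
        raise ValueError("training_rows length must match the model's "
                         "training sample count")
    region_percent: dict[int, float] = {}
    voxel_weights: dict[int, np.ndarray] = {}
    voxel_coords: dict[int, np.ndarray] = {}
    for rid, dm in zip(model.region_ids, model.kernel_weights):
        block = by_id[rid]
        region_percent[rid] = 100.0 * float(dm)
        voxel_coords[rid] = block.voxel_coords
        if dm == 0.0:
            voxel_weights[rid] = np.zeros(block.n_voxels)
            continue
        phi = transform_block(block, tr)[tr]          # training samples only
        voxel_weights[rid] = dm * (model.dual_coef @ phi)
    return WeightMap(region_percent=region_percent,
                     voxel_weights=voxel_weights, voxel_coords=voxel_coords)
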