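"""Large-margin-distribution SVM (LM_SVM), primal form.

Beyond the classic SVM, which cares only about the worst (minimum)
margin, this head also rewards the *first-order statistic of the margin
distribution*: the sample mean of the functional margins

    gamma_bar = (1/N) sum_i y_i (phi(x_i)^T w + b).

The training objective is

    min_{w,b}  1/2 ||w||^2 + C sum_i xi_i^2 - lambda * gamma_bar
    s.t.       y_i (phi(x_i)^T w + b) >= 1 - xi_i,   xi_i >= 0,

with squared (L2) slacks. Because the slack penalty is quadratic, the
optimal slack is xi_i = max(0, 1 - y_i f(x_i)) and the xi_i >= 0
constraint is automatically satisfied, so the constrained problem
collapses to a smooth unconstrained convex primal — piecewise quadratic
with continuous gradient — which we minimize by a finite Newton
active-set iteration with an Armijo safeguard. A brute-force constrained
QP solver over (w, b, xi) is kept alongside as an independent oracle for
tests. At lambda = 0 the model is exactly the L2-slack SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

__all__ = [
    "LMSVMModel",
    "margin_mean",
    "lmsvm_objective",
    "fit_lmsvm",
    "qp_oracle_fit",
    "decision_function",
    "predict",
]


@dataclass
class LMSVMModel:
    """Fitted linear head over mapped features.

    Diagnostics are recomputable from (w, b) and the training data:
    ``gamma_bar`` is the training margin mean, ``slacks`` the per-sample
    xi_i = max(0, 1 - y_i f(x_i)), ``objective`` the primal value.
    """

    w: np.ndarray
    b: float
    C: float
    lam: float
    gamma_bar: float = np.nan
    slacks: np.ndarray = field(default_factory=lambda: np.empty(0))
    objective: float = np.nan
    n_iter: int = 0
    grad_norm: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        self.b = float(self.b)


def _check_xy(Phi, y):
    Phi = np.atleast_2d(np.asarray(Phi, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if Phi.shape[0] != y.size:
        raise ValueError(f"Phi has {Phi.shape[0]} rows but y has {y.size} entries")
    if y.size == 0:
        raise ValueError("empty sample set")
    if not np.isin(y, (1.0, -1.0)).all():
        raise ValueError("labels must be +1 or -1")
    return Phi, y


def margin_mean(w, b, Phi, y) -> float:
    """Mean signed functional margin (1/N) sum y_i (phi_i^T w + b)."""
    Phi, y = _check_xy(Phi, y)
    w = np.asarray(w, dtype=np.float64).ravel()
    return float(np.mean(y * (Phi @ w + b)))


def _slacks(w, b, Phi, y) -> np.ndarray:
    return np.maximum(0.0, 1.0 - y * (Phi @ w + b))


def lmsvm_objective(w, b, Phi, y, C: float, lam: float) -> float:
    """Primal value at (w, b), with slacks at their optimal active value."""
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    Phi, y = _check_xy(Phi, y)
    w = np.asarray(w, dtype=np.float64).ravel()
    if not (np.isfinite(w).all() and np.isfinite(b)):
        raise ValueError("non-finite (w, b)")
    xi = _slacks(w, b, Phi, y)
    return float(
        0.5 * w @ w + C * np.sum(xi**2) - lam * margin_mean(w, b, Phi, y)
    )


def fit_lmsvm(
    Phi,
    y,
    C: float = 1.0,
    lam: float = 0.1,
    fit_intercept: bool = True,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> LMSVMModel:
    """Minimize the unconstrained smooth primal.

    Finite Newton active-set iteration: the objective is convex, C^1 and
    piecewise quadratic, so on each piece (fixed set A of samples with
    margin below 1) the exact minimizer solves the linear system

        (P + 2C M_A^T M_A) theta = 2C M_A^T y_A + (lam/N) M^T y,

    with theta = (w, b), M = [Phi, 1] and P the projection that leaves
    the bias unregularized. Each Newton direction is safeguarded by an
    Armijo backtracking line search; the iteration terminates when the
    gradient infinity-norm drops below ``tol`` (typically a handful of
    steps). Raises on single-class input; reports ``converged=False``
    with the final gradient norm if ``max_iter`` is exhausted.
    """
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    Phi, y = _check_xy(Phi, y)
    if y.size < 2 or np.unique(y).size < 2:
        raise ValueError("need at least two samples with both classes present")

    n, d = Phi.shape
    M = np.hstack([Phi, np.ones((n, 1))]) if fit_intercept else Phi
    p = M.shape[1]
    Pdiag = np.ones(p)
    if fit_intercept:
        Pdiag[-1] = 0.0
    theta = np.zeros(p)

    def value_grad(th):
        f = M @ th
        xi = np.maximum(0.0, 1.0 - y * f)
        obj = 0.5 * th[:d] @ th[:d] + C * xi @ xi - (lam / n) * (y @ f)
        gf = -2.0 * C * xi * y - (lam / n) * y
        return obj, Pdiag * th + M.T @ gf, xi

    obj, grad, xi = value_grad(theta)
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() < tol:
            break
        active = xi > 0
        H = np.diag(Pdiag) + 2.0 * C * M[active].T @ M[active]
        rhs = 2.0 * C * M[active].T @ y[active] + (lam / n) * (M.T @ y)
        try:
            target = np.linalg.solve(H, rhs)
        except np.linalg.LinAlgError:
            target = np.linalg.lstsq(H, rhs, rcond=None)[0]
        direction = target - theta
        slope = grad @ direction
        if slope >= 0:  # numerical corner case: fall back to steepest descent
            direction = -grad
            slope = -(grad @ grad)
        step = 1.0
        while True:
            cand = theta + step * direction
            obj_new, grad_new, xi_new = value_grad(cand)
            if obj_new <= obj + 1e-4 * step * slope or step < 1e-16:
                break
            step *= 0.5
        theta, obj, grad, xi = cand, obj_new, grad_new, xi_new

    gnorm = float(np.abs(grad).max())
    w = theta[:d]
    b = float(theta[d]) if fit_intercept else 0.0
    xi = _slacks(w, b, Phi, y)
    return LMSVMModel(
        w=w,
        b=b,
        C=C,
        lam=lam,
        gamma_bar=margin_mean(w, b, Phi, y),
        slacks=xi,
        objective=lmsvm_objective(w, b, Phi, y, C, lam),
        n_iter=it,
        grad_norm=float(gnorm),
        converged=gnorm < tol,
    )


def qp_oracle_fit(
    Phi, y, C: float = 1.0, lam: float = 0.1, fit_intercept: bool = True
) -> LMSVMModel:
    """Brute-force constrained QP over (w, b, xi); test oracle.

    Solves the original constrained program explicitly — variables
    (w, b, xi), linear margin constraints, xi bounded below by 0 — with a
    trust-region interior method (analytic gradient, constant Hessian).
    Intended for small instances (N up to a few hundred); the production
    path is :func:`fit_lmsvm`.
    """
    Phi, y = _check_xy(Phi, y)
    n, d = Phi.shape
    nb = 1 if fit_intercept else 0
    # z = (w, [b], xi)
    H = np.zeros((d + nb + n, d + nb + n))
    H[:d, :d] = np.eye(d)
    H[d + nb :, d + nb :] = 2.0 * C * np.eye(n)
    lin = np.zeros(d + nb + n)
    lin[:d] = -(lam / n) * (Phi.T @ y)
    if fit_intercept:
        lin[d] = -(lam / n) * np.sum(y)

    def fun(z):
        return 0.5 * z @ H @ z + lin @ z

    def jac(z):
        return H @ z + lin

    A = np.zeros((n, d + nb + n))
    A[:, :d] = Phi * y[:, None]
    if fit_intercept:
        A[:, d] = y
    A[:, d + nb :] = np.eye(n)
    constraints = [scipy.optimize.LinearConstraint(A, lb=1.0, ub=np.inf)]
    lb = np.full(d + nb + n, -np.inf)
    lb[d + nb :] = 0.0
    bounds = scipy.optimize.Bounds(lb=lb, ub=np.full_like(lb, np.inf))

    res = scipy.optimize.minimize(
        fun,
        np.zeros(d + nb + n),
        jac=jac,
        hess=lambda z: H,
        method="trust-constr",
        constraints=constraints,
        bounds=bounds,
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000},
    )
    if not res.success and res.status not in (1, 2):  # 1/2: tolerance reached
        raise RuntimeError(f"QP oracle failed: {res.message}")
    w = res.x[:d]
    b = float(res.x[d]) if fit_intercept else 0.0
    return LMSVMModel(
        w=w,
        b=b,
        C=C,
        lam=lam,
        gamma_bar=margin_mean(w, b, Phi, y),
        slacks=_slacks(w, b, Phi, y),
        objective=lmsvm_objective(w, b, Phi, y, C, lam),
        n_iter=int(res.nit),
        grad_norm=float(res.optimality),
        converged=True,
    )


def decision_function(m: LMSVMModel, Phi) -> np.ndarray:
    """Per-sample score phi^T w + b."""
    Phi = np.atleast_2d(np.asarray(Phi, dtype=np.float64))
    if Phi.shape[1] != m.w.size:
        raise ValueError(f"model expects d={m.w.size}, got d={Phi.shape[1]}")
    return Phi @ m.w + m.b


def predict(m: LMSVMModel, Phi) -> np.ndarray:
    """Labels sign(score); a score of exactly 0 maps to +1."""
    s = decision_function(m, Phi)
    return np.where(s >= 0, 1, -1)
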