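"""Variance-weighted least-squares consistency of measurements with the
constraint-based model.

The residual ``phi = min_v (w - v_m)' F^-1 (w - v_m)`` over the feasible
set {N·v = 0, D·v >= 0} is a rough consistency index; each measurement is
given a relative standard deviation (default 10%).  Under inequality
constraints phi no longer follows a chi-square distribution, so no p-value
is attached -- the chi-square threshold is reported for reference only when
no inequality constraint is active at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import LinearConstraint, minimize
from scipy.stats import chi2

from .model import MetabolicModel
from .possibilistic import DEFAULT_ZERO_FLOOR, MeasurementSet, SolverError

__all__ = ["WlsSpec", "WlsResult", "wls_residual"]

DEFAULT_REL_SD = 0.10


@dataclass
class WlsSpec:
    """Diagonal variance model: sd_i = rel_sd * max(|w_i|, zero_floor)."""

    rel_sd: float = DEFAULT_REL_SD
    zero_floor: float = DEFAULT_ZERO_FLOOR

    def sd(self, w: float) -> float:
        return self.rel_sd * max(abs(w), self.zero_floor)


@dataclass
class WlsResult:
    phi: float
    v_hat: np.ndarray
    n_active_inequalities: int = 0
    chi2_reference: float | None = None


def wls_residual(
    model: MetabolicModel, meas: MeasurementSet, spec: WlsSpec | None = None
) -> WlsResult:
    """Minimize the variance-weighted squared measurement error over the
    feasible flux set (convex QP, solved in the nullspace of N).

    The chi-square reference threshold (95%, dof = number of measurements)
    is attached only when the optimum touches no irreversibility constraint,
    the one case where the classical test's assumptions can hold.
    """
    if spec is None:
        spec = WlsSpec()
    n = model.n_reactions
    N = model.N
    Z = null_space(N) if N.size else np.eye(n)
    if Z.size == 0:
        raise SolverError("model admits only the zero flux vector")

    # residuals r_k(t) = (w_k - sign * (Z t)_jk) / sd_k
    K = len(meas)
    C = np.zeros((K, n))
    w = np.zeros(K)
    sd = np.zeros(K)
    for k, m in enumerate(meas):
        C[k, m.reaction_index] = m.sign
        w[k] = m.w_m
        sd[k] = spec.sd(m.w_m)
    if np.any(sd <= 0):
        raise ValueError("measurement standard deviations must be positive")
    A = (C @ Z) / sd[:, None]
    b = w / sd

    # irreversibility: rows of Z for irreversible reactions must stay >= 0
    irrev = model.irreversible_indices
    G = Z[irrev, :]

    H = 2.0 * A.T @ A

    def fun(t):
        r = A @ t - b
        return float(r @ r)

    def grad(t):
        return 2.0 * A.T @ (A @ t - b)

    # least-squares start, then polish under constraints
    t0, *_ = np.linalg.lstsq(A, b, rcond=None)
    cons = [LinearConstraint(G, 0.0, np.inf)] if len(irrev) else []
    res = minimize(
        fun,
        t0,
        jac=grad,
        hess=lambda t: H,
        method="trust-constr",
        constraints=cons,
        options={"xtol": 1e-14, "gtol": 1e-12, "maxiter": 2000},
    )
    if not res.success and res.status not in (1, 2):  # xtol/gtol termination
        raise SolverError(f"WLS QP failed: {res.message}")
    t = res.x
    # clip tiny negative irreversible fluxes from the interior-point polish
    v = Z @ t
    active = int(np.sum(np.abs(G @ t) < 1e-7)) if len(irrev) else 0
    out = WlsResult(phi=fun(t), v_hat=v, n_active_inequalities=active)
    if active == 0:
        out.chi2_reference = float(chi2.ppf(0.95, df=K))
    return out
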