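"""Adaptive-augmented PI controller.

A fixed PI law stabilizes an assumed first-order linear model of the
muscle, ``x' = a x + b u``; an adaptive term cancels the matched
uncertainty on top of it: an unknown input-gain factor ``lambda* > 0``
and an unknown combination ``W*^T phi(x)`` of basis functions

    phi(x) = [x^2, e^x, sin(x), x].

The position is augmented with the error integral,
``xa = [x, xI]``, ``xI' = x - xd``, and the closed linear loop

    xlin' = A_r xlin + [b kP, -1]^T xd,
    A_r   = [[a - b kP, -b kI], [1, 0]]   (Hurwitz by design)

serves as the reference system.  With tracking error
``e_a = xa - xlin``, the adaptation laws

    K^' = sign(lambda*) Gamma_K (xa - [xd, 0]) e_a^T P [b, 0]^T
    W^' = sign(lambda*) Gamma_W phi(x)        e_a^T P [b, 0]^T

with ``P`` the positive definite solution of the Lyapunov equation
``A_r^T P + P A_r + Q = 0`` make the Lyapunov function
``e_a^T P e_a + |l*| K~^T Gamma_K^-1 K~ + |l*| W~^T Gamma_W^-1 W~``
nonincreasing, so ``e_a -> 0``.  The applied effort is

    u = -(K* + K^)^T (xa - [xd, 0]) - W^^T phi(x),   K* = [kP, kI].

With zero adaptation gains and zero initial estimates the law collapses
bit-for-bit onto the plain PI controller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

__all__ = [
    "ADPPIParams",
    "ADPPIState",
    "adppi_basis",
    "build_Ar",
    "solve_P",
    "adppi_update",
    "advance_xlin",
]

N_BASIS = 4


def adppi_basis(x: float) -> np.ndarray:
    """Basis functions of the matched uncertainty: [x^2, e^x, sin x, x].

    The last component is the identity, so the nominally "known" linear
    coefficient of the plant is itself covered by the adaptation.
    """
    if not math.isfinite(x):
        raise ValueError("state must be finite")
    return np.array([x * x, math.exp(x), math.sin(x), x])


def build_Ar(a_lin: float, b_lin: float, kp: float, ki: float) -> np.ndarray:
    """Closed-loop matrix of the PI-stabilized linear model."""
    return np.array([[a_lin - b_lin * kp, -b_lin * ki], [1.0, 0.0]])


def solve_P(A_r: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Positive definite P solving ``A_r^T P + P A_r + Q = 0``.

    Raises ``ValueError`` if ``A_r`` is not Hurwitz or ``Q`` is not
    symmetric positive definite.
    """
    A_r = np.asarray(A_r, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q, Q.T):
        raise ValueError("Q must be symmetric")
    if np.any(np.linalg.eigvalsh(Q) <= 0.0):
        raise ValueError("Q must be positive definite")
    eig = np.linalg.eigvals(A_r)
    if np.any(eig.real >= 0.0):
        raise ValueError(
            f"A_r is not Hurwitz (eigenvalues {np.round(eig, 4)}); "
            "check the linear gains against the assumed plant constants"
        )
    P = solve_continuous_lyapunov(A_r.T, -Q)
    return 0.5 * (P + P.T)


@dataclass
class ADPPIParams:
    """Gains and model constants of the adaptive-augmented PI loop."""

    kp: float = 0.090            # proportional gain (s/m)
    ki: float = 0.40             # integral gain (1/m)
    a_lin: float = -3.50         # assumed plant pole (1/s)
    b_lin: float = 8.50          # assumed input gain (m/s^2 per effort)
    Gamma_K: np.ndarray = field(default_factory=lambda: np.full(2, 0.010))
    Gamma_W: np.ndarray = field(default_factory=lambda: np.full(N_BASIS, 1.0e-5))
    Q: np.ndarray = field(default_factory=lambda: np.eye(2))
    sign_lambda: float = 1.0
    A_r: np.ndarray = field(init=False)
    P: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.Gamma_K = np.asarray(self.Gamma_K, dtype=float)
        self.Gamma_W = np.asarray(self.Gamma_W, dtype=float)
        if self.Gamma_K.shape != (2,) or np.any(self.Gamma_K < 0.0):
            raise ValueError("Gamma_K must be 2 nonnegative diagonal entries")
        if self.Gamma_W.shape != (N_BASIS,) or np.any(self.Gamma_W < 0.0):
            raise ValueError(
                f"Gamma_W must be {N_BASIS} nonnegative diagonal entries"
            )
        if self.sign_lambda not in (-1.0, 1.0):
            raise ValueError("sign_lambda must be +1 or -1")
        self.A_r = build_Ar(self.a_lin, self.b_lin, self.kp, self.ki)
        self.P = solve_P(self.A_r, self.Q)


@dataclass
class ADPPIState:
    K_hat: np.ndarray = field(default_factory=lambda: np.zeros(2))
    W_hat: np.ndarray = field(default_factory=lambda: np.zeros(N_BASIS))
    xI: float = 0.0              # integral of (x - xd), in m s

    def copy(self) -> "ADPPIState":
        return ADPPIState(self.K_hat.copy(), self.W_hat.copy(), self.xI)


def adppi_update(
    state: ADPPIState,
    x: float,
    xd: float,
    xlin: np.ndarray,
    dt: float,
    params: ADPPIParams,
) -> tuple[float, ADPPIState]:
    """One controller tick; returns (effort, new state).

    ``xlin`` is the current 2-vector state of the linear reference
    system (advanced externally, see :func:`advance_xlin`).
    """
    if not dt > 0.0:
        raise ValueError("dt must be positive")
    e = x - xd
    xI = state.xI + e * dt
    ea0 = x - xlin[0]
    ea1 = xI - xlin[1]
    # e_a^T P [b, 0]^T  (scalar adaptation drive)
    P = params.P
    drive = params.b_lin * (ea0 * P[0, 0] + ea1 * P[1, 0])
    s = params.sign_lambda * dt * drive
    K_hat = state.K_hat + params.Gamma_K * np.array([e, xI]) * s
    W_hat = state.W_hat + params.Gamma_W * adppi_basis(x) * s
    # scalar arithmetic so the zero-adaptation case is bit-identical to PI
    u_lin = -1.0 * (params.kp * e + params.ki * xI)
    u_ad = -(K_hat[0] * e + K_hat[1] * xI) - float(W_hat @ adppi_basis(x))
    effort = u_lin + u_ad
    return effort, ADPPIState(K_hat=K_hat, W_hat=W_hat, xI=xI)


def advance_xlin(
    xlin: np.ndarray, xd: float, dt: float, params: ADPPIParams
) -> np.ndarray:
    """Advance the linear reference system exactly over one tick.

    Zero-order hold on ``xd``:
    ``xlin(t+dt) = Phi xlin + A_r^-1 (Phi - I) B xd`` with
    ``Phi = expm(A_r dt)`` and ``B = [b kP, -1]^T``.
    """
    from scipy.linalg import expm

    cache = getattr(params, "_xlin_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(params, "_xlin_cache", cache)
    if dt not in cache:
        Phi = expm(params.A_r * dt)
        B = np.array([params.b_lin * params.kp, -1.0])
        cache[dt] = (Phi, np.linalg.solve(params.A_r, (Phi - np.eye(2)) @ B))
    Phi, forced = cache[dt]
    return Phi @ xlin + forced * xd
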