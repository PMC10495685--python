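"""Continuous approximations of the step function and their DC decompositions.

The number of nonzeros of a vector t equals a sum of step functions
step(t_j) = 0 if t_j == 0 else 1.  Each family here is a continuous
surrogate psi(t) in [0, 1] with psi(0) = 0, even, nondecreasing in |t| and
converging pointwise to the step function as the sharpness parameter theta
grows.  Every family is concave as a function of u = |t|, which yields a
uniform difference-of-convex (DC) split

    psi(t) = s0*|t| - (s0*|t| - psi(t)),

where s0 is the (finite) slope of psi at the origin: both pieces are convex,
and the first is linear — so cardinality *minimization* always reduces to a
sequence of LPs.  For cardinality *maximization* one minimizes the co-step
sum 1 - psi, whose DC split swaps the roles of the two pieces.

The default family is the capped-L1 function psi(t) = min{1, theta*|t|},
which performs best in practice and keeps both DC components piecewise
linear in either mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

__all__ = [
    "StepApprox",
    "DCProgram",
    "KINDS",
    "eval_step",
    "dc_decompose",
    "subgrad_phi2",
]

KINDS = ("cappedL1", "exp", "scad", "log", "lpPos", "lpNeg")

Mode = Literal["minimize", "maximize"]

# inner-segment height below which the lpPos family is linearized so that
# its DC majorant slope stays finite (|t|^p has unbounded slope at 0)
_LP_POS_KNEE = 0.01


@dataclass(frozen=True)
class StepApprox:
    """An approximate step function family.

    Parameters
    ----------
    kind:
        One of :data:`KINDS`.
    theta:
        Sharpness; psi converges to the exact step function as theta grows.
    p:
        Exponent for the lpPos (0 < p < 1) and lpNeg (p < 0) families.
    a:
        SCAD shoulder parameter (a > 2).
    """

    kind: str = "cappedL1"
    theta: float = 0.5
    p: float | None = None
    a: float = 3.7

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown step-approximation kind {self.kind!r}")
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.kind == "lpPos":
            p = 0.5 if self.p is None else self.p
            if not 0 < p < 1:
                raise ValueError("lpPos requires 0 < p < 1")
            object.__setattr__(self, "p", p)
        elif self.kind == "lpNeg":
            p = -1.0 if self.p is None else self.p
            if not p < 0:
                raise ValueError("lpNeg requires p < 0")
            object.__setattr__(self, "p", p)
        if self.kind == "scad" and not self.a > 2:
            raise ValueError("scad requires a > 2")

    def with_theta(self, theta: float) -> "StepApprox":
        return StepApprox(self.kind, theta, self.p, self.a)

    # -- psi and its derivative on u = |t| >= 0 -------------------------------

    def _psi_u(self, u: np.ndarray) -> np.ndarray:
        th = self.theta
        if self.kind == "cappedL1":
            return np.minimum(1.0, th * u)
        if self.kind == "exp":
            return -np.expm1(-th * u)
        if self.kind == "log":
            return np.minimum(1.0, np.log1p(th * u) / np.log(2.0))
        if self.kind == "scad":
            lam = 1.0 / th
            a = self.a
            top = lam * lam * (a + 1.0) / 2.0
            rho = np.where(
                u <= lam,
                lam * u,
                np.where(
                    u <= a * lam,
                    (2.0 * a * lam * u - u * u - lam * lam) / (2.0 * (a - 1.0)),
                    top,
                ),
            )
            return rho / top
        if self.kind == "lpPos":
            p = self.p
            u0 = _LP_POS_KNEE ** (1.0 / p) / th
            outer = np.minimum(1.0, (th * u) ** p)
            inner = _LP_POS_KNEE * u / u0
            return np.where(u <= u0, inner, outer)
        if self.kind == "lpNeg":
            return 1.0 - (1.0 + th * u) ** self.p
        raise AssertionError(self.kind)

    def _dpsi_u(self, u: np.ndarray) -> np.ndarray:
        """Derivative of psi w.r.t. u at u > 0 (right-derivative at kinks)."""
        th = self.theta
        if self.kind == "cappedL1":
            return np.where(th * u < 1.0, th, 0.0)
        if self.kind == "exp":
            return th * np.exp(-th * u)
        if self.kind == "log":
            inside = np.log1p(th * u) < np.log(2.0)
            return np.where(inside, th / ((1.0 + th * u) * np.log(2.0)), 0.0)
        if self.kind == "scad":
            lam = 1.0 / th
            a = self.a
            top = lam * lam * (a + 1.0) / 2.0
            drho = np.where(
                u <= lam,
                lam,
                np.where(u <= a * lam, (a * lam - u) / (a - 1.0), 0.0),
            )
            return drho / top
        if self.kind == "lpPos":
            p = self.p
            u0 = _LP_POS_KNEE ** (1.0 / p) / th
            s_in = _LP_POS_KNEE / u0
            with np.errstate(divide="ignore"):
                d_out = np.where(
                    (th * u) ** p < 1.0,
                    p * th * np.where(u > 0, (th * np.maximum(u, 1e-300)) ** (p - 1.0), 0.0),
                    0.0,
                )
            return np.where(u <= u0, s_in, d_out)
        if self.kind == "lpNeg":
            return -self.p * th * (1.0 + th * u) ** (self.p - 1.0)
        raise AssertionError(self.kind)

    @property
    def s0(self) -> float:
        """Slope of psi at the origin — the linear majorant coefficient."""
        th = self.theta
        if self.kind in ("cappedL1", "exp"):
            return th
        if self.kind == "log":
            return th / np.log(2.0)
        if self.kind == "scad":
            lam = 1.0 / th
            return lam / (lam * lam * (self.a + 1.0) / 2.0)
        if self.kind == "lpPos":
            u0 = _LP_POS_KNEE ** (1.0 / self.p) / th
            return _LP_POS_KNEE / u0
        if self.kind == "lpNeg":
            return -self.p * th
        raise AssertionError(self.kind)


@dataclass
class DCProgram:
    """A difference-of-convex split zeta(t) = convex(t) - subtracted(t).

    Both components are convex; ``subgrad_subtracted`` returns an element of
    the subdifferential of the subtracted component (0 at the origin, by the
    symmetry of every family).
    """

    convex: Callable[[np.ndarray], float]
    subtracted: Callable[[np.ndarray], float]
    subgrad_subtracted: Callable[[np.ndarray], np.ndarray]
    approx: StepApprox = field(default_factory=StepApprox)
    mode: Mode = "minimize"

    def value(self, t: np.ndarray) -> float:
        return self.convex(t) - self.subtracted(t)


def eval_step(approx: StepApprox, t: np.ndarray) -> np.ndarray:
    """Componentwise psi(t) in [0, 1]."""
    t = np.asarray(t, dtype=float)
    return approx._psi_u(np.abs(t))


def _convex_piece(approx: StepApprox, t: np.ndarray) -> float:
    """The convex remainder s0*sum|t| - sum psi(|t|) (>= 0)."""
    u = np.abs(np.asarray(t, dtype=float))
    return float(approx.s0 * u.sum() - approx._psi_u(u).sum())


def _subgrad_convex_piece(approx: StepApprox, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    u = np.abs(t)
    return np.sign(t) * (approx.s0 - approx._dpsi_u(u))


def dc_decompose(approx: StepApprox, mode: Mode = "minimize") -> DCProgram:
    """DC split of sum psi(t_j) (minimize) or sum (1 - psi(t_j)) (maximize).

    minimize:  sum psi   = [s0*sum|t|] - [s0*sum|t| - sum psi]
    maximize:  sum 1-psi = [s0*sum|t| - sum psi + n] - [s0*sum|t|]

    (the constant n is dropped; only differences matter to the solver).
    """
    if mode not in ("minimize", "maximize"):
        raise ValueError(f"mode must be 'minimize' or 'maximize', got {mode!r}")
    s0 = approx.s0
    if mode == "minimize":
        return DCProgram(
            convex=lambda t: float(s0 * np.abs(np.asarray(t, float)).sum()),
            subtracted=lambda t: _convex_piece(approx, t),
            subgrad_subtracted=lambda t: _subgrad_convex_piece(approx, t),
            approx=approx,
            mode=mode,
        )
    return DCProgram(
        convex=lambda t: _convex_piece(approx, t),
        subtracted=lambda t: float(s0 * np.abs(np.asarray(t, float)).sum()),
        subgrad_subtracted=lambda t: s0 * np.sign(np.asarray(t, float)),
        approx=approx,
        mode=mode,
    )


def subgrad_phi2(approx: StepApprox, mode: Mode, t: np.ndarray) -> np.ndarray:
    """Subgradient of the subtracted DC component at ``t`` (0 at the origin)."""
    return dc_decompose(approx, mode).subgrad_subtracted(np.asarray(t, dtype=float))
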