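"""The intermittently forced linear model on delay coordinates.

Given eigen-time-delay coordinates v_1 .. v_r, the first r-1 coordinates
are modeled as a linear time-invariant system driven by the last,
lowest-energy coordinate treated as an exogenous forcing input:

    d/dt v(t) = A v(t) + B v_r(t),        v = (v_1, ..., v_{r-1}).

A and B are found by least-squares regression of finite-difference
derivatives onto the coordinates; an optional sequentially thresholded
least-squares path yields sparse models.  For chaotic attractors the
fitted A is dominantly skew-symmetric with eigenvalues near the imaginary
axis — quiescent stretches of the trajectory are genuinely linear
oscillations, and all nonlinearity is concentrated in the forcing v_r.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "HavokModel",
    "StructureReport",
    "estimate_derivatives",
    "fit_havok",
    "simulate_model",
    "analyze_structure",
    "integerize_model",
]


@dataclass(frozen=True, eq=False)
class HavokModel:
    """Fitted forced linear model: A is (r-1)x(r-1), B is (r-1,).

    Units of A and B entries are 1/time.  ``r2`` holds the per-equation
    coefficient of determination of the regression.
    """

    A: np.ndarray
    B: np.ndarray
    r: int
    dt: float
    method: str = "least_squares"
    sparsity_threshold: float = 0.0
    derivative_scheme: str = "central4"
    r2: np.ndarray = None

    def __post_init__(self):
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.atleast_1d(np.asarray(self.B, dtype=float))
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        n = self.r - 1
        if A.shape != (n, n) or B.shape != (n,):
            raise ValueError(f"A must be {n}x{n} and B length {n} for r={self.r}")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
            raise ValueError("model coefficients must be finite")

    def propagator(self, dt: float = None) -> np.ndarray:
        """Discrete-time one-step map exp(A*dt), for diagnostics."""
        from scipy.linalg import expm

        return expm(self.A * (self.dt if dt is None else dt))

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "r": self.r,
            "dt": self.dt,
            "method": self.method,
            "sparsity_threshold": self.sparsity_threshold,
            "derivative_scheme": self.derivative_scheme,
            "r2": None if self.r2 is None else np.asarray(self.r2).tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "HavokModel":
        if d.get("format_version") != 1:
            raise ValueError("unsupported model format version")
        return cls(
            A=np.array(d["A"], dtype=float),
            B=np.array(d["B"], dtype=float),
            r=int(d["r"]),
            dt=float(d["dt"]),
            method=d.get("method", "least_squares"),
            sparsity_threshold=float(d.get("sparsity_threshold", 0.0)),
            derivative_scheme=d.get("derivative_scheme", "central4"),
            r2=None if d.get("r2") is None else np.array(d["r2"], dtype=float),
        )

    @classmethod
    def load(cls, path) -> "HavokModel":
        path = Path(path)
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: corrupted model JSON ({exc})") from exc
        missing = {"A", "B", "r", "dt"} - set(d)
        if missing:
            raise ValueError(f"{path}: model JSON missing fields {sorted(missing)}")
        return cls.from_dict(d)


@dataclass(frozen=True)
class StructureReport:
    """Summary of the algebraic structure of a fitted A matrix.

    skew_ratio = ||sym(A)||_F / ||A||_F, 0 for exactly skew-symmetric A;
    max_real_eig is the spectral abscissa (growth rate of the autonomous
    part); near_integer_fraction is the fraction of large entries
    (|A_ij| > 1) lying within 1.0 of an integer multiple of ``base``.
    """

    skew_ratio: float
    max_real_eig: float
    near_integer_fraction: float
    base: float = 5.0


def estimate_derivatives(V: np.ndarray, dt: float) -> np.ndarray:
    """Fourth-order central differences on interior points.

    d/dt f_i ~ (f_{i-2} - 8 f_{i-1} + 8 f_{i+1} - f_{i+2}) / (12 dt).
    Two samples are trimmed at each end; the output is aligned with
    ``V[2:-2]``.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float).T).T  # keep 1-D input working
    if V.shape[0] < 5:
        raise ValueError("need at least 5 samples for 4th-order differences")
    if not dt > 0:
        raise ValueError("dt must be positive")
    return (V[:-4] - 8.0 * V[1:-3] + 8.0 * V[3:-1] - V[4:]) / (12.0 * dt)


def _lstsq_r2(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    W, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient regressors (rank {rank} < {X.shape[1]}); "
            "coefficients from pseudo-inverse",
            stacklevel=3,
        )
    resid = Y - X @ W
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return W, r2


def _stls(X: np.ndarray, Y: np.ndarray, threshold: float, max_iter: int = 25):
    """Sequentially thresholded least squares, column by column of Y."""
    W, r2 = _lstsq_r2(X, Y)
    if threshold <= 0:
        return W, r2
    for j in range(Y.shape[1]):
        support = np.abs(W[:, j]) >= threshold
        w = np.zeros(X.shape[1])
        for _ in range(max_iter):
            w = np.zeros(X.shape[1])
            if support.any():
                w[support] = np.linalg.lstsq(X[:, support], Y[:, j], rcond=None)[0]
            new_support = np.abs(w) >= threshold
            if np.array_equal(new_support, support):
                break
            support = new_support
        w[~support] = 0.0
        W[:, j] = w
        resid = Y[:, j] - X @ w
        ss_tot = np.sum((Y[:, j] - Y[:, j].mean()) ** 2)
        r2[j] = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return W, r2


def fit_havok(
    V: np.ndarray,
    dt: float,
    r: int = None,
    dV: np.ndarray = None,
    method: str = "least_squares",
    sparsity_threshold: float = 0.0,
) -> HavokModel:
    """Regress coordinate derivatives onto the coordinates.

    Parameters
    ----------
    V : (n, >=r) array
        Eigen-time-delay coordinate series (rows are time samples).
    dt : float
        Sample interval of the rows.
    r : int
        Truncation rank; the model has r-1 states and v_r as input.
        Defaults to the number of columns of V.
    dV : (n-4, >=r-1) array, optional
        Derivatives aligned with ``V[2:-2]``; computed by 4th-order
        central differences when omitted.
    method : "least_squares" or "sparse"
        "sparse" applies sequentially thresholded least squares with
        ``sparsity_threshold``; with threshold 0 it coincides with plain
        least squares.
    """
    V = np.asarray(V, dtype=float)
    if r is None:
        r = V.shape[1]
    r = int(r)
    if r < 3:
        raise ValueError("r must be >= 3 (at least a 2-state model plus forcing)")
    if V.shape[1] < r:
        raise ValueError(f"V has {V.shape[1]} columns, need >= r={r}")
    if dV is None:
        dV = estimate_derivatives(V[:, :r], dt)
        X = V[2:-2, :r]
    else:
        dV = np.asarray(dV, dtype=float)
        if dV.shape[0] != V.shape[0]:
            raise ValueError("explicit dV must be row-aligned with V")
        X = V[:, :r]
    if X.shape[0] <= r:
        raise ValueError("need more samples than regressors")
    Y = dV[:, : r - 1]
    if method == "least_squares":
        W, r2 = _lstsq_r2(X, Y)
    elif method == "sparse":
        W, r2 = _stls(X, Y, sparsity_threshold)
    else:
        raise ValueError(f"unknown regression method {method!r}")
    A = W[: r - 1, :].T
    B = W[r - 1, :]
    return HavokModel(
        A=A, B=B, r=r, dt=dt, method=method,
        sparsity_threshold=float(sparsity_threshold), r2=r2,
    )


def simulate_model(
    model: HavokModel,
    forcing: np.ndarray,
    v0: np.ndarray,
    dt: float = None,
) -> np.ndarray:
    """Integrate dv/dt = A v + B u(t) with a measured forcing signal.

    The forcing is sampled uniformly at ``dt`` (defaults to the model's);
    between samples it is linearly interpolated, so the RK4 half-step uses
    the midpoint average.  The output (len(forcing), r-1) is sampled at
    the forcing timestamps, starting from ``v0``.
    """
    forcing = np.asarray(forcing, dtype=float)
    if not np.all(np.isfinite(forcing)):
        raise ValueError("forcing contains non-finite values")
    h = model.dt if dt is None else float(dt)
    A, B = model.A, model.B
    n = forcing.size
    v = np.empty((n, A.shape[0]))
    v[0] = np.asarray(v0, dtype=float)
    if v[0].shape != (A.shape[0],):
        raise ValueError(f"v0 must have length {A.shape[0]}")
    for k in range(n - 1):
        u0, u1 = forcing[k], forcing[k + 1]
        um = 0.5 * (u0 + u1)
        x = v[k]
        k1 = A @ x + B * u0
        k2 = A @ (x + 0.5 * h * k1) + B * um
        k3 = A @ (x + 0.5 * h * k2) + B * um
        k4 = A @ (x + h * k3) + B * u1
        x_next = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        v[k + 1] = x_next
        if not np.all(np.isfinite(x_next)):
            raise FloatingPointError(f"simulation diverged at t = {(k + 1) * h:.6g}")
    return v


def analyze_structure(model: HavokModel, base: float = 5.0) -> StructureReport:
    """Quantify skew-symmetry, stability and near-integer structure of A."""
    A = model.A
    norm = np.linalg.norm(A)
    sym = 0.5 * (A + A.T)
    skew_ratio = float(np.linalg.norm(sym) / norm) if norm > 0 else 0.0
    max_real_eig = float(np.max(np.linalg.eigvals(A).real))
    big = np.abs(A) > 1.0
    if big.any():
        vals = A[big]
        dist = np.abs(vals - base * np.round(vals / base))
        near_integer_fraction = float(np.mean(dist < 1.0))
    else:
        near_integer_fraction = 0.0
    return StructureReport(
        skew_ratio=skew_ratio,
        max_real_eig=max_real_eig,
        near_integer_fraction=near_integer_fraction,
        base=float(base),
    )


def integerize_model(model: HavokModel, base: float = 5.0) -> HavokModel:
    """Snap every coefficient to the nearest integer multiple of ``base``.

    Entries with magnitude at most base/2 round to 0.  Returns a modified
    copy; the input model is untouched.
    """
    A = base * np.round(model.A / base)
    B = base * np.round(model.B / base)
    return replace(model, A=A, B=B, method=model.method + "+integerized")
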