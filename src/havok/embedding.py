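"""Hankel matrix construction and eigen-time-delay coordinates.

A scalar series x(t) sampled at dt is stacked into a Hankel matrix H whose
q rows are successively shifted copies of the signal.  The economy SVD
H = U S V* yields delay modes U (window shapes, ordered by energy — for
smooth chaotic signals they resemble polynomials of increasing order) and
eigen-time-delay coordinate series V.  Truncating at rank r gives the
coordinate system in which the forced linear model is fit.

New data is projected into a fitted embedding by sliding a length-q window
over the series and applying S^-1 U^T; the coordinate for each window is
time-stamped at the window's final sample, so projected coordinates lag
the raw measurement by (q-1)*dt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .systems import TimeSeries

__all__ = [
    "HankelMatrix",
    "DelayEmbedding",
    "build_hankel",
    "compute_embedding",
    "project_coordinates",
]


@dataclass(frozen=True, eq=False)
class HankelMatrix:
    """q x p Hankel matrix of a time series (constant anti-diagonals).

    ``data`` is a strided view into the source signal; entry (i, j) is
    sample i + j, so p = m - q + 1 for a length-m series.
    """

    data: np.ndarray
    q: int
    p: int
    dt: float

    @property
    def shape(self):
        return (self.q, self.p)


def build_hankel(series: TimeSeries, q: int) -> HankelMatrix:
    """Stack ``series`` into a Hankel matrix with ``q`` rows.

    Row i (0-based) holds samples i .. i + m - q; all windows are fully
    contained in the series (no padding).  The returned ``data`` is a
    read-only view, so the matrix costs no extra memory.
    """
    q = int(q)
    if q < 2:
        raise ValueError("q must be >= 2")
    m = len(series)
    if m < q + 1:
        raise ValueError(f"series of length {m} too short for q={q} (need >= q+1)")
    windows = sliding_window_view(series.values, q)  # (p, q) view
    data = windows.T  # (q, p), still a view
    return HankelMatrix(data=data, q=q, p=m - q + 1, dt=series.dt)


@dataclass(frozen=True, eq=False)
class DelayEmbedding:
    """Rank-r truncated SVD of a Hankel matrix.

    U : (q, r) orthonormal delay-mode shapes.
    S : (r,) nonincreasing positive singular values.
    V : (p, r) orthonormal eigen-time-delay coordinate series
        (row k is the coordinate vector of window k).
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    r: int
    q: int
    dt: float
    singular_values_full: np.ndarray = None  # all min(q,p) values, for diagnostics
    name: str = ""

    def truncate(self, r: int) -> "DelayEmbedding":
        """Re-truncate to a smaller rank without recomputing the SVD."""
        if not 2 <= r <= self.r:
            raise ValueError(f"r must be in [2, {self.r}]")
        return replace(
            self, U=self.U[:, :r], S=self.S[:r], V=self.V[:, :r], r=int(r)
        )

    @property
    def coordinate_times(self) -> np.ndarray:
        """Times of the V rows: each window reports at its final sample."""
        return self.dt * (self.q - 1 + np.arange(self.V.shape[0]))

    # ---- serialization -------------------------------------------------
    def save(self, path) -> None:
        """Write U, S, V as CSV matrices plus a JSON header to a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "U.csv", self.U, delimiter=",", fmt="%.17g")
        np.savetxt(path / "S.csv", self.S, delimiter=",", fmt="%.17g")
        np.savetxt(path / "V.csv", self.V, delimiter=",", fmt="%.17g")
        header = {
            "format_version": 1,
            "q": self.q,
            "r": self.r,
            "dt": self.dt,
            "name": self.name,
            "sign_convention": "largest-magnitude entry of each U column positive",
        }
        (path / "embedding.json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path) -> "DelayEmbedding":
        path = Path(path)
        header = json.loads((path / "embedding.json").read_text())
        if header.get("format_version") != 1:
            raise ValueError(f"{path}: unsupported embedding format version")
        U = np.loadtxt(path / "U.csv", delimiter=",", ndmin=2)
        S = np.atleast_1d(np.loadtxt(path / "S.csv", delimiter=","))
        V = np.loadtxt(path / "V.csv", delimiter=",", ndmin=2)
        return cls(
            U=U, S=S, V=V, r=int(header["r"]), q=int(header["q"]),
            dt=float(header["dt"]), name=header.get("name", ""),
        )


def _fix_signs(U: np.ndarray, V: np.ndarray) -> None:
    """Resolve SVD sign ambiguity: largest-|entry| of each U column positive."""
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] *= -1.0
            V[:, j] *= -1.0


def compute_embedding(
    H: HankelMatrix, r: int, method: str = "direct", name: str = ""
) -> DelayEmbedding:
    """Economy SVD of the Hankel matrix, truncated to rank ``r``.

    method="direct" uses a LAPACK economy SVD of the full q x p matrix.
    method="snapshots" diagonalizes the q x q Gram matrix H H^T instead,
    which is cheaper for very long series but squares the condition
    number, degrading the trailing singular triplets; use it only when r
    is well inside the numerically resolved part of the spectrum.
    """
    r = int(r)
    if not 2 <= r <= min(H.q, H.p):
        raise ValueError(f"r={r} out of range [2, {min(H.q, H.p)}]")
    if not np.all(np.isfinite(H.data)):
        raise ValueError("Hankel matrix contains non-finite entries")
    if method == "direct":
        U, s, Vt = np.linalg.svd(np.ascontiguousarray(H.data), full_matrices=False)
        V_full = Vt.T
        U_r, S_r, V_r = U[:, :r].copy(), s[:r].copy(), V_full[:, :r].copy()
        s_full = s
    elif method == "snapshots":
        G = H.data @ H.data.T  # q x q
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        s_full = np.sqrt(evals)
        U_r = evecs[:, order[:r]]
        S_r = s_full[:r]
        if np.any(S_r <= 0):
            raise np.linalg.LinAlgError(
                "requested rank exceeds numerical rank in snapshot SVD"
            )
        V_r = (H.data.T @ U_r) / S_r
        U_r, S_r = U_r.copy(), S_r.copy()
    else:
        raise ValueError(f"unknown SVD method {method!r}")
    _fix_signs(U_r, V_r)
    return DelayEmbedding(
        U=U_r, S=S_r, V=V_r, r=r, q=H.q, dt=H.dt,
        singular_values_full=s_full, name=name,
    )


def project_coordinates(
    series: TimeSeries, emb: DelayEmbedding, chunk: int = 1 << 16
) -> tuple[np.ndarray, np.ndarray]:
    """Project a series into a fitted embedding's coordinate system.

    Each fully contained length-q window h_k maps to v_k = S^-1 U^T h_k.
    Returns ``(times, V_new)`` where ``V_new`` has shape (m - q + 1, r)
    and ``times[k]`` is the time of window k's final sample, i.e. the
    coordinates carry a (q-1)*dt reporting delay relative to the raw
    measurement.  Applied to the training series this reproduces the
    embedding's own V rows.
    """
    if not np.isclose(series.dt, emb.dt, rtol=1e-9, atol=0.0):
        raise ValueError(f"dt mismatch: series {series.dt} vs embedding {emb.dt}")
    q = emb.q
    if len(series) < q:
        raise ValueError(f"series length {len(series)} shorter than window q={q}")
    windows = sliding_window_view(series.values, q)  # (p', q) view
    W = emb.U / emb.S  # (q, r); v = h^T U S^-1
    out = np.empty((windows.shape[0], emb.r))
    for i in range(0, windows.shape[0], chunk):
        out[i : i + chunk] = windows[i : i + chunk] @ W
    times = series.t0 + series.dt * (q - 1 + np.arange(windows.shape[0]))
    return times, out
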