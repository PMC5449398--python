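"""Ulam discretization of the transfer operator and almost-invariant sets.

The Perron-Frobenius (transfer) operator propagates densities under the
flow; its dominant non-trivial eigenfunctions reveal almost-invariant
sets — regions of phase space that map nearly onto themselves over the
chosen lag.  We approximate the operator on the embedded attractor
(coordinates v1, v2, v3) by Ulam's method: partition the point cloud into
boxes, count box-to-box transitions of the trajectory at a fixed lag, and
row-normalize into a sparse stochastic matrix P.

Because a trajectory average samples the invariant measure pi, the
additive reversibilization R = (P + P_hat)/2 with
P_hat_ij = pi_j P_ji / pi_i has real spectrum, and thresholding its
second right eigenvector at level 0 splits the boxes into two
almost-invariant sets.  This partition can be compared against the
linear/nonlinear partition induced by the HAVOK forcing activity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "UlamPartition",
    "make_grid",
    "assign_boxes",
    "transition_matrix",
    "almost_invariant_sets",
    "compare_partitions",
    "ulam_partition",
]


@dataclass(frozen=True, eq=False)
class UlamPartition:
    """Box discretization of the embedded attractor plus spectral partition.

    ``occupied`` holds flat grid indices of retained boxes, in the order
    used by rows/columns of ``P`` and ``R``; ``set_labels`` assigns each
    occupied box to almost-invariant set 1 or 2.
    """

    edges: list  # per-axis bin edges
    occupied: np.ndarray
    P: sp.csr_matrix
    pi: np.ndarray
    R: sp.csr_matrix
    eigvals: np.ndarray  # real, descending
    second_eigvec: np.ndarray
    set_labels: np.ndarray
    lag: int
    dropped_boxes: np.ndarray = None  # boxes with no outgoing transition

    @property
    def n_boxes(self) -> int:
        return self.occupied.size

    @property
    def grid_shape(self) -> tuple:
        return tuple(len(e) - 1 for e in self.edges)

    def box_centers(self) -> np.ndarray:
        """(n_boxes, d) centers of the occupied boxes."""
        shape = self.grid_shape
        multi = np.unravel_index(self.occupied, shape)
        centers = [0.5 * (e[:-1] + e[1:]) for e in self.edges]
        return np.column_stack([c[i] for c, i in zip(centers, multi)])

    def save(self, path) -> None:
        """Export P as (row, col, value) triplets plus box centers and labels."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        coo = self.P.tocoo()
        np.savetxt(
            path / "P.txt",
            np.column_stack([coo.row, coo.col, coo.data]),
            fmt=["%d", "%d", "%.17g"],
        )
        centers = self.box_centers()
        np.savetxt(
            path / "boxes.csv",
            np.column_stack([self.occupied, centers, self.pi, self.set_labels]),
            delimiter=",",
            header="flat_index," + ",".join(f"c{i+1}" for i in range(centers.shape[1]))
            + ",pi,set_label",
            fmt="%.17g",
            comments="",
        )
        header = {
            "format_version": 1,
            "lag": int(self.lag),
            "eigvals": [float(v) for v in self.eigvals],
            "edges": [e.tolist() for e in map(np.asarray, self.edges)],
        }
        (path / "partition.json").write_text(json.dumps(header))


def make_grid(points: np.ndarray, n_bins: int = 40, pad: float = 0.01) -> list:
    """Per-axis bin edges covering the point cloud, padded by ``pad`` relative."""
    points = np.atleast_2d(points)
    edges = []
    for k in range(points.shape[1]):
        lo, hi = points[:, k].min(), points[:, k].max()
        span = hi - lo if hi > lo else max(abs(lo), 1.0)
        edges.append(np.linspace(lo - pad * span, hi + pad * span, n_bins + 1))
    return edges


def assign_boxes(points: np.ndarray, edges: list) -> np.ndarray:
    """Flat box index of every point under half-open bins [e_k, e_{k+1}).

    The last bin of each axis is closed.  Points outside the grid raise.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    shape = tuple(len(e) - 1 for e in edges)
    multi = []
    for k, e in enumerate(edges):
        col = points[:, k]
        if col.min() < e[0] or col.max() > e[-1]:
            bad = int(np.argmax((col < e[0]) | (col > e[-1])))
            raise ValueError(f"point {bad} outside grid on axis {k}")
        idx = np.searchsorted(e, col, side="right") - 1
        idx[col == e[-1]] = shape[k] - 1  # close the last bin
        multi.append(idx)
    return np.ravel_multi_index(multi, shape)


def transition_matrix(
    box_sequence: np.ndarray, lag: int = 1
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray, np.ndarray]:
    """Ulam transition matrix from a box-index sequence at a fixed lag.

    P_ij = (# transitions box i -> box j over ``lag`` steps) / (# visits
    to i with a successor); pi is the empirical visit frequency of each
    box over the whole sequence.  Boxes with no outgoing transition are
    dropped from P (and recorded).

    Returns ``(P, pi, occupied, dropped)`` where ``occupied`` maps row
    indices of P back to the input box labels.
    """
    seq = np.asarray(box_sequence)
    lag = int(lag)
    if seq.size <= lag:
        raise ValueError("sequence must be longer than the lag")
    occupied, inverse = np.unique(seq, return_inverse=True)
    n = occupied.size
    counts = np.bincount(inverse, minlength=n).astype(float)
    pi = counts / counts.sum()
    src, dst = inverse[:-lag], inverse[lag:]
    C = sp.coo_matrix((np.ones(src.size), (src, dst)), shape=(n, n)).tocsr()
    row_sums = np.asarray(C.sum(axis=1)).ravel()
    keep = row_sums > 0
    dropped = occupied[~keep]
    if dropped.size:
        C = C[keep][:, keep]
        occupied = occupied[keep]
        pi = pi[keep]
        pi = pi / pi.sum()
        row_sums = np.asarray(C.sum(axis=1)).ravel()
        zero_after = row_sums == 0
        if zero_after.any():
            # transitions into dropped boxes can empty further rows; give
            # those a self-loop rather than iterating removals
            C = C.tolil()
            for i in np.nonzero(zero_after)[0]:
                C[i, i] = 1.0
            C = C.tocsr()
            row_sums = np.asarray(C.sum(axis=1)).ravel()
    P = C.tocsr().astype(float)
    # divide (not multiply by reciprocal) so count/count == 1 exactly
    P.data = P.data / np.repeat(row_sums, np.diff(P.indptr))
    return P, pi, occupied, dropped


def almost_invariant_sets(
    P: sp.csr_matrix, pi: np.ndarray, n_sets: int = 2, return_eigvec: bool = False
):
    """Two-set almost-invariant partition from the reversibilized matrix.

    R = (P + P_hat)/2 with P_hat_ij = pi_j P_ji / pi_i is pi-reversible,
    so D^{1/2} R D^{-1/2} (D = diag(pi)) is symmetric with real spectrum.
    Box labels come from the sign of the second right eigenvector of R
    (level set at 0).  Returns ``(R, eigvals, labels)`` with eigvals the
    two leading eigenvalues in descending order and labels in {1, 2}.
    """
    if n_sets != 2:
        raise NotImplementedError("only the two-set (sign) partition is implemented")
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("pi must be positive on occupied boxes")
    n = P.shape[0]
    Dinv = sp.diags(1.0 / pi)
    D = sp.diags(pi)
    P_hat = Dinv @ P.T @ D
    R = ((P + P_hat) * 0.5).tocsr()

    n_comp, comp = connected_components(R, directed=True, connection="weak")
    if n_comp > 1:
        warnings.warn(
            f"transition graph has {n_comp} weakly connected components; "
            "labeling by component"
        )
        labels = np.where(comp == np.bincount(comp).argmax(), 1, 2)
        vec = np.where(labels == 1, 1.0, -1.0)
        out = (R, np.array([1.0, 1.0]), labels)
        return out + (vec,) if return_eigvec else out

    sqrt_pi = np.sqrt(pi)
    S = sp.diags(sqrt_pi) @ R @ sp.diags(1.0 / sqrt_pi)
    S = (S + S.T) * 0.5  # symmetrize roundoff
    if n <= 400:
        evals, evecs = np.linalg.eigh(S.toarray())
        idx = np.argsort(evals)[::-1][:2]
        evals, evecs = evals[idx], evecs[:, idx]
    else:
        evals, evecs = sp.linalg.eigsh(S, k=2, which="LA")
        idx = np.argsort(evals)[::-1]
        evals, evecs = evals[idx], evecs[:, idx]
    second = evecs[:, 1] / sqrt_pi  # right eigenvector of R
    if abs(evals[1]) < 1e-12:
        warnings.warn("second eigenvalue ~ 0: no almost-invariant structure; labels degenerate")
    # deterministic orientation: first entry non-negative
    if second[np.argmax(np.abs(second))] < 0:
        second = -second
    labels = np.where(second >= 0, 1, 2)
    out = (R, evals[:2], labels)
    return out + (second,) if return_eigvec else out


def compare_partitions(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Best-matching agreement between two binary partitions of the samples.

    Agreement is the fraction of concordant samples maximized over the
    two possible label matchings, so it is invariant to swapping set
    names.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    same = float(np.mean(a == b))
    return {"agreement": max(same, 1.0 - same), "n_samples": int(a.size)}


def boundary_distance(
    partition: UlamPartition, boundary_points: np.ndarray
) -> float:
    """Median distance from given points to the nearest set-boundary box center.

    A boundary box is an occupied box with an occupied axis-neighbor of
    the other label.  Used to quantify how closely the HAVOK
    linear/nonlinear boundary tracks the almost-invariant set boundary.
    """
    shape = partition.grid_shape
    multi = np.column_stack(np.unravel_index(partition.occupied, shape))
    label_of = dict(zip(map(tuple, multi), partition.set_labels))
    is_boundary = np.zeros(partition.n_boxes, dtype=bool)
    for i, cell in enumerate(map(tuple, multi)):
        for ax in range(len(shape)):
            for step in (-1, 1):
                nb = list(cell)
                nb[ax] += step
                other = label_of.get(tuple(nb))
                if other is not None and other != partition.set_labels[i]:
                    is_boundary[i] = True
                    break
            if is_boundary[i]:
                break
    centers = partition.box_centers()[is_boundary]
    if centers.shape[0] == 0:
        return float("nan")
    tree = cKDTree(centers)
    dist, _ = tree.query(np.atleast_2d(boundary_points))
    return float(np.median(dist))


def ulam_partition(
    points: np.ndarray,
    n_bins: int = 40,
    lag: int = 100,
    min_count: int = 5,
) -> UlamPartition:
    """Full Ulam pipeline on an embedded trajectory.

    Boxes visited fewer than ``min_count`` times are merged into the
    nearest well-sampled box (by center distance) to stabilize the
    empirical invariant measure before the spectral analysis.
    """
    points = np.atleast_2d(points)
    edges = make_grid(points, n_bins=n_bins)
    boxes = assign_boxes(points, edges)

    if min_count > 1:
        ids, counts = np.unique(boxes, return_counts=True)
        rare = ids[counts < min_count]
        solid = ids[counts >= min_count]
        if rare.size and solid.size:
            shape = tuple(len(e) - 1 for e in edges)
            centers = [0.5 * (e[:-1] + e[1:]) for e in edges]

            def _centers_of(flat):
                multi = np.unravel_index(flat, shape)
                return np.column_stack([c[i] for c, i in zip(centers, multi)])

            tree = cKDTree(_centers_of(solid))
            _, nearest = tree.query(_centers_of(rare))
            remap = dict(zip(rare, solid[nearest]))
            boxes = np.array([remap.get(b, b) for b in boxes])

    P, pi, occupied, dropped = transition_matrix(boxes, lag=lag)
    R, eigvals, labels, second = almost_invariant_sets(P, pi, return_eigvec=True)
    return UlamPartition(
        edges=edges,
        occupied=occupied,
        P=P,
        pi=pi,
        R=R,
        eigvals=np.asarray(eigvals, dtype=float),
        second_eigvec=second,
        set_labels=labels,
        lag=int(lag),
        dropped_boxes=dropped,
    )
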