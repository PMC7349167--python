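"""Dense 2D EEG frames from sparse electrode grids.

A sparse frame has signal only at electrode cells.  To obtain a dense scalp
image f̂ the gaps are filled by Gaussian radial-basis-function interpolation:
with electrode grid coordinates x_i and observed values v_i, solve

    Phi @ lam = v,    Phi_ij = phi(||x_i - x_j||),    phi(r) = exp(-eps^2 r^2)

and evaluate f̂(x) = sum_i lam_i * phi(||x - x_i||) on a regular query grid
spanning the montage's [0, d-1] x [0, d-1] coordinate square.  Because the
weights solve the collocation system, the surface passes through every
measured electrode value — the interpolation fills zeros without disturbing
observations.

The shape parameter ``eps`` controls kernel width in grid-cell units; the
default 1.0 puts the kernel scale on the order of inter-electrode spacing.

Subject-level normalization (z-scoring each channel over all of a subject's
retained samples) lives here too, since frames are only comparable across
electrodes after it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.linalg
from scipy.interpolate import RegularGridInterpolator

from .montage import ElectrodeMontage, SparseFrame, place_vector

__all__ = [
    "GaussianRBF",
    "normalize_subject",
    "fit_rbf",
    "evaluate_rbf",
    "make_frame",
    "FrameMaker",
]

logger = logging.getLogger(__name__)

#: condition-number ceiling above which the collocation system is rejected
MAX_CONDITION = 1e12

InterpMode = Literal["direct", "two_stage"]


class IllConditionedError(np.linalg.LinAlgError):
    """Collocation matrix is numerically singular for the requested shape parameter."""


@dataclass
class GaussianRBF:
    """Fitted Gaussian RBF interpolant.

    Attributes
    ----------
    node_coords : (n, 2) array
        Electrode (row, col) grid coordinates.
    weights : (n,) or (n, m) array
        Collocation weights lambda; a second axis interpolates m fields that
        share the same nodes (used to densify whole windows at once).
    shape_param : float
        Gaussian shape parameter eps in phi(r) = exp(-eps^2 r^2).
    extent : float
        Half-open evaluation square is [0, extent]^2 (extent = d - 1).
    """

    node_coords: np.ndarray
    weights: np.ndarray
    shape_param: float
    extent: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the interpolant at (m, 2) query points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        sq = (
            ((points[:, None, :] - self.node_coords[None, :, :]) ** 2).sum(-1)
        )
        k = np.exp(-(self.shape_param**2) * sq)
        return k @ self.weights


def normalize_subject(trials: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Z-score each channel over all of one subject's concatenated samples.

    Every trial must share the channel count.  A channel whose pooled standard
    deviation is below 1e-12 carries no signal; it is zeroed and a warning is
    logged rather than dividing by ~0.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial to normalize")
    trials = [np.asarray(t, dtype=float) for t in trials]
    n_ch = trials[0].shape[0]
    if any(t.ndim != 2 or t.shape[0] != n_ch for t in trials):
        raise ValueError("all trials must be 2-D with a common channel count")
    pooled = np.concatenate(trials, axis=1)
    mean = pooled.mean(axis=1)
    std = pooled.std(axis=1)
    degenerate = std < 1e-12
    if np.any(degenerate):
        logger.warning(
            "channels %s are constant; set to zero during normalization",
            np.flatnonzero(degenerate).tolist(),
        )
    safe_std = np.where(degenerate, 1.0, std)
    out = []
    for t in trials:
        z = (t - mean[:, None]) / safe_std[:, None]
        z[degenerate, :] = 0.0
        out.append(z)
    return out


def _collocation_matrix(coords: np.ndarray, shape_param: float) -> np.ndarray:
    sq = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    return np.exp(-(shape_param**2) * sq)


def fit_rbf(
    frame: SparseFrame,
    montage: ElectrodeMontage,
    shape_param: float = 1.0,
    ridge: float = 0.0,
) -> GaussianRBF:
    """Solve the Gaussian-RBF collocation system for one sparse frame.

    Parameters
    ----------
    frame : SparseFrame
        Electrode values on the montage grid (occupied cells must match the
        montage placements).
    shape_param : float
        eps > 0; smaller values widen the kernel.
    ridge : float
        Optional Tikhonov term added to the diagonal for ill-conditioned
        montages (default 0: exact interpolation).
    """
    if shape_param <= 0:
        raise ValueError("shape_param must be positive")
    coords = montage.grid_coords()
    occ_cells = {(p.row, p.col) for p in montage.placements}
    frame_cells = set(map(tuple, np.argwhere(frame.occupied)))
    if frame_cells != occ_cells:
        raise ValueError("frame occupancy does not match montage placements")
    v = np.array([frame.values[p.row, p.col] for p in montage.by_channel()])
    phi = _collocation_matrix(coords, shape_param)
    if ridge:
        phi = phi + ridge * np.eye(len(coords))
    cond = np.linalg.cond(phi)
    if cond > MAX_CONDITION:
        raise IllConditionedError(
            f"collocation matrix condition number {cond:.3g} exceeds "
            f"{MAX_CONDITION:.0e}; use a smaller shape_param or a ridge term"
        )
    weights = scipy.linalg.solve(phi, v, assume_a="sym")
    return GaussianRBF(
        node_coords=coords,
        weights=weights,
        shape_param=shape_param,
        extent=float(montage.grid_side - 1),
    )


def _query_grid(extent: float, out_height: int, out_width: int) -> np.ndarray:
    rows = np.linspace(0.0, extent, out_height)
    cols = np.linspace(0.0, extent, out_width)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def evaluate_rbf(interp: GaussianRBF, out_height: int, out_width: int) -> np.ndarray:
    """Evaluate the interpolant on a uniform out_height x out_width grid.

    Query points span the montage square [0, extent]^2 with inclusive
    endpoints, so electrode nodes are interior points and no extrapolation
    occurs.  Returns the dense frame as a 2-D array.
    """
    if out_height < 1 or out_width < 1:
        raise ValueError("output grid must be at least 1x1")
    pts = _query_grid(interp.extent, out_height, out_width)
    vals = interp(pts)
    return vals.reshape(out_height, out_width)


def _bilinear_resize(frame: np.ndarray, out_size: int) -> np.ndarray:
    d = frame.shape[0]
    if out_size == d:
        return frame.copy()
    rgi = RegularGridInterpolator(
        (np.arange(d, dtype=float), np.arange(d, dtype=float)), frame, method="linear"
    )
    pts = _query_grid(float(d - 1), out_size, out_size)
    return rgi(pts).reshape(out_size, out_size)


def make_frame(
    v: Sequence[float],
    montage: ElectrodeMontage,
    shape_param: float = 1.0,
    out_size: int = 64,
    mode: InterpMode = "direct",
    ridge: float = 0.0,
) -> np.ndarray:
    """Dense out_size x out_size EEG frame from one channel vector.

    ``mode="direct"`` fits the RBF at the electrode nodes and evaluates it
    straight onto the output grid.  ``mode="two_stage"`` first evaluates onto
    the native d x d grid and then bilinearly resizes — provided for ablation
    against pipelines that resize images after interpolation.
    """
    if out_size < montage.grid_side:
        raise ValueError(
            f"out_size {out_size} is smaller than the montage grid {montage.grid_side}"
        )
    interp = fit_rbf(place_vector(v, montage), montage, shape_param, ridge)
    if mode == "direct":
        return evaluate_rbf(interp, out_size, out_size)
    if mode == "two_stage":
        native = evaluate_rbf(interp, montage.grid_side, montage.grid_side)
        return _bilinear_resize(native, out_size)
    raise ValueError(f"unknown interpolation mode {mode!r}")


class FrameMaker:
    """Precomputed frame pipeline for one (montage, eps, out_size, mode) setting.

    Factors the collocation matrix once and caches the query-kernel matrix, so
    densifying a whole window of samples is two small matrix products instead
    of per-sample solves.  Output matches :func:`make_frame` to solver
    round-off.
    """

    def __init__(
        self,
        montage: ElectrodeMontage,
        shape_param: float = 1.0,
        out_size: int = 64,
        mode: InterpMode = "direct",
        ridge: float = 0.0,
    ) -> None:
        if shape_param <= 0:
            raise ValueError("shape_param must be positive")
        if out_size < montage.grid_side:
            raise ValueError(
                f"out_size {out_size} is smaller than the montage grid "
                f"{montage.grid_side}"
            )
        if mode not in ("direct", "two_stage"):
            raise ValueError(f"unknown interpolation mode {mode!r}")
        self.montage = montage
        self.shape_param = float(shape_param)
        self.out_size = int(out_size)
        self.mode: InterpMode = mode
        coords = montage.grid_coords()
        phi = _collocation_matrix(coords, self.shape_param)
        if ridge:
            phi = phi + ridge * np.eye(len(coords))
        cond = np.linalg.cond(phi)
        if cond > MAX_CONDITION:
            raise IllConditionedError(
                f"collocation matrix condition number {cond:.3g} exceeds "
                f"{MAX_CONDITION:.0e}; use a smaller shape_param or a ridge term"
            )
        self._cho = scipy.linalg.cho_factor(phi)
        extent = float(montage.grid_side - 1)
        eval_size = self.out_size if mode == "direct" else montage.grid_side
        pts = _query_grid(extent, eval_size, eval_size)
        sq = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        self._query_kernel = np.exp(-(self.shape_param**2) * sq)
        self._eval_size = eval_size

    def frame(self, v: Sequence[float]) -> np.ndarray:
        """Dense frame for one channel vector."""
        return self.frames(np.asarray(v, dtype=float)[:, None])[0]

    def frames(self, segment: np.ndarray) -> np.ndarray:
        """Dense frames for a channels x w segment, stacked as (w, size, size)."""
        segment = np.asarray(segment, dtype=float)
        if segment.ndim != 2 or segment.shape[0] != self.montage.n_electrodes:
            raise ValueError(
                f"segment must be ({self.montage.n_electrodes}, w), got {segment.shape}"
            )
        lam = scipy.linalg.cho_solve(self._cho, segment)  # (n_nodes, w)
        dense = (self._query_kernel @ lam).T.reshape(
            segment.shape[1], self._eval_size, self._eval_size
        )
        if self.mode == "two_stage" and self.out_size != self._eval_size:
            dense = np.stack([_bilinear_resize(f, self.out_size) for f in dense])
        return dense
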