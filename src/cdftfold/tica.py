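"""Time-lagged independent component analysis on dihedral features.

tICA finds the linear combinations of input features with the slowest
decorrelation: the generalized eigenproblem C(τ)·v = λ·C(0)·v, where
C(τ) is the symmetrized time-lagged covariance and C(0) the
instantaneous covariance of mean-free features.  The symmetrized
estimator used here averages the forward and reversed statistics of
both time windows, which guarantees a real spectrum with |λ| ≤ 1.

The first component (tIC1) serves as the folding coordinate: frames are
sampled along it by stratified equal-width binning, and free-energy
("kinetic") maps are built from 2-D histograms of the leading two
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .structures import DihedralTable

__all__ = [
    "TicaModel",
    "KineticMap",
    "featurize",
    "fit_tica",
    "project",
    "free_energy_map",
    "sample_along_tic1",
]


@dataclass
class TicaModel:
    lag: int
    mean: np.ndarray                 # feature mean
    eigenvalues: np.ndarray          # descending
    components: np.ndarray           # feature × component, C(0)-orthonormal
    kinetic_map: bool = True
    constant_columns: np.ndarray = field(default=None)  # flagged, not used

    @property
    def n_features(self) -> int:
        return len(self.mean)


@dataclass
class KineticMap:
    """Relative free energy −ln(p/p_max) on a 2-D grid over (tIC1, tIC2)."""

    values: np.ndarray       # (nx, ny); NaN on empty bins
    empty: np.ndarray        # (nx, ny) bool mask of empty bins
    x_edges: np.ndarray
    y_edges: np.ndarray


def featurize(tables: list[DihedralTable]) -> np.ndarray:
    """Embed φ/ψ angles as (sin θ, cos θ) pairs, frames × features.

    Angles undefined in the first frame (chain termini) are dropped from
    every frame; a frame whose defined-angle pattern differs raises.
    """
    if not tables:
        raise ValueError("no frames")
    ref = tables[0]
    masks = [np.isfinite(ref.phi), np.isfinite(ref.psi)]
    rows = []
    for t in tables:
        if len(t.phi) != len(ref.phi):
            raise ValueError("inconsistent residue sets across frames")
        if (not np.array_equal(np.isfinite(t.phi), masks[0])
                or not np.array_equal(np.isfinite(t.psi), masks[1])):
            raise ValueError("inconsistent dihedral definitions across "
                             "frames")
        ang = np.deg2rad(np.concatenate([t.phi[masks[0]], t.psi[masks[1]]]))
        rows.append(np.concatenate([np.sin(ang), np.cos(ang)]))
    return np.array(rows)


def fit_tica(features: np.ndarray, lag: int,
             regularization: float | None = None,
             kinetic_map: bool = True) -> TicaModel:
    """Fit a tICA model at lag time ``lag`` (frames).

    ``regularization`` is added to the diagonal of C(0); the default is
    1e−8·trace(C(0))/k, enough to handle duplicated or constant feature
    columns.  Pass 0 to disable (singular C(0) then raises).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be frames × features")
    T, k = X.shape
    if lag < 1:
        raise ValueError("lag must be >= 1 (lag 0 is the identity problem)")
    if T <= lag + 1:
        raise ValueError("need more frames than lag + 1")

    mean = X.mean(axis=0)
    Xc = X - mean
    constant = Xc.std(axis=0) < 1e-12
    X0, Xt = Xc[:-lag], Xc[lag:]
    n = T - lag
    c0 = (X0.T @ X0 + Xt.T @ Xt) / (2.0 * n)
    ct = (X0.T @ Xt + Xt.T @ X0) / (2.0 * n)

    if regularization is None:
        regularization = 1e-8 * np.trace(c0) / k
    c0r = c0 + regularization * np.eye(k)
    try:
        evals, evecs = scipy.linalg.eigh(ct, c0r)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "singular instantaneous covariance; increase regularization"
        ) from exc
    order = np.argsort(evals)[::-1]
    return TicaModel(
        lag=lag,
        mean=mean,
        eigenvalues=evals[order],
        components=evecs[:, order],
        kinetic_map=kinetic_map,
        constant_columns=constant,
    )


def project(model: TicaModel, features: np.ndarray,
            n_components: int = 2) -> np.ndarray:
    """Project features onto the leading tICA components.

    With the kinetic-map flag each component is scaled by its
    eigenvalue, so Euclidean distances in the projection approximate
    kinetic distances.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model {model.n_features}")
    n_components = min(n_components, model.components.shape[1])
    Y = (X - model.mean) @ model.components[:, :n_components]
    if model.kinetic_map:
        Y = Y * model.eigenvalues[:n_components]
    return Y


def free_energy_map(projections: np.ndarray,
                    bins: int | tuple[int, int] = 50) -> KineticMap:
    """2-D histogram of (tIC1, tIC2) turned into −ln(count/max count).

    Minimum value is 0 (the most populated bin); empty bins are NaN and
    flagged in ``empty`` rather than set to infinity.
    """
    P = np.asarray(projections, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("need projections with at least 2 components")
    if P.shape[0] < 2:
        raise ValueError("need at least 2 frames for a free-energy map")
    H, xe, ye = np.histogram2d(P[:, 0], P[:, 1], bins=bins)
    empty = H == 0
    F = np.full_like(H, np.nan)
    F[~empty] = -np.log(H[~empty] / H.max())
    return KineticMap(values=F, empty=empty, x_edges=xe, y_edges=ye)


def sample_along_tic1(projections: np.ndarray, n: int = 100) -> np.ndarray:
    """Stratified sample of ``n`` frame indices along tIC1, ordered.

    The tIC1 range is split into ``n`` equal-width bins; each non-empty
    bin contributes the frame nearest its center.  If fewer than ``n``
    bins are non-empty, remaining picks are backfilled with the nearest
    unused frames (by tIC1 distance to the empty bins' centers).  The
    result is ordered by tIC1 with no duplicates.
    """
    P = np.asarray(projections, dtype=float)
    tic1 = P[:, 0] if P.ndim == 2 else P
    n_frames = len(tic1)
    if n_frames < n:
        raise ValueError(f"only {n_frames} frames for {n} samples")
    lo, hi = tic1.min(), tic1.max()
    if hi - lo < 1e-12:
        raise ValueError("degenerate coordinate: tIC1 has zero range")
    edges = np.linspace(lo, hi, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.searchsorted(edges, tic1, side="right") - 1, 0, n - 1)

    chosen: list[int] = []
    taken = np.zeros(n_frames, dtype=bool)
    empty_centers = []
    for b in range(n):
        members = np.flatnonzero(which == b)
        if members.size == 0:
            empty_centers.append(centers[b])
            continue
        pick = members[np.argmin(np.abs(tic1[members] - centers[b]))]
        chosen.append(int(pick))
        taken[pick] = True
    for c in empty_centers:
        if len(chosen) >= n:
            break
        free = np.flatnonzero(~taken)
        pick = free[np.argmin(np.abs(tic1[free] - c))]
        chosen.append(int(pick))
        taken[pick] = True
    idx = np.array(chosen)
    return idx[np.argsort(tic1[idx], kind="stable")]
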