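"""eLORETA inverse operator and per-IC source-projection features.

eLORETA is a weighted minimum-norm inverse with depth weights determined by
a fixed-point iteration; for noiseless data from a single grid dipole its
source-power maximum falls on the true grid point (zero localization
error). The feature matrix stacks, for every independent component, the
source time courses estimated at the n_l fMRI-selected dipole locations
from that component's channel-space back-projection, giving (n_l × M) rows
over N_s samples (124 rows for M = 31 components and n_l = 4 dipoles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import EEGRecording
from .preprocess import ICADecomposition

logger = logging.getLogger(__name__)


@dataclass
class InverseOperator:
    """Linear source-estimation kernel: ``moments = kernel @ data``.

    ``kernel`` has shape (3 * n_sources, n_channels); three consecutive rows
    per source are its x/y/z moment components. ``converged`` reports whether
    the depth-weight fixed point reached ``tol`` within ``max_iter``.
    """

    kernel: np.ndarray
    grid: np.ndarray  # (n_sources, 3) mm
    spacing_mm: float
    alpha: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel rows must be finite")

    @property
    def n_sources(self) -> int:
        return self.grid.shape[0]

    def kernel_at(self, source_index: int) -> np.ndarray:
        """(3, n_channels) kernel block of one source."""
        return self.kernel[3 * source_index : 3 * source_index + 3]


def _block_sqrt(A: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Symmetric psd square root of a 3x3 block."""
    w, U = np.linalg.eigh((A + A.T) / 2.0)
    w = np.maximum(w, floor * max(w.max(), floor))
    return (U * np.sqrt(w)) @ U.T


def _block_inv(A: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    w, U = np.linalg.eigh((A + A.T) / 2.0)
    w = np.maximum(w, floor * max(w.max(), floor))
    return (U / w) @ U.T


def eloreta_kernel(
    leadfield,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> InverseOperator:
    """Iterative eLORETA depth weights and the resulting inverse kernel.

    Per source v the 3x3 weight block is updated as
    ``W_v = [L_v^T (L W^-1 L^T + alpha * (tr(G)/N) * H)^+ L_v]^(1/2)``
    with H the average-reference centering matrix, iterated to a fixed
    point (max relative Frobenius change of any block < ``tol``). The
    kernel is ``W^-1 L^T (L W^-1 L^T + alpha * (tr(G)/N) * H)^+``.

    ``alpha`` is dimensionless: it scales the trace-normalised channel gram.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    L = leadfield.gain
    n_ch = L.shape[0]
    n_src = leadfield.n_sources
    H = np.eye(n_ch) - np.ones((n_ch, n_ch)) / n_ch

    Lb = L.reshape(n_ch, n_src, 3)
    Winv = np.tile(np.eye(3), (n_src, 1, 1))
    converged = False
    iterations = 0
    W = np.tile(np.eye(3), (n_src, 1, 1))
    for iterations in range(1, max_iter + 1):
        # G = L W^-1 L^T accumulated over source blocks
        LWinv = np.einsum("cvk,vkl->cvl", Lb, Winv)
        G = np.einsum("cvl,dvl->cd", LWinv, Lb)
        reg = alpha * (np.trace(G) / n_ch)
        M = np.linalg.pinv(G + reg * H, hermitian=True)
        W_new = np.empty_like(W)
        ML = np.einsum("cd,dvk->cvk", M, Lb)
        for v in range(n_src):
            W_new[v] = _block_sqrt(Lb[:, v, :].T @ ML[:, v, :])
        num = np.linalg.norm(W_new - W, axis=(1, 2))
        den = np.linalg.norm(W, axis=(1, 2))
        change = float((num / np.maximum(den, 1e-300)).max())
        W = W_new
        for v in range(n_src):
            Winv[v] = _block_inv(W[v])
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "eLORETA weights did not converge in %d iterations "
            "(last change %.2e)", max_iter, change,
        )

    LWinv = np.einsum("cvk,vkl->cvl", Lb, Winv)
    G = np.einsum("cvl,dvl->cd", LWinv, Lb)
    reg = alpha * (np.trace(G) / n_ch)
    M = np.linalg.pinv(G + reg * H, hermitian=True)
    kernel = np.einsum("vkl,cvl,cd->vkd", Winv, Lb, M).reshape(3 * n_src, n_ch)
    return InverseOperator(
        kernel=kernel,
        grid=leadfield.grid,
        spacing_mm=leadfield.spacing_mm,
        alpha=alpha,
        iterations=iterations,
        converged=converged,
    )


def lcmv_kernel(
    leadfield,
    data_cov: np.ndarray,
    alpha: float = 0.05,
) -> InverseOperator:
    """Unit-gain LCMV vector beamformer behind the same kernel interface.

    ``W_v = (L_v^T C^-1 L_v)^-1 L_v^T C^-1`` with the data covariance C
    regularised by ``alpha * tr(C)/N`` on the diagonal. A secondary
    alternative to :func:`eloreta_kernel`; adaptive (data-dependent) rather
    than data-independent.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    L = leadfield.gain
    n_ch = L.shape[0]
    n_src = leadfield.n_sources
    C = np.asarray(data_cov, dtype=float)
    if C.shape != (n_ch, n_ch):
        raise ValueError(f"data covariance must be {n_ch}x{n_ch}")
    Creg = C + alpha * (np.trace(C) / n_ch) * np.eye(n_ch)
    Cinv = np.linalg.pinv(Creg, hermitian=True)
    kernel = np.empty((3 * n_src, n_ch))
    for v in range(n_src):
        Lv = L[:, 3 * v : 3 * v + 3]
        LtCi = Lv.T @ Cinv
        kernel[3 * v : 3 * v + 3] = _block_inv(LtCi @ Lv) @ LtCi
    return InverseOperator(
        kernel=kernel,
        grid=leadfield.grid,
        spacing_mm=leadfield.spacing_mm,
        alpha=alpha,
        iterations=1,
        converged=True,
    )


def snap_to_grid(invop: InverseOperator, locations) -> list[int]:
    """Nearest grid indices of dipole locations; error beyond one spacing."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    out = []
    for loc in locations:
        d = np.linalg.norm(invop.grid - loc, axis=1)
        idx = int(np.argmin(d))
        if d[idx] > invop.spacing_mm:
            raise ValueError(
                f"dipole {loc} is {d[idx]:.1f} mm from the nearest grid point "
                f"(> one grid spacing {invop.spacing_mm} mm)"
            )
        if d[idx] > 1e-6:
            logger.info("dipole %s snapped %.2f mm to grid", loc, d[idx])
        out.append(idx)
    return out


def _principal_orientation(moment: np.ndarray) -> np.ndarray:
    """Dominant-singular-vector orientation of a (3, N) moment time course."""
    w, U = np.linalg.eigh(moment @ moment.T)
    u = U[:, np.argmax(w)]
    k = int(np.argmax(np.abs(u)))
    return u if u[k] >= 0 else -u


def principal_orientations(invop: InverseOperator, data: np.ndarray,
                           dipoles) -> np.ndarray:
    """Per-dipole principal orientations of the source moments of ``data``."""
    X = data.data if isinstance(data, EEGRecording) else np.asarray(data, float)
    idx = snap_to_grid(invop, getattr(dipoles, "locations", dipoles))
    return np.stack(
        [_principal_orientation(invop.kernel_at(v) @ X) for v in idx]
    )


def estimate_sources(
    invop: InverseOperator,
    recording,
    dipoles,
    orientations: np.ndarray | None = None,
) -> np.ndarray:
    """Single time course per requested dipole location, (n_l, N_s).

    The 3-orientation moment at each (grid-snapped) dipole is reduced to one
    time course by projecting onto its principal orientation (SVD of the
    3 x N_s moment), or onto ``orientations`` when given — passing fixed
    orientations keeps the reduction linear across inputs.
    """
    X = recording.data if isinstance(recording, EEGRecording) \
        else np.asarray(recording, float)
    locations = getattr(dipoles, "locations", dipoles)
    idx = snap_to_grid(invop, locations)
    out = np.empty((len(idx), X.shape[1]))
    for row, v in enumerate(idx):
        moment = invop.kernel_at(v) @ X
        ori = (
            orientations[row]
            if orientations is not None
            else _principal_orientation(moment)
        )
        out[row] = ori @ moment
    return out


@dataclass
class FeatureMatrix:
    """(n_l × M) × N_s per-IC source-projection features.

    ``row_map[r] = (ic_index, dipole_index)``: rows are grouped by
    independent component, dipole-major within each block.
    """

    values: np.ndarray
    row_map: list[tuple[int, int]]
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_map = [tuple(int(v) for v in rm) for rm in self.row_map]
        if self.values.shape[0] != len(self.row_map):
            raise ValueError("row_map must have one entry per feature row")
        if len(set(self.row_map)) != len(self.row_map):
            raise ValueError("row_map entries must be unique (bijection)")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_components(self) -> int:
        return len({ic for ic, _ in self.row_map})

    @property
    def n_l(self) -> int:
        return len({d for _, d in self.row_map})


def feature_scalings(
    decomp: ICADecomposition,
    invop: InverseOperator,
    dipoles,
) -> np.ndarray:
    """Per-(IC, dipole) projection scalars, shape (M, n_l).

    The back-projection of component i is rank-1, so its source estimate at
    dipole v along a fixed orientation is a scalar multiple of the component
    time course: ``scal[i, v] * sources[i]``. Orientations are the principal
    orientations of the full reconstructed data, shared across components.
    """
    if decomp.sources is None:
        raise ValueError("decomposition does not carry source time courses")
    idx = snap_to_grid(invop, getattr(dipoles, "locations", dipoles))
    full = decomp.mixing @ decomp.sources
    orientations = np.stack(
        [_principal_orientation(invop.kernel_at(v) @ full) for v in idx]
    )
    scal = np.empty((decomp.n_components, len(idx)))
    for i in range(decomp.n_components):
        w = np.stack([invop.kernel_at(v) @ decomp.mixing[:, i] for v in idx])
        scal[i] = np.einsum("vk,vk->v", orientations, w)
    return scal


def build_features(
    decomp: ICADecomposition,
    invop: InverseOperator,
    dipoles,
    fs: float = 1000.0,
) -> FeatureMatrix:
    """Per-IC source projections at the selected dipoles, stacked IC-major.

    Every component is back-projected to the channels and its source
    activity estimated at the n_l dipole locations; the n_l × N_s blocks are
    concatenated in component order. All blocks share the principal
    orientations of the full reconstructed data, so the blocks of all
    components sum to the source estimate of the full data (linearity of
    the kernel).
    """
    if decomp.sources is None:
        raise ValueError("decomposition does not carry source time courses")
    scal = feature_scalings(decomp, invop, dipoles)  # (M, n_l)
    M, n_l = scal.shape
    # rank-1 shortcut: kernel @ (a_i s_i^T) = (kernel a_i) s_i^T
    values = np.empty((n_l * M, decomp.sources.shape[1]))
    row_map = []
    for i in range(M):
        values[i * n_l : (i + 1) * n_l] = (
            scal[i][:, None] * decomp.sources[i][None, :]
        )
        row_map.extend((i, d) for d in range(n_l))
    return FeatureMatrix(values=values, row_map=row_map, fs=fs)
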