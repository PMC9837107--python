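"""SOBI blind source separation, back-projection and component rejection.

Second-order blind identification separates the EEG into components by
whitening the data and jointly diagonalizing a set of time-lagged covariance
matrices with Jacobi rotations. The algorithm is deterministic: the same
data and lags give identical matrices. Components can be back-projected one
at a time (the channel-space signal if only that component were present) or
removed to reconstruct cleaned EEG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import EEGRecording

logger = logging.getLogger(__name__)

DEFAULT_LAGS = tuple(range(1, 101))


@dataclass
class ICADecomposition:
    """Linear decomposition: ``sources = unmixing @ data``.

    ``mixing`` is the (pseudo-)inverse of ``unmixing``; for the full-rank
    square case ``mixing @ unmixing`` is the identity.
    """

    unmixing: np.ndarray  # (n_comp, n_ch)
    mixing: np.ndarray  # (n_ch, n_comp)
    sources: np.ndarray | None = None  # (n_comp, n_samples)
    lags: tuple[int, ...] = DEFAULT_LAGS

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def n_channels(self) -> int:
        return self.unmixing.shape[1]


def _lagged_covariances(X: np.ndarray, lags) -> np.ndarray:
    """Symmetrised lagged covariance matrices, shape (n_lags, n, n)."""
    n, T = X.shape
    covs = np.empty((len(lags), n, n))
    for i, tau in enumerate(lags):
        if tau >= T:
            raise ValueError(f"lag {tau} exceeds the number of samples {T}")
        C = X[:, : T - tau] @ X[:, tau:].T / (T - tau)
        covs[i] = (C + C.T) / 2.0
    return covs


def joint_diagonalize(matrices: np.ndarray, tol: float = 1e-8,
                      max_sweeps: int = 200) -> tuple[np.ndarray, int]:
    """Jacobi joint approximate diagonalization (Cardoso–Souloumiac).

    Finds an orthogonal V maximising the sum of squared diagonals of
    ``V.T @ M_k @ V`` over all matrices. Converges when the largest rotation
    angle of a sweep falls below ``tol``.

    Returns the orthogonal matrix and the number of sweeps used.
    """
    M = np.array(matrices, dtype=float, copy=True)
    K, n, _ = M.shape
    V = np.eye(n)
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_theta = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                # closed-form Givens angle for the pair (p, q)
                h_diff = M[:, p, p] - M[:, q, q]
                h_off = M[:, p, q] + M[:, q, p]
                ton = h_diff @ h_diff - h_off @ h_off
                toff = 2.0 * (h_diff @ h_off)
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                if abs(theta) > max_theta:
                    max_theta = abs(theta)
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) < 1e-300:
                    continue
                # rotate rows/cols p,q of every matrix and update V
                Mp = M[:, :, p].copy()
                Mq = M[:, :, q].copy()
                M[:, :, p] = c * Mp + s * Mq
                M[:, :, q] = -s * Mp + c * Mq
                Mp = M[:, p, :].copy()
                Mq = M[:, q, :].copy()
                M[:, p, :] = c * Mp + s * Mq
                M[:, q, :] = -s * Mp + c * Mq
                Vp = V[:, p].copy()
                Vq = V[:, q].copy()
                V[:, p] = c * Vp + s * Vq
                V[:, q] = -s * Vp + c * Vq
        if max_theta < tol:
            break
    else:
        logger.warning("joint diagonalization hit max_sweeps=%d", max_sweeps)
    return V, sweeps


def sobi(eeg, lags=DEFAULT_LAGS, rank_tol: float = 1e-10,
         keep_sources: bool = True) -> ICADecomposition:
    """Second-order blind identification of an EEG recording.

    Parameters
    ----------
    eeg : EEGRecording or ndarray
        (n_channels, n_samples) data; channels must be fewer than samples.
    lags : iterable of int
        Positive sample offsets of the covariance matrices (default 1..100).
    rank_tol : float
        Relative eigenvalue cutoff of the whitener; rank-deficient data
        yields a reduced-rank decomposition with a warning.
    """
    X = eeg.data if isinstance(eeg, EEGRecording) else np.asarray(eeg, float)
    n, T = X.shape
    if n >= T:
        raise ValueError("need more samples than channels")
    lags = tuple(int(v) for v in lags)
    if any(v <= 0 for v in lags):
        raise ValueError("lags must be positive sample offsets")

    Xc = X - X.mean(axis=1, keepdims=True)
    C0 = Xc @ Xc.T / T
    evals, evecs = np.linalg.eigh(C0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rank_tol * evals[0]
    if keep.sum() < n:
        logger.warning(
            "rank-deficient data: %d of %d components retained", keep.sum(), n
        )
    evals, evecs = evals[keep], evecs[:, keep]
    whitener = evecs.T / np.sqrt(evals)[:, None]  # (r, n)

    Z = whitener @ Xc
    covs = _lagged_covariances(Z, lags)
    V, sweeps = joint_diagonalize(covs)
    logger.debug("joint diagonalization converged in %d sweeps", sweeps)

    unmixing = V.T @ whitener  # (r, n)
    # deterministic ordering and signs: sort by source variance, make the
    # largest-magnitude mixing coefficient of each component positive
    S = unmixing @ X
    order = np.argsort(-S.var(axis=1), kind="stable")
    unmixing = unmixing[order]
    mixing = np.linalg.pinv(unmixing)
    flips = np.sign(mixing[np.abs(mixing).argmax(axis=0), np.arange(mixing.shape[1])])
    flips[flips == 0] = 1.0
    unmixing *= flips[:, None]
    mixing = np.linalg.pinv(unmixing)
    return ICADecomposition(
        unmixing=unmixing,
        mixing=mixing,
        sources=(unmixing @ X) if keep_sources else None,
        lags=lags,
    )


def project_component(decomp: ICADecomposition, component_index: int) -> np.ndarray:
    """Channel-space signal if only one independent component were present.

    Rank-1 back-projection ``mixing[:, i] @ sources[i, :]``; the projections
    of all components sum to the decomposed data.
    """
    if not 0 <= component_index < decomp.n_components:
        raise IndexError(
            f"component {component_index} out of range "
            f"(0..{decomp.n_components - 1})"
        )
    if decomp.sources is None:
        raise ValueError("decomposition does not carry source time courses")
    return np.outer(decomp.mixing[:, component_index],
                    decomp.sources[component_index])


def remove_components(decomp: ICADecomposition, reject_indices) -> np.ndarray:
    """Reconstruct channel-space EEG with the listed components removed."""
    reject = sorted(set(int(i) for i in reject_indices))
    for i in reject:
        if not 0 <= i < decomp.n_components:
            raise IndexError(f"component {i} out of range")
    if len(reject) == decomp.n_components:
        raise ValueError("cannot reject every component")
    if decomp.sources is None:
        raise ValueError("decomposition does not carry source time courses")
    keep = [i for i in range(decomp.n_components) if i not in reject]
    return decomp.mixing[:, keep] @ decomp.sources[keep]


def automatic_rejection(decomp: ICADecomposition, fs: float,
                        kurtosis_max: float = 10.0,
                        line_freq_hz: float = 50.0,
                        line_ratio_max: float = 10.0) -> list[int]:
    """Config-driven artifact heuristics: excess kurtosis and line-noise ratio.

    Returns component indices whose source kurtosis exceeds ``kurtosis_max``
    or whose power within ±1 Hz of ``line_freq_hz`` exceeds
    ``line_ratio_max`` times the broadband mean.
    """
    from scipy import signal as sps
    from scipy import stats

    if decomp.sources is None:
        raise ValueError("decomposition does not carry source time courses")
    reject = []
    for i, s in enumerate(decomp.sources):
        if stats.kurtosis(s) > kurtosis_max:
            reject.append(i)
            continue
        if fs > 2 * line_freq_hz:
            f, p = sps.welch(s, fs=fs, nperseg=min(len(s), 4096))
            band = (f > line_freq_hz - 1) & (f < line_freq_hz + 1)
            if band.any() and p[band].mean() > line_ratio_max * p.mean():
                reject.append(i)
    return reject


def amari_index(P: np.ndarray) -> float:
    """Amari performance index of a permutation-like matrix (0 = perfect).

    Standard measure of how far ``unmixing @ mixing_true`` is from a scaled
    permutation; below ~0.1 indicates good source recovery.
    """
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * n * (n - 1)))
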