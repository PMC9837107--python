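"""GLM T-contrast on BOLD volumes and greedy dipole selection.

A mass-univariate ordinary-least-squares GLM contrasts music-listening
trials (music-only and music-with-reporting) against no-music trials
(reporting-only), with boxcar regressors convolved with a canonical
double-gamma haemodynamic response and per-run intercept plus linear drift
nuisance columns. From the thresholded T-map, dipole locations are chosen by
a greedy loop that repeatedly takes the strongest remaining voxel and keeps
it only if it lies more than a minimum distance m from every voxel already
selected, stopping at n_l locations (defaults m = 30 mm, n_l = 4).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Documented cap on |T| for numerically perfect fits (zero residual).
T_MAX = 1e6

MUSIC_TRIAL_TYPES = ("music_only", "music_reporting")
NO_MUSIC_TRIAL_TYPES = ("reporting_only",)


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at times ``t`` (s).

    Positive gamma peaking at ``peak_s``, undershoot gamma peaking at
    ``undershoot_s``, undershoot amplitude 1/``ratio``; normalised to unit
    peak.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_s, scale=1.0) - stats.gamma.pdf(
        t, undershoot_s, scale=1.0
    ) / ratio
    peak = np.abs(h).max()
    return h / peak if peak > 0 else h


def _trial_boxcar(trials, run_length_s: float, dt: float) -> np.ndarray:
    n = int(np.ceil(run_length_s / dt))
    box = np.zeros(n)
    tax = np.arange(n) * dt
    for tr in trials:
        box[(tax >= tr.onset) & (tax < tr.onset + tr.duration)] = 1.0
    return box


def build_design(schedule, tr_s: float = 2.0, oversample: int = 20):
    """Design matrix for the music vs no-music GLM.

    Columns: [music, no_music, run-wise intercepts, run-wise linear drifts].
    Boxcars are built on a fine grid (``tr_s / oversample``), convolved with
    the double-gamma response and sampled at volume acquisition times.

    Returns
    -------
    X : ndarray, shape (n_volumes, n_regressors)
    names : list of str
    n_vols_per_run : list of int
    """
    dt = tr_s / oversample
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt))
    runs = sorted({tr.run for tr in schedule.trials})
    cols_task = {"music": [], "no_music": []}
    run_blocks = []
    n_vols_per_run = []
    for run in runs:
        run_trials = [tr for tr in schedule.trials if tr.run == run]
        run_len = schedule.run_lengths_s[run - 1]
        n_vol = int(np.floor(run_len / tr_s))
        n_vols_per_run.append(n_vol)
        vol_idx = (np.arange(n_vol) * tr_s / dt).astype(int)
        for name, types in (
            ("music", MUSIC_TRIAL_TYPES),
            ("no_music", NO_MUSIC_TRIAL_TYPES),
        ):
            box = _trial_boxcar(
                [tr for tr in run_trials if tr.type in types], run_len, dt
            )
            reg = np.convolve(box, hrf)[: len(box)]
            cols_task[name].append(reg[vol_idx])
        run_blocks.append(n_vol)

    music = np.concatenate(cols_task["music"])
    no_music = np.concatenate(cols_task["no_music"])
    n_total = len(music)
    names = ["music", "no_music"]
    cols = [music, no_music]
    offset = 0
    for i, n_vol in enumerate(run_blocks):
        intercept = np.zeros(n_total)
        intercept[offset : offset + n_vol] = 1.0
        drift = np.zeros(n_total)
        drift[offset : offset + n_vol] = np.linspace(-0.5, 0.5, n_vol)
        cols += [intercept, drift]
        names += [f"intercept_run{runs[i]}", f"drift_run{runs[i]}"]
        offset += n_vol
    return np.column_stack(cols), names, n_vols_per_run


@dataclass
class TMap:
    """Voxelwise T statistics of the music vs no-music contrast."""

    coords: np.ndarray  # (n_vox, 3) mm
    t: np.ndarray  # (n_vox,)
    p: np.ndarray  # (n_vox,) two-sided
    df: int
    affine: np.ndarray | None = None
    shape: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if not (len(self.coords) == len(self.t) == len(self.p)):
            raise ValueError("coords, t and p must have one entry per voxel")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("T values must be finite")
        if np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValueError("p values must lie in (0, 1]")


def glm_tmap(bold, schedule, tr_s: float = 2.0, affine: np.ndarray | None = None,
             coords: np.ndarray | None = None) -> TMap:
    """Fit the music vs no-music GLM at every voxel and return the T-map.

    Parameters
    ----------
    bold : nibabel image or ndarray
        4D BOLD data, last axis time, or a (n_vox, n_volumes) matrix when
        ``coords`` is given explicitly.
    schedule : TrialSchedule
        Trial timing; run volumes are concatenated along the time axis.
    tr_s : float
        Repetition time in seconds.
    affine, coords
        Voxel-to-mm mapping. For a 4D array, ``affine`` maps ijk indices to
        mm; for a flat (n_vox, n_t) matrix pass ``coords`` directly.
    """
    shape = None
    if hasattr(bold, "get_fdata"):  # nibabel image
        affine = bold.affine if affine is None else affine
        data = np.asarray(bold.get_fdata(), dtype=float)
    else:
        data = np.asarray(bold, dtype=float)
    if data.ndim == 4:
        shape = data.shape[:3]
        if affine is None:
            raise ValueError("4D input requires an affine")
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        ijk1 = np.column_stack(
            [ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)]
        )
        coords = (ijk1 @ affine.T)[:, :3]
        Y = data.reshape(-1, data.shape[3])
    elif data.ndim == 2:
        if coords is None:
            raise ValueError("2D input requires voxel coordinates")
        Y = data
    else:
        raise ValueError("bold must be 4D or (n_vox, n_volumes)")

    X, names, _ = build_design(schedule, tr_s=tr_s)
    if Y.shape[1] != X.shape[0]:
        raise ValueError(
            f"BOLD has {Y.shape[1]} volumes but the design expects {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    c = np.zeros(X.shape[1])
    c[names.index("music")] = 1.0
    c[names.index("no_music")] = -1.0

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (xtx_inv @ X.T).T  # (n_vox, n_reg)
    resid = Y - beta @ X.T
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=1) / df
    denom = np.sqrt(np.maximum(sigma2 * (c @ xtx_inv @ c), 0.0))
    num = beta @ c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0),
                     np.sign(num) * T_MAX)
    t = np.clip(t, -T_MAX, T_MAX)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return TMap(coords=coords, t=t, p=p, df=df, affine=affine, shape=shape)


@dataclass
class DipoleSet:
    """fMRI-selected source locations with their T-values.

    Selection order preserves the greedy sequence, so ``t_values`` is
    non-increasing and every pairwise distance is at least ``m_mm``.
    """

    locations: np.ndarray  # (k, 3) mm
    t_values: np.ndarray  # (k,)
    m_mm: float
    n_l: int
    indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float).reshape(-1, 3)
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.locations) > self.n_l:
            raise ValueError("more locations than n_l")
        if np.any(np.diff(self.t_values) > 1e-12):
            raise ValueError("t_values must be non-increasing in selection order")
        if len(self.locations) >= 2:
            d = np.linalg.norm(
                self.locations[:, None, :] - self.locations[None, :, :], axis=-1
            )
            off = d[~np.eye(len(d), dtype=bool)]
            if off.min() < self.m_mm:
                raise ValueError("pairwise distance below the minimum distance m")

    def __len__(self) -> int:
        return len(self.locations)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "locations_mm": self.locations.tolist(),
                "t_values": self.t_values.tolist(),
                "m_mm": self.m_mm,
                "n_l": self.n_l,
                "indices": self.indices.tolist(),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "DipoleSet":
        if hasattr(source, "read"):
            obj = json.load(source)
        else:
            try:
                obj = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    obj = json.load(fh)
        return cls(
            locations=np.array(obj["locations_mm"]),
            t_values=np.array(obj["t_values"]),
            m_mm=obj["m_mm"],
            n_l=obj["n_l"],
            indices=np.array(obj.get("indices", []), dtype=int),
        )


def select_dipoles(
    tmap: TMap,
    alpha: float = 0.05,
    m_mm: float = 30.0,
    n_l: int = 4,
    correction: str = "bonferroni",
) -> DipoleSet:
    """Greedy minimum-distance selection of dipole locations from a T-map.

    Candidates are voxels significant at ``alpha`` (family-wise Bonferroni
    correction by default; ``correction='none'`` thresholds uncorrected p).
    The loop pops the candidate with the largest T (ties broken by lowest
    linear voxel index), adds it to the selected set only if its smallest
    distance to the set is strictly greater than ``m_mm``, and repeats until
    ``n_l`` locations are selected or candidates are exhausted.
    """
    if correction == "bonferroni":
        thresh = alpha / len(tmap.p)
    elif correction == "none":
        thresh = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    candidates = np.flatnonzero(tmap.p < thresh)
    if candidates.size == 0:
        logger.warning("no significant voxels at alpha=%g (%s)", alpha, correction)
        return DipoleSet(
            locations=np.empty((0, 3)),
            t_values=np.empty(0),
            m_mm=m_mm,
            n_l=n_l,
        )
    # sort candidates by (-T, linear index): deterministic greedy order
    order = np.lexsort((candidates, -tmap.t[candidates]))
    queue = candidates[order]
    chosen: list[int] = []
    for idx in queue:
        if len(chosen) >= n_l:
            break
        loc = tmap.coords[idx]
        if chosen:
            dmin = np.linalg.norm(tmap.coords[chosen] - loc, axis=1).min()
            if not dmin > m_mm:
                continue
        chosen.append(int(idx))
    if len(chosen) < n_l:
        logger.warning(
            "candidate set exhausted: selected %d of %d dipoles", len(chosen), n_l
        )
    return DipoleSet(
        locations=tmap.coords[chosen],
        t_values=tmap.t[chosen],
        m_mm=m_mm,
        n_l=n_l,
        indices=np.array(chosen, dtype=int),
    )
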