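"""Similarity, significance, identification and tempo statistics.

Reconstruction quality is measured per trial by the Pearson correlation in
the time domain, the Pearson correlation between Welch power spectra, and
the structural similarity (SSIM) of log-power time–frequency spectrograms.
Significance comes from a bootstrap that re-pairs reconstructed and
original trials (4000 resamples). Identification uses rank accuracy: the
normalised position of the true pairing's spectrogram similarity C[k,k]
among the similarities C[k,i] to the other pieces — 0.5 at chance, 1.0 for
perfect identification — with a permutation test for its significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from skimage.metrics import structural_similarity

logger = logging.getLogger(__name__)


@dataclass
class SpectrogramConfig:
    """STFT settings for the SSIM comparisons: 1 s Hann windows with 50 %
    overlap, log power, frequencies up to 50 Hz."""

    win_s: float = 1.0
    overlap: float = 0.5
    fmax_hz: float = 50.0
    log_floor: float = 1e-10


@dataclass
class SSIMConfig:
    """Standard SSIM constants: K1/K2 weights and an 11-bin Gaussian window
    of sigma 1.5; images are jointly min–max normalised per comparison."""

    k1: float = 0.01
    k2: float = 0.03
    win_size: int = 11
    sigma: float = 1.5


def spectrogram(x: np.ndarray, fs: float,
                cfg: SpectrogramConfig | None = None) -> np.ndarray:
    """Log-power time–frequency spectrogram (freq x time)."""
    cfg = cfg or SpectrogramConfig()
    nperseg = max(int(round(cfg.win_s * fs)), 8)
    nperseg = min(nperseg, len(x))
    noverlap = int(round(nperseg * cfg.overlap))
    f, _, S = signal.spectrogram(
        np.asarray(x, float), fs=fs, window="hann",
        nperseg=nperseg, noverlap=noverlap, mode="psd",
    )
    keep = f <= cfg.fmax_hz
    return np.log10(S[keep] + cfg.log_floor)


def ssim(image_a: np.ndarray, image_b: np.ndarray,
         cfg: SSIMConfig | None = None) -> float:
    """Structural similarity of two images on a shared dynamic range.

    Both images are normalised by their joint min and max, so the dynamic
    range is 1; symmetric, ssim(x, x) = 1.
    """
    cfg = cfg or SSIMConfig()
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    rng = hi - lo
    if rng == 0:
        return 1.0  # identical constant images
    a = (a - lo) / rng
    b = (b - lo) / rng
    win = min(cfg.win_size, *a.shape)
    if win % 2 == 0:
        win -= 1
    return float(
        structural_similarity(
            a, b, win_size=win, gaussian_weights=True, sigma=cfg.sigma,
            K1=cfg.k1, K2=cfg.k2, data_range=1.0,
            use_sample_covariance=False,
        )
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; NaN for constant inputs (recorded as missing)."""
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def _power_spectrum(x: np.ndarray, fs: float) -> np.ndarray:
    nperseg = min(256, len(x))
    _, p = signal.welch(np.asarray(x, float), fs=fs, nperseg=nperseg)
    return p


def bootstrap_null(similarity_matrix: np.ndarray, n_boot: int = 4000,
                   seed: int = 0) -> float:
    """Bootstrap p for a mean similarity under shuffled trial pairing.

    ``similarity_matrix[k, i]`` is the similarity between reconstruction k
    and original trial i; the observed statistic is the mean diagonal. Each
    resample re-pairs reconstructions with originals by a random
    permutation; ``p = (1 + #{null >= observed}) / (n_boot + 1)``.
    """
    C = np.asarray(similarity_matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("similarity matrix must be square")
    if C.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    if n_boot < 100:
        logger.warning("n_boot=%d is very small; p-values will be coarse", n_boot)
    observed = np.nanmean(np.diag(C))
    rng = np.random.default_rng(seed)
    n = C.shape[0]
    rows = np.arange(n)
    count = 0
    for _ in range(n_boot):
        perm = rng.permutation(n)
        if np.nanmean(C[rows, perm]) >= observed:
            count += 1
    return (1 + count) / (n_boot + 1)


@dataclass
class SimilarityReport:
    """Per-trial similarity measures with bootstrap significance."""

    r_time: np.ndarray
    r_freq: np.ndarray
    ssim_tf: np.ndarray
    mean_r_time: float
    mean_r_freq: float
    mean_ssim: float
    p_r_time: float
    p_r_freq: float
    p_ssim: float
    n_boot: int


def similarity_suite(
    orig_trials: list[np.ndarray],
    recon_trials: list[np.ndarray],
    fs: float = 100.0,
    spectrogram_cfg: SpectrogramConfig | None = None,
    ssim_cfg: SSIMConfig | None = None,
    n_boot: int = 4000,
    seed: int = 0,
) -> SimilarityReport:
    """Time/frequency correlations and spectrogram SSIM over aligned trials.

    Constant series yield undefined correlations; those trials are recorded
    as NaN and excluded from the means with a log notice.
    """
    if len(orig_trials) != len(recon_trials):
        raise ValueError("need one reconstruction per original trial")
    n = len(orig_trials)
    for o, r in zip(orig_trials, recon_trials):
        if len(o) != len(r):
            raise ValueError("trials must be aligned and of equal length")

    specs_o = [spectrogram(o, fs, spectrogram_cfg) for o in orig_trials]
    specs_r = [spectrogram(r, fs, spectrogram_cfg) for r in recon_trials]
    pows_o = [_power_spectrum(o, fs) for o in orig_trials]
    pows_r = [_power_spectrum(r, fs) for r in recon_trials]

    C_time = np.empty((n, n))
    C_freq = np.empty((n, n))
    C_ssim = np.empty((n, n))
    for k in range(n):
        for i in range(n):
            C_time[k, i] = _pearson(recon_trials[k], orig_trials[i])
            C_freq[k, i] = _pearson(pows_r[k], pows_o[i])
            C_ssim[k, i] = ssim(specs_r[k], specs_o[i], ssim_cfg)

    r_time = np.diag(C_time).copy()
    r_freq = np.diag(C_freq).copy()
    ssim_tf = np.diag(C_ssim).copy()
    for name, vals in (("r_time", r_time), ("r_freq", r_freq)):
        bad = np.isnan(vals)
        if bad.any():
            logger.info(
                "%s undefined (constant series) for trials %s; excluded "
                "from the mean", name, np.flatnonzero(bad).tolist(),
            )
    return SimilarityReport(
        r_time=r_time,
        r_freq=r_freq,
        ssim_tf=ssim_tf,
        mean_r_time=float(np.nanmean(r_time)),
        mean_r_freq=float(np.nanmean(r_freq)),
        mean_ssim=float(np.nanmean(ssim_tf)),
        p_r_time=bootstrap_null(C_time, n_boot, seed),
        p_r_freq=bootstrap_null(C_freq, n_boot, seed + 1),
        p_ssim=bootstrap_null(C_ssim, n_boot, seed + 2),
        n_boot=n_boot,
    )


@dataclass
class RankResult:
    """Identification result: similarity matrix, per-trial rank accuracies
    and, once computed, the permutation p-value."""

    C: np.ndarray
    rank_acc: np.ndarray
    mean_rank_acc: float
    piece_ids: np.ndarray
    comparison_sizes: np.ndarray
    exclusion: str
    p_value: float | None = None


def rank_accuracy_matrix(
    C: np.ndarray,
    piece_ids=None,
    exclusion: str = "different_piece",
    true_cols=None,
) -> np.ndarray:
    """Per-trial rank accuracies from a similarity matrix.

    For trial k the true similarity ``C[k, true_cols[k]]`` (diagonal by
    default) is ranked within the comparison set A_k: all other trials, or
    only trials of a different piece when ``exclusion='different_piece'``.
    Ties count half, which keeps the chance level at exactly 0.5.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if piece_ids is None:
        piece_ids = np.arange(n)
    piece_ids = np.asarray(piece_ids)
    if true_cols is None:
        true_cols = np.arange(n)
    acc = np.empty(n)
    for k in range(n):
        kk = true_cols[k]
        if exclusion == "different_piece":
            A = np.flatnonzero(piece_ids != piece_ids[kk])
        elif exclusion == "self_only":
            A = np.array([i for i in range(n) if i != kk])
        else:
            raise ValueError(f"unknown exclusion {exclusion!r}")
        if A.size == 0:
            raise ValueError(
                f"trial {k}: empty comparison set (all trials share its piece)"
            )
        truth = C[k, kk]
        wins = np.sum(truth > C[k, A])
        ties = np.sum(truth == C[k, A])
        acc[k] = (wins + 0.5 * ties) / A.size
    return acc


def rank_accuracy(
    orig_trials: list[np.ndarray],
    recon_trials: list[np.ndarray],
    piece_ids,
    fs: float = 100.0,
    filter_band: tuple[float, float] = (0.035, 4.75),
    spectrogram_cfg: SpectrogramConfig | None = None,
    ssim_cfg: SSIMConfig | None = None,
    exclusion: str = "different_piece",
) -> RankResult:
    """Rank-accuracy identification of the heard piece from spectrogram SSIM.

    Original and reconstructed series are z-scored and band-pass filtered
    (zero-phase Butterworth, 0.035–4.75 Hz) as continuous concatenated
    series before segmentation back into trials; C[k, i] is the SSIM between
    the spectrogram of reconstruction k and of original trial i.
    """
    n = len(orig_trials)
    if n != len(recon_trials):
        raise ValueError("need one reconstruction per original trial")
    piece_ids = np.asarray(piece_ids)
    if piece_ids.shape != (n,):
        raise ValueError("need one piece id per trial")
    lengths = {len(t) for t in orig_trials} | {len(t) for t in recon_trials}
    if len(lengths) != 1:
        raise ValueError("all trials must have equal length")

    def prep(trials):
        cat = np.concatenate([np.asarray(t, float) for t in trials])
        sd = cat.std()
        cat = (cat - cat.mean()) / (sd if sd > 0 else 1.0)
        lo, hi = filter_band
        sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
        cat = signal.sosfiltfilt(sos, cat)
        L = len(trials[0])
        return [cat[i * L : (i + 1) * L] for i in range(len(trials))]

    orig_f = prep(orig_trials)
    recon_f = prep(recon_trials)
    specs_o = [spectrogram(t, fs, spectrogram_cfg) for t in orig_f]
    specs_r = [spectrogram(t, fs, spectrogram_cfg) for t in recon_f]
    C = np.empty((n, n))
    for k in range(n):
        for i in range(n):
            C[k, i] = ssim(specs_r[k], specs_o[i], ssim_cfg)
    acc = rank_accuracy_matrix(C, piece_ids, exclusion)
    sizes = np.array(
        [
            np.sum(piece_ids != piece_ids[k])
            if exclusion == "different_piece"
            else n - 1
            for k in range(n)
        ]
    )
    return RankResult(
        C=C,
        rank_acc=acc,
        mean_rank_acc=float(acc.mean()),
        piece_ids=piece_ids,
        comparison_sizes=sizes,
        exclusion=exclusion,
    )


def rank_significance(rank_result: RankResult, n_perm: int = 10000,
                      seed: int = 0) -> float:
    """Permutation p-value for the mean rank accuracy.

    The null re-pairs reconstructions with original trials by a random
    permutation and recomputes the mean rank accuracy from the same C
    matrix; ``p = (1 + #{null >= observed}) / (n_perm + 1)``. The result is
    stored on ``rank_result.p_value``.
    """
    C = rank_result.C
    n = C.shape[0]
    rng = np.random.default_rng(seed)
    observed = rank_result.mean_rank_acc
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        acc = rank_accuracy_matrix(
            C, rank_result.piece_ids, rank_result.exclusion, true_cols=perm
        )
        if acc.mean() >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    rank_result.p_value = p
    return p


def estimate_tempo(
    waveform: np.ndarray,
    fs: float,
    envelope_lowpass_hz: float = 20.0,
    min_ioi_s: float = 0.18,
) -> tuple[float, tuple[float, float]]:
    """Mean tempo and 10–90 % tempo range (bpm) from onset detection.

    Onsets are peaks of the envelope derivative above an adaptive threshold;
    tempo is 60 / median inter-onset interval. Fewer than 3 detected onsets
    leaves the tempo undefined (NaN, with a warning).
    """
    w = np.asarray(waveform, dtype=float)
    env = np.abs(w)
    if envelope_lowpass_hz < fs / 2:
        sos = signal.butter(4, envelope_lowpass_hz, btype="low", fs=fs,
                            output="sos")
        env = signal.sosfiltfilt(sos, env)
    d = np.diff(env)
    d[d < 0] = 0.0
    if d.max() <= 0:
        logger.warning("flat envelope: tempo undefined")
        return float("nan"), (float("nan"), float("nan"))
    peaks, _ = signal.find_peaks(
        d, height=0.25 * d.max(), distance=max(int(min_ioi_s * fs), 1)
    )
    if len(peaks) < 3:
        logger.warning("fewer than 3 onsets detected: tempo undefined")
        return float("nan"), (float("nan"), float("nan"))
    ioi = np.diff(peaks) / fs
    mean_bpm = 60.0 / float(np.median(ioi))
    q10, q90 = np.quantile(ioi, [0.1, 0.9])
    return mean_bpm, (60.0 / float(q90), 60.0 / float(q10))


@dataclass
class TempoReport:
    """Tempo-confound check: correlations of decoding performance with
    trial tempo and with tempo typicality."""

    tempos_bpm: np.ndarray
    typicality: np.ndarray
    r_tempo: float
    p_tempo: float
    r_typicality: float
    p_typicality: float


def tempo_confound(tempos, rank_accs) -> TempoReport:
    """Correlate per-trial tempo (and its typicality) with rank accuracy.

    Typicality is the Gaussian density of a trial's mean tempo under the
    distribution (mean, sd) of mean tempos over all trials. Zero-variance
    tempos leave the correlations undefined (NaN, with a warning).
    """
    tempos = np.asarray(tempos, dtype=float)
    accs = np.asarray(rank_accs, dtype=float)
    if tempos.shape != accs.shape:
        raise ValueError("need one tempo and one rank accuracy per trial")
    sd = tempos.std(ddof=1) if len(tempos) > 1 else 0.0
    if sd == 0:
        logger.warning("zero-variance tempos: correlations undefined")
        nan = float("nan")
        return TempoReport(tempos, np.full_like(tempos, nan), nan, nan, nan, nan)
    typ = stats.norm.pdf(tempos, loc=tempos.mean(), scale=sd)
    r1, p1 = stats.pearsonr(tempos, accs)
    r2, p2 = stats.pearsonr(typ, accs)
    return TempoReport(
        tempos_bpm=tempos,
        typicality=typ,
        r_tempo=float(r1),
        p_tempo=float(p1),
        r_typicality=float(r2),
        p_typicality=float(p2),
    )
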