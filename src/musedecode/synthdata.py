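"""Synthetic music-listening data with the statistical structure the
decoding pipeline assumes.

The generator emulates a joint EEG–fMRI music-listening session: 36
monophonic piano-like pieces of 40 s targeting 9 valence/arousal classes,
3 runs of 12 trials (fixation 1–3 s, 40 s task, 0.5 s break), 31-channel
EEG at 1000 Hz whose active cortical sources track the low-passed amplitude
envelope of the concurrently playing piece (lagged 100 ms), and a BOLD-like
voxel volume whose music-responsive clusters follow the trial boxcar
convolved with a double-gamma haemodynamic response.

Every generator is a pure function of its arguments and seed: the same seed
gives bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .fmri_select import MUSIC_TRIAL_TYPES, build_design
from .io import EEGRecording

logger = logging.getLogger(__name__)

AFFECT_LEVELS = ("low", "neutral", "high")
#: The 9 valence/arousal targets, in deterministic order.
AFFECT_TARGETS = tuple((v, a) for v in AFFECT_LEVELS for a in AFFECT_LEVELS)

TRIAL_TYPES = ("music_only", "music_reporting", "reporting_only")


@dataclass
class Piece:
    """One generated piece of monophonic piano-like music."""

    piece_id: int
    waveform: np.ndarray
    fs: float
    duration_s: float
    affect_target: tuple[str, str]
    tempo_bpm: float  # realised mean tempo (from the onset train)
    nominal_tempo_bpm: float
    onsets_s: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class StimulusSet:
    """The collection of music pieces played in the trials."""

    pieces: list[Piece]

    def __post_init__(self) -> None:
        if not self.pieces:
            raise ValueError("stimulus set must contain at least one piece")
        fs = {p.fs for p in self.pieces}
        dur = {p.duration_s for p in self.pieces}
        if len(fs) != 1 or len(dur) != 1:
            raise ValueError("all pieces must share one fs and one duration")
        for p in self.pieces:
            if not np.all(np.isfinite(p.waveform)):
                raise ValueError(f"piece {p.piece_id} has non-finite samples")
            if np.ptp(p.waveform) == 0:
                raise ValueError(f"piece {p.piece_id} is constant")

    @property
    def fs(self) -> float:
        return self.pieces[0].fs

    @property
    def duration_s(self) -> float:
        return self.pieces[0].duration_s

    def __len__(self) -> int:
        return len(self.pieces)

    def piece(self, piece_id: int) -> Piece:
        for p in self.pieces:
            if p.piece_id == piece_id:
                return p
        raise KeyError(f"no piece with id {piece_id}")


@dataclass
class Trial:
    trial_id: int
    run: int
    type: str
    onset: float  # seconds, relative to run start
    duration: float
    piece_id: int | None = None


@dataclass
class TrialSchedule:
    """Trials of all runs plus per-run total lengths (seconds)."""

    trials: list[Trial]
    run_lengths_s: list[float]

    def __post_init__(self) -> None:
        for tr in self.trials:
            if tr.type not in TRIAL_TYPES:
                raise ValueError(f"unknown trial type {tr.type!r}")
            if tr.type in MUSIC_TRIAL_TYPES and tr.piece_id is None:
                raise ValueError(f"music trial {tr.trial_id} lacks a piece_id")
            if tr.type == "reporting_only" and tr.piece_id is not None:
                raise ValueError(
                    f"reporting_only trial {tr.trial_id} must not carry a piece_id"
                )
        for run in self.runs:
            onsets = [tr.onset for tr in self.trials if tr.run == run]
            if np.any(np.diff(onsets) <= 0):
                raise ValueError(f"trial onsets in run {run} must strictly increase")

    @property
    def runs(self) -> list[int]:
        return sorted({tr.run for tr in self.trials})

    def music_trials(self, run: int | None = None) -> list[Trial]:
        return [
            tr
            for tr in self.trials
            if tr.type in MUSIC_TRIAL_TYPES and (run is None or tr.run == run)
        ]

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class SimulationConfig:
    """Knobs of the EEG forward simulation.

    ``coupling_gain`` scales the music-envelope drive of the active dipoles
    relative to the unit-variance 1/f source background; ``envelope_lag_s``
    is the cortical tracking delay. ``sensor_noise_sd`` is expressed
    relative to the RMS of the source-driven sensor data, so its meaning
    does not depend on the physical gain scale of the leadfield.
    """

    seed: int = 0
    n_channels: int = 31
    fs_eeg: float = 1000.0
    coupling_gain: float = 5.0
    source_noise_sd: float = 1.0
    sensor_noise_sd: float = 0.5
    envelope_lowpass_hz: float = 8.0
    envelope_lag_s: float = 0.1
    n_background_sources: int = 20

    def __post_init__(self) -> None:
        if self.source_noise_sd < 0 or self.sensor_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.fs_eeg <= 0:
            raise ValueError("fs_eeg must be positive")


def generate_music(
    n_pieces: int = 36,
    duration_s: float = 40.0,
    fs: float = 1000.0,
    tempo_range_bpm: tuple[float, float] = (60.0, 180.0),
    seed: int = 0,
    onset_jitter_sd: float = 0.0,
    fundamental_range_hz: tuple[float, float] = (2.0, 10.0),
    decay_s: float = 0.4,
) -> StimulusSet:
    """Generate piano-like monophonic pieces as decaying note trains.

    Each piece draws a tempo uniformly from ``tempo_range_bpm``; note onsets
    form a metronome train at that tempo (optionally jittered by
    ``onset_jitter_sd`` beats). Each note is a sinusoid at a low fundamental
    (log-spaced scale within ``fundamental_range_hz``, so spectral content
    survives downsampling to 100 Hz) under an exponential-decay envelope.

    Same seed, same arguments: bit-identical output.
    """
    if n_pieces < 1:
        raise ValueError("n_pieces must be >= 1")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    lo, hi = tempo_range_bpm
    if not (20.0 < lo <= hi < 300.0):
        raise ValueError("tempo range must lie within (20, 300) bpm")
    if onset_jitter_sd < 0:
        raise ValueError("onset_jitter_sd must be >= 0")

    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    t_note = np.arange(int(round(4 * decay_s * fs))) / fs
    scale = np.geomspace(fundamental_range_hz[0], fundamental_range_hz[1], 8)

    pieces = []
    for pid in range(n_pieces):
        tempo = float(rng.uniform(lo, hi))
        beat = 60.0 / tempo
        onsets = np.arange(0.0, duration_s + beat / 2, beat)
        if onset_jitter_sd > 0:
            jitter = rng.normal(0.0, onset_jitter_sd * beat, size=len(onsets))
            jitter[0] = 0.0
            onsets = np.sort(np.clip(onsets + jitter, 0.0, duration_s))
        w = np.zeros(n_samples)
        freqs = rng.choice(scale, size=len(onsets))
        amps = rng.uniform(0.5, 1.0, size=len(onsets))
        for t0, f0, a in zip(onsets, freqs, amps):
            i0 = int(round(t0 * fs))
            if i0 >= n_samples:
                continue
            seg = min(len(t_note), n_samples - i0)
            w[i0 : i0 + seg] += (
                a * np.exp(-t_note[:seg] / decay_s) * np.sin(2 * np.pi * f0 *
                                                             t_note[:seg])
            )
        peak = np.abs(w).max()
        if peak > 0:
            w /= peak
        realised = (
            60.0 / float(np.mean(np.diff(onsets))) if len(onsets) >= 2 else tempo
        )
        pieces.append(
            Piece(
                piece_id=pid,
                waveform=w,
                fs=fs,
                duration_s=duration_s,
                affect_target=AFFECT_TARGETS[pid % len(AFFECT_TARGETS)],
                tempo_bpm=realised,
                nominal_tempo_bpm=tempo,
                onsets_s=onsets,
            )
        )
    return StimulusSet(pieces)


def generate_schedule(
    n_runs: int = 3,
    trials_per_run: int = 12,
    stimuli: StimulusSet | None = None,
    seed: int = 0,
    type_mix: tuple[int, int, int] = (5, 5, 2),
    fixation_range_s: tuple[float, float] = (1.0, 3.0),
    break_s: float = 0.5,
    trial_duration_s: float | None = None,
    replace: bool = False,
    post_run_rest_s: float = 10.0,
) -> TrialSchedule:
    """Pseudo-random trial schedule.

    Per run, ``type_mix`` gives the counts of (music_only, music_reporting,
    reporting_only) trials, shuffled; each trial is preceded by a uniform
    1–3 s fixation and followed by a 0.5 s break. Pieces are assigned to
    music trials without replacement by default (each piece used at most
    once across the session).
    """
    if sum(type_mix) != trials_per_run:
        raise ValueError("type_mix must sum to trials_per_run")
    if stimuli is None:
        raise ValueError("a stimulus set is required")
    duration = (
        float(trial_duration_s) if trial_duration_s is not None
        else stimuli.duration_s
    )
    n_music = n_runs * (type_mix[0] + type_mix[1])
    piece_ids = [p.piece_id for p in stimuli.pieces]
    if not replace and n_music > len(piece_ids):
        raise ValueError(
            f"{n_music} music trials but only {len(piece_ids)} pieces "
            "(set replace=True to reuse pieces)"
        )
    rng = np.random.default_rng(seed)
    if replace:
        assigned = list(rng.choice(piece_ids, size=n_music, replace=True))
    else:
        assigned = list(rng.permutation(piece_ids)[:n_music])

    trials: list[Trial] = []
    run_lengths: list[float] = []
    trial_id = 0
    pick = 0
    for run in range(1, n_runs + 1):
        types = (
            ["music_only"] * type_mix[0]
            + ["music_reporting"] * type_mix[1]
            + ["reporting_only"] * type_mix[2]
        )
        types = [types[i] for i in rng.permutation(len(types))]
        t = 0.0
        for ttype in types:
            fix = float(rng.uniform(*fixation_range_s))
            onset = t + fix
            pid = None
            if ttype in MUSIC_TRIAL_TYPES:
                pid = int(assigned[pick])
                pick += 1
            trials.append(
                Trial(
                    trial_id=trial_id,
                    run=run,
                    type=ttype,
                    onset=onset,
                    duration=duration,
                    piece_id=pid,
                )
            )
            trial_id += 1
            t = onset + duration + break_s
        run_lengths.append(t + post_run_rest_s)
    return TrialSchedule(trials=trials, run_lengths_s=run_lengths)


def one_over_f_noise(n_samples: int, rng: np.random.Generator,
                     n_series: int = 1) -> np.ndarray:
    """Unit-variance 1/f-amplitude (pink-like) noise, shape (n_series, n)."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def music_envelope(waveform: np.ndarray, fs: float, lowpass_hz: float,
                   lag_s: float = 0.0) -> np.ndarray:
    """Low-passed amplitude envelope, optionally lagged (zero-padded)."""
    env = np.abs(np.asarray(waveform, float))
    if lowpass_hz and lowpass_hz < fs / 2:
        sos = signal.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
        env = signal.sosfiltfilt(sos, env)
    lag = int(round(lag_s * fs))
    if lag > 0:
        env = np.concatenate([np.zeros(lag), env[:-lag]])
    return env


def simulate_eeg(
    stimuli: StimulusSet,
    schedule: TrialSchedule,
    leadfield,
    active_dipoles,
    config: SimulationConfig,
) -> EEGRecording:
    """Forward-model EEG for the whole session (runs concatenated).

    Active dipoles (the fMRI-selected locations) carry
    ``coupling_gain * envelope`` of the scheduled music plus 1/f source
    noise; during reporting-only trials and rests they carry noise only.
    Background sources at random grid points add spatially structured 1/f
    noise, and white sensor noise is added at the channels.
    """
    locations = getattr(active_dipoles, "locations", active_dipoles)
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    src_idx = []
    for loc in locations:
        idx, dist = leadfield.nearest_source(loc)
        if dist > 1e-3:
            raise LookupError(
                f"active dipole {loc} is not on the leadfield grid "
                f"(nearest point {dist:.2f} mm away)"
            )
        src_idx.append(idx)

    if leadfield.n_channels != config.n_channels:
        raise ValueError(
            f"leadfield has {leadfield.n_channels} channels, "
            f"config expects {config.n_channels}"
        )
    fs = config.fs_eeg
    rng = np.random.default_rng(config.seed)
    run_samples = [int(round(L * fs)) for L in schedule.run_lengths_s]
    n_total = sum(run_samples)
    run_offsets = np.concatenate([[0], np.cumsum(run_samples)])[:-1]

    # one fixed orientation and relative gain per active dipole
    orientations = rng.standard_normal((len(src_idx), 3))
    orientations /= np.linalg.norm(orientations, axis=1, keepdims=True)
    rel_gain = rng.uniform(0.5, 1.0, size=len(src_idx))

    # stimulus drive, common to all active dipoles
    drive = np.zeros(n_total)
    for tr in schedule.music_trials():
        piece = stimuli.piece(tr.piece_id)
        wav = piece.waveform
        if piece.fs != fs:
            from .io import resample_waveform

            wav = resample_waveform(wav, piece.fs, fs)
        env = music_envelope(wav, fs, config.envelope_lowpass_hz,
                             config.envelope_lag_s)
        start = int(run_offsets[tr.run - 1] + round(tr.onset * fs))
        seg = min(len(env), n_total - start)
        drive[start : start + seg] = env[:seg]

    data = np.zeros((leadfield.n_channels, n_total))
    for j, (v, ori, g) in enumerate(zip(src_idx, orientations, rel_gain)):
        activity = config.coupling_gain * g * drive
        if config.source_noise_sd > 0:
            activity = activity + config.source_noise_sd * one_over_f_noise(
                n_total, rng
            )[0]
        data += (leadfield.gain_at(v) @ ori)[:, None] * activity[None, :]

    if config.n_background_sources > 0 and config.source_noise_sd > 0:
        bg_pool = [i for i in range(leadfield.n_sources) if i not in set(src_idx)]
        bg = rng.choice(bg_pool, size=min(config.n_background_sources,
                                          len(bg_pool)), replace=False)
        noise = one_over_f_noise(n_total, rng, n_series=len(bg))
        for j, v in enumerate(bg):
            ori = rng.standard_normal(3)
            ori /= np.linalg.norm(ori)
            data += (leadfield.gain_at(v) @ ori)[:, None] * (
                config.source_noise_sd * noise[j][None, :]
            )

    if config.sensor_noise_sd > 0:
        brain_rms = np.sqrt(np.mean(data**2))
        noise_sd = config.sensor_noise_sd * (brain_rms or 1.0)
        data += rng.normal(0.0, noise_sd, size=data.shape)

    return EEGRecording(
        data=data,
        fs=fs,
        ch_names=list(leadfield.channel_names),
        run_offsets_s=[float(o / fs) for o in run_offsets],
    )


@dataclass
class BOLDVolume4D:
    """BOLD-like 4D volume with the planted activation truth attached."""

    img: object  # nibabel Nifti1Image
    coords: np.ndarray  # (n_vox, 3) voxel-centre mm
    active_mask: np.ndarray  # (n_vox,) bool
    tr_s: float


def cube_grid(spacing_mm: float, half_extent: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic voxel lattice: returns (coords (n,3) mm, affine 4x4)."""
    ax = np.arange(-half_extent, half_extent + 1) * spacing_mm
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[:3, 3] = -half_extent * spacing_mm
    return pts, affine


def simulate_bold(
    schedule: TrialSchedule,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    active_cluster_centres: np.ndarray | None = None,
    seed: int = 0,
    tr_s: float = 2.0,
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    cluster_radius_mm: float = 15.0,
    spacing_mm: float = 15.0,
    half_extent: int = 5,
) -> BOLDVolume4D:
    """BOLD-like volume whose active clusters follow the music boxcar * HRF.

    ``grid`` may be a (coords, affine) pair; by default a cubic lattice with
    the leadfield spacing is used, so cluster centres coincide with leadfield
    grid points. Voxels within ``cluster_radius_mm`` of a centre carry the
    HRF-convolved music regressor scaled by ``amplitude`` on top of white
    noise of ``noise_sd``.
    """
    import nibabel as nib

    if grid is None:
        coords, affine = cube_grid(spacing_mm, half_extent)
    else:
        coords, affine = grid
        coords = np.asarray(coords, dtype=float)
    side = int(round(len(coords) ** (1 / 3)))
    if side**3 != len(coords):
        raise ValueError("grid must be a full cube lattice")

    active = np.zeros(len(coords), dtype=bool)
    if active_cluster_centres is not None:
        centres = np.atleast_2d(np.asarray(active_cluster_centres, dtype=float))
        for c in centres:
            d = np.linalg.norm(coords - c, axis=1)
            if d.min() > 1e-3:
                raise LookupError(f"cluster centre {c} is not on the grid")
            active |= d <= cluster_radius_mm

    X, _, n_vols = build_design(schedule, tr_s=tr_s)
    regressor = X[:, 0]  # HRF-convolved music boxcar
    peak = np.abs(regressor).max()
    if peak > 0:
        regressor = regressor / peak
    n_t = len(regressor)

    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, noise_sd, size=(len(coords), n_t)) if noise_sd > 0 \
        else np.zeros((len(coords), n_t))
    data[active] += amplitude * regressor[None, :]

    vol = data.reshape(side, side, side, n_t)
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    img.header.set_zooms((spacing_mm, spacing_mm, spacing_mm, tr_s))
    return BOLDVolume4D(img=img, coords=coords, active_mask=active, tr_s=tr_s)
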