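"""File formats, containers and provenance helpers.

EEG goes out as EDF (16-bit) or BrainVision (IEEE float32, multiplexed) and
comes back in through MNE's readers. Audio is plain WAV via scipy. Leadfields,
ICA decompositions, feature matrices and decoder weights live in small HDF5
containers. Amplitudes are treated as microvolts throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

logger = logging.getLogger(__name__)


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is (n_channels, n_samples) in µV."""

    data: np.ndarray
    fs: float
    ch_names: list[str]
    run_offsets_s: list[float] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.ch_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# audio

def write_wav(path, waveform: np.ndarray, fs: float, subtype: str = "float32") -> None:
    """Write a mono waveform as WAV (``float32`` or ``pcm16``)."""
    w = np.asarray(waveform, dtype=float)
    if subtype == "float32":
        wavfile.write(path, int(fs), w.astype(np.float32))
    elif subtype == "pcm16":
        peak = np.abs(w).max() or 1.0
        wavfile.write(path, int(fs), np.round(w / peak * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def read_audio(path) -> tuple[np.ndarray, float]:
    """Read a WAV file as mono float; stereo is averaged with a notice."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483647.0
    else:
        data = data.astype(float)
    if data.ndim == 2:
        logger.info("stereo WAV %s averaged to mono", path)
        data = data.mean(axis=1)
    return data, float(fs)


def resample_waveform(waveform: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling, e.g. audio at 44.1 kHz down to the EEG rate."""
    frac = Fraction(fs_out / fs_in).limit_denominator(10**6)
    return signal.resample_poly(np.asarray(waveform, float), frac.numerator,
                                frac.denominator)


# ---------------------------------------------------------------------------
# EEG writers (EDF 16-bit; BrainVision float32) and the MNE-backed reader

def write_edf(path, rec: EEGRecording) -> None:
    """Write an EDF file with 1 s data records and 16-bit samples.

    The last record is zero-padded to a whole second; reading the file back
    therefore returns ``ceil(n_samples / fs) * fs`` samples.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    pmin = np.floor(data.min(axis=1))
    pmax = np.ceil(data.max(axis=1))
    same = pmax <= pmin
    pmax[same] = pmin[same] + 1.0

    def pad(text: str, n: int) -> bytes:
        s = text[:n]
        return (s + " " * (n - len(s))).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("synthetic recording", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    per_channel = [
        [pad(nm, 16) for nm in rec.ch_names],
        [pad("EEG", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{v:g}"[:8], 8) for v in pmin],
        [pad(f"{v:g}"[:8], 8) for v in pmax],
        [pad("-32768", 8)] * n_ch,
        [pad("32767", 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(fs), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    for block in per_channel:
        header += b"".join(block)

    pmin_r = np.array([float(f"{v:g}"[:8]) for v in pmin])
    pmax_r = np.array([float(f"{v:g}"[:8]) for v in pmax])
    scale = (pmax_r - pmin_r) / 65535.0
    digital = np.round((data - pmin_r[:, None]) / scale[:, None]) - 32768
    digital = np.clip(digital, -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def write_brainvision(basepath, rec: EEGRecording) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, float32 multiplexed).

    Returns the path of the .vhdr file.
    """
    base = Path(basepath)
    if base.suffix == ".vhdr":
        base = base.with_suffix("")
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    sampling_interval_us = 1e6 / rec.fs
    with open(vhdr, "w", encoding="utf-8") as fh:
        fh.write("Brain Vision Data Exchange Header File Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write("Codepage=UTF-8\n")
        fh.write(f"DataFile={eeg.name}\n")
        fh.write(f"MarkerFile={vmrk.name}\n")
        fh.write("DataFormat=BINARY\n")
        fh.write("DataOrientation=MULTIPLEXED\n")
        fh.write(f"NumberOfChannels={rec.n_channels}\n")
        fh.write(f"SamplingInterval={sampling_interval_us:.6f}\n\n")
        fh.write("[Binary Infos]\n")
        fh.write("BinaryFormat=IEEE_FLOAT_32\n\n")
        fh.write("[Channel Infos]\n")
        for i, name in enumerate(rec.ch_names, start=1):
            fh.write(f"Ch{i}={name},,1,µV\n")
    with open(vmrk, "w", encoding="utf-8") as fh:
        fh.write("Brain Vision Data Exchange Marker File, Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write("Codepage=UTF-8\n")
        fh.write(f"DataFile={eeg.name}\n\n")
        fh.write("[Marker Infos]\n")
        fh.write("Mk1=New Segment,,1,1,0,00000000000000000000\n")
        if rec.run_offsets_s:
            for i, off in enumerate(rec.run_offsets_s, start=1):
                samp = int(round(off * rec.fs)) + 1
                fh.write(f"Mk{i + 1}=Stimulus,run{i},{samp},1,0\n")
    rec.data.astype("<f4").T.tofile(eeg)
    return vhdr


def read_eeg(path) -> EEGRecording:
    """Read EDF or BrainVision EEG through MNE; amplitudes returned in µV."""
    import mne

    path = Path(path)
    try:
        if path.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif path.suffix.lower() == ".vhdr":
            for line in path.read_text(encoding="utf-8",
                                       errors="replace").splitlines():
                if line.startswith(("MarkerFile=", "DataFile=")):
                    ref = path.parent / line.split("=", 1)[1].strip()
                    if not ref.exists():
                        raise FileNotFoundError(
                            f"{path} references missing file {ref.name} "
                            "(.vhdr/.vmrk/.eeg names must match)"
                        )
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unsupported EEG format: {path.suffix}")
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"could not read {path}: a BrainVision triplet needs matching "
            f".vhdr/.vmrk/.eeg files ({exc})"
        ) from exc
    data = raw.get_data() * 1e6  # MNE returns volts
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        ch_names=list(raw.ch_names))


# ---------------------------------------------------------------------------
# trial schedules

def write_schedule_tsv(path, schedule) -> None:
    rows = [
        {
            "trial_id": tr.trial_id,
            "run": tr.run,
            "type": tr.type,
            "onset_s": tr.onset,
            "duration_s": tr.duration,
            "piece_id": "" if tr.piece_id is None else tr.piece_id,
        }
        for tr in schedule.trials
    ]
    with open(path, "w") as fh:
        fh.write("# run_lengths_s=" + ",".join(f"{v:.6f}" for v in
                                               schedule.run_lengths_s) + "\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_schedule_tsv(path):
    from .synthdata import Trial, TrialSchedule

    with open(path) as fh:
        first = fh.readline().strip()
        run_lengths = None
        if first.startswith("# run_lengths_s="):
            run_lengths = [float(v) for v in first.split("=", 1)[1].split(",")]
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    trials = [
        Trial(
            trial_id=int(r.trial_id),
            run=int(r.run),
            type=str(r.type),
            onset=float(r.onset_s),
            duration=float(r.duration_s),
            piece_id=None
            if (isinstance(r.piece_id, float) and np.isnan(r.piece_id))
            or r.piece_id == ""
            else int(r.piece_id),
        )
        for r in df.itertuples()
    ]
    if run_lengths is None:
        run_lengths = [
            max(tr.onset + tr.duration for tr in trials if tr.run == run) + 1.0
            for run in sorted({tr.run for tr in trials})
        ]
    return TrialSchedule(trials=trials, run_lengths_s=run_lengths)


# ---------------------------------------------------------------------------
# HDF5 containers

def save_decomposition(path, decomp) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mixing", data=decomp.mixing)
        f.create_dataset("unmixing", data=decomp.unmixing)
        if decomp.sources is not None:
            f.create_dataset("sources", data=decomp.sources)
        f.attrs["lags"] = list(decomp.lags)


def load_decomposition(path):
    from .preprocess import ICADecomposition

    with h5py.File(path, "r") as f:
        return ICADecomposition(
            unmixing=f["unmixing"][()],
            mixing=f["mixing"][()],
            sources=f["sources"][()] if "sources" in f else None,
            lags=tuple(int(v) for v in f.attrs["lags"]),
        )


def save_features(path, fm) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=fm.values)
        f.create_dataset("row_map", data=np.asarray(fm.row_map, dtype=int))
        f.attrs["fs"] = fm.fs
        f.attrs["n_l"] = fm.n_l
        f.attrs["M"] = fm.n_components


def load_features(path):
    from .source_features import FeatureMatrix

    with h5py.File(path, "r") as f:
        return FeatureMatrix(
            values=f["features"][()],
            row_map=[tuple(r) for r in f["row_map"][()]],
            fs=float(f.attrs["fs"]),
        )


def save_model(path, model) -> None:
    """Persist decoder weights plus the JSON-encoded spec."""
    with h5py.File(path, "w") as f:
        for name, arr in model.parameters().items():
            f.create_dataset(f"params/{name}", data=arr)
        f.attrs["spec"] = json.dumps(model.spec.to_dict())


def load_model(path):
    from .decoder import BiLSTMRegressor, DecoderSpec

    with h5py.File(path, "r") as f:
        spec = DecoderSpec.from_dict(json.loads(f.attrs["spec"]))
        model = BiLSTMRegressor(spec)
        params = {name: f[f"params/{name}"][()] for name in f["params"]}
        model.set_parameters(params)
    return model


# ---------------------------------------------------------------------------
# provenance

def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_block(config: dict) -> dict:
    from . import __version__

    return {"package_version": __version__, "config_hash": config_hash(config)}
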