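"""End-to-end pipeline: simulate → GLM → select → SOBI → features → train →
evaluate.

:func:`run_pipeline` chains every stage on a single configuration and seed;
the same configuration and seed reproduce the same report bit-for-bit on
one CPU thread. With an output directory, expensive stage artifacts
(decomposition, reconstructions, report) are written with a configuration
hash and reloaded on rerun instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import decoder as dec
from . import evaluation as ev
from . import fmri_select as fm
from . import headmodel as hm
from . import io as mio
from . import preprocess as pp
from . import source_features as sf
from . import synthdata as sd

logger = logging.getLogger(__name__)


@dataclass
class StimulusParams:
    n_pieces: int = 36
    duration_s: float = 40.0
    fs: float = 1000.0
    tempo_range_bpm: tuple[float, float] = (60.0, 180.0)
    onset_jitter_sd: float = 0.05


@dataclass
class ScheduleParams:
    n_runs: int = 3
    trials_per_run: int = 12
    type_mix: tuple[int, int, int] = (5, 5, 2)


@dataclass
class HeadParams:
    shell_radii_mm: tuple[float, ...] = hm.DEFAULT_SHELL_RADII_MM
    conductivities: tuple[float, ...] = hm.DEFAULT_CONDUCTIVITIES
    grid_spacing_mm: float = hm.DEFAULT_GRID_SPACING_MM
    n_terms: int = 100


@dataclass
class BoldParams:
    tr_s: float = 2.0
    amplitude: float = 1.0
    noise_sd: float = 0.5
    cluster_radius_mm: float = 15.0
    n_clusters: int = 4
    min_separation_mm: float = 45.0


@dataclass
class SelectParams:
    alpha: float = 0.05
    m_mm: float = 30.0
    n_l: int = 4
    correction: str = "bonferroni"


@dataclass
class EvalParams:
    n_boot: int = 4000
    n_perm: int = 10000
    filter_band: tuple[float, float] = (0.035, 4.75)
    exclusion: str = "different_piece"


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run; ``seed`` feeds every stage."""

    seed: int = 0
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    head: HeadParams = field(default_factory=HeadParams)
    sim: sd.SimulationConfig = field(default_factory=sd.SimulationConfig)
    bold: BoldParams = field(default_factory=BoldParams)
    select: SelectParams = field(default_factory=SelectParams)
    sobi_lags: int = 100
    eloreta_alpha: float = 0.05
    decoder_spec: str = "desk"
    decoder_overrides: dict = field(default_factory=dict)
    evaluation: EvalParams = field(default_factory=EvalParams)
    downsample_factor: int = 10

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("stimulus", StimulusParams),
            ("schedule", ScheduleParams),
            ("head", HeadParams),
            ("sim", sd.SimulationConfig),
            ("bold", BoldParams),
            ("select", SelectParams),
            ("evaluation", EvalParams),
        ):
            if key in d and isinstance(d[key], dict):
                kw = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d[key].items()
                }
                d[key] = sub(**kw)
        return cls(**d)

    @classmethod
    def smoke(cls) -> "PipelineConfig":
        """Tiny configuration for fast end-to-end smoke runs."""
        return cls(
            stimulus=StimulusParams(n_pieces=6, duration_s=8.0),
            schedule=ScheduleParams(n_runs=2, trials_per_run=3,
                                    type_mix=(1, 1, 1)),
            decoder_overrides={"epochs": 3, "hidden_units": 8, "chunk_s": 4.0},
            evaluation=EvalParams(n_boot=200, n_perm=200),
        )


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    stimuli: sd.StimulusSet
    schedule: sd.TrialSchedule
    leadfield: hm.Leadfield
    planted_centres: np.ndarray
    tmap: fm.TMap
    dipoles: fm.DipoleSet
    decomposition: pp.ICADecomposition
    inverse: sf.InverseOperator
    trials: list[dec.TrialData]
    models: dict
    reconstruction: dec.Reconstruction
    similarity: ev.SimilarityReport
    rank_result: ev.RankResult
    tempo_report: ev.TempoReport
    report: dict


def choose_planted_centres(leadfield: hm.Leadfield, n: int,
                           min_separation_mm: float, seed: int,
                           depth_range_mm: tuple[float, float] = (30.0, 70.0),
                           ) -> np.ndarray:
    """Well-separated, EEG-visible grid points to plant activity at."""
    rng = np.random.default_rng(seed)
    r = np.linalg.norm(leadfield.grid, axis=1)
    pool = np.flatnonzero((r >= depth_range_mm[0]) & (r <= depth_range_mm[1]))
    pool = pool[rng.permutation(len(pool))]
    chosen: list[int] = []
    for idx in pool:
        if len(chosen) >= n:
            break
        loc = leadfield.grid[idx]
        if chosen and np.linalg.norm(
            leadfield.grid[chosen] - loc, axis=1
        ).min() <= min_separation_mm:
            continue
        chosen.append(int(idx))
    if len(chosen) < n:
        raise RuntimeError(
            f"could not place {n} centres at {min_separation_mm} mm separation"
        )
    return leadfield.grid[chosen]


def assemble_trials(
    schedule: sd.TrialSchedule,
    stimuli: sd.StimulusSet,
    decomp: pp.ICADecomposition,
    invop: sf.InverseOperator,
    dipoles,
    fs_eeg: float,
    run_offsets_s: list[float],
    factor: int = 10,
) -> list[dec.TrialData]:
    """Aligned per-music-trial feature blocks and targets at the decoder rate.

    Feature rows are the per-IC source projections at the selected dipoles,
    computed on each trial's EEG segment and downsampled by ``factor``;
    targets are the piece waveforms downsampled the same way.
    """
    scal = sf.feature_scalings(decomp, invop, dipoles)  # (M, n_l)
    M, n_l = scal.shape
    trials = []
    for tr in schedule.music_trials():
        piece = stimuli.piece(tr.piece_id)
        start = int(round(run_offsets_s[tr.run - 1] * fs_eeg)
                    + round(tr.onset * fs_eeg))
        length = int(round(tr.duration * fs_eeg))
        seg = decomp.sources[:, start : start + length]  # (M, T)
        feats = (scal[:, :, None] * seg[:, None, :]).reshape(M * n_l, -1)
        feats = dec.downsample(feats, factor, axis=1)
        target = dec.downsample(piece.waveform, factor)
        T = min(feats.shape[1], len(target))
        trials.append(
            dec.TrialData(
                trial_id=tr.trial_id,
                run=tr.run,
                piece_id=tr.piece_id,
                features=feats[:, :T],
                target=target[:T],
            )
        )
    return trials


def _stage(out_dir, name, loader, saver, compute, chash):
    """Load a stage artifact if present (matching config hash), else compute
    and save."""
    if out_dir is None:
        return compute()
    path = Path(out_dir) / name
    if path.exists():
        try:
            obj, stored = loader(path)
            if stored == chash:
                logger.info("stage %s: loaded from %s", name, path)
                return obj
            logger.info("stage %s: stale hash, recomputing", name)
        except Exception as exc:  # corrupt artifact: recompute
            logger.warning("stage %s: could not load (%s), recomputing",
                           name, exc)
    obj = compute()
    saver(path, obj)
    return obj


def run_pipeline(config: PipelineConfig, out_dir=None,
                 shuffle_targets_seed: int | None = None) -> PipelineResult:
    """Execute every stage and return the collected results.

    ``shuffle_targets_seed`` trains the decoder on randomly re-paired
    targets — the chance-level control; evaluation then measures what the
    pipeline reports when the features carry no information about their
    own trial's music.
    """
    cfg = config
    chash = mio.config_hash(cfg.to_dict())
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage: stimuli + schedule")
    stimuli = sd.generate_music(
        n_pieces=cfg.stimulus.n_pieces,
        duration_s=cfg.stimulus.duration_s,
        fs=cfg.stimulus.fs,
        tempo_range_bpm=cfg.stimulus.tempo_range_bpm,
        seed=cfg.seed,
        onset_jitter_sd=cfg.stimulus.onset_jitter_sd,
    )
    schedule = sd.generate_schedule(
        n_runs=cfg.schedule.n_runs,
        trials_per_run=cfg.schedule.trials_per_run,
        stimuli=stimuli,
        seed=cfg.seed + 1,
        type_mix=cfg.schedule.type_mix,
    )

    logger.info("stage: leadfield")
    sensors = hm.standard_sensor_array(
        scalp_radius_mm=cfg.head.shell_radii_mm[-1]
    )
    leadfield = hm.build_spherical_leadfield(
        sensors,
        shell_radii_mm=cfg.head.shell_radii_mm,
        shell_conductivities=cfg.head.conductivities,
        grid_spacing_mm=cfg.head.grid_spacing_mm,
        n_terms=cfg.head.n_terms,
    )

    planted = choose_planted_centres(
        leadfield, cfg.bold.n_clusters, cfg.bold.min_separation_mm,
        seed=cfg.seed + 2,
    )

    logger.info("stage: BOLD simulation + GLM + dipole selection")
    half_extent = int(np.floor(cfg.head.shell_radii_mm[0]
                               / cfg.head.grid_spacing_mm))
    bold = sd.simulate_bold(
        schedule,
        active_cluster_centres=planted,
        seed=cfg.seed + 3,
        tr_s=cfg.bold.tr_s,
        amplitude=cfg.bold.amplitude,
        noise_sd=cfg.bold.noise_sd,
        cluster_radius_mm=cfg.bold.cluster_radius_mm,
        spacing_mm=cfg.head.grid_spacing_mm,
        half_extent=half_extent,
    )
    tmap = fm.glm_tmap(bold.img, schedule, tr_s=cfg.bold.tr_s)
    dipoles = fm.select_dipoles(
        tmap,
        alpha=cfg.select.alpha,
        m_mm=cfg.select.m_mm,
        n_l=cfg.select.n_l,
        correction=cfg.select.correction,
    )
    if len(dipoles) == 0:
        raise RuntimeError("no dipoles selected: GLM found no significant voxels")
    # keep only selected dipoles that fall inside the source grid
    inside = [
        i for i, loc in enumerate(dipoles.locations)
        if np.linalg.norm(leadfield.grid - loc, axis=1).min()
        <= leadfield.spacing_mm
    ]
    if len(inside) < len(dipoles):
        logger.warning(
            "%d selected voxel(s) fall outside the source grid; kept %d",
            len(dipoles) - len(inside), len(inside),
        )
        dipoles = fm.DipoleSet(
            locations=dipoles.locations[inside],
            t_values=dipoles.t_values[inside],
            m_mm=dipoles.m_mm,
            n_l=dipoles.n_l,
            indices=dipoles.indices[inside],
        )

    logger.info("stage: EEG simulation")
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed + 4)
    eeg = sd.simulate_eeg(stimuli, schedule, leadfield, planted, sim)

    logger.info("stage: SOBI")

    def compute_sobi():
        return pp.sobi(eeg, lags=range(1, cfg.sobi_lags + 1))

    def load_sobi(path):
        with h5py.File(path, "r") as f:
            stored = f.attrs.get("config_hash", "")
        return mio.load_decomposition(path), stored

    def save_sobi(path, obj):
        mio.save_decomposition(path, obj)
        with h5py.File(path, "a") as f:
            f.attrs["config_hash"] = chash

    decomp = _stage(out_dir, "sobi.h5", load_sobi, save_sobi, compute_sobi,
                    chash)

    logger.info("stage: eLORETA + features")
    invop = sf.eloreta_kernel(leadfield, alpha=cfg.eloreta_alpha)
    trials = assemble_trials(
        schedule, stimuli, decomp, invop, dipoles,
        fs_eeg=cfg.sim.fs_eeg,
        run_offsets_s=eeg.run_offsets_s,
        factor=cfg.downsample_factor,
    )

    logger.info("stage: decoder training (%s spec)", cfg.decoder_spec)
    fs_dec = cfg.sim.fs_eeg / cfg.downsample_factor
    input_dim = trials[0].features.shape[0]
    make_spec = (dec.reference_spec if cfg.decoder_spec == "reference"
                 else dec.desk_spec)
    spec = make_spec(input_dim, seed=cfg.seed + 5, **cfg.decoder_overrides)
    plan = dec.make_fold_plan(schedule.runs)
    models, recon = dec.train_decoder(
        trials, spec, plan, fs=fs_dec,
        shuffle_targets_seed=shuffle_targets_seed,
    )

    logger.info("stage: evaluation")
    orig = [t for t in recon.targets]
    pred = [w for w in recon.waveforms]
    similarity = ev.similarity_suite(
        orig, pred, fs=fs_dec,
        n_boot=cfg.evaluation.n_boot, seed=cfg.seed + 6,
    )
    rank = ev.rank_accuracy(
        orig, pred, recon.piece_ids, fs=fs_dec,
        filter_band=cfg.evaluation.filter_band,
        exclusion=cfg.evaluation.exclusion,
    )
    ev.rank_significance(rank, n_perm=cfg.evaluation.n_perm,
                         seed=cfg.seed + 7)
    tempos = np.array(
        [stimuli.piece(pid).tempo_bpm for pid in recon.piece_ids]
    )
    tempo_rep = ev.tempo_confound(tempos, rank.rank_acc)

    report = {
        "provenance": mio.provenance_block(cfg.to_dict()),
        "n_trials": len(recon),
        "mean_r_time": similarity.mean_r_time,
        "mean_r_freq": similarity.mean_r_freq,
        "mean_ssim": similarity.mean_ssim,
        "p_r_time": similarity.p_r_time,
        "p_r_freq": similarity.p_r_freq,
        "p_ssim": similarity.p_ssim,
        "mean_rank_accuracy": rank.mean_rank_acc,
        "rank_accuracy_p": rank.p_value,
        "tempo_r": tempo_rep.r_tempo,
        "tempo_p": tempo_rep.p_tempo,
        "typicality_r": tempo_rep.r_typicality,
        "typicality_p": tempo_rep.p_typicality,
        "n_dipoles": len(dipoles),
        "shuffled_targets": shuffle_targets_seed is not None,
    }
    if out_dir is not None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        dipoles.to_json(out_dir / "dipoles.json")
        mio.write_schedule_tsv(out_dir / "schedule.tsv", schedule)
        per_trial = {
            "trial_id": recon.trial_ids,
            "piece_id": recon.piece_ids,
            "run": recon.runs,
            "fold": recon.fold_of_origin,
            "r_time": similarity.r_time.tolist(),
            "r_freq": similarity.r_freq.tolist(),
            "ssim": similarity.ssim_tf.tolist(),
            "rank_accuracy": rank.rank_acc.tolist(),
        }
        import pandas as pd

        pd.DataFrame(per_trial).to_csv(out_dir / "per_trial.tsv", sep="\t",
                                       index=False)

    return PipelineResult(
        config=cfg,
        stimuli=stimuli,
        schedule=schedule,
        leadfield=leadfield,
        planted_centres=planted,
        tmap=tmap,
        dipoles=dipoles,
        decomposition=decomp,
        inverse=invop,
        trials=trials,
        models=models,
        reconstruction=recon,
        similarity=similarity,
        rank_result=rank,
        tempo_report=tempo_rep,
        report=report,
    )
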