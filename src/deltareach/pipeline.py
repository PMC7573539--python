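"""End-to-end orchestration: cohort generation through group statistics.

One synthetic subject = one generated dataset with its own seeds; group
analyses consume the cohort. Every stage can be cached to disk so the CLI
subcommands can resume mid-pipeline. All randomness derives from
``base_seed``; identical configuration and seeds give identical reports.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    OnsetDetectionParams,
    detect_all_trials,
    detect_eye_onset,
    rm_anova_two_way,
)
from .core import CONDITIONS, DIRECTIONS, ROI_NAMES, Recording
from .decoding import (
    AccuracyCurve,
    crossval_accuracy_curve,
    shuffle_significance_level,
    summarize_peaks,
)
from .encoding import build_design_matrix, fit_glm_epochs
from .epochs import apply_rejection, extract_epochs, reject_artifact_epochs
from .permstats import fdr_bh, permutation_paired_ttest, permutation_signflip_test
from .preprocess import PreprocessConfig, preprocess_recording
from .simulate import Experiment, SimulationConfig, generate_experiment
from .sourcespace import (
    compute_sloreta_operator,
    estimate_gfp,
    estimate_noise_covariance,
    roi_average,
    voxel_norm,
)

STAGES = (
    "generate",
    "preprocess",
    "behavior",
    "epochs",
    "encoding",
    "source",
    "decoding",
    "stats",
)

ALIGNMENTS = ("trial_start", "movement_onset")


@dataclass
class PipelineConfig:
    """Stage parameters; defaults follow the emulated study."""

    n_subjects: int = 15
    base_seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    prep: PreprocessConfig = field(default_factory=PreprocessConfig)

    window_trial: tuple = (0.75, 4.75)
    window_move: tuple = (-2.0, 1.25)
    outlier_k: float = 2.5

    # intervals (s) over which factor maps are averaged for group tests
    peak_window_trial: tuple = (2.9, 3.4)
    peak_window_move: tuple = (-0.3, 0.3)

    noise_shrink: float = 0.1
    inverse_lam: float = 0.05
    gfp_reps: int = 10000

    decode_condition: bool = True
    decode_direction: bool = True
    decode_per_condition: bool = True
    decode_windowed: bool = True
    window_len: int = 6
    n_shuffles: int = 1000       # 0 disables shuffle significance levels
    decode_min_per_class: int = 6  # skip a decoding task below this count

    n_perm: int = 10000
    fdr_q: float = 0.05
    stages: tuple = STAGES

    @classmethod
    def desk(cls) -> "PipelineConfig":
        """Desk-scale cohort: small enough for a single CPU smoke run."""
        return cls(
            n_subjects=5,
            sim=SimulationConfig(n_trials=80, n_voxels=120),
            gfp_reps=1000,
            n_perm=1000,
            n_shuffles=0,
            decode_per_condition=False,
        )

    def to_yaml(self) -> str:
        d = asdict(self)
        d["sim"] = asdict(self.sim)
        d["prep"] = asdict(self.prep)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        d["sim"] = SimulationConfig(**d.get("sim", {}))
        d["prep"] = PreprocessConfig(**d.get("prep", {}))
        for key in ("window_trial", "window_move", "peak_window_trial",
                    "peak_window_move", "stages"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def subject_seed(base_seed: int, subject: int) -> int:
    return int((base_seed * 100003 + subject * 7919 + 1) % (2**31 - 1))


@dataclass
class SubjectResult:
    subject: int
    seed: int
    trials: pd.DataFrame
    eye_onsets: dict
    cell_means: dict                       # metric -> 2 x 4 array
    n_rejected: dict
    gfp: float
    factor_maps: dict                      # (alignment, factor) -> V x 3 (peak-window avg)
    factor_src: dict                       # alignment -> T x V x 3 x n_factors
    factor_names: dict                     # alignment -> tuple of factor names
    cond_dir_maps: dict                    # (alignment, condition) -> V (direction norm)
    curves: dict                           # task name -> AccuracyCurve
    mean_move_onset: float
    mean_move_offset: float


@dataclass
class Report:
    config_yaml: str
    behavior: dict
    encoding: dict
    decoding: dict
    provenance: dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="list")
            return str(o)

        return json.dumps(
            {
                "behavior": self.behavior,
                "encoding": self.encoding,
                "decoding": self.decoding,
                "provenance": self.provenance,
            },
            default=default,
            sort_keys=True,
            indent=1,
        )


def _interval_mask(times: np.ndarray, interval) -> np.ndarray:
    return (times >= interval[0]) & (times <= interval[1])


def run_subject(cfg: PipelineConfig, subject: int) -> SubjectResult:
    """Run all within-subject stages for one synthetic participant."""
    seed = subject_seed(cfg.base_seed, subject)
    exp: Experiment = generate_experiment(cfg.sim, seed=seed)
    prep = preprocess_recording(exp.eeg, exp.calibration, cfg.prep)

    # --- behavior ---------------------------------------------------------
    trials = detect_all_trials(
        exp.cursor, exp.trials, OnsetDetectionParams(), cfg.outlier_k
    )
    eye_onsets = detect_eye_onset(exp.eeg, trials)
    good_beh = ~trials["outlier"].to_numpy()
    cell_means = {}
    rel_onset = trials["detected_onset"] - trials["t_trial_start"]
    for metric, series in (("onset", rel_onset), ("duration", trials["duration"])):
        table = np.full((2, 4), np.nan)
        for ic, c in enumerate(CONDITIONS):
            for idx, d in enumerate(DIRECTIONS):
                sel = (
                    (trials["condition"] == c)
                    & (trials["direction"] == d)
                    & good_beh
                )
                table[ic, idx] = series[sel].mean()
        cell_means[metric] = table
    mean_onset = float(rel_onset[good_beh].mean())
    mean_offset = float(
        (trials["detected_offset"] - trials["t_trial_start"])[good_beh].mean()
    )

    # --- epochs + rejection ----------------------------------------------
    keep = trials.index[good_beh].to_numpy()
    anchors = {
        "trial_start": trials.loc[keep, "t_trial_start"].to_numpy(),
        "movement_onset": trials.loc[keep, "detected_onset"].to_numpy(),
    }
    windows = {"trial_start": cfg.window_trial, "movement_onset": cfg.window_move}
    delta_ep, n_rejected = {}, {}
    for al in ALIGNMENTS:
        bb = extract_epochs(
            prep.broadband, anchors[al], windows[al], alignment=al
        )
        mask, reasons = reject_artifact_epochs(bb)
        d = extract_epochs(
            prep.delta, anchors[al], windows[al], alignment=al, band="delta"
        )
        delta_ep[al] = apply_rejection(d, mask, reasons)
        n_rejected[al] = int(mask.sum())

    # --- inverse operator + GFP ------------------------------------------
    rest_n = int(cfg.sim.calib_rest_end * prep.calib_delta.fs)
    rest = prep.calib_delta.data[
        prep.calib_delta.picks("eeg")][:, :rest_n]
    noise_cov = estimate_noise_covariance(rest, cfg.noise_shrink)
    operator = compute_sloreta_operator(exp.leadfield, noise_cov, cfg.inverse_lam)
    ts_good = delta_ep["trial_start"].subset(
        np.flatnonzero(delta_ep["trial_start"].good())
    )
    gfp = estimate_gfp(ts_good, operator, n_reps=cfg.gfp_reps, seed=seed)

    # --- encoding + source maps ------------------------------------------
    factor_maps, factor_src, factor_names, cond_dir_maps = {}, {}, {}, {}
    peak_windows = {
        "trial_start": cfg.peak_window_trial,
        "movement_onset": cfg.peak_window_move,
    }
    for al in ALIGNMENTS:
        ep = delta_ep[al]
        surv = np.flatnonzero(ep.good())
        sub_trials = trials.loc[keep].reset_index(drop=True).iloc[surv]
        design = build_design_matrix(sub_trials.reset_index(drop=True), seed=seed)
        ep_fit = ep.subset(surv[design.trial_index])
        a = fit_glm_epochs(ep_fit, design)              # T x C x 4
        # kernel (V,3,C) applied over channels -> T x V x 3 x n_factors
        src = np.moveaxis(operator.apply(np.moveaxis(a, 1, 0)), 2, 0) / gfp
        tmask = _interval_mask(ep.times, peak_windows[al])
        factor_src[al] = src
        factor_names[al] = tuple(design.factor_names)
        for fi, fname in enumerate(design.factor_names):
            factor_maps[(al, fname)] = src[tmask][..., fi].mean(axis=0)  # V x 3

        # condition-specific direction encoding (for the ROI contrast)
        for cond in CONDITIONS:
            csel = np.flatnonzero(
                sub_trials["condition"].to_numpy() == cond
            )
            cdesign = build_design_matrix(
                sub_trials.iloc[csel].reset_index(drop=True),
                seed=seed,
                factors="direction",
            )
            cep = ep.subset(surv[csel[cdesign.trial_index]])
            ca = fit_glm_epochs(cep, cdesign)
            csrc = np.moveaxis(operator.apply(np.moveaxis(ca, 1, 0)), 2, 0) / gfp
            dmap = (
                voxel_norm(csrc[..., 0], axis=2)
                + voxel_norm(csrc[..., 1], axis=2)
            )                                           # T x V
            cond_dir_maps[(al, cond)] = dmap[tmask].mean(axis=0)

    # --- decoding ---------------------------------------------------------
    curves: dict[str, AccuracyCurve] = {}
    if "decoding" in cfg.stages:
        ref_times = {
            "trial_start": {
                "condition": cfg.sim.onset_mean,
                "direction": cfg.sim.t_direction_cue + cfg.sim.dir_latency,
            },
            "movement_onset": {
                "condition": 0.0,
                "direction": cfg.sim.t_direction_cue
                + cfg.sim.dir_latency
                - cfg.sim.onset_mean,
            },
        }
        for al in ALIGNMENTS:
            ep = delta_ep[al]
            surv = np.flatnonzero(ep.good())
            sub_trials = trials.loc[keep].reset_index(drop=True).iloc[surv]
            ep_good = ep.subset(surv)
            cond_labels = sub_trials["condition"].to_numpy()
            dir_labels = sub_trials["direction"].to_numpy()
            tasks = []
            if cfg.decode_condition:
                tasks.append((f"condition/{al}", ep_good, cond_labels, "single", "condition"))
            if cfg.decode_direction:
                tasks.append((f"direction/{al}", ep_good, dir_labels, "single", "direction"))
            if cfg.decode_per_condition:
                for cond in CONDITIONS:
                    sel = np.flatnonzero(cond_labels == cond)
                    tasks.append(
                        (
                            f"direction_{cond}/{al}",
                            ep_good.subset(sel),
                            dir_labels[sel],
                            "single",
                            "direction",
                        )
                    )
            if cfg.decode_windowed:
                sel = np.flatnonzero(cond_labels == "exe")
                tasks.append(
                    (
                        f"direction_windowed_exe/{al}",
                        ep_good.subset(sel),
                        dir_labels[sel],
                        "windowed",
                        "direction",
                    )
                )
            for name, e, labels, mode, kind in tasks:
                _, counts = np.unique(labels, return_counts=True)
                if counts.min() < cfg.decode_min_per_class:
                    continue
                curve = crossval_accuracy_curve(
                    e, labels, mode=mode, window_len=cfg.window_len
                )
                if cfg.n_shuffles >= 100:
                    t_ref = int(
                        np.argmin(np.abs(e.times - ref_times[al][kind]))
                    )
                    curve.significance_level = shuffle_significance_level(
                        e.data[:, :, t_ref],
                        labels,
                        n_shuffles=cfg.n_shuffles,
                        seed=seed,
                    )
                curves[name] = curve

    return SubjectResult(
        subject=subject,
        seed=seed,
        trials=trials,
        eye_onsets=eye_onsets,
        cell_means=cell_means,
        n_rejected=n_rejected,
        gfp=gfp,
        factor_maps=factor_maps,
        factor_src=factor_src,
        factor_names=factor_names,
        cond_dir_maps=cond_dir_maps,
        curves=curves,
        mean_move_onset=mean_onset,
        mean_move_offset=mean_offset,
    )


def roi_direction_contrast(
    subjects: list[SubjectResult],
    roi_labels: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired permutation t-tests of condition differences in direction
    encoding: 8 ROIs x 2 alignments = 16 tests."""
    rows = []
    for k, al in enumerate(ALIGNMENTS):
        exe = np.stack([s.cond_dir_maps[(al, "exe")] for s in subjects])
        obs = np.stack([s.cond_dir_maps[(al, "obs")] for s in subjects])
        for j, roi in enumerate(ROI_NAMES):
            sel = np.flatnonzero(roi_labels == roi)
            res = permutation_paired_ttest(
                exe[:, sel].mean(axis=1),
                obs[:, sel].mean(axis=1),
                sides="two",
                n_perm=n_perm,
                seed=seed + 31 * k + j,
            )
            rows.append(
                {
                    "roi": roi,
                    "alignment": al,
                    "t": res.statistic,
                    "p": res.p,
                    "n_perm": res.n_perm,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    cfg: PipelineConfig,
    cache_dir: str | Path | None = None,
    stop_after: str = "stats",
) -> Report:
    """Execute the cohort pipeline and assemble the report.

    ``cache_dir`` enables per-subject caching keyed by the configuration
    hash, so CLI stage commands can resume; ``stop_after`` truncates the
    stage list (sections after it are omitted from the report).
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    subjects: list[SubjectResult] = []
    for s in range(cfg.n_subjects):
        res = None
        cache_file = None
        if cache_dir is not None:
            cache_file = Path(cache_dir) / (
                f"subject-{s}-{cfg.config_hash()}.pkl"
            )
            if cache_file.exists():
                with open(cache_file, "rb") as fh:
                    res = pickle.load(fh)
        if res is None:
            try:
                res = run_subject(cfg, s)
            except Exception as err:  # attach subject context
                raise RuntimeError(
                    f"pipeline failed for subject {s}: {err}"
                ) from err
            if cache_file is not None:
                cache_file.parent.mkdir(parents=True, exist_ok=True)
                with open(cache_file, "wb") as fh:
                    pickle.dump(res, fh)
        subjects.append(res)

    lf_labels = None
    behavior: dict = {}
    encoding: dict = {}
    decoding: dict = {}

    # --- group behavior ---------------------------------------------------
    onset_tab = np.stack([s.cell_means["onset"] for s in subjects])
    dur_tab = np.stack([s.cell_means["duration"] for s in subjects])
    behavior["mean_onset"] = float(onset_tab.mean())
    if len(subjects) >= 2:
        behavior["sd_onset"] = float(onset_tab.mean(axis=(1, 2)).std(ddof=1))
    behavior["mean_duration"] = float(dur_tab.mean())
    behavior["eye_onsets"] = {
        d: float(
            np.mean(
                [s.eye_onsets[d] for s in subjects if s.eye_onsets[d] is not None]
            )
        )
        for d in DIRECTIONS
    }
    if cfg.n_subjects >= 3:
        behavior["anova_onset"] = rm_anova_two_way(onset_tab)
        behavior["anova_duration"] = rm_anova_two_way(dur_tab)
    behavior["n_rejected"] = {
        al: [s.n_rejected[al] for s in subjects] for al in ALIGNMENTS
    }

    all_p: list[np.ndarray] = []

    # --- group encoding / source stats -----------------------------------
    if (
        "stats" in cfg.stages
        and stop_after in ("source", "decoding", "stats")
        and len(subjects) >= 2
    ):
        # fetch ROI labels from a fresh leadfield (deterministic per subject 0)
        from .leadfield import build_leadfield

        lf0 = build_leadfield(
            cfg.sim.n_channels,
            cfg.sim.n_voxels,
            seed=cfg.sim.leadfield_seed
            if cfg.sim.leadfield_seed is not None
            else subjects[0].seed,
        )
        lf_labels = lf0.roi_labels
        signflip = {}
        factor_names = sorted({k[1] for k in subjects[0].factor_maps})
        for al in ALIGNMENTS:
            for fname in factor_names:
                eff = np.stack([s.factor_maps[(al, fname)] for s in subjects])
                p = permutation_signflip_test(
                    eff, n_perm=cfg.n_perm, seed=cfg.base_seed
                )
                signflip[f"{fname}/{al}"] = p
                all_p.append(p)
        encoding["signflip_p"] = signflip
        roi_tests = roi_direction_contrast(
            subjects, lf_labels, n_perm=cfg.n_perm, seed=cfg.base_seed
        )
        encoding["roi_tests"] = roi_tests
        encoding["n_roi_tests"] = len(roi_tests)
        all_p.append(roi_tests["p"].to_numpy())
        # group-average the signed source coefficients across subjects,
        # then extract voxel norms (noise cancels in the signed average)
        roi_curves = {}
        for al in ALIGNMENTS:
            names = subjects[0].factor_names[al]
            gsrc = np.mean([s.factor_src[al] for s in subjects], axis=0)
            for fi, fname in enumerate(names):
                norm_t = voxel_norm(gsrc[..., fi], axis=2)  # T x V
                for roi in ROI_NAMES:
                    roi_curves[f"{fname}/{al}/{roi}"] = roi_average(
                        norm_t.T, lf_labels, roi
                    )
        encoding["roi_norm_curves"] = roi_curves

    # --- group decoding ---------------------------------------------------
    if subjects[0].curves and stop_after in ("decoding", "stats"):
        mean_onset = float(np.mean([s.mean_move_onset for s in subjects]))
        mean_offset = float(np.mean([s.mean_move_offset for s in subjects]))
        intervals = {
            "trial_start": (cfg.sim.t_condition_cue, mean_offset),
            "movement_onset": (
                cfg.sim.t_condition_cue - mean_onset,
                mean_offset - mean_onset,
            ),
        }
        group_curves = {}
        import warnings

        for name in subjects[0].curves:
            accs = np.stack([s.curves[name].accuracy for s in subjects])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                group_curves[name] = {
                    "times": subjects[0].curves[name].times,
                    "mean_accuracy": np.nanmean(accs, axis=0),
                }
        decoding["group_curves"] = group_curves

        tasks = sorted({n.split("/")[0] for n in subjects[0].curves})
        peak_tables = {}
        for task in tasks:
            curves = {
                (s.subject, al): s.curves[f"{task}/{al}"]
                for s in subjects
                for al in ALIGNMENTS
                if f"{task}/{al}" in s.curves
            }
            summary = summarize_peaks(curves, intervals)
            peak_tables[task] = summary.peaks
            if summary.paired_differences is not None and len(subjects) >= 2:
                # alignments sort as movement_onset < trial_start:
                # diffs = movement - trial; test trial > movement (one-sided)
                res = permutation_paired_ttest(
                    -summary.paired_differences,
                    np.zeros_like(summary.paired_differences),
                    sides="one",
                    n_perm=cfg.n_perm,
                    seed=cfg.base_seed,
                )
                decoding[f"alignment_test/{task}"] = {
                    "delta_peak": float(-summary.paired_differences.mean()),
                    "t": res.statistic,
                    "p": res.p,
                }
                all_p.append(np.array([res.p]))
        decoding["peaks"] = peak_tables

    # --- pooled FDR -------------------------------------------------------
    if all_p and stop_after == "stats":
        family = np.concatenate(all_p)
        mask, crit = fdr_bh(family, cfg.fdr_q)
        encoding["fdr"] = {
            "n_tests": int(family.size),
            "n_significant": int(mask.sum()),
            "critical_p": crit,
        }

    provenance = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "base_seed": cfg.base_seed,
        "subject_seeds": [s.seed for s in subjects],
        "stages_run": [st for st in cfg.stages if STAGES.index(st) <= STAGES.index(stop_after)],
    }
    return Report(
        config_yaml=cfg.to_yaml(),
        behavior=behavior,
        encoding=encoding,
        decoding=decoding,
        provenance=provenance,
    )
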