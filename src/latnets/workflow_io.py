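"""Configuration, storage and the end-to-end pipeline driver.

Stage artifacts are written as one HDF5 array container per stage plus a
JSON sidecar carrying labels and axis metadata; tabular reports go to CSV.
``run_pipeline`` chains simulate → preprocess → ica → causality → erc →
tensor → stats → infer in dependency order, records a manifest (parameter
hashes, output paths, wall-clock) and reuses a stage's outputs when its
parameter hash is unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import h5py
import numpy as np
import yaml

from . import causality_normalization as cn
from . import preprocessing as pp
from . import source_separation as ica
from . import spectral_causality as sc
from . import structure_inference as si
from . import structure_statistics as ss
from . import synthetic_data as sd
from . import tensor_factorization as tf
from .types import CONDITIONS, TRIAL_TYPES, ScenarioLabel, TaskTimeline, TrialRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "DataError",
    "RunManifest",
    "run_pipeline",
    "SubjectData",
    "prepare_subject",
    "build_delta_maps",
    "DeltaTensorBuilder",
    "save_array_container",
    "load_array_container",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class DataError(RuntimeError):
    """Missing or inconsistent data/artifacts."""


# ---------------------------------------------------------------------------
# configuration


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class SimulateConfig:
    n_subjects: int = 3
    n_channels: int = 12
    n_sources: int = 6
    n_trials_per_type: int = 120
    fs: float = 250.0
    trial_len: float = 8.0
    p_cplus: float = 0.5
    artifact_fraction: float = 0.05
    effects: Optional[list] = None  # None → default five-structure schedule


@dataclass
class PreprocessConfig:
    screening_threshold: float = 0.8
    artifact_z: float = 4.0
    decimate_factor: int = 1
    line_hz: Optional[float] = None


@dataclass
class IcaConfig:
    m: Optional[int] = None
    variance_fraction: float = 0.90
    restarts: int = 20
    kurtosis_z: float = 15.0
    spectrum_z: float = 20.0


@dataclass
class CausalityConfig:
    window_ms: float = 250.0
    step_ms: float = 50.0
    p: Optional[int] = None  # None → AIC selection
    p_max: int = 8
    n_freqs: int = 19
    f_min: float = 4.0
    f_max: float = 120.0


@dataclass
class ErcConfig:
    alpha_fdr: float = 0.05
    n_boot: int = 200
    method: str = "normal"
    min_trials: int = 20
    baseline: Optional[tuple] = None  # None → timeline baseline interval


@dataclass
class TensorConfig:
    r: Optional[int] = None  # None → core-consistency scan
    r_max: int = 7
    threshold: float = 80.0
    n_restarts: int = 20
    tol: float = 1e-6


@dataclass
class InferConfig:
    n_shuffles: int = 50
    alpha: float = 0.05
    shuffle_n_boot: Optional[int] = None


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "latnets_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ica: IcaConfig = field(default_factory=IcaConfig)
    causality: CausalityConfig = field(default_factory=CausalityConfig)
    erc: ErcConfig = field(default_factory=ErcConfig)
    tensor: TensorConfig = field(default_factory=TensorConfig)
    infer: InferConfig = field(default_factory=InferConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        blocks = {
            "simulate": SimulateConfig,
            "preprocess": PreprocessConfig,
            "ica": IcaConfig,
            "causality": CausalityConfig,
            "erc": ErcConfig,
            "tensor": TensorConfig,
            "infer": InferConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, sub in blocks.items():
            if key in d:
                kwargs[key] = _from_dict(sub, d.pop(key) or {})
        for key in ("seed", "out_dir"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ConfigError(f"unknown top-level keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# array container


def save_array_container(path: str | Path, arrays: dict[str, np.ndarray], sidecar: dict):
    """HDF5 container + JSON sidecar (labels/axes) next to it."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for name, arr in arrays.items():
            fh.create_dataset(name, data=np.asarray(arr))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, default=str, indent=1)
    )


def load_array_container(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing artifact {path}")
    arrays = {}
    with h5py.File(path, "r") as fh:
        fh.visititems(
            lambda name, obj: arrays.__setitem__(name, obj[()])
            if isinstance(obj, h5py.Dataset)
            else None
        )
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return arrays, sidecar


# ---------------------------------------------------------------------------
# per-subject analysis state


@dataclass
class SubjectData:
    """Everything the comparison/shuffle machinery needs for one subject:
    precomputed window statistics over all kept trials plus labels."""

    subject: str
    stats: sc.WindowEnsembleStats
    trial_types: list[str]
    conditions: list[str]
    grid: sc.WindowGrid
    freqs: np.ndarray
    fs: float
    baseline_windows: np.ndarray
    kept_ics: list[int]
    mixing: Optional[np.ndarray] = None

    def type_indices(self, trial_type: str, condition: str, assignment=None) -> np.ndarray:
        types = self.trial_types if assignment is None else assignment
        return np.array(
            [
                i
                for i, (t, c) in enumerate(zip(types, self.conditions))
                if t == trial_type and c == condition
            ],
            dtype=int,
        )

    def shuffled_types(self, rng: np.random.Generator) -> list[str]:
        """Permute trial-type labels within each condition."""
        types = list(self.trial_types)
        for cond in CONDITIONS:
            idx = [i for i, c in enumerate(self.conditions) if c == cond]
            perm = rng.permutation(len(idx))
            vals = [types[i] for i in idx]
            for i, pi in zip(idx, perm):
                types[i] = vals[pi]
        return types


def prepare_subject(
    rec: TrialRecording,
    cfg: PipelineConfig,
    seed: int,
    use_ica: bool = True,
) -> tuple[SubjectData, dict]:
    """Preprocess one recording through screening, artifact rejection,
    optional filtering/decimation, source separation, stationarization and
    window-statistics precomputation."""
    report: dict[str, Any] = {}
    screening = pp.screen_condition(rec, threshold=cfg.preprocess.screening_threshold)
    rec = pp.apply_screening(rec, screening)
    report["screening"] = screening.counts()

    if cfg.preprocess.line_hz:
        rec = pp.remove_line_noise(rec, cfg.preprocess.line_hz)
    if cfg.preprocess.decimate_factor > 1:
        rec = pp.decimate(rec, cfg.preprocess.decimate_factor)

    kept, art_report = pp.reject_artifact_trials(rec, cfg.preprocess.artifact_z)
    rec = rec.subset(kept)
    report["artifacts"] = art_report

    if use_ica:
        model = ica.decompose(
            rec,
            m=cfg.ica.m,
            variance_fraction=cfg.ica.variance_fraction,
            restarts=cfg.ica.restarts,
            seed=seed,
        )
        ica.screen_components(model, cfg.ica.kurtosis_z, cfg.ica.spectrum_z)
        sources = model.kept_sources()
        kept_ics = list(model.kept)
        mixing = model.kept_mixing()
        report["ica"] = {
            "m": model.n_components,
            "kept": kept_ics,
            "variance_explained": model.variance_explained,
        }
    else:
        sources = rec.data
        kept_ics = list(range(rec.n_channels))
        mixing = None

    src_rec = TrialRecording(
        data=sources,
        fs=rec.fs,
        labels=rec.labels,
        timeline=rec.timeline,
        subject=rec.subject,
    )
    # local stationarization per condition ensemble (the unit the windowed
    # VARs are fitted over; keeps shuffle refits on a fixed normalization)
    data = np.empty_like(src_rec.data)
    for cond in CONDITIONS:
        idx = [i for i, lab in enumerate(rec.labels) if lab.condition == cond]
        if len(idx) >= 2:
            data[idx] = pp.stationarize(src_rec.subset(idx)).data
        elif idx:
            raise DataError(f"condition {cond} has a single trial; cannot normalize")

    ccfg = cfg.causality
    grid = sc.segment(data.shape[2], rec.fs, ccfg.window_ms, ccfg.step_ms)
    freqs = sc.default_frequency_grid(ccfg.n_freqs, ccfg.f_min, min(ccfg.f_max, rec.fs / 2 * 0.96))
    if ccfg.p is None:
        mid = grid.n_windows // 2
        s0 = grid.starts()[mid]
        p, aic_curve = sc.select_order_aic(
            data[:, :, s0 : s0 + grid.window_samples], ccfg.p_max
        )
        report["aic_curve"] = aic_curve.tolist()
    else:
        p = ccfg.p
    report["var_order"] = p
    n_per_type = min(
        len([t for t in rec.labels if t.trial_type == tt and t.condition == c])
        for tt in TRIAL_TYPES
        for c in CONDITIONS
    ) or 1
    report["sample_budget"] = sc.check_sample_budget(
        grid.window_samples, len(kept_ics), p, max(n_per_type, 1)
    )

    stats = sc.WindowEnsembleStats(data, grid, p)
    baseline = cfg.erc.baseline or rec.timeline.baseline
    baseline_windows = grid.windows_within(tuple(baseline))
    if baseline_windows.size == 0:
        raise DataError("no windows fall inside the baseline interval")
    subj = SubjectData(
        subject=rec.subject,
        stats=stats,
        trial_types=[lab.trial_type for lab in rec.labels],
        conditions=[lab.condition for lab in rec.labels],
        grid=grid,
        freqs=freqs,
        fs=rec.fs,
        baseline_windows=baseline_windows,
        kept_ics=kept_ics,
        mixing=mixing,
    )
    return subj, report


def build_delta_maps(
    subj: SubjectData,
    ecfg: ErcConfig,
    seed: int,
    assignment: Optional[list[str]] = None,
    n_boot: Optional[int] = None,
) -> dict[str, cn.DeltaERC]:
    """All 18 ΔERC maps for one subject (optionally under a label
    re-assignment, e.g. a shuffle)."""
    out = {}
    for ci, spec in enumerate(cn.build_comparisons()):
        ia = subj.type_indices(spec.minuend, spec.condition, assignment)
        ib = subj.type_indices(spec.subtrahend, spec.condition, assignment)
        out[spec.key] = cn.delta_erc(
            subj.stats.subset(ia),
            subj.stats.subset(ib),
            spec,
            subj.baseline_windows,
            subj.freqs,
            subj.fs,
            alpha_fdr=ecfg.alpha_fdr,
            n_boot=n_boot or ecfg.n_boot,
            seed=seed * 100 + ci,
            method=ecfg.method,
            min_trials=ecfg.min_trials,
        )
    return out


class DeltaTensorBuilder:
    """Rebuilds the ΔERC tensor, optionally under within-condition label
    shuffles — the null generator for the loading-significance test."""

    def __init__(
        self,
        subjects: list[SubjectData],
        ecfg: ErcConfig,
        seed: int,
        shuffle_n_boot: Optional[int] = None,
    ):
        self.subjects = subjects
        self.ecfg = ecfg
        self.seed = seed
        self.shuffle_n_boot = shuffle_n_boot
        self.axes: Optional[tf.TensorAxes] = None

    def build(self, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        shuffled = rng is not None
        maps = {}
        for subj in self.subjects:
            assignment = subj.shuffled_types(rng) if shuffled else None
            boot_seed = self.seed if not shuffled else int(rng.integers(2**31)) % (2**24)
            maps[subj.subject] = build_delta_maps(
                subj,
                self.ecfg,
                seed=boot_seed,
                assignment=assignment,
                n_boot=self.shuffle_n_boot if shuffled and self.shuffle_n_boot else None,
            )
        tensor, axes = tf.assemble(
            maps,
            subjects=[s.subject for s in self.subjects],
            ics_per_subject={s.subject: s.kept_ics for s in self.subjects},
        )
        self.axes = axes
        return tensor


# ---------------------------------------------------------------------------
# manifest + pipeline


@dataclass
class RunManifest:
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, params_hash: str, outputs: list[str], seconds: float, reused=False):
        self.stages[stage] = {
            "params_hash": params_hash,
            "outputs": outputs,
            "wall_clock_s": round(seconds, 3),
            "reused": reused,
        }

    def save(self, path: Path):
        path.write_text(json.dumps(self.stages, indent=1))


STAGE_ORDER = ("simulate", "preprocess", "ica", "causality", "erc", "tensor", "stats", "infer")


def run_pipeline(config: PipelineConfig, stages: Optional[set] = None) -> RunManifest:
    """Execute the pipeline end-to-end (or a requested subset of stages).

    Stage results are held in memory within one invocation; a stage subset
    that starts after ``simulate``/``preprocess`` requires upstream stages
    in the same call or raises DataError.  Artifacts and the manifest are
    written under ``config.out_dir``; reruns with unchanged parameters
    reuse existing simulate output (hash match).
    """
    requested = set(stages or STAGE_ORDER)
    unknown = requested - set(STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    state: dict[str, Any] = {}

    def need(stage, key):
        if key not in state:
            raise DataError(f"stage '{stage}' requires upstream artifact '{key}'")
        return state[key]

    # --- simulate
    if "simulate" in requested:
        t0 = time.time()
        scfg = config.simulate
        h = _hash(["simulate", dataclasses.asdict(scfg), config.seed])
        sim_path = out_dir / "simulate.h5"
        reused = False
        if sim_path.exists():
            try:
                _, side = load_array_container(sim_path)
                reused = side.get("params_hash") == h
            except Exception:
                reused = False
        if reused:
            arrays, side = load_array_container(sim_path)
            recs = _recs_from_container(arrays, side)
        else:
            recs, _ = sd.simulate_dataset(
                n_subjects=scfg.n_subjects,
                n_channels=scfg.n_channels,
                n_sources=scfg.n_sources,
                n_trials_per_type=scfg.n_trials_per_type,
                fs=scfg.fs,
                trial_len=scfg.trial_len,
                seed=config.seed,
                effects=scfg.effects,
                p_cplus=scfg.p_cplus,
                artifact_fraction=scfg.artifact_fraction,
            )
            _save_recs(sim_path, recs, h)
        state["recordings"] = recs
        manifest.record("simulate", h, [str(sim_path)], time.time() - t0, reused)

    # --- preprocess + ica + causality (per subject, fused internally)
    if {"preprocess", "ica", "causality", "erc", "tensor", "stats", "infer"} & requested:
        if "preprocess" in requested or "causality" in requested or "ica" in requested:
            t0 = time.time()
            recs = need("preprocess", "recordings")
            subjects, reports = [], {}
            for i, rec in enumerate(recs):
                subj, rep = prepare_subject(rec, config, seed=config.seed + 17 * i)
                subjects.append(subj)
                reports[rec.subject] = rep
            state["subjects"] = subjects
            rep_path = out_dir / "preprocess_report.json"
            rep_path.write_text(json.dumps(reports, indent=1, default=str))
            h = _hash(
                [
                    "prep",
                    dataclasses.asdict(config.preprocess),
                    dataclasses.asdict(config.ica),
                    dataclasses.asdict(config.causality),
                    config.seed,
                ]
            )
            for st in ("preprocess", "ica", "causality"):
                if st in requested:
                    manifest.record(st, h, [str(rep_path)], (time.time() - t0) / 3)

    if {"erc", "tensor", "stats", "infer"} & requested:
        t0 = time.time()
        subjects = need("erc", "subjects")
        builder = DeltaTensorBuilder(subjects, config.erc, seed=config.seed)
        builder.shuffle_n_boot = config.infer.shuffle_n_boot
        tensor = builder.build()
        axes = builder.axes
        state["tensor"], state["axes"], state["builder"] = tensor, axes, builder
        h = _hash(["erc", dataclasses.asdict(config.erc), config.seed])
        tpath = out_dir / "tensor.h5"
        save_array_container(
            tpath,
            {"tensor": tensor},
            {
                "params_hash": h,
                "comparisons": [sp.key for sp in axes.comparisons],
                "subjects": axes.subjects,
                "ics_per_subject": axes.ics_per_subject,
                "n_windows": axes.n_windows,
                "n_freqs": axes.n_freqs,
            },
        )
        if "erc" in requested or "tensor" in requested:
            manifest.record("erc", h, [str(tpath)], time.time() - t0)

    if {"tensor", "stats", "infer"} & requested:
        t0 = time.time()
        tensor = need("tensor", "tensor")
        tcfg = config.tensor
        if tcfg.r is None:
            scan = tf.scan_components(
                tensor,
                min(tcfg.r_max, min(tensor.shape)),
                threshold=tcfg.threshold,
                seed=config.seed,
                n_restarts=tcfg.n_restarts,
                tol=tcfg.tol,
            )
            model = scan["models"][scan["selected_r"] - 1]
            curve_path = out_dir / "consistency_curve.csv"
            _write_csv(
                curve_path,
                ["r", "consistency", "dtld", "random"],
                [
                    [r + 1, scan["consistency"][r], scan["curves"]["dtld"][r], scan["curves"]["random"][r]]
                    for r in range(len(scan["consistency"]))
                ],
            )
        else:
            model = tf.parafac(
                tensor,
                tcfg.r,
                tol=tcfg.tol,
                n_restarts=tcfg.n_restarts,
                seed=config.seed,
                compute_corcondia=True,
            )
        state["model"] = model
        h = _hash(["tensor", dataclasses.asdict(tcfg), config.seed])
        mpath = out_dir / "parafac.h5"
        save_array_container(
            mpath,
            {"mode0": model.mode0, "mode1": model.mode1, "mode2": model.mode2},
            {
                "params_hash": h,
                "fit_percent": model.fit_percent,
                "core_consistency": model.core_consistency,
                "rank": model.rank,
            },
        )
        if "tensor" in requested:
            manifest.record("tensor", h, [str(mpath)], time.time() - t0)

    if "stats" in requested:
        t0 = time.time()
        model = need("stats", "model")
        axes = need("stats", "axes")
        graphs = ss.loadings_to_graphs(model, axes)
        rows = []
        for r, per_subj in graphs.items():
            for s, g in per_subj.items():
                for a in range(g.k):
                    for b in range(g.k):
                        if a != b and g.weights[a, b] > 0:
                            rows.append([r, s, g.ics[a], g.ics[b], g.weights[a, b]])
        epath = out_dir / "structure_edges.csv"
        _write_csv(epath, ["structure", "subject", "source_ic", "sink_ic", "weight"], rows)
        state["graphs"] = graphs
        manifest.record("stats", _hash(["stats"]), [str(epath)], time.time() - t0)

    if "infer" in requested:
        t0 = time.time()
        model = need("infer", "model")
        tensor = need("infer", "tensor")
        builder = need("infer", "builder")
        icfg = config.infer
        sig = si.loading_significance(
            lambda rng: builder.build(rng),
            tensor,
            model,
            n_shuffles=icfg.n_shuffles,
            alpha=icfg.alpha,
            seed=config.seed + 999,
        )
        levels = si.reconstruct_activation(sig)
        rows = [
            [ci, sp.key, r, sig.observed[ci, r], bool(sig.significant[ci, r])]
            for ci, sp in enumerate(sig.comparisons)
            for r in range(model.rank)
        ]
        spath = out_dir / "loading_significance.csv"
        _write_csv(spath, ["index", "comparison", "structure", "loading", "significant"], rows)
        state["significance"] = sig
        state["activation"] = levels
        manifest.record("infer", _hash(["infer", dataclasses.asdict(icfg)]), [str(spath)], time.time() - t0)

    manifest.save(out_dir / "manifest.json")
    manifest.state = state  # in-memory results for library callers
    return manifest


def _write_csv(path: Path, header: list[str], rows: list[list]):
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def _save_recs(path: Path, recs: list[TrialRecording], params_hash: str):
    arrays = {}
    side: dict[str, Any] = {"params_hash": params_hash, "subjects": []}
    for rec in recs:
        arrays[f"{rec.subject}/data"] = rec.data
        if rec.gaze is not None:
            arrays[f"{rec.subject}/gaze"] = rec.gaze
        side["subjects"].append(
            {
                "subject": rec.subject,
                "fs": rec.fs,
                "gaze_fs": rec.gaze_fs,
                "labels": [[l.context, l.response, l.condition] for l in rec.labels],
                "timeline": dataclasses.asdict(rec.timeline),
            }
        )
    save_array_container(path, arrays, side)


def _recs_from_container(arrays: dict, side: dict) -> list[TrialRecording]:
    recs = []
    for meta in side["subjects"]:
        s = meta["subject"]
        tl = meta["timeline"]
        tl["baseline"] = tuple(tl["baseline"])
        recs.append(
            TrialRecording(
                data=arrays[f"{s}/data"],
                fs=meta["fs"],
                labels=[
                    ScenarioLabel(c, r, None if cond in (None, "None") else cond)
                    for c, r, cond in meta["labels"]
                ],
                timeline=TaskTimeline(**tl),
                gaze=arrays.get(f"{s}/gaze"),
                gaze_fs=meta["gaze_fs"],
                subject=s,
            )
        )
    return recs
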