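"""End-to-end orchestration: simulate -> prep -> decode -> fuse -> infer -> report.

A single YAML config (validated into :class:`RunConfig`) drives the whole
chain; every stage persists its outputs under the run directory, records
a SHA-256 hash per file in the run manifest, and derives its random seed
from the global seed by a fixed counter scheme
(``SeedSequence([global_seed, stage_index])``), so reruns of the same
config are bit-identical and individual stages can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .containers import EpochedRecording
from .epochs_prep import preprocess, rejection_report
from .mvpa import (
    DecodingParams,
    PairPartition,
    TimeResolvedRDM,
    categorical_division,
    partition_mean,
    temporal_generalization,
    pairwise_decoding_timecourse,
)
from .nonparam_stats import (
    bootstrap_latency,
    dprime,
    sign_permutation_clusters,
    signed_rank_test,
)
from .rsa_fusion import correlation_rdm, fusion_timecourse
from .synthgen import (
    Envelope,
    SyntheticSpec,
    generate_behavior,
    generate_fmri_patterns,
    generate_meg_subjects,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_report", "load_config"]

STAGES = ("simulate", "prep", "decode", "fuse", "stats", "report")


# ---------------------------------------------------------------------------
# configuration


class EnvelopeConfig(BaseModel):
    onset_ms: float
    peak_ms: float
    fwhm_ms: float
    amplitude: float

    def to_envelope(self) -> Envelope:
        return Envelope(self.onset_ms, self.peak_ms, self.fwhm_ms, self.amplitude)


class SynthSection(BaseModel):
    n_subjects: int = 4
    n_conditions: int = 8
    n_trials_per_condition: int = 9
    n_channels: int = 32
    time_start_ms: float = -100.0
    time_stop_ms: float = 300.0
    time_step_ms: float = 1.0
    noise_sd: float = 1.0
    identity_envelope: EnvelopeConfig = Field(
        default_factory=lambda: EnvelopeConfig(
            onset_ms=40.0, peak_ms=100.0, fwhm_ms=100.0, amplitude=1.0
        )
    )
    category_envelope: EnvelopeConfig = Field(
        default_factory=lambda: EnvelopeConfig(
            onset_ms=90.0, peak_ms=170.0, fwhm_ms=140.0, amplitude=0.6
        )
    )

    def to_spec(self, seed: int) -> SyntheticSpec:
        return SyntheticSpec(
            n_subjects=self.n_subjects,
            n_conditions=self.n_conditions,
            n_trials_per_condition=self.n_trials_per_condition,
            n_channels=self.n_channels,
            time_start_ms=self.time_start_ms,
            time_stop_ms=self.time_stop_ms,
            time_step_ms=self.time_step_ms,
            noise_sd=self.noise_sd,
            identity_envelope=self.identity_envelope.to_envelope(),
            category_envelope=self.category_envelope.to_envelope(),
            seed=seed,
        )


class PrepSection(BaseModel):
    reject_threshold: float = 6000.0
    lowpass_hz: float = 20.0


class DecodeSection(BaseModel):
    group_size: int = 3
    n_repetitions: int = 100
    svm_cost: float = 1.0
    time_stride: int = 1
    temporal_generalization: bool = False

    def to_params(self, seed: int) -> DecodingParams:
        return DecodingParams(
            group_size=self.group_size,
            n_repetitions=self.n_repetitions,
            svm_cost=self.svm_cost,
            time_stride=self.time_stride,
            seed=seed,
        )


class RoiSection(BaseModel):
    roi_id: str
    latency_ms: float
    n_voxels: int = 64
    noise_sd: float = 0.1
    n_subjects: int = 4


class StatsSection(BaseModel):
    n_boot: int = 1000
    n_perm: int = 1000
    cdt: float = 0.05
    alpha: float = 0.05
    q: float = 0.05
    min_consecutive: int = 5


class BehaviorCondition(BaseModel):
    label: str
    dprime: float
    criterion: float = 0.0
    n_signal: int = 50
    n_noise: int = 50


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    seed: int
    synth: SynthSection = Field(default_factory=SynthSection)
    prep: PrepSection = Field(default_factory=PrepSection)
    decode: DecodeSection = Field(default_factory=DecodeSection)
    fusion_rois: list[RoiSection] = Field(
        default_factory=lambda: [
            RoiSection(roi_id="EVC", latency_ms=100.0),
            RoiSection(roi_id="IT", latency_ms=170.0),
        ]
    )
    stats: StatsSection = Field(default_factory=StatsSection)
    behavior: list[BehaviorCondition] = Field(
        default_factory=lambda: [
            BehaviorCondition(label="fast", dprime=1.95),
            BehaviorCondition(label="slow", dprime=3.58),
        ]
    )

    @field_validator("seed")
    @classmethod
    def _seed_bounds(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be non-negative")
        return v


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)


def stage_seed(global_seed: int, stage_index: int, offset: int = 0) -> int:
    """Deterministic per-stage (and per-substream) seed below 2**31."""
    ss = np.random.SeedSequence([global_seed, stage_index, offset])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# manifest


@dataclass
class StageRecord:
    name: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    wall_clock_s: float = 0.0


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[StageRecord] = field(default_factory=list)

    def stage(self, name: str) -> StageRecord:
        for rec in self.stages:
            if rec.name == name:
                return rec
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "stages": [
                {
                    "name": s.name,
                    "seed": s.seed,
                    "outputs": dict(sorted(s.outputs.items())),
                    "wall_clock_s": s.wall_clock_s,
                }
                for s in self.stages
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as f:
            raw = json.load(f)
        man = cls(config=raw["config"], version=raw["version"])
        for s in raw["stages"]:
            man.stages.append(
                StageRecord(
                    name=s["name"],
                    seed=s["seed"],
                    outputs=s["outputs"],
                    wall_clock_s=s["wall_clock_s"],
                )
            )
        return man


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def _epoch_paths(outdir: Path, sub: str) -> list[Path]:
    return sorted((outdir / sub).glob("sub-*.h5"))


def stage_simulate(cfg: RunConfig, outdir: Path, seed: int) -> list[Path]:
    spec = cfg.synth.to_spec(seed)
    subjects, truth = generate_meg_subjects(spec)
    epoch_dir = outdir / "epochs"
    epoch_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s, rec in enumerate(subjects):
        p = epoch_dir / f"sub-{s:02d}.h5"
        rec.save(p, seed=seed)
        paths.append(p)

    gt_path = outdir / "ground_truth.h5"
    with h5py.File(gt_path, "w", track_order=True) as f:
        f.create_dataset(
            "condition_patterns", data=truth.condition_patterns, track_times=False
        )
        f.create_dataset(
            "category_patterns", data=truth.category_patterns, track_times=False
        )
        f.create_dataset(
            "mean_geometry", data=truth.mean_geometry(), track_times=False
        )
        f.create_dataset("time_axis", data=spec.time_axis, track_times=False)
        f.create_dataset("category_of", data=spec.category_of, track_times=False)
        f.attrs["identity_peak_ms"] = truth.true_identity_peak_ms
        f.attrs["category_peak_ms"] = truth.true_category_peak_ms
        f.attrs["seed"] = seed

    frames = []
    for s in range(spec.n_subjects):
        for c_idx, cond in enumerate(cfg.behavior):
            df = generate_behavior(
                cond.dprime,
                cond.criterion,
                cond.n_signal,
                cond.n_noise,
                seed=stage_seed(seed, 99, s * len(cfg.behavior) + c_idx),
                condition_speed=cond.label,
            )
            df.insert(0, "subject", s)
            frames.append(df)
    behavior_path = outdir / "behavior.csv"
    pd.concat(frames, ignore_index=True).to_csv(behavior_path, index=False)
    return [*paths, gt_path, behavior_path]


def stage_prep(cfg: RunConfig, outdir: Path) -> list[Path]:
    prep_dir = outdir / "prepped"
    prep_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    report: dict[str, list] = {}
    for p in _epoch_paths(outdir, "epochs"):
        rec = EpochedRecording.load(p)
        report[p.stem] = rejection_report(rec, cfg.prep.reject_threshold)
        clean, _ = preprocess(rec, cfg.prep.reject_threshold, cfg.prep.lowpass_hz)
        out = prep_dir / p.name
        clean.save(out)
        paths.append(out)
    rej_path = outdir / "rejection.json"
    with open(rej_path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    return [*paths, rej_path]


def _save_rdm(path: Path, rdm: TimeResolvedRDM, seed: int) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("accuracy", data=rdm.accuracy, track_times=False)
        f.create_dataset("condition_ids", data=rdm.condition_ids, track_times=False)
        f.create_dataset("time_axis", data=rdm.time_axis, track_times=False)
        if rdm.category_of is not None:
            f.create_dataset("category_of", data=rdm.category_of, track_times=False)
        f.attrs["seed"] = seed


def _load_rdm(path: Path) -> TimeResolvedRDM:
    with h5py.File(path, "r") as f:
        return TimeResolvedRDM(
            accuracy=f["accuracy"][()],
            condition_ids=f["condition_ids"][()],
            time_axis=f["time_axis"][()],
            category_of=f["category_of"][()] if "category_of" in f else None,
        )


def _category_of(outdir: Path) -> np.ndarray:
    with h5py.File(outdir / "ground_truth.h5", "r") as f:
        return f["category_of"][()]


def _subject_series(outdir: Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-subject partition-mean series from the persisted RDMs."""
    cat = _category_of(outdir)
    partition = PairPartition.from_categories(cat, "face", "object")
    rows = []
    time_axis = None
    for s, p in enumerate(sorted((outdir / "rdms").glob("sub-*.h5"))):
        rdm = _load_rdm(p)
        time_axis = rdm.time_axis
        all_pair_set = partition.within | partition.between
        series = {
            "grand": partition_mean(rdm, all_pair_set),
            "within": partition_mean(rdm, partition.within),
            "between": partition_mean(rdm, partition.between),
            "division": categorical_division(rdm, partition),
        }
        for name, vals in series.items():
            for t, v in zip(rdm.time_axis, vals):
                rows.append(
                    {"subject": s, "series": name, "time_ms": t, "value": v}
                )
    return pd.DataFrame(rows), time_axis


def stage_decode(cfg: RunConfig, outdir: Path, seed: int) -> list[Path]:
    rdm_dir = outdir / "rdms"
    rdm_dir.mkdir(parents=True, exist_ok=True)
    cat = _category_of(outdir)
    paths = []
    tg_mean = None
    for s, p in enumerate(_epoch_paths(outdir, "prepped")):
        rec = EpochedRecording.load(p)
        rec.category_of = cat  # carried onto the RDM
        params = cfg.decode.to_params(stage_seed(seed, 2, s))
        rdm = pairwise_decoding_timecourse(rec, params)
        out = rdm_dir / p.name
        _save_rdm(out, rdm, params.seed)
        paths.append(out)
        if cfg.decode.temporal_generalization:
            tgm = temporal_generalization(rec, params)
            tg_mean = tgm.accuracy if tg_mean is None else tg_mean + tgm.accuracy
    if tg_mean is not None:
        tg_path = outdir / "tgm.h5"
        with h5py.File(tg_path, "w", track_order=True) as f:
            f.create_dataset(
                "accuracy", data=tg_mean / len(paths), track_times=False
            )
        paths.append(tg_path)
    df, _ = _subject_series(outdir)
    series_path = outdir / "partition_means.csv"
    df.to_csv(series_path, index=False)
    paths.append(series_path)
    return paths


def stage_fuse(cfg: RunConfig, outdir: Path, seed: int) -> list[Path]:
    rdm_paths = sorted((outdir / "rdms").glob("sub-*.h5"))
    rdms = [_load_rdm(p) for p in rdm_paths]
    mean_acc = np.mean([r.accuracy for r in rdms], axis=0)
    meg_mean = TimeResolvedRDM(
        accuracy=mean_acc,
        condition_ids=rdms[0].condition_ids,
        time_axis=rdms[0].time_axis,
        category_of=rdms[0].category_of,
    )
    with h5py.File(outdir / "ground_truth.h5", "r") as f:
        geometry = f["mean_geometry"][()]
        gt_time = f["time_axis"][()]

    rows = []
    for r_idx, roi in enumerate(cfg.fusion_rois):
        t_idx = int(np.argmin(np.abs(gt_time - roi.latency_ms)))
        target = geometry[:, :, t_idx]
        for sub in range(roi.n_subjects):
            patterns = generate_fmri_patterns(
                target,
                n_voxels=roi.n_voxels,
                noise_sd=roi.noise_sd,
                seed=stage_seed(seed, 3, r_idx * 1000 + sub),
                roi_id=roi.roi_id,
            )
            series = fusion_timecourse(meg_mean, correlation_rdm(patterns), sub)
            for t, rho in zip(series.time_axis, series.rho):
                rows.append(
                    {
                        "time_ms": t,
                        "rho": rho,
                        "subject": sub,
                        "roi": roi.roi_id,
                    }
                )
    fusion_path = outdir / "fusion.csv"
    pd.DataFrame(rows).to_csv(fusion_path, index=False)
    return [fusion_path]


def _pivot_series(df: pd.DataFrame, name: str) -> np.ndarray:
    sub = df[df["series"] == name]
    wide = sub.pivot(index="subject", columns="time_ms", values="value")
    return wide.to_numpy()


def stage_stats(cfg: RunConfig, outdir: Path, seed: int) -> list[Path]:
    st = cfg.stats
    df = pd.read_csv(outdir / "partition_means.csv")
    time_axis = np.array(sorted(df["time_ms"].unique()))
    latencies: dict[str, dict] = {}
    clusters_out: dict[str, list] = {}
    masks: dict[str, np.ndarray] = {}

    for k, name in enumerate(("grand", "within", "between", "division")):
        series = _pivot_series(df, name)
        null_value = 0.0 if name == "division" else 50.0
        effects = series - null_value
        clu = sign_permutation_clusters(
            effects,
            n_perm=st.n_perm,
            cdt=st.cdt,
            alpha=st.alpha,
            seed=stage_seed(seed, 4, k),
        )
        clusters_out[name] = [
            {"size": c["size"], "p": c["p"], "significant": c["significant"]}
            for c in clu.clusters
        ]
        masks[name] = clu.sig_mask
        peak = bootstrap_latency(
            series,
            time_axis,
            kind="peak",
            n_boot=st.n_boot,
            seed=stage_seed(seed, 5, k),
        )
        onset = bootstrap_latency(
            effects,
            time_axis,
            kind="onset",
            n_boot=st.n_boot,
            seed=stage_seed(seed, 6, k),
            onset_threshold=clu.pointwise_threshold,
            min_consecutive=st.min_consecutive,
        )
        latencies[name] = {
            "peak": peak.to_record(),
            "onset": onset.to_record(),
            "n_significant_clusters": clu.n_significant,
        }

    fus = pd.read_csv(outdir / "fusion.csv")
    fusion_stats: dict[str, dict] = {}
    for k, roi in enumerate(sorted(fus["roi"].unique())):
        sub = fus[fus["roi"] == roi]
        wide = sub.pivot(index="subject", columns="time_ms", values="rho")
        rho = np.nan_to_num(wide.to_numpy())  # undefined rho carries no evidence
        t_ax = wide.columns.to_numpy(dtype=float)
        clu = sign_permutation_clusters(
            rho,
            n_perm=st.n_perm,
            cdt=st.cdt,
            alpha=st.alpha,
            seed=stage_seed(seed, 7, k),
        )
        peak = bootstrap_latency(
            rho,
            t_ax,
            kind="peak",
            n_boot=st.n_boot,
            seed=stage_seed(seed, 8, k),
        )
        masks[f"fusion_{roi}"] = clu.sig_mask
        fusion_stats[roi] = {
            "peak": peak.to_record(),
            "n_significant_clusters": clu.n_significant,
            "clusters": [
                {"size": c["size"], "p": c["p"], "significant": c["significant"]}
                for c in clu.clusters
            ],
        }

    beh = pd.read_csv(outdir / "behavior.csv")
    behavior_stats: dict = {"conditions": {}, "comparison": None}
    per_cond: dict[str, list[float]] = {}
    for label, group in beh.groupby("condition_speed", sort=False):
        vals = []
        for _, g in group.groupby("subject"):
            hits = int((g.signal_present & g.response_present).sum())
            misses = int((g.signal_present & ~g.response_present).sum())
            fas = int((~g.signal_present & g.response_present).sum())
            crs = int((~g.signal_present & ~g.response_present).sum())
            vals.append(dprime(hits, misses, fas, crs))
        per_cond[label] = vals
        arr = np.array(vals)
        behavior_stats["conditions"][label] = {
            "dprime_mean": float(arr.mean()),
            "dprime_sem": float(arr.std(ddof=1) / np.sqrt(arr.size)),
            "n_subjects": int(arr.size),
        }
    labels = list(per_cond)
    if len(labels) >= 2 and len(per_cond[labels[0]]) >= 5:
        behavior_stats["comparison"] = {
            "labels": labels[:2],
            "signed_rank_p": signed_rank_test(
                per_cond[labels[0]], per_cond[labels[1]]
            ),
        }

    out_paths = []
    stats_dir = outdir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    mask_path = stats_dir / "cluster_masks.h5"
    with h5py.File(mask_path, "w", track_order=True) as f:
        f.create_dataset("time_ms", data=time_axis, track_times=False)
        for name, mask in masks.items():
            f.create_dataset(name, data=mask, track_times=False)
    out_paths.append(mask_path)
    for name, payload in (
        ("latencies.json", latencies),
        ("clusters.json", clusters_out),
        ("fusion_stats.json", fusion_stats),
        ("behavior_stats.json", behavior_stats),
    ):
        p = outdir / "stats" / name
        p.parent.mkdir(parents=True, exist_ok=True)
        with open(p, "w") as f:
            json.dump(payload, f, indent=2, sort_keys=True)
        out_paths.append(p)
    return out_paths


def _fmt_ms(x: float) -> str:
    return "undefined" if (x is None or np.isnan(x)) else f"{x:.0f} ms"


def make_report(manifest: RunManifest, outdir: Path) -> str:
    """Render the run summary (markdown) from the persisted stage outputs.

    The report contains no timestamps, so regenerating it from the same
    manifest and artifacts is byte-identical.
    """
    outdir = Path(outdir)
    with open(outdir / "stats" / "latencies.json") as f:
        latencies = json.load(f)
    with open(outdir / "stats" / "fusion_stats.json") as f:
        fusion_stats = json.load(f)
    with open(outdir / "stats" / "behavior_stats.json") as f:
        behavior = json.load(f)

    lines = [
        "# Pipeline run report",
        "",
        f"Package version: {manifest.version}",
        f"Global seed: {manifest.config['seed']}",
        "",
        "## Behavioral sensitivity (d')",
        "",
        "| condition | d' mean | SEM | n |",
        "|---|---|---|---|",
    ]
    for label, rec in behavior["conditions"].items():
        lines.append(
            f"| {label} | {rec['dprime_mean']:.2f} | {rec['dprime_sem']:.2f} "
            f"| {rec['n_subjects']} |"
        )
    if behavior.get("comparison"):
        comp = behavior["comparison"]
        lines += [
            "",
            f"Signed-rank test {comp['labels'][0]} vs {comp['labels'][1]}: "
            f"p = {comp['signed_rank_p']:.3g}",
        ]

    lines += [
        "",
        "## Peak and onset latency of the decoding time series",
        "",
        "| series | peak | 95% CI | onset | 95% CI | significant clusters |",
        "|---|---|---|---|---|---|",
    ]
    total_sig = 0
    for name, rec in latencies.items():
        pk, on = rec["peak"], rec["onset"]
        n_sig = rec["n_significant_clusters"]
        total_sig += n_sig
        lines.append(
            f"| {name} | {_fmt_ms(pk['point_ms'])} "
            f"| [{_fmt_ms(pk['ci_low_ms'])}, {_fmt_ms(pk['ci_high_ms'])}] "
            f"| {_fmt_ms(on['point_ms'])} "
            f"| [{_fmt_ms(on['ci_low_ms'])}, {_fmt_ms(on['ci_high_ms'])}] "
            f"| {n_sig} |"
        )

    lines += [
        "",
        "## MEG-fMRI fusion peaks per ROI",
        "",
        "| ROI | peak | 95% CI | significant clusters |",
        "|---|---|---|---|",
    ]
    for roi, rec in fusion_stats.items():
        pk = rec["peak"]
        n_sig = rec["n_significant_clusters"]
        total_sig += n_sig
        lines.append(
            f"| {roi} | {_fmt_ms(pk['point_ms'])} "
            f"| [{_fmt_ms(pk['ci_low_ms'])}, {_fmt_ms(pk['ci_high_ms'])}] "
            f"| {n_sig} |"
        )

    lines += ["", "## Cluster summary", ""]
    if total_sig == 0:
        lines.append(
            "No significant clusters in any analyzed time series "
            f"(total significant clusters: 0)."
        )
    else:
        lines.append(f"Total significant clusters across series: {total_sig}.")
    lines.append("")
    return "\n".join(lines)


def stage_report(cfg: RunConfig, outdir: Path, manifest: RunManifest) -> list[Path]:
    text = make_report(manifest, outdir)
    path = outdir / "report.md"
    path.write_text(text)
    return [path]


# ---------------------------------------------------------------------------
# driver


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute all stages in order; halt on failure with a partial manifest.

    Returns the manifest (also saved as ``manifest.json`` in `outdir`)
    listing, per stage, the derived seed and the SHA-256 hash of every
    output file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=json.loads(config.model_dump_json()), version=__version__
    )
    runners = {
        "simulate": lambda seed: stage_simulate(config, outdir, seed),
        "prep": lambda seed: stage_prep(config, outdir),
        "decode": lambda seed: stage_decode(config, outdir, seed),
        "fuse": lambda seed: stage_fuse(config, outdir, seed),
        "stats": lambda seed: stage_stats(config, outdir, seed),
        "report": lambda seed: stage_report(config, outdir, manifest),
    }
    for idx, name in enumerate(STAGES):
        seed = stage_seed(config.seed, idx)
        t0 = time.perf_counter()
        try:
            outputs = runners[name](seed)
        except Exception as exc:
            manifest.save(outdir / "manifest.json")
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        rec = StageRecord(name=name, seed=seed, wall_clock_s=time.perf_counter() - t0)
        for p in outputs:
            rec.outputs[str(Path(p).relative_to(outdir))] = _sha256(Path(p))
        manifest.stages.append(rec)
    manifest.save(outdir / "manifest.json")
    return manifest
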