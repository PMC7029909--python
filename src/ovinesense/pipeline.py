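"""End-to-end orchestration: simulate → window → extract → rank → CV → report.

A run is driven by one :class:`PipelineConfig` and one master seed; every
stage derives its own seed from the master by a fixed offset, so a run is
reproducible from a single knob.  Each stage writes its output into the
run directory and can be re-run from its predecessor's files; a manifest
records the config, seeds, library versions and a digest of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ovinesense import __version__
from ovinesense.classify import ALGORITHMS, ClassifierSpec, feature_sweep, run_cv
from ovinesense.evaluate import evaluate_sheep_level
from ovinesense.features import FEATURE_NAMES, FeatureConfig, feature_table
from ovinesense.fieldstudy import behaviour_accounting
from ovinesense.preprocess import window_recording
from ovinesense.relieff import RankedFeatures, relieff_rank
from ovinesense.simulate import (
    ACTIVITIES,
    SimulationConfig,
    config_from_mapping,
    default_profiles,
    generate_flock,
    read_recording,
    write_recording,
)

logger = logging.getLogger("ovinesense")

# fixed seed offsets per stage, derived from the master seed
_SEED_OFFSETS = {"simulate": 0, "rank": 1, "folds": 2, "classify": 3}


@dataclass
class PipelineConfig:
    """Configuration for a full run.

    ``n_features_grid`` is the sweep grid over top-ranked feature counts;
    ``sheep_level_n_features`` and ``sheep_level_algorithm`` pick the
    model whose out-of-fold predictions feed the sheep-level evaluation.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    effect_size: float = 1.0
    algorithms: tuple[str, ...] = ALGORITHMS
    n_features_grid: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    k_folds: int = 10
    sheep_level_algorithm: str = "RF"
    sheep_level_n_features: int = 32
    relieff_k: int = 10
    seed: int = 0
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping)
        if "simulation" in mapping:
            mapping["simulation"] = config_from_mapping(mapping["simulation"])
        if "feature_config" in mapping:
            mapping["feature_config"] = FeatureConfig(**mapping["feature_config"])
        for key in ("algorithms", "n_features_grid"):
            if key in mapping:
                mapping[key] = tuple(mapping[key])
        return cls(**mapping)

    def to_mapping(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _SEED_OFFSETS[stage]) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(run_dir: Path, config: PipelineConfig) -> None:
    import scipy
    import sklearn

    files = sorted(
        p for p in run_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": json.loads(json.dumps(config.to_mapping(), default=str)),
        "seeds": {stage: config.stage_seed(stage) for stage in _SEED_OFFSETS},
        "versions": {
            "ovinesense": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "outputs": {str(p.relative_to(run_dir)): _sha256(p) for p in files},
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def stage_simulate(config: PipelineConfig, run_dir: Path) -> list:
    sim = dataclasses.replace(config.simulation, rng_seed=config.stage_seed("simulate"))
    profiles = default_profiles(
        sim, effect_size=config.effect_size, rng=np.random.default_rng(sim.rng_seed)
    )
    recordings = generate_flock(sim, profiles)
    rec_dir = run_dir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(
            rec, rec_dir / f"sensor_{rec.sheep_id}.csv", rec_dir / f"annotations_{rec.sheep_id}.csv"
        )
    logger.info("simulated %d recordings (%d lame)", len(recordings), sum(r.is_lame for r in recordings))
    return recordings


def load_recordings(run_dir: Path) -> list:
    rec_dir = Path(run_dir) / "recordings"
    recordings = []
    for sensor_path in sorted(rec_dir.glob("sensor_*.csv")):
        sheep_id = sensor_path.stem.removeprefix("sensor_")
        recordings.append(read_recording(sensor_path, rec_dir / f"annotations_{sheep_id}.csv"))
    if not recordings:
        raise FileNotFoundError(f"no recordings under {rec_dir}")
    return recordings


def stage_extract(config: PipelineConfig, run_dir: Path, recordings: list) -> pd.DataFrame:
    all_windows = []
    for rec in recordings:
        windows = window_recording(rec)
        all_windows.extend(windows)
    logger.info("windowed %d recordings -> %d windows", len(recordings), len(all_windows))
    f_s = recordings[0].sampling_rate
    table = feature_table(all_windows, f_s, config.feature_config)
    table.to_csv(run_dir / "features.csv", index=False)
    logger.info("extracted %d x %d feature table", len(table), len(FEATURE_NAMES))
    return table

def load_features(run_dir: Path) -> pd.DataFrame:
    path = Path(run_dir) / "features.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing feature table {path}; run the extract stage first")
    return pd.read_csv(path, float_precision="round_trip")


def stage_rank(config: PipelineConfig, run_dir: Path, table: pd.DataFrame) -> dict[str, RankedFeatures]:
    rankings = {}
    frames = []
    for activity in ACTIVITIES:
        sub = table[table["activity"] == activity]
        ranking = relieff_rank(
            sub[FEATURE_NAMES],
            sub["lame"].to_numpy(),
            k_neighbors=config.relieff_k,
            seed=config.stage_seed("rank"),
            activity=activity,
        )
        rankings[activity] = ranking
        frames.append(ranking.to_frame())
        logger.info("ranked features for %s: top = %s", activity, ranking.feature_names[0])
    pd.concat(frames, ignore_index=True).to_csv(run_dir / "rankings.csv", index=False)
    return rankings


def load_rankings(run_dir: Path) -> dict[str, RankedFeatures]:
    frame = pd.read_csv(Path(run_dir) / "rankings.csv")
    rankings = {}
    for activity, sub in frame.groupby("activity"):
        sub = sub.sort_values("rank")
        rankings[str(activity)] = RankedFeatures(
            feature_names=list(sub["feature"]),
            weights=sub["weight"].to_numpy(),
            activity=str(activity),
        )
    return rankings


def stage_classify(
    config: PipelineConfig,
    run_dir: Path,
    table: pd.DataFrame,
    rankings: dict[str, RankedFeatures],
) -> dict:
    """Sweep every algorithm over the feature grid within each activity and
    run the sheep-level evaluation on the designated model."""
    cv_dir = run_dir / "cv"
    cv_dir.mkdir(parents=True, exist_ok=True)
    curves = {}
    sheep_level = {}
    for activity in ACTIVITIES:
        sub = table[table["activity"] == activity].reset_index(drop=True)
        for algorithm in config.algorithms:
            spec = ClassifierSpec(algorithm, seed=config.stage_seed("classify"))
            results = feature_sweep(
                sub,
                rankings[activity],
                spec,
                n_features_grid=list(config.n_features_grid),
                k_folds=config.k_folds,
                fold_seed=config.stage_seed("folds"),
            )
            curve = {
                "activity": activity,
                "algorithm": algorithm,
                "n_features": list(config.n_features_grid),
                "accuracy": [r.mean_accuracy for r in results],
                "metrics": [dataclasses.asdict(r.mean_metrics) for r in results],
            }
            curves[f"{activity}_{algorithm}"] = curve
            (cv_dir / f"sweep_{activity}_{algorithm}.json").write_text(
                json.dumps(curve, indent=2)
            )
            logger.info(
                "CV sweep %s/%s: accuracy %.3f at %d features",
                activity, algorithm, curve["accuracy"][-1], curve["n_features"][-1],
            )
        # sheep-level evaluation from the designated model's out-of-fold predictions
        spec = ClassifierSpec(config.sheep_level_algorithm, seed=config.stage_seed("classify"))
        result = run_cv(
            sub,
            rankings[activity],
            spec,
            n_features=config.sheep_level_n_features,
            k_folds=config.k_folds,
            fold_seed=config.stage_seed("folds"),
        )
        result.predictions.to_csv(cv_dir / f"predictions_{activity}.csv", index=False)
        separation, verdicts, accuracy = evaluate_sheep_level(result.predictions)
        verdicts.to_csv(run_dir / f"verdicts_{activity}.csv")
        sheep_level[activity] = {
            "mu_lame": separation.mu_lame,
            "sigma_lame": separation.sigma_lame,
            "mu_nonlame": separation.mu_nonlame,
            "sigma_nonlame": separation.sigma_nonlame,
            "delta_sigma": separation.delta_sigma,
            "threshold": separation.threshold,
            "mann_whitney_u": separation.mann_whitney_u,
            "p_value": separation.p_value,
            "sheep_accuracy_pct": accuracy,
            "window_accuracy": result.mean_accuracy,
        }
        logger.info(
            "sheep-level %s: delta_sigma=%.3f p=%.4f accuracy=%.2f%%",
            activity, separation.delta_sigma, separation.p_value, accuracy,
        )
    (run_dir / "sheep_level.json").write_text(json.dumps(sheep_level, indent=2))
    return {"curves": curves, "sheep_level": sheep_level}


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> Path:
    """Execute every stage in order and write the manifest.

    A stage failure halts the run with the failing stage named; outputs
    of completed stages are retained for inspection or re-running.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        recordings = stage_simulate(config, run_dir)
        stage = "extract"
        table = stage_extract(config, run_dir, recordings)
        stage = "rank"
        rankings = stage_rank(config, run_dir, table)
        stage = "classify"
        stage_classify(config, run_dir, table, rankings)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    _write_manifest(run_dir, config)
    logger.info("run complete: %s", run_dir)
    return run_dir


def summarize(run_dir: str | Path) -> str:
    """Human-readable report over a (possibly partial) run directory.

    Pure function of the run directory: regenerating the report is
    idempotent.  Missing stages are flagged as gaps rather than errors.
    """
    run_dir = Path(run_dir)
    lines = [f"ovinesense run report: {run_dir}", "=" * 50]

    features_path = run_dir / "features.csv"
    if features_path.exists():
        table = pd.read_csv(features_path)
        lines.append("\nWindow accounting (count, % within behaviour):")
        counts = {
            activity: {
                "nonlame": int(((table["activity"] == activity) & (~table["lame"])).sum()),
                "lame": int(((table["activity"] == activity) & (table["lame"])).sum()),
            }
            for activity in ACTIVITIES
        }
        accounting = behaviour_accounting(counts)
        lines.append(accounting.to_string(index=False))
        lines.append(f"total windows: {accounting.attrs['grand_total']}")
    else:
        lines.append("\n[gap] no feature table (extract stage not run)")

    rankings_path = run_dir / "rankings.csv"
    if rankings_path.exists():
        frame = pd.read_csv(rankings_path)
        lines.append("\nTop 10 features per activity (ReliefF):")
        for activity in ACTIVITIES:
            sub = frame[frame["activity"] == activity].nsmallest(10, "rank")
            if len(sub):
                lines.append(f"  {activity}: " + ", ".join(sub["feature"]))
    else:
        lines.append("\n[gap] no rankings (rank stage not run)")

    cv_dir = run_dir / "cv"
    sweeps = sorted(cv_dir.glob("sweep_*.json")) if cv_dir.exists() else []
    if sweeps:
        lines.append("\nAccuracy vs number of top-ranked features:")
        for path in sweeps:
            curve = json.loads(path.read_text())
            pairs = ", ".join(
                f"{n}:{a:.3f}" for n, a in zip(curve["n_features"], curve["accuracy"])
            )
            lines.append(f"  {curve['activity']}/{curve['algorithm']}: {pairs}")
    else:
        lines.append("\n[gap] no CV sweeps (classify stage not run)")

    sheep_path = run_dir / "sheep_level.json"
    if sheep_path.exists():
        sheep = json.loads(sheep_path.read_text())
        lines.append("\nSheep-level separation (per activity):")
        for activity, s in sheep.items():
            lines.append(
                f"  {activity}: delta_sigma={s['delta_sigma']:.4f} "
                f"threshold={s['threshold']:.4f} U={s['mann_whitney_u']:.1f} "
                f"p={s['p_value']:.4f} sheep accuracy={s['sheep_accuracy_pct']:.2f}%"
            )
    else:
        lines.append("\n[gap] no sheep-level report (classify stage not run)")
    return "\n".join(lines) + "\n"
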