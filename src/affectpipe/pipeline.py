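"""End-to-end orchestration: simulate -> score -> features -> stats -> classify.

One :class:`RunConfig` (YAML-loadable) drives all six stages; a JSON
manifest records the seed, per-stage input hashes and outputs, and a stage
whose inputs are unchanged and whose outputs already exist is skipped on
rerun. Reruns with the same config reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ans as ans_mod
from . import cognitive, eeg, ml, stats
from . import synthetic as syn

logger = logging.getLogger("affectpipe.pipeline")

__all__ = ["RunConfig", "StageError", "STAGES", "run_all", "load_config"]

STAGES = (
    "simulate",
    "score_cognitive",
    "eeg_features",
    "ans_features",
    "stats",
    "classify",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Whole-run configuration; ``seed`` propagates to every stage."""

    seed: int = 0
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    cv: ml.CVConfig = field(default_factory=ml.CVConfig)
    physio_n: int = 4
    pca_k: int = 5
    pca_mode: str = "fold"
    edge_rule: str = "rate"

    def __post_init__(self) -> None:
        self.sim.seed = self.seed
        self.cv.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["sim"].get("measure_correlation") is not None:
            d["sim"]["measure_correlation"] = np.asarray(
                d["sim"]["measure_correlation"]
            ).tolist()
        return d


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file with optional sim/cv subsections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kwargs = raw.pop("sim", {}) or {}
    eeg_kwargs = sim_kwargs.pop("eeg", {}) or {}
    ans_kwargs = sim_kwargs.pop("ans", {}) or {}
    sim = syn.SimConfig(
        **sim_kwargs,
        eeg=syn.EEGParams(**eeg_kwargs),
        ans=syn.ANSParams(**ans_kwargs),
    )
    cv = ml.CVConfig(**(raw.pop("cv", {}) or {}))
    return RunConfig(sim=sim, cv=cv, **raw)


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_files(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _physio_dirs(datadir: Path) -> list[Path]:
    root = Path(datadir) / "physio"
    return sorted(root.iterdir()) if root.is_dir() else []


def extract_all_eeg_features(config: RunConfig, datadir: str | Path) -> pd.DataFrame:
    """Per-task EEG features for every recording under ``datadir/physio``.

    Each recording is preprocessed, artifact-masked, re-timed from its sync
    channel, and summarized into the per-task grouped feature row; the
    result is indexed by (participant_id, session, task).
    """
    rows = {}
    for pdir in _physio_dirs(datadir):
        pid, session = pdir.name.rsplit("_", 1)
        events = syn.EventTimeline.read_tsv(pdir / "events.tsv")
        rec = syn.read_eeg_csv(pdir / "eeg.csv", sfreq=config.sim.eeg.sampling_rate)
        clean = eeg.preprocess(rec)
        mask = eeg.mark_artifacts(clean)
        onsets = eeg.detect_sync_events(rec.sync, rec.sfreq)
        ev = events.events.copy()
        if len(onsets) == len(ev):
            ev["onset"] = np.asarray(onsets) / rec.sfreq
        for task in ev["trial_type"].unique():
            rows[(pid, session, task)] = eeg.extract_event_features(
                clean, mask, ev[ev["trial_type"] == task]
            )
    return _feature_table(rows)


def extract_all_ans_features(config: RunConfig, datadir: str | Path) -> pd.DataFrame:
    """Per-task autonomic features for every wristband recording under
    ``datadir/physio``, indexed by (participant_id, session, task)."""
    rows = {}
    for pdir in _physio_dirs(datadir):
        pid, session = pdir.name.rsplit("_", 1)
        events = syn.EventTimeline.read_tsv(pdir / "events.tsv")
        streams = syn.WristbandStreams.read_csvs(pdir)
        for task in events.events["trial_type"].unique():
            rows[(pid, session, task)] = ans_mod.extract_event_ans_features(
                streams, events, task
            )
    return _feature_table(rows)


def _feature_table(rows: dict) -> pd.DataFrame:
    table = pd.DataFrame.from_dict(rows, orient="index")
    names = ["participant_id", "session", "task"]
    if rows:
        table.index = pd.MultiIndex.from_tuples(table.index, names=names)
        table = table.sort_index()
    else:
        table.index = pd.MultiIndex.from_arrays([[], [], []], names=names)
    return table


def run_all(
    config: RunConfig, outdir: str | Path, stages: tuple[str, ...] | None = None
) -> dict:
    """Execute the pipeline stages in dependency order; returns the manifest.

    Any stage failure aborts with a :class:`StageError` naming the stage;
    outputs of completed stages are preserved. A stage is skipped when the
    manifest records the same input hash and its outputs still exist.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stages is None else tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    manifest_path = outdir / "manifest.json"
    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "stages": {}}
    if manifest_path.exists():
        try:
            manifest = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            pass
        manifest.setdefault("stages", {})
        manifest["config"] = config.to_dict()
        manifest["seed"] = config.seed

    runners = {
        "simulate": _stage_simulate,
        "score_cognitive": _stage_score_cognitive,
        "eeg_features": _stage_eeg_features,
        "ans_features": _stage_ans_features,
        "stats": _stage_stats,
        "classify": _stage_classify,
    }
    cfg_hash = _hash_obj(config.to_dict())
    for stage in STAGES:
        if stage not in stages:
            continue
        record = manifest["stages"].get(stage)
        if (
            record
            and record.get("input_hash") == cfg_hash
            and all((outdir / f).exists() for f in record.get("outputs", []))
        ):
            logger.info("stage %s up to date; skipped", stage)
            continue
        logger.info("running stage %s", stage)
        try:
            outputs = runners[stage](config, outdir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "input_hash": cfg_hash,
            "outputs": [str(p.relative_to(outdir)) for p in outputs],
            "output_hash": _hash_files(outputs),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    datadir = outdir / "data"
    syn.write_dataset(config.sim, datadir, physio_participants=config.physio_n)
    outputs = [datadir / "cohort.csv", datadir / "manifest.json"] + [
        datadir / f"{k}_log.csv" for k in ("recognition", "construal", "word_find")
    ]
    for pdir in _physio_dirs(datadir):
        outputs.extend(sorted(pdir.iterdir()))
    return outputs


def _load_logs(outdir: Path) -> dict[str, pd.DataFrame]:
    datadir = outdir / "data"
    return {
        name: pd.read_csv(datadir / f"{name}_log.csv")
        for name in ("recognition", "construal", "word_find")
    }


def _stage_score_cognitive(config: RunConfig, outdir: Path) -> list[Path]:
    table = cognitive.score_all(_load_logs(outdir), edge_rule=config.edge_rule)
    path = outdir / "cognitive_measures.csv"
    table.to_csv(path)
    return [path]


def _stage_eeg_features(config: RunConfig, outdir: Path) -> list[Path]:
    table = extract_all_eeg_features(config, outdir / "data")
    path = outdir / "eeg_features.csv"
    table.to_csv(path)
    return [path]


def _stage_ans_features(config: RunConfig, outdir: Path) -> list[Path]:
    table = extract_all_ans_features(config, outdir / "data")
    path = outdir / "ans_features.csv"
    table.to_csv(path)
    return [path]


def _changes(config: RunConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    """Change tables per feature group from the stage outputs on disk."""
    cohort = syn.read_cohort(outdir / "data" / "cohort.csv")
    condition = cohort.condition
    groups: dict[str, pd.DataFrame] = {
        "self_report": stats.compute_change_table(cohort)
    }
    cog = pd.read_csv(
        outdir / "cognitive_measures.csv", index_col=["participant_id", "session"]
    )
    groups["cognitive"] = stats.change_from_sessions(cog, condition)
    for name in ("ans", "eeg"):
        path = outdir / f"{name}_features.csv"
        if path.exists():
            feats = pd.read_csv(path, index_col=["participant_id", "session", "task"])
            if feats.empty:
                continue
            # per-task features side by side, then change scores
            wide = feats.unstack("task")
            wide.columns = [f"{task}:{col}" for col, task in wide.columns]
            groups[name] = stats.change_from_sessions(wide, condition)
    return groups


def _stage_stats(config: RunConfig, outdir: Path) -> list[Path]:
    groups = _changes(config, outdir)
    frames = []
    for family, table in groups.items():
        table = table.dropna()
        if table.shape[1] <= 1:
            continue
        if len(table) < 4 or table["condition"].nunique() < 2:
            logger.warning(
                "family %s: too few participants for change regressions; skipped",
                family,
            )
            continue
        frames.append(stats.run_change_regressions(table, family))
    results = pd.concat(frames, ignore_index=True)
    csv_path = outdir / "change_regressions.csv"
    results.to_csv(csv_path, index=False)
    summary = {
        family: {
            "n_measures": int((results["family"] == family).sum()),
            "alpha_adjusted": float(
                results.loc[results["family"] == family, "alpha_adjusted"].iloc[0]
            ),
            "significant": results.loc[
                (results["family"] == family) & results["significant"], "measure"
            ].tolist(),
        }
        for family in results["family"].unique()
    }
    json_path = outdir / "change_regressions.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return [csv_path, json_path]


#: Smallest cohort on which the nested CV scheme is attempted; below this
#: the 80/20 split cannot hold both classes in every inner fold.
MIN_CLASSIFY_N = 16


def _stage_classify(config: RunConfig, outdir: Path) -> list[Path]:
    """Hierarchical classification, mirroring the study design.

    Self-report and cognitive change scores cover the whole cohort and are
    evaluated together; the physiological groups exist only for the
    participants with recordings, so the full four-group hierarchy runs on
    that subcohort (skipped, with a logged reason, when it is too small for
    the splitting scheme).
    """
    groups = _changes(config, outdir)
    labels = groups["self_report"]["condition"]
    feature_groups = {
        name: table.drop(columns="condition").dropna()
        for name, table in groups.items()
    }
    feature_groups = {k: v for k, v in feature_groups.items() if v.shape[1] > 0}

    tables = []
    cognitive_names = [n for n in ("self_report", "cognitive") if n in feature_groups]
    common = labels.index
    for n in cognitive_names:
        common = common.intersection(feature_groups[n].index)
    tab = ml.hierarchical_evaluation(
        {n: feature_groups[n].loc[common] for n in cognitive_names},
        labels.loc[common], config.cv, k=config.pca_k, pca_mode=config.pca_mode,
    )
    tab.insert(0, "cohort", "combined")
    tables.append(tab)

    physio_names = [n for n in ("ans", "eeg") if n in feature_groups]
    n_physio = 0
    if physio_names:
        sub = labels.index
        for n in cognitive_names + physio_names:
            sub = sub.intersection(feature_groups[n].index)
        n_physio = len(sub)
        if n_physio >= MIN_CLASSIFY_N and labels.loc[sub].nunique() == 2:
            tab = ml.hierarchical_evaluation(
                {n: feature_groups[n].loc[sub] for n in cognitive_names + physio_names},
                labels.loc[sub], config.cv, k=config.pca_k, pca_mode=config.pca_mode,
            )
            tab.insert(0, "cohort", "physio")
            tables.append(tab)
        else:
            logger.warning(
                "physio subcohort too small for classification (n=%d < %d); skipped",
                n_physio, MIN_CLASSIFY_N,
            )
    table = pd.concat(tables, ignore_index=True)
    csv_path = outdir / "classification_accuracy.csv"
    table.to_csv(csv_path, index=False)
    meta = {
        "seed": config.seed,
        "n_combined": int(len(common)),
        "n_physio": n_physio,
        "groups": {k: list(v.columns) for k, v in feature_groups.items()},
        "cv": asdict(config.cv),
    }
    json_path = outdir / "classification_meta.json"
    json_path.write_text(json.dumps(meta, indent=2, default=str))
    return [csv_path, json_path]
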