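"""End-to-end pipeline: ingest → scenes → features → mix/norm → thin →
embed → cluster → timeline, driven by a single declarative config.

Every stage writes its artifact into the output directory together with a
resolved copy of the config and a JSON run report (row counts per stage and
all parameters), so a run is fully reproducible and self-documenting: the
pipeline is a pure function of (input files, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coding, reduce, scenes as scenes_mod, synth, trackio, transform
from .errors import PipelineError, ValidationError
from .features import FeatureRecipe, apply_recipe, get_preset
from .reduce import EmbedParams
from .schemes import get_scheme

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    ``dialect`` selects the input source: ``"track"`` (native container),
    ``"dlc"`` (DeepLabCut HDF5; requires ``fps``) or ``"synthetic"`` (the
    built-in desk-task simulator; ``input`` is ignored and ``synthetic``
    holds the generator parameters).
    """

    out_dir: str
    dialect: str = "synthetic"
    input: str | None = None
    fps: float | None = None
    person_id: int = 0
    scheme: str = "halpe26_upper_body"
    scenes: str | None = None
    recipe: str | list = "desk_task"
    normalize: bool = True
    thin_step: int = 5
    n_neighbors: int = 20
    min_dist: float = 0.1
    seed: int = 42
    clustering: dict = field(
        default_factory=lambda: {"mode": "auto"}
    )
    synthetic: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.dialect not in ("track", "dlc", "synthetic"):
            raise ValidationError(f"unknown dialect '{self.dialect}'")
        if self.dialect != "synthetic":
            if not self.input:
                raise ValidationError("config lacks 'input' path")
            if not Path(self.input).exists():
                raise ValidationError(f"input file '{self.input}' does not exist")
        if self.dialect == "dlc" and (self.fps is None or self.fps <= 0):
            raise ValidationError("dialect 'dlc' requires fps > 0")
        if self.scenes and not Path(self.scenes).exists():
            raise ValidationError(f"scene table '{self.scenes}' does not exist")
        mode = self.clustering.get("mode", "auto")
        if mode not in ("auto", "kmeans", "picks"):
            raise ValidationError(f"unknown clustering mode '{mode}'")
        if mode == "kmeans" and "k" not in self.clustering:
            raise ValidationError("clustering mode 'kmeans' requires 'k'")
        if mode == "picks":
            for key in ("picks", "cluster_table"):
                if key not in self.clustering:
                    raise ValidationError(f"clustering mode 'picks' requires '{key}'")
                if not Path(self.clustering[key]).exists():
                    raise ValidationError(
                        f"clustering file '{self.clustering[key]}' does not exist"
                    )
        try:
            self.resolve_recipe()
        except Exception as exc:  # unknown preset or malformed inline list
            raise ValidationError(f"invalid recipe: {exc}") from exc

    def resolve_recipe(self) -> FeatureRecipe:
        if isinstance(self.recipe, str):
            return get_preset(self.recipe)
        return FeatureRecipe.from_list(self.recipe)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file into a :class:`PipelineConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stage(name):
    """Wrap stage exceptions with the stage name for context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write every artifact to ``out_dir``.

    Returns the run report: row counts at each stage, all parameters, and
    the set of behavior codes in the final timeline.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": asdict(config)}

    # -- ingest -------------------------------------------------------------
    truth = None
    with _stage("ingest"):
        if config.dialect == "synthetic":
            spec = synth.desk_task_spec(
                seed=config.synthetic.get("seed", config.seed),
                **{k: v for k, v in config.synthetic.items() if k != "seed"},
            )
            track, truth = synth.simulate(spec)
            synth.write_ethogram(truth, track.fps, out / "ethogram_truth.csv")
        elif config.dialect == "dlc":
            track = trackio.read_dlc_keypoints(
                config.input, fps=config.fps, person_id=config.person_id,
                scheme=get_scheme(config.scheme),
            )
        else:
            track = trackio.read_track(config.input)
        if len(track.persons) > 1:
            track = trackio.select_person(track, config.person_id)
        trackio.write_track(track, out / "input.track")
        report["stages"]["ingest"] = {"rows": len(track),
                                      "frames": int(len(track.frames))}

    # -- scene filter ---------------------------------------------------------
    if config.scenes:
        with _stage("scenes"):
            table = scenes_mod.read_scene_table(config.scenes)
            track = scenes_mod.filter_by_scenes(track, table)
            report["stages"]["scenes"] = {"rows": len(track)}

    # -- featurize ------------------------------------------------------------
    with _stage("features"):
        recipe = config.resolve_recipe()
        feats = apply_recipe(track, recipe)
        trackio.write_features(feats, out / "features.feat")
        trackio.write_features_csv(feats, out / "features.csv")
        report["stages"]["features"] = {"rows": len(feats),
                                        "columns": feats.columns}

    # -- mix/norm --------------------------------------------------------------
    if config.normalize:
        with _stage("mixnorm"):
            feats = transform.minmax_normalize(feats)
            trackio.write_features_csv(feats, out / "features_normalized.csv")
            report["stages"]["mixnorm"] = {"rows": len(feats)}

    # -- thin -------------------------------------------------------------------
    with _stage("thin"):
        thinned = reduce.thin(feats, config.thin_step)
        report["stages"]["thin"] = {"rows": len(thinned),
                                    "step": config.thin_step}

    # -- embed ------------------------------------------------------------------
    with _stage("embed"):
        params = EmbedParams(
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            thin_step=config.thin_step,
            random_seed=config.seed,
        )
        embedding = reduce.embed(thinned, params)
        reduce.write_embedding(embedding, out / "embedding.csv")
        report["stages"]["embed"] = {"points": len(embedding)}

    # -- cluster ------------------------------------------------------------------
    with _stage("cluster"):
        mode = config.clustering.get("mode", "auto")
        if mode == "auto":
            assignment = coding.auto_cluster(embedding, k=None,
                                             random_seed=config.seed)
        elif mode == "kmeans":
            assignment = coding.auto_cluster(
                embedding, k=int(config.clustering["k"]),
                random_seed=config.seed,
            )
        else:  # picks: replay a manual clustering session
            ct = pd.read_csv(config.clustering["cluster_table"])
            assignment = coding.ClusterAssignment(
                clusters=dict(zip(ct["cluster_id"].astype(int), ct["name"]))
            )
            picks = pd.read_csv(config.clustering["picks"])
            for _, row in picks.iterrows():
                assignment = coding.assign_by_pick(
                    embedding, assignment,
                    pick=(row["u"], row["v"]),
                    picker_range=row["radius"],
                    cluster_id=int(row["cluster_id"]),
                )
        coding.write_cluster_table(assignment, out / "clusters.csv")
        report["stages"]["cluster"] = {
            "n_clusters": len(assignment.clusters),
            "n_labeled": assignment.n_labeled,
        }

    # -- timeline ------------------------------------------------------------------
    with _stage("timeline"):
        frames = track.frames
        timeline = coding.build_timeline(
            assignment, embedding,
            full_frame_range=(int(frames.min()), int(frames.max())),
            fps=track.fps,
        )
        coding.export_timeline(timeline, out / "timeline.csv")
        coding.export_intervals(timeline, out / "intervals.csv")
        report["stages"]["timeline"] = {
            "frames": len(timeline),
            "codes": sorted(timeline.code_set()),
        }

    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=True)
    )
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
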