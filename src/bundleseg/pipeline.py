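"""Config-driven orchestration of the full comparison experiment.

generate -> segment (ROI recipes and template-guided clustering, four
bundles) -> shape measures -> paired cohort comparison -> report. Everything
is reproducible from (config, master seed): the master seed fans out to
per-subject seeds by fixed arithmetic, and every stage is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .clustering import DistanceConfig, TemplatePolicy, auto_segment_by_template
from .core import Tractogram, write_labels, write_tractogram
from .roi import BundleRecipe, default_recipes, apply_recipe
from .shape import BundleSegmentation, bundle_shape_measures
from .stats import ComparisonReport, compare_cohort

log = logging.getLogger("bundleseg")

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class PhantomSection:
    n_subjects: int = 25
    master_seed: int = 42
    n_per_bundle: int = 500
    n_per_artefact: int = 100
    n_background: int = 1000
    radius: float = 2.2
    jitter: float = 0.8
    trim: float = 4.0
    step: float = 2.0
    max_rotation_deg: float = 5.0
    max_scale_dev: float = 0.05


@dataclass
class RecipesSection:
    refined: bool = True
    x_mid: float = 90.0


@dataclass
class ClusteringSection:
    n_points: int = 20
    tau_select: float = 15.0
    tau_final: float = 8.0
    k_schedule: list[int] = field(default_factory=lambda: [50, 100, 200, 400])


@dataclass
class IOSection:
    write_tractograms: bool = False
    write_bundles: bool = False


@dataclass
class RunConfig:
    phantom: PhantomSection = field(default_factory=PhantomSection)
    recipes: RecipesSection = field(default_factory=RecipesSection)
    clustering: ClusteringSection = field(default_factory=ClusteringSection)
    io: IOSection = field(default_factory=IOSection)
    output_dir: str = "runs/default"
    verbosity: str = "info"
    schema_version: int = SCHEMA_VERSION

    def as_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- construction --------------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {version}")
        sections = {"phantom": PhantomSection, "recipes": RecipesSection,
                    "clustering": ClusteringSection, "io": IOSection}
        kwargs: dict = {"schema_version": version}
        for name, klass in sections.items():
            sub = raw.pop(name, {}) or {}
            unknown = set(sub) - {f for f in klass.__dataclass_fields__}
            if unknown:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
            kwargs[name] = klass(**sub)
        for scalar in ("output_dir", "verbosity"):
            if scalar in raw:
                kwargs[scalar] = raw.pop(scalar)
        if raw:
            raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
        cfg = cls(**kwargs)
        if cfg.phantom.n_subjects < 2:
            raise ValueError("phantom.n_subjects must be >= 2")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def phantom_config(self) -> ph.PhantomConfig:
        p = self.phantom
        return ph.PhantomConfig(
            n_per_bundle=p.n_per_bundle, n_per_artefact=p.n_per_artefact,
            n_background=p.n_background, radius=p.radius, jitter=p.jitter,
            trim=p.trim, step=p.step, max_rotation_deg=p.max_rotation_deg,
            max_scale_dev=p.max_scale_dev,
        )

    def distance_config(self) -> DistanceConfig:
        return DistanceConfig(n_points=self.clustering.n_points)

    def template_policy(self) -> TemplatePolicy:
        c = self.clustering
        return TemplatePolicy(tau_select=c.tau_select, tau_final=c.tau_final,
                              k_schedule=tuple(c.k_schedule))


# ---------------------------------------------------------------------------
# Per-subject segmentation stages
# ---------------------------------------------------------------------------

def segment_subject_roi(
    t: Tractogram, recipes: dict[str, BundleRecipe]
) -> dict[str, set[int]]:
    return {name: apply_recipe(t, recipe) for name, recipe in recipes.items()}


def segment_subject_cluster(
    subject: ph.PhantomSubject,
    policy: TemplatePolicy,
    cfg: DistanceConfig,
    seed: int,
) -> dict[str, set[int]]:
    from .clustering import resample_many

    R = resample_many(subject.tractogram.streamlines, cfg.n_points)
    out = {}
    for j, (bundle, template) in enumerate(sorted(subject.templates.items())):
        out[bundle] = auto_segment_by_template(
            subject.tractogram, [template], policy, cfg, seed=seed + 17 * j,
            resampled=R,
        )
    return out


# ---------------------------------------------------------------------------
# The experiment
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    subject_seeds: list[int]
    stages: dict[str, str]
    outputs: list[str]
    elapsed_s: float

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _setup_logging(outdir: Path, verbosity: str) -> None:
    level = getattr(logging, verbosity.upper(), logging.INFO)
    log.setLevel(level)
    for h in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        log.removeHandler(h)  # each run logs to its own outdir
        h.close()
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(type(h) is logging.StreamHandler for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def run_experiment(
    cfg: RunConfig, outdir: str | Path | None = None
) -> tuple[RunManifest, ComparisonReport, pd.DataFrame]:
    """Run the full study on a synthetic cohort.

    Returns the manifest, the comparison report, and the per-(subject,
    bundle, method) shape-measures table. All files are written under
    ``outdir`` (defaults to ``cfg.output_dir``).
    """
    t0 = time.time()
    outdir = Path(outdir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, cfg.verbosity)
    stages: dict[str, str] = {}
    outputs: list[str] = []
    pcfg = cfg.phantom_config()
    recipes = default_recipes(refined=cfg.recipes.refined, x_mid=cfg.recipes.x_mid)
    policy = cfg.template_policy()
    dcfg = cfg.distance_config()
    master = int(cfg.phantom.master_seed)
    n_subjects = cfg.phantom.n_subjects
    subject_seeds = [master + i for i in range(n_subjects)]

    rows = []
    seg_records = []
    current = ("init", -1)
    try:
        cohort = ph.generate_cohort(pcfg, n_subjects, master)
        stages["generate"] = "ok"
        for subject in cohort.subjects:
            sid = subject.spec.subject_id
            t = subject.tractogram
            if cfg.io.write_tractograms:
                trk = outdir / f"subject_{sid:02d}.trk"
                write_tractogram(t, trk)
                write_labels(t.labels, outdir / f"subject_{sid:02d}_labels.csv")
                outputs += [str(trk)]
            current = ("segment_roi", sid)
            roi_segs = segment_subject_roi(t, recipes)
            current = ("segment_cluster", sid)
            cl_segs = segment_subject_cluster(subject, policy, dcfg, seed=subject.spec.seed)
            current = ("shape", sid)
            for method, segs in (("roi", roi_segs), ("streamline", cl_segs)):
                for bundle, ids in segs.items():
                    seg = BundleSegmentation(sid, bundle, method, ids)
                    m = bundle_shape_measures(t, seg)
                    rows.append({"subject": sid, "bundle": bundle, "method": method,
                                 **m.as_dict()})
                    seg_records.append(seg)
                    if cfg.io.write_bundles and ids:
                        bt = t.subset(ids)
                        bpath = outdir / f"subject_{sid:02d}_{bundle}_{method}.trk"
                        write_tractogram(bt, bpath)
                        outputs.append(str(bpath))
            log.info("subject %02d done (roi sizes %s)", sid,
                     {b: len(s) for b, s in roi_segs.items()})
        stages["segment+shape"] = "ok"
        measures = pd.DataFrame(rows).sort_values(
            ["bundle", "subject", "method"]).reset_index(drop=True)
        current = ("compare", -1)
        report = compare_cohort(measures)
        stages["compare"] = "ok"
    except Exception:
        log.exception("stage %s failed (subject %s)", *current)
        raise

    measures_path = outdir / "shape_measures.csv"
    measures.to_csv(measures_path, index=False)
    report.write(outdir / "table1.csv", outdir / "table2.csv", outdir / "report.json")
    outputs += [str(measures_path), str(outdir / "table1.csv"),
                str(outdir / "table2.csv"), str(outdir / "report.json")]
    manifest = RunManifest(
        config_hash=cfg.config_hash(),
        master_seed=master,
        subject_seeds=subject_seeds,
        stages=stages,
        outputs=outputs,
        elapsed_s=round(time.time() - t0, 3),
    )
    manifest.write(outdir / "manifest.json")
    log.info("experiment complete in %.1f s", manifest.elapsed_s)
    return manifest, report, measures
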