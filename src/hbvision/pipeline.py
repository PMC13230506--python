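"""End-to-end pipeline orchestration: simulate -> refine -> featurize ->
fit/evaluate -> decide, driven by a single config with reproducible seeds.

Artifacts are written under the configured output directory and listed in a
manifest with content hashes; identical config + seed yields identical
metric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as sd
from .chromatic_features import EmptyRoiError, hue_histogram, rgb_to_hue
from .corridor_decision import decide_frame
from .evaluation import run_grouped_cv
from .predictors import GbmParams
from .roi_refinement import refine_eyelid, refine_fingernail

__all__ = [
    "RunConfig",
    "MMOL_PER_GDL",
    "mmol_to_gdl",
    "gdl_to_mmol",
    "run_pipeline",
    "refine_samples",
    "histogram_table",
    "build_image_benchmark",
    "quick_histogram_features",
]

logger = logging.getLogger("hbvision")

#: g/dL per mmol/L (monomer convention); reproduces +-1.02 mmol/L ~ +-1.64 g/dL
MMOL_PER_GDL = 1.611


def mmol_to_gdl(hb_mmol: float) -> float:
    return hb_mmol * MMOL_PER_GDL


def gdl_to_mmol(hb_gdl: float) -> float:
    return hb_gdl / MMOL_PER_GDL


_STAGES = ("simulate", "refine", "featurize", "evaluate", "decide")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    cohort: sd.CohortConfig = field(default_factory=sd.CohortConfig)
    render: sd.RenderParams = field(default_factory=sd.RenderParams)
    modality: str = "combined"  # eyelid | fingernail | combined
    family: str = "gbm"  # ridge | gbm
    task: str = "regression"  # regression | classification
    k_folds: int = 10
    n_components: int = 8
    use_metadata: bool = False
    ridge_penalty: float = 1.0
    gbm: GbmParams = field(default_factory=GbmParams)
    histogram_bins: int = 36
    seed: int = 0
    outdir: str = "runs/demo"
    stages: tuple = _STAGES
    save_images: bool = True

    def __post_init__(self) -> None:
        if self.modality not in ("eyelid", "fingernail", "combined"):
            raise ValueError(f"modality must be eyelid|fingernail|combined")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            seed=seed,
            cohort=self.cohort.with_seed(seed),
            gbm=replace(self.gbm, seed=seed),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "cohort" in payload:
            cohort = dict(payload["cohort"])
            if "subgroups" in cohort:
                cohort["subgroups"] = {
                    name: sd.SubgroupParams(
                        **{
                            **params,
                            "hb_range": tuple(params["hb_range"]),
                            "age_range": tuple(params.get("age_range", (18, 85))),
                        }
                    )
                    for name, params in cohort["subgroups"].items()
                }
            if "qol_link" in cohort:
                cohort["qol_link"] = sd.QolLink(**cohort["qol_link"])
            payload["cohort"] = sd.CohortConfig(**cohort)
        if "render" in payload:
            render = dict(payload["render"])
            for key in ("image_size", "background_rgb"):
                if key in render:
                    render[key] = tuple(render[key])
            payload["render"] = sd.RenderParams(**render)
        if "gbm" in payload:
            payload["gbm"] = GbmParams(**payload["gbm"])
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# Stage helpers (pure, in-memory)
# ---------------------------------------------------------------------------


def render_cohort_images(
    entries: Sequence[sd.SubjectEntry],
    params: sd.RenderParams,
    seed: int,
) -> list[sd.ImageSample]:
    """Render all visit images; one spawned substream per entry."""
    streams = np.random.SeedSequence(seed).spawn(len(entries))
    samples: list[sd.ImageSample] = []
    for entry, ss in zip(entries, streams):
        samples.extend(
            sd.render_visit_images(entry, params, np.random.default_rng(ss))
        )
    return samples


def refine_samples(
    samples: Sequence[sd.ImageSample], target_fraction: float = 0.30
) -> tuple[list[np.ndarray], list[dict]]:
    """Apply the modality-specific refinement route to every sample."""
    masks, infos = [], []
    for s in samples:
        if s.modality == "eyelid":
            refined, info = refine_eyelid(
                s.pixels, s.coarse_mask, target_fraction=target_fraction
            )
        else:
            refined = refine_fingernail(s.coarse_mask, target_fraction=target_fraction)
            info = {"fallback": False, "degenerate": refined.degenerate}
        info = {
            **info,
            "modality": s.modality,
            "retained_fraction": refined.retained_fraction,
            "n_pixels": refined.count,
        }
        masks.append(refined.pixels)
        infos.append(info)
    return masks, infos


def histogram_table(
    samples: Sequence[sd.ImageSample],
    masks: Sequence[np.ndarray],
    bins: int = 36,
) -> pd.DataFrame:
    """Per-image normalized hue histograms as a flat table (h00..hBB columns)."""
    rows = []
    for s, mask in zip(samples, masks):
        hues, chromatic = rgb_to_hue(s.pixels)
        try:
            hist = hue_histogram(hues, chromatic=chromatic, mask=mask, bins=bins)
        except EmptyRoiError:
            logger.warning("empty ROI for %s %s; skipped", s.entry_ref, s.modality)
            continue
        row = {
            "patient_id": s.entry_ref[0],
            "visit_index": s.entry_ref[1],
            "modality": s.modality,
            "n_pixels": hist.n_pixels,
        }
        row.update({f"h{i:02d}": m for i, m in enumerate(hist.mass)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------


def build_image_benchmark(
    seed: int,
    cohort: Optional[sd.CohortConfig] = None,
    render: Optional[sd.RenderParams] = None,
    bins: int = 36,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-image synthetic benchmark: simulate, render, refine, featurize.

    Defaults to the standard 551-entry cohort with one eyelid and one
    fingernail image per entry at 80x80 px (strong hue-Hb link, pixel hue
    noise 5 deg).  Returns (features, entries) tables ready for
    :func:`hbvision.evaluation.run_grouped_cv`.
    """
    cohort = (cohort or sd.CohortConfig()).with_seed(seed)
    render = render or sd.RenderParams(
        image_size=(80, 80), eyelid_images=1, fingernail_images=1
    )
    entries = sd.generate_cohort(cohort)
    samples = render_cohort_images(entries, render, seed=cohort.seed + 1)
    masks, _ = refine_samples(samples)
    features = histogram_table(samples, masks, bins=bins)
    return features, sd.cohort_to_frame(entries)


def quick_histogram_features(
    entries_frame: pd.DataFrame,
    render: Optional[sd.RenderParams] = None,
    seed: int = 0,
    bins: int = 36,
    pixels_per_image: int = 400,
) -> pd.DataFrame:
    """Render-free shortcut: draw ROI hue samples directly from the rendering
    model (link + image offset + pixel noise) and histogram them.

    Statistically equivalent to the image route without rasterization; used
    for cheap property tests and null-signal controls.
    """
    render = render or sd.RenderParams(eyelid_images=1, fingernail_images=1)
    rng = np.random.default_rng(seed)
    rows = []
    for _, entry in entries_frame.iterrows():
        link = sd.hue_for_hb(float(entry["hb_true"]), render)
        plan = ["eyelid"] * render.eyelid_images + ["fingernail"] * render.fingernail_images
        for modality in plan:
            offset = rng.normal(0.0, render.image_hue_offset_sd) if render.image_hue_offset_sd else 0.0
            hues = np.clip(
                link + offset + rng.normal(0.0, render.pixel_hue_noise_sd, pixels_per_image),
                0.0,
                359.999,
            )
            hist = hue_histogram(hues, bins=bins)
            row = {
                "patient_id": entry["patient_id"],
                "visit_index": entry["visit_index"],
                "modality": modality,
                "n_pixels": hist.n_pixels,
            }
            row.update({f"h{i:02d}": m for i, m in enumerate(hist.mass)})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    The manifest maps stage names to artifact paths and sha256 content
    hashes; the resolved config snapshot is logged and written alongside.
    On stage failure the exception propagates after logging the stage name;
    artifacts of completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "artifacts": {}}
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))
    logger.info("resolved config: %s", json.dumps(config.to_dict(), default=str))

    def register(stage: str, name: str, path: Path) -> None:
        manifest["artifacts"].setdefault(stage, {})[name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    entries = samples = masks = features = None
    predictions = report = None
    try:
        if "simulate" in config.stages:
            logger.info("stage simulate")
            entries = sd.generate_cohort(config.cohort)
            cohort_frame = sd.cohort_to_frame(entries)
            path = outdir / "cohort.csv"
            cohort_frame.to_csv(path, index=False)
            register("simulate", "cohort", path)
            samples = render_cohort_images(
                entries, config.render, seed=config.cohort.seed + 1
            )
            if config.save_images:
                sd.save_samples(samples, outdir / "samples")
                register("simulate", "sample_index", outdir / "samples" / "index.csv")

        if "refine" in config.stages:
            logger.info("stage refine")
            if samples is None:
                samples = sd.load_samples(outdir / "samples")
            masks, infos = refine_samples(samples)
            path = outdir / "refine_summary.json"
            path.write_text(json.dumps(infos, default=float))
            register("refine", "summary", path)

        if "featurize" in config.stages:
            logger.info("stage featurize")
            if samples is None:
                samples = sd.load_samples(outdir / "samples")
            if masks is None:
                masks, _ = refine_samples(samples)
            features = histogram_table(samples, masks, bins=config.histogram_bins)
            path = outdir / "histograms.csv"
            features.to_csv(path, index=False)
            register("featurize", "histograms", path)

        if "evaluate" in config.stages:
            logger.info("stage evaluate")
            if features is None:
                features = pd.read_csv(outdir / "histograms.csv")
            cohort_frame = pd.read_csv(outdir / "cohort.csv")
            predictions, report = run_grouped_cv(
                features,
                cohort_frame,
                modality=config.modality,
                family=config.family,
                task=config.task,
                k=config.k_folds,
                seed=config.seed,
                n_components=config.n_components,
                use_metadata=config.use_metadata,
                ridge_penalty=config.ridge_penalty,
                gbm_params=config.gbm,
            )
            pred_path = outdir / "predictions.csv"
            predictions.to_csv(pred_path, index=False)
            register("evaluate", "predictions", pred_path)
            report_path = outdir / "evaluation.json"
            report_path.write_text(json.dumps(report.to_dict(), indent=2, default=float))
            register("evaluate", "report", report_path)
            if report.confusion is not None:
                conf_path = outdir / "confusion.csv"
                labels = ["Red", "Yellow", "Green"]
                pd.DataFrame(report.confusion, index=labels, columns=labels).to_csv(
                    conf_path
                )
                register("evaluate", "confusion", conf_path)
            if config.task == "regression" and not predictions.empty:
                scatter_path = outdir / "scatter.csv"
                predictions[["patient_id", "visit_index", "hb_true", "hb_pred"]].to_csv(
                    scatter_path, index=False
                )
                register("evaluate", "scatter", scatter_path)

        if "decide" in config.stages and config.task == "regression":
            logger.info("stage decide")
            if predictions is None:
                predictions = pd.read_csv(outdir / "predictions.csv")
            cohort_frame = pd.read_csv(outdir / "cohort.csv")
            table = predictions.merge(
                cohort_frame[
                    [
                        "patient_id",
                        "visit_index",
                        "qol_global_health",
                        "qol_fatigue",
                        "clinician_label",
                    ]
                ],
                on=["patient_id", "visit_index"],
                how="left",
            ).rename(
                columns={
                    "hb_pred": "predicted_hb",
                    "qol_global_health": "global_health",
                    "qol_fatigue": "fatigue",
                }
            )
            decisions, concordance = decide_frame(table)
            path = outdir / "decisions.csv"
            decisions.to_csv(path, index=False)
            register("decide", "decisions", path)
            if concordance is not None:
                conc_path = outdir / "concordance.json"
                payload = dict(concordance)
                payload["confusion"] = payload["confusion"].tolist()
                conc_path.write_text(json.dumps(payload, indent=2))
                register("decide", "concordance", conc_path)
    except Exception:
        logger.exception("pipeline stage failed")
        raise

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
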