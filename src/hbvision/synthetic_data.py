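"""Synthetic cohort, QoL, clinician-label and image generation.

Everything downstream of data collection is testable offline: this module
generates a three-subgroup cohort (healthy donors A, anemic patients B,
non-anemic patients C) with repeated visits, Hb-linked QoL scores, a
documented clinician labeling rule, and rendered eyelid/fingernail image
patches whose ROI hue is a monotone function of the entry's true Hb.

Default distribution parameters mirror the study cohort structure:
A n=184 (Hb median 8.6, range 6.5-11.4), B n=101 (5.2, 3.4-6.2),
C n=266 (7.9, 6.3-11.3), anemia threshold 6.21 mmol/L.  Hb is sampled from
a truncated normal per subgroup (location = median, truncation = range,
scale = span/4) since only medians and ranges are available.

The hue-Hb link is linear, ``hue = h0 - beta * hb`` with beta > 0, so hue
shifts red-ward (toward 0 deg) as Hb rises; defaults map the clinical Hb
span onto a ~30 deg shift and keep all hues inside [0, 120] deg, away from
the circular seam.  One global seed is split into per-stage substreams so
partial reruns stay reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.stats import truncnorm
from skimage.color import hsv2rgb
from skimage.draw import ellipse as draw_ellipse

from .corridor_decision import (
    DEFAULT_CUTPOINTS,
    CorridorLabel,
    QoLCutpoints,
    hb_to_corridor,
)

__all__ = [
    "ANEMIA_THRESHOLD",
    "SubgroupParams",
    "QolLink",
    "CohortConfig",
    "RenderParams",
    "SubjectEntry",
    "ImageSample",
    "generate_cohort",
    "generate_qol",
    "assign_clinician_label",
    "render_visit_images",
    "hue_for_hb",
    "cohort_to_frame",
    "save_samples",
    "load_samples",
]

#: Hb threshold (mmol/L) splitting anemic (B) from non-anemic (C) patients.
ANEMIA_THRESHOLD = 6.21


class ConfigurationError(ValueError):
    """Invalid cohort or rendering configuration."""


@dataclass(frozen=True)
class SubgroupParams:
    """Sampling parameters for one cohort subgroup."""

    n: int
    hb_median: float
    hb_range: tuple[float, float]
    hb_scale: Optional[float] = None  # defaults to range span / 4
    age_median: float = 50.0
    age_range: tuple[float, float] = (18.0, 85.0)
    female_fraction: float = 0.5

    def validate(self, name: str) -> None:
        if self.n < 0:
            raise ConfigurationError(f"subgroup {name}: count must be >= 0")
        lo, hi = self.hb_range
        if not lo < hi:
            raise ConfigurationError(f"subgroup {name}: Hb range bounds must be ordered")
        if lo <= 0:
            raise ConfigurationError(f"subgroup {name}: Hb must be positive")
        if self.hb_scale is not None and self.hb_scale <= 0:
            raise ConfigurationError(f"subgroup {name}: Hb scale must be positive")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ConfigurationError(f"subgroup {name}: female fraction in [0,1]")

    @property
    def scale(self) -> float:
        return self.hb_scale if self.hb_scale is not None else (
            (self.hb_range[1] - self.hb_range[0]) / 4.0
        )


@dataclass(frozen=True)
class QolLink:
    """Linear links from Hb to the two QoL scores, plus noise SDs.

    Global Health increases with Hb; Fatigue (reverse-scaled) decreases.
    Scores are clipped to [0, 100] after noise.
    """

    gh_intercept: float = 10.0
    gh_slope: float = 7.5
    gh_noise_sd: float = 8.0
    fatigue_intercept: float = 110.0
    fatigue_slope: float = -9.0
    fatigue_noise_sd: float = 8.0

    def validate(self) -> None:
        if self.gh_noise_sd < 0 or self.fatigue_noise_sd < 0:
            raise ConfigurationError("QoL noise SDs must be >= 0")


_DEFAULT_SUBGROUPS = {
    "A": SubgroupParams(
        n=184, hb_median=8.6, hb_range=(6.5, 11.4),
        age_median=39, age_range=(18, 78), female_fraction=89 / 184,
    ),
    "B": SubgroupParams(
        n=101, hb_median=5.2, hb_range=(3.4, 6.2),
        age_median=62, age_range=(21, 83), female_fraction=51 / 101,
    ),
    "C": SubgroupParams(
        n=266, hb_median=7.9, hb_range=(6.3, 11.3),
        age_median=59, age_range=(21, 81), female_fraction=114 / 266,
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the cohort generator.

    ``qol_fraction`` controls the size of the QoL subset (drawn from patient
    entries, default 47/551); ``qol_missing_prob`` independently blanks one
    of the two scores to emulate pairwise-incomplete questionnaires.
    """

    subgroups: dict = field(default_factory=lambda: dict(_DEFAULT_SUBGROUPS))
    visit_repeat_prob: float = 0.15
    qol_fraction: float = 47 / 551
    qol_missing_prob: float = 0.0
    qol_link: QolLink = field(default_factory=QolLink)
    seed: int = 0

    def validate(self) -> None:
        for name, sub in self.subgroups.items():
            sub.validate(name)
        if not (0.0 <= self.visit_repeat_prob <= 1.0):
            raise ConfigurationError("visit_repeat_prob must lie in [0, 1]")
        if not (0.0 <= self.qol_fraction <= 1.0):
            raise ConfigurationError("qol_fraction must lie in [0, 1]")
        if not (0.0 <= self.qol_missing_prob <= 1.0):
            raise ConfigurationError("qol_missing_prob must lie in [0, 1]")
        self.qol_link.validate()
        hi_b = self.subgroups.get("B")
        lo_c = self.subgroups.get("C")
        if hi_b and hi_b.hb_range[1] >= ANEMIA_THRESHOLD:
            raise ConfigurationError("subgroup B Hb range must stay below 6.21 mmol/L")
        if lo_c and lo_c.hb_range[0] <= ANEMIA_THRESHOLD:
            raise ConfigurationError("subgroup C Hb range must stay above 6.21 mmol/L")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass
class SubjectEntry:
    """One (patient, visit) record."""

    patient_id: str
    visit_index: int
    subgroup: str
    age: float
    sex: str
    hb_true: float
    qol_global_health: Optional[float] = None
    qol_fatigue: Optional[float] = None
    clinician_label: Optional[CorridorLabel] = None


@dataclass
class ImageSample:
    """One rendered RGB photograph plus its coarse mask and ground truth."""

    entry_ref: tuple[str, int]
    modality: str  # "eyelid" | "fingernail"
    pixels: np.ndarray  # H x W x 3 uint8
    coarse_mask: np.ndarray  # H x W bool
    ground_truth: dict  # true_mask, hue_offset, lighting_gain, link_hue, ...


def _substream(seed: int, stage: int) -> np.random.Generator:
    """Per-stage child stream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stage + 1)[stage])


def _sample_truncnorm(
    rng: np.random.Generator, n: int, loc: float, scale: float, lo: float, hi: float
) -> np.ndarray:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def generate_cohort(config: CohortConfig) -> list[SubjectEntry]:
    """Generate the full cohort: exactly sum of subgroup counts entries.

    Subgroup Hb values respect the configured ranges (and hence the 6.21
    mmol/L anemia threshold for B and C).  With probability
    ``visit_repeat_prob`` an entry re-enrolls an existing subject of the
    same pool (donors for A, patients for B/C) with the next visit index;
    patients may switch between B and C across visits as their Hb changes.
    Deterministic given the config seed.
    """
    config.validate()
    rng_hb = _substream(config.seed, 0)
    rng_demo = _substream(config.seed, 1)
    rng_visits = _substream(config.seed, 2)
    rng_qol = _substream(config.seed, 3)

    entries: list[SubjectEntry] = []
    donor_ids: list[str] = []
    patient_ids: list[str] = []
    visit_counts: dict[str, int] = {}
    demographics: dict[str, tuple[float, str]] = {}
    counters = {"donor": 0, "patient": 0}

    for name in sorted(config.subgroups):
        sub = config.subgroups[name]
        if sub.n == 0:
            continue
        hb = _sample_truncnorm(
            rng_hb, sub.n, sub.hb_median, sub.scale, *sub.hb_range
        )
        age_scale = (sub.age_range[1] - sub.age_range[0]) / 4.0
        ages = _sample_truncnorm(
            rng_demo, sub.n, sub.age_median, age_scale, *sub.age_range
        )
        female = rng_demo.random(sub.n) < sub.female_fraction
        pool = donor_ids if name == "A" else patient_ids
        prefix = "D" if name == "A" else "P"
        counter_key = "donor" if name == "A" else "patient"
        for i in range(sub.n):
            if pool and rng_visits.random() < config.visit_repeat_prob:
                pid = pool[rng_visits.integers(len(pool))]
                age, sex = demographics[pid]
            else:
                pid = f"{prefix}{counters[counter_key]:04d}"
                counters[counter_key] += 1
                pool.append(pid)
                age, sex = float(ages[i]), ("female" if female[i] else "male")
                demographics[pid] = (age, sex)
            visit = visit_counts.get(pid, 0)
            visit_counts[pid] = visit + 1
            entries.append(
                SubjectEntry(
                    patient_id=pid,
                    visit_index=visit,
                    subgroup=name,
                    age=age,
                    sex=sex,
                    hb_true=float(hb[i]),
                )
            )

    # QoL subset: patient entries only, mirroring partial questionnaire coverage
    total = len(entries)
    qol_n = int(round(config.qol_fraction * total))
    patient_entries = [i for i, e in enumerate(entries) if e.subgroup != "A"]
    candidates = patient_entries if patient_entries else list(range(total))
    qol_n = min(qol_n, len(candidates))
    if qol_n > 0:
        chosen = rng_qol.choice(len(candidates), size=qol_n, replace=False)
        for j in np.sort(chosen):
            entry = entries[candidates[int(j)]]
            gh, fatigue = generate_qol(entry.hb_true, config.qol_link, rng_qol)
            if config.qol_missing_prob and rng_qol.random() < config.qol_missing_prob:
                if rng_qol.random() < 0.5:
                    gh = None
                else:
                    fatigue = None
            entry.qol_global_health = gh
            entry.qol_fatigue = fatigue
            if fatigue is not None:
                entry.clinician_label = assign_clinician_label(entry.hb_true, fatigue)
    return entries


def generate_qol(
    hb: float,
    link: QolLink = QolLink(),
    rng: Union[int, np.random.Generator, None] = None,
) -> tuple[float, float]:
    """Sample (Global Health, Fatigue) scores linked linearly to Hb.

    Global Health increases and Fatigue decreases in Hb on average; both
    are clipped to [0, 100].  With zero noise the outputs equal the exact
    (clipped) linear links.  Deterministic given the same seed.
    """
    if hb <= 0:
        raise ValueError("hb must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    gh = link.gh_intercept + link.gh_slope * hb
    fatigue = link.fatigue_intercept + link.fatigue_slope * hb
    if link.gh_noise_sd > 0:
        gh += rng.normal(0.0, link.gh_noise_sd)
    if link.fatigue_noise_sd > 0:
        fatigue += rng.normal(0.0, link.fatigue_noise_sd)
    return float(np.clip(gh, 0.0, 100.0)), float(np.clip(fatigue, 0.0, 100.0))


def assign_clinician_label(
    hb_true: float,
    fatigue: float,
    cutpoints: QoLCutpoints = DEFAULT_CUTPOINTS,
) -> CorridorLabel:
    """Deterministic clinician decision rule used to label synthetic entries.

    Default rule: the Hb corridor, escalated one level (Yellow -> Red) when
    the Hb corridor is Yellow and the fatigue score falls in its low-QoL
    band (>= 39).  Monotone: lower Hb never yields a less severe label at
    fixed fatigue.
    """
    if not (0.0 <= fatigue <= 100.0):
        raise ValueError("fatigue score must lie in [0, 100]")
    base = hb_to_corridor(hb_true)
    if base is CorridorLabel.YELLOW and fatigue >= cutpoints.fatigue_low_lower:
        return CorridorLabel.RED
    return base


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderParams:
    """Rendering model for synthetic eyelid/fingernail patches.

    ROI hue expectation follows the monotone link ``h0 - beta * hb`` (red-ward
    shift as Hb rises) plus an image-level lighting hue offset and per-pixel
    noise.  The lighting gain multiplies the HSV value channel, leaving hue
    invariant.  The coarse mask is the true ROI dilated by a contaminating
    rim, emulating over-segmentation that erosion must remove.
    """

    image_size: tuple[int, int] = (96, 96)
    eyelid_images: int = 2
    fingernail_images: int = 2
    nails_per_image: int = 1
    hue_intercept: float = 60.0  # degrees at Hb = 0
    hue_slope: float = 3.75  # degrees per mmol/L, subtracted
    pixel_hue_noise_sd: float = 5.0
    image_hue_offset_sd: float = 1.0
    lighting_gain_sd: float = 0.05
    saturation: float = 0.6
    value: float = 0.7
    background_rgb: tuple[int, int, int] = (247, 243, 239)
    background_noise_sd: float = 2.0
    coarse_dilation: int = 4

    def validate(self) -> None:
        if min(self.image_size) < 32:
            raise ConfigurationError("image size must be at least 32 px")
        for name in ("pixel_hue_noise_sd", "image_hue_offset_sd", "lighting_gain_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.coarse_dilation < 1:
            raise ConfigurationError("coarse_dilation must be >= 1 (strict superset)")


def hue_for_hb(hb: float, params: RenderParams = RenderParams()) -> float:
    """The documented monotone hue-Hb link, clipped to [0, 120] degrees."""
    return float(np.clip(params.hue_intercept - params.hue_slope * hb, 0.0, 120.0))


_CROSS = ndimage.generate_binary_structure(2, 1)


def _eyelid_truth(
    shape: tuple[int, int], rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    h, w = shape
    m = min(h, w)
    radius = rng.uniform(0.25, 0.33) * m
    cr = 0.40 * h + rng.uniform(-0.03, 0.03) * h
    cc = 0.50 * w + rng.uniform(-0.03, 0.03) * w
    rows, cols = np.ogrid[:h, :w]
    mask = ((rows - cr) ** 2 + (cols - cc) ** 2 < radius**2) & (rows >= cr)
    return mask, {"center_row": cr, "center_col": cc, "radius": radius}


def _fingernail_truth(
    shape: tuple[int, int], rng: np.random.Generator, n_nails: int
) -> tuple[np.ndarray, dict]:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    nails = []
    for i in range(n_nails):
        cr = h * (0.5 + rng.uniform(-0.06, 0.06))
        cc = w * ((i + 0.5) / n_nails + rng.uniform(-0.04, 0.04) / n_nails)
        a = rng.uniform(0.20, 0.28) * h  # semi-axis along rows
        b = rng.uniform(0.14, 0.20) * (w / n_nails)
        rot = rng.uniform(-0.3, 0.3)
        rr, cc_idx = draw_ellipse(cr, cc, a, b, shape=shape, rotation=rot)
        mask[rr, cc_idx] = True
        nails.append({"center_row": cr, "center_col": cc, "a": a, "b": b, "rot": rot})
    return mask, {"nails": nails}


def render_visit_images(
    entry: SubjectEntry,
    params: RenderParams = RenderParams(),
    rng: Union[int, np.random.Generator, None] = None,
) -> list[ImageSample]:
    """Render the eyelid and fingernail patches for one (patient, visit) entry.

    The expected ROI hue equals :func:`hue_for_hb` at the entry's Hb plus the
    per-image lighting hue offset; the background is near-white.  The coarse
    mask strictly contains the true ROI (dilated rim).  Eyelid images carry a
    circular lower-segment ROI, fingernail images elliptical ROIs.
    """
    params.validate()
    if entry.hb_true is None or entry.hb_true <= 0:
        raise ValueError("entry must carry a positive hb_true")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    samples: list[ImageSample] = []
    plan = [("eyelid", i) for i in range(params.eyelid_images)] + [
        ("fingernail", i) for i in range(params.fingernail_images)
    ]
    link_hue = hue_for_hb(entry.hb_true, params)
    h, w = params.image_size
    for modality, _ in plan:
        if modality == "eyelid":
            true_mask, geometry = _eyelid_truth((h, w), rng)
        else:
            true_mask, geometry = _fingernail_truth((h, w), rng, params.nails_per_image)

        offset = (
            rng.normal(0.0, params.image_hue_offset_sd)
            if params.image_hue_offset_sd > 0
            else 0.0
        )
        gain = (
            rng.normal(0.0, params.lighting_gain_sd)
            if params.lighting_gain_sd > 0
            else 0.0
        )

        canvas = np.empty((h, w, 3), dtype=float)
        canvas[...] = np.asarray(params.background_rgb, dtype=float)
        if params.background_noise_sd > 0:
            canvas += rng.normal(0.0, params.background_noise_sd, size=canvas.shape)

        n_roi = int(true_mask.sum())
        hues = np.full(n_roi, link_hue + offset)
        if params.pixel_hue_noise_sd > 0:
            hues += rng.normal(0.0, params.pixel_hue_noise_sd, size=n_roi)
        hues = np.clip(hues, 0.0, 120.0)
        hsv = np.stack(
            [
                hues / 360.0,
                np.full(n_roi, params.saturation),
                np.full(n_roi, np.clip(params.value * (1.0 + gain), 0.05, 1.0)),
            ],
            axis=-1,
        )
        roi_rgb = hsv2rgb(hsv.reshape(1, n_roi, 3)).reshape(n_roi, 3) * 255.0
        canvas[true_mask] = roi_rgb
        pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

        coarse = ndimage.binary_dilation(
            true_mask, structure=_CROSS, iterations=params.coarse_dilation
        )
        samples.append(
            ImageSample(
                entry_ref=(entry.patient_id, entry.visit_index),
                modality=modality,
                pixels=pixels,
                coarse_mask=coarse,
                ground_truth={
                    "true_mask": true_mask,
                    "hue_offset": float(offset),
                    "lighting_gain": float(gain),
                    "link_hue": link_hue,
                    "geometry": geometry,
                },
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def cohort_to_frame(entries: Sequence[SubjectEntry]) -> pd.DataFrame:
    """One row per entry; absent QoL / labels become NaN / empty strings."""
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in entries],
            "visit_index": [e.visit_index for e in entries],
            "subgroup": [e.subgroup for e in entries],
            "age": [e.age for e in entries],
            "sex": [e.sex for e in entries],
            "hb_true": [e.hb_true for e in entries],
            "qol_global_health": [e.qol_global_health for e in entries],
            "qol_fatigue": [e.qol_fatigue for e in entries],
            "clinician_label": [
                e.clinician_label.value if e.clinician_label else "" for e in entries
            ],
        }
    )


def _mask_to_png(mask: np.ndarray, path: Path) -> None:
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


def _png_to_mask(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def save_samples(samples: Sequence[ImageSample], outdir: Union[str, Path]) -> pd.DataFrame:
    """Write samples as PNG images/masks plus JSON ground-truth sidecars.

    Returns (and writes as ``index.csv``) an index table with the artifact
    paths relative to ``outdir``.
    """
    outdir = Path(outdir)
    for sub in ("images", "coarse_masks", "true_masks", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        stem = f"{s.entry_ref[0]}_v{s.entry_ref[1]}_{s.modality}_{i:05d}"
        img_path = f"images/{stem}.png"
        coarse_path = f"coarse_masks/{stem}.png"
        true_path = f"true_masks/{stem}.png"
        truth_path = f"truth/{stem}.json"
        Image.fromarray(s.pixels, mode="RGB").save(outdir / img_path)
        _mask_to_png(s.coarse_mask, outdir / coarse_path)
        _mask_to_png(s.ground_truth["true_mask"], outdir / true_path)
        sidecar = {k: v for k, v in s.ground_truth.items() if k != "true_mask"}
        (outdir / truth_path).write_text(json.dumps(sidecar))
        rows.append(
            {
                "patient_id": s.entry_ref[0],
                "visit_index": s.entry_ref[1],
                "modality": s.modality,
                "image_path": img_path,
                "coarse_mask_path": coarse_path,
                "true_mask_path": true_path,
                "truth_path": truth_path,
            }
        )
    index = pd.DataFrame(rows)
    index.to_csv(outdir / "index.csv", index=False)
    return index


def load_samples(outdir: Union[str, Path]) -> list[ImageSample]:
    """Inverse of :func:`save_samples`."""
    outdir = Path(outdir)
    index = pd.read_csv(outdir / "index.csv")
    samples = []
    for _, row in index.iterrows():
        truth = json.loads((outdir / row["truth_path"]).read_text())
        truth["true_mask"] = _png_to_mask(outdir / row["true_mask_path"])
        samples.append(
            ImageSample(
                entry_ref=(row["patient_id"], int(row["visit_index"])),
                modality=row["modality"],
                pixels=np.asarray(Image.open(outdir / row["image_path"]).convert("RGB")),
                coarse_mask=_png_to_mask(outdir / row["coarse_mask_path"]),
                ground_truth=truth,
            )
        )
    return samples
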