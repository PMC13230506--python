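"""Clinical corridor discretization and the rule-based decision layer.

Hemoglobin values (mmol/L) are mapped onto three ordered severity corridors
(Red > Yellow > Green).  EORTC Global Health and Fatigue scores are mapped to
the same corridors via fixed cut-points, and the three component labels are
combined by an equal-weight majority vote with a conservative tie-break.

The layer is fully deterministic and rule-based: no weights are learned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CorridorLabel",
    "LABEL_ORDER",
    "QoLCutpoints",
    "DEFAULT_CUTPOINTS",
    "RED_UPPER",
    "GREEN_LOWER",
    "hb_to_corridor",
    "qol_to_corridor",
    "majority_vote",
    "concordance_report",
    "decide_frame",
]


class CorridorLabel(str, Enum):
    """Three-level severity label with total order Red > Yellow > Green."""

    RED = "Red"
    YELLOW = "Yellow"
    GREEN = "Green"

    @property
    def severity(self) -> int:
        """Severity rank: Green 0 < Yellow 1 < Red 2."""
        return _SEVERITY[self]

    @classmethod
    def from_string(cls, value: str) -> "CorridorLabel":
        try:
            return cls(str(value).strip().capitalize())
        except ValueError as exc:  # pragma: no cover - defensive
            raise ValueError(f"not a corridor label: {value!r}") from exc


_SEVERITY = {CorridorLabel.GREEN: 0, CorridorLabel.YELLOW: 1, CorridorLabel.RED: 2}

#: Row/column order used for confusion matrices throughout the package.
LABEL_ORDER: tuple[CorridorLabel, ...] = (
    CorridorLabel.RED,
    CorridorLabel.YELLOW,
    CorridorLabel.GREEN,
)

#: Corridor boundaries in mmol/L.  Yellow is closed at both ends.
RED_UPPER = 4.5
GREEN_LOWER = 6.0


def hb_to_corridor(
    hb: float, red_upper: float = RED_UPPER, green_lower: float = GREEN_LOWER
) -> CorridorLabel:
    """Map an Hb value (mmol/L) to its clinical corridor.

    Red iff hb < ``red_upper``; Yellow iff ``red_upper`` <= hb <= ``green_lower``
    (closed at both boundaries); Green iff hb > ``green_lower``.

    Raises
    ------
    ValueError
        If ``hb`` is non-positive or non-finite.
    """
    hb = float(hb)
    if not np.isfinite(hb) or hb <= 0:
        raise ValueError(f"Hb must be a positive finite value in mmol/L, got {hb!r}")
    if hb < red_upper:
        return CorridorLabel.RED
    if hb <= green_lower:
        return CorridorLabel.YELLOW
    return CorridorLabel.GREEN


@dataclass(frozen=True)
class QoLCutpoints:
    """Cut-points partitioning [0, 100] QoL scores into low/moderate/high strata.

    Global Health (higher is better): low [0, 45), moderate [45, 66),
    high [66, 100].  Fatigue (higher is worse, reverse-scaled): low-QoL
    [39, 100], moderate [17, 39), high [0, 17).  Boundaries are half-open;
    the overlap in the published Global Health bands (0-45 vs 45-65) is
    resolved as 45 -> moderate and 66 -> high.
    """

    global_health_low_upper: float = 45.0
    global_health_moderate_upper: float = 66.0
    fatigue_low_lower: float = 39.0
    fatigue_moderate_lower: float = 17.0

    def __post_init__(self) -> None:
        if not (0 < self.global_health_low_upper < self.global_health_moderate_upper <= 100):
            raise ValueError("Global Health cut-points must satisfy 0 < low < moderate <= 100")
        if not (0 < self.fatigue_moderate_lower < self.fatigue_low_lower <= 100):
            raise ValueError("Fatigue cut-points must satisfy 0 < moderate < low <= 100")


DEFAULT_CUTPOINTS = QoLCutpoints()


def qol_to_corridor(
    score: float, scale: str, cutpoints: QoLCutpoints = DEFAULT_CUTPOINTS
) -> CorridorLabel:
    """Map a QoL score in [0, 100] to a corridor (low stratum -> Red, ...).

    Parameters
    ----------
    score:
        EORTC score on the 0-100 scale.
    scale:
        ``"global_health"`` (higher is better) or ``"fatigue"``
        (reverse-scaled: higher is worse).
    """
    score = float(score)
    if not np.isfinite(score) or not (0.0 <= score <= 100.0):
        raise ValueError(f"QoL score must lie in [0, 100], got {score!r}")
    if scale == "global_health":
        if score < cutpoints.global_health_low_upper:
            return CorridorLabel.RED
        if score < cutpoints.global_health_moderate_upper:
            return CorridorLabel.YELLOW
        return CorridorLabel.GREEN
    if scale == "fatigue":
        if score >= cutpoints.fatigue_low_lower:
            return CorridorLabel.RED
        if score >= cutpoints.fatigue_moderate_lower:
            return CorridorLabel.YELLOW
        return CorridorLabel.GREEN
    raise ValueError(f"unknown QoL scale {scale!r}")


def majority_vote(
    hb_corridor: Optional[CorridorLabel],
    global_health_corridor: Optional[CorridorLabel] = None,
    fatigue_corridor: Optional[CorridorLabel] = None,
) -> CorridorLabel:
    """Equal-weight majority vote over the available component corridors.

    A label occurring at least twice wins.  When no label has a majority
    (all three distinct, or a 1-1 tie with a missing component) the most
    severe tied label is selected (Red > Yellow > Green).  Missing components
    are skipped; a single component passes through unchanged.
    """
    votes = [v for v in (hb_corridor, global_health_corridor, fatigue_corridor) if v is not None]
    if not votes:
        raise ValueError("majority_vote requires at least one component corridor")
    counts = Counter(votes)
    top = max(counts.values())
    tied = [label for label, c in counts.items() if c == top]
    return max(tied, key=lambda label: label.severity)


def concordance_report(
    aggregated_labels: Sequence[CorridorLabel],
    clinician_labels: Sequence[CorridorLabel],
) -> dict:
    """Compare aggregated decision labels against clinician labels.

    Returns a dict with the 3x3 confusion matrix (rows = clinician/true,
    cols = aggregated/predicted, order Red/Yellow/Green), total counts and
    the agreement fraction (diagonal sum / total).
    """
    # local import to avoid a module cycle (evaluation imports corridors)
    from .evaluation import corridor_confusion

    if len(aggregated_labels) != len(clinician_labels):
        raise ValueError(
            f"length mismatch: {len(aggregated_labels)} aggregated vs "
            f"{len(clinician_labels)} clinician labels"
        )
    summary = corridor_confusion(clinician_labels, aggregated_labels)
    total = int(summary["total"])
    agreement = float(summary["total_correct"] / total) if total else float("nan")
    return {
        "confusion": summary["confusion"],
        "per_class_accuracy": summary["per_class_accuracy"],
        "total_correct": summary["total_correct"],
        "total": total,
        "agreement": agreement,
    }


def decide_frame(
    frame: pd.DataFrame, cutpoints: QoLCutpoints = DEFAULT_CUTPOINTS
) -> tuple[pd.DataFrame, Optional[dict]]:
    """Apply the decision layer to a table of predictions.

    ``frame`` must contain ``predicted_hb`` and may contain ``global_health``,
    ``fatigue`` and ``clinician_label`` columns (NaN = absent).  Returns the
    table with component-corridor and ``aggregated_label`` columns appended,
    plus a concordance report when clinician labels are present.
    """
    out = frame.copy()
    hb_corr, gh_corr, fat_corr, agg = [], [], [], []
    for _, row in out.iterrows():
        hb_label = hb_to_corridor(row["predicted_hb"])
        gh = row.get("global_health")
        fat = row.get("fatigue")
        gh_label = (
            qol_to_corridor(gh, "global_health", cutpoints) if pd.notna(gh) else None
        )
        fat_label = qol_to_corridor(fat, "fatigue", cutpoints) if pd.notna(fat) else None
        hb_corr.append(hb_label.value)
        gh_corr.append(gh_label.value if gh_label else "")
        fat_corr.append(fat_label.value if fat_label else "")
        agg.append(majority_vote(hb_label, gh_label, fat_label).value)
    out["hb_corridor"] = hb_corr
    out["global_health_corridor"] = gh_corr
    out["fatigue_corridor"] = fat_corr
    out["aggregated_label"] = agg

    report = None
    if "clinician_label" in out.columns:
        have = out["clinician_label"].notna() & (out["clinician_label"] != "")
        if have.any():
            clin = [CorridorLabel.from_string(v) for v in out.loc[have, "clinician_label"]]
            pred = [CorridorLabel.from_string(v) for v in out.loc[have, "aggregated_label"]]
            report = concordance_report(pred, clin)
    return out, report
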