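"""Rectangular latent-space partition, tissue scores and lesion reports.

The fitted autoencoder places every axial cross-section at a point (x, y)
in its 2-D latent space.  Classification partitions the plane into four
rectangles with one vertical and one horizontal threshold; each quadrant is
one tissue class:

    class 1  lumen patent                  score 0
    class 2  lumen partially patent        score 1
    class 3  mostly occluded, soft tissue  score 3
    class 4  mostly occluded, hard tissue  score 5

Cells are half-open (a coordinate equal to a threshold falls on the upper
side), so the four regions tile the plane exactly.  Reference thresholds of
0.8/0.8 are kept as documented defaults, but latent geometry differs
between training runs, so :func:`calibrate_boundaries` — a grid search over
thresholds and quadrant-to-class assignments against a labelled subset — is
the supported route for any new fit.

A lesion's average tissue score is the sum of its per-slice scores divided
by the number of slices, i.e. the dot product of the class fractions with
(0, 1, 3, 5).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TISSUE_SCORES",
    "CLASS_LABELS",
    "ClassBoundaries",
    "LesionReport",
    "classify_point",
    "classify_points",
    "score_lesion",
    "calibrate_boundaries",
    "summarize_cohort",
]

#: Immutable tissue-score map: class id -> score.
TISSUE_SCORES: Mapping[int, int] = {1: 0, 2: 1, 3: 3, 4: 5}

CLASS_LABELS: Mapping[int, str] = {
    1: "lumen patent",
    2: "lumen partially patent",
    3: "lumen mostly occluded, soft tissue",
    4: "lumen mostly occluded, hard tissue",
}

#: Default quadrant -> class map.  Key is (x_side, y_side) with 0 = below
#: threshold, 1 = at/above.  Lower-left patent, upper-left partially patent,
#: lower-right soft occlusion, upper-right hard occlusion.
DEFAULT_CLASS_MAP: Mapping[tuple[int, int], int] = {
    (0, 0): 1,
    (0, 1): 2,
    (1, 0): 3,
    (1, 1): 4,
}


@dataclass(frozen=True)
class ClassBoundaries:
    """One vertical and one horizontal threshold plus a quadrant->class map."""

    x_threshold: float = 0.8
    y_threshold: float = 0.8
    class_map: Mapping[tuple[int, int], int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAP)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_map", dict(self.class_map))
        if set(self.class_map.keys()) != {(0, 0), (0, 1), (1, 0), (1, 1)}:
            raise ValueError("class_map must cover the four quadrants")
        if sorted(self.class_map.values()) != [1, 2, 3, 4]:
            raise ValueError("class_map must assign the four classes bijectively")
        if not (np.isfinite(self.x_threshold) and np.isfinite(self.y_threshold)):
            raise ValueError("thresholds must be finite")

    def to_dict(self) -> dict:
        return {
            "x_threshold": self.x_threshold,
            "y_threshold": self.y_threshold,
            "class_map": {f"{k[0]},{k[1]}": v for k, v in self.class_map.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassBoundaries":
        cmap = {
            tuple(int(t) for t in k.split(",")): int(v)
            for k, v in d["class_map"].items()
        }
        return cls(float(d["x_threshold"]), float(d["y_threshold"]), cmap)


def classify_point(point, boundaries: ClassBoundaries | None = None) -> int:
    """Tissue class of one latent point.

    ``point`` may be a (x, y) pair or an object with .x/.y.  With default
    boundaries: x < 0.8 and y < 0.8 -> class 1; x < 0.8, y >= 0.8 -> 2;
    x >= 0.8, y < 0.8 -> 3; x >= 0.8, y >= 0.8 -> 4.
    """
    b = boundaries or ClassBoundaries()
    if hasattr(point, "x"):
        x, y = float(point.x), float(point.y)
    else:
        x, y = (float(v) for v in np.asarray(point, dtype=np.float64).ravel()[:2])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError(f"latent point must be finite, got ({x}, {y})")
    return b.class_map[(int(x >= b.x_threshold), int(y >= b.y_threshold))]


def classify_points(
    points: np.ndarray, boundaries: ClassBoundaries | None = None
) -> np.ndarray:
    """Vectorized :func:`classify_point` over an (n, 2) array."""
    b = boundaries or ClassBoundaries()
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if not np.isfinite(pts).all():
        raise ValueError("latent points must be finite")
    xs = (pts[:, 0] >= b.x_threshold).astype(int)
    ys = (pts[:, 1] >= b.y_threshold).astype(int)
    lut = np.empty((2, 2), dtype=int)
    for (i, j), c in b.class_map.items():
        lut[i, j] = c
    return lut[xs, ys]


@dataclass
class LesionReport:
    """Per-lesion classification summary.

    ``class_percentages`` maps class id -> percentage of slices, rounded to
    one decimal for reporting; ``class_fractions`` keeps the raw values.
    """

    lesion_id: str
    per_slice_class: list[int]
    average_tissue_score: float
    class_percentages: dict[int, float]
    class_fractions: dict[int, float]

    @property
    def n_slices(self) -> int:
        return len(self.per_slice_class)

    def to_dict(self) -> dict:
        return {
            "lesion_id": self.lesion_id,
            "n_slices": self.n_slices,
            "per_slice_class": list(map(int, self.per_slice_class)),
            "average_tissue_score": self.average_tissue_score,
            "class_percentages": {str(k): v for k, v in self.class_percentages.items()},
        }

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def score_lesion(classes: Sequence[int], lesion_id: str = "") -> LesionReport:
    """Average tissue score and class percentages for one lesion.

    average score = (sum of per-slice tissue scores) / (number of slices),
    with the fixed score map {1: 0, 2: 1, 3: 3, 4: 5}.  Percentages are
    reported to one decimal; raw fractions are retained.
    """
    classes = [int(c) for c in classes]
    if not classes:
        raise ValueError("cannot score a lesion with no slices")
    for i, c in enumerate(classes):
        if c not in TISSUE_SCORES:
            raise ValueError(f"invalid tissue class {c} at slice index {i}")
    n = len(classes)
    counts = {k: classes.count(k) for k in (1, 2, 3, 4)}
    avg = sum(TISSUE_SCORES[c] for c in classes) / n
    fractions = {k: counts[k] / n for k in counts}
    percentages = {k: round(100.0 * fractions[k], 1) for k in counts}
    return LesionReport(
        lesion_id=lesion_id,
        per_slice_class=classes,
        average_tissue_score=avg,
        class_percentages=percentages,
        class_fractions=fractions,
    )


def calibrate_boundaries(
    points: np.ndarray,
    labels: Sequence[int],
    n_candidates: int = 33,
) -> tuple[ClassBoundaries, float]:
    """Fit rectangular boundaries to a labelled latent subset.

    Grid search over candidate thresholds (quantile grid per axis, midpoints
    between data quantiles) crossed with all 24 quadrant-to-class
    assignments, maximizing labelled agreement.  Returns the best boundaries
    and the achieved agreement fraction.

    This automates the by-inspection placement of the boundaries: each new
    training run has its own latent geometry, so thresholds must be placed
    relative to the realized embedding.
    """
    pts = np.asarray(points, dtype=np.float64)
    labels = np.asarray([int(c) for c in labels])
    if pts.ndim != 2 or pts.shape[1] != 2 or len(labels) != len(pts):
        raise ValueError("need (n, 2) points and n labels")
    present = set(labels.tolist())
    for c in (1, 2, 3, 4):
        if c not in present:
            raise ValueError(f"no labelled points for tissue class {c}")

    qs = np.linspace(0.02, 0.98, n_candidates)
    cand_x = np.unique(np.quantile(pts[:, 0], qs))
    cand_y = np.unique(np.quantile(pts[:, 1], qs))

    best_agree = -1.0
    best: ClassBoundaries | None = None
    onehot = np.stack([(labels == c) for c in (1, 2, 3, 4)]).astype(int)  # 4 x n
    perms = list(itertools.permutations((1, 2, 3, 4)))
    for tx in cand_x:
        xs = (pts[:, 0] >= tx).astype(int)
        for ty in cand_y:
            ys = (pts[:, 1] >= ty).astype(int)
            quad = 2 * xs + ys  # 0..3 for (0,0),(0,1),(1,0),(1,1)
            # confusion[q, c] = number of points in quadrant q with label c+1
            confusion = np.zeros((4, 4), dtype=int)
            for q in range(4):
                in_q = quad == q
                confusion[q] = onehot[:, in_q].sum(axis=1)
            for perm in perms:
                agree = sum(confusion[q, perm[q] - 1] for q in range(4))
                frac = agree / len(labels)
                if frac > best_agree:
                    best_agree = frac
                    cmap = {
                        (0, 0): perm[0],
                        (0, 1): perm[1],
                        (1, 0): perm[2],
                        (1, 1): perm[3],
                    }
                    best = ClassBoundaries(float(tx), float(ty), cmap)
    assert best is not None
    return best, float(best_agree)


def summarize_cohort(reports: Sequence[LesionReport]) -> pd.DataFrame:
    """Cohort-level table: per-class range of nonzero percentages.

    Returns a DataFrame indexed by tissue class (I-IV) with the minimum and
    maximum of the nonzero reported percentages across lesions plus the
    number of lesions expressing the class; ``df.attrs['total_slices']``
    holds the cohort slice count.
    """
    if not reports:
        raise ValueError("need at least one lesion report")
    roman = {1: "I", 2: "II", 3: "III", 4: "IV"}
    rows = []
    for c in (1, 2, 3, 4):
        vals = [
            r.class_percentages[c] for r in reports if r.class_percentages[c] > 0
        ]
        rows.append(
            {
                "tissue_class": roman[c],
                "min_pct": min(vals) if vals else np.nan,
                "max_pct": max(vals) if vals else np.nan,
                "n_lesions_present": len(vals),
            }
        )
    df = pd.DataFrame(rows).set_index("tissue_class")
    df.attrs["total_slices"] = int(sum(r.n_slices for r in reports))
    return df


def cohort_table(reports: Sequence[LesionReport]) -> pd.DataFrame:
    """Per-lesion table: class I-IV percentages, average score, slice count."""
    rows = []
    for r in reports:
        rows.append(
            {
                "sample": r.lesion_id,
                "class_I_pct": r.class_percentages[1],
                "class_II_pct": r.class_percentages[2],
                "class_III_pct": r.class_percentages[3],
                "class_IV_pct": r.class_percentages[4],
                "average_tissue_score": round(r.average_tissue_score, 3),
                "n_slices": r.n_slices,
            }
        )
    return pd.DataFrame(rows)
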