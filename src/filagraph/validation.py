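"""Scoring traced filaments against synthetic ground truth.

The harness runs the full pipeline on every image of a synthetic bank,
matches traced filaments one-to-one to ground-truth filaments by centerline
proximity, and reports the two validation statistics: the maximum per-image
relative error in filament count and the maximum per-image RMSE of matched
filament lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .synthetic import GroundTruthNetwork

__all__ = [
    "ValidationReport",
    "match_filaments",
    "count_relative_error",
    "length_rmse",
    "run_validation",
]

DEFAULT_MAX_MATCH_DIST_PX = 5.0


@dataclass
class ValidationReport:
    per_image: pd.DataFrame
    max_count_rel_error: float
    max_length_rmse_px: float
    config: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "max_count_rel_error": self.max_count_rel_error,
            "max_length_rmse_px": self.max_length_rmse_px,
            "n_images": int(len(self.per_image)),
            "per_image": self.per_image.to_dict(orient="records"),
            "config": self.config,
        }


def _centerline_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean closest-point distance between two polylines."""
    d = cdist(np.asarray(a, float), np.asarray(b, float))
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def match_filaments(
    pred_centerlines: list[np.ndarray],
    truth: GroundTruthNetwork | list[np.ndarray],
    max_match_dist_px: float = DEFAULT_MAX_MATCH_DIST_PX,
) -> list[tuple[int, int]]:
    """One-to-one assignment of predicted to true centerlines.

    The assignment minimises the total symmetric mean closest-point distance
    (Hungarian algorithm); pairs farther apart than ``max_match_dist_px`` are
    rejected afterwards, so each filament appears in at most one pair.
    """
    if max_match_dist_px <= 0:
        raise ValueError("max_match_dist_px must be positive")
    truth_lines = (
        [f.centerline for f in truth.filaments]
        if isinstance(truth, GroundTruthNetwork)
        else list(truth)
    )
    preds = [np.asarray(getattr(p, "pixels", p), dtype=float) for p in pred_centerlines]
    if not preds or not truth_lines:
        return []
    big = 1e6
    cost = np.empty((len(preds), len(truth_lines)))
    for i, p in enumerate(preds):
        for j, t in enumerate(truth_lines):
            d = _centerline_distance(p, t)
            cost[i, j] = d if d <= max_match_dist_px else big
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < big]


def count_relative_error(n_pred: int, n_true: int) -> float:
    """Relative filament-count error: |predicted - true| / true."""
    if n_true < 1:
        raise ValueError("n_true must be >= 1")
    return abs(n_pred - n_true) / n_true


def length_rmse(
    matches: list[tuple[int, int]],
    pred_lengths: np.ndarray,
    true_lengths: np.ndarray,
) -> float:
    """RMSE of matched filament lengths in pixels (NaN for zero matches)."""
    if not matches:
        return float("nan")
    pred_lengths = np.asarray(pred_lengths, dtype=float)
    true_lengths = np.asarray(true_lengths, dtype=float)
    errs = np.asarray([pred_lengths[i] - true_lengths[j] for i, j in matches])
    return float(np.sqrt(np.mean(errs**2)))


def run_validation(
    bank,
    config=None,
    max_match_dist_px: float = DEFAULT_MAX_MATCH_DIST_PX,
) -> ValidationReport:
    """Run the full pipeline on every image of a bank and score it.

    ``bank`` is a list of (IntensityImage, GroundTruthNetwork) pairs as
    produced by :func:`filagraph.synthetic.generate_validation_bank`.
    Unmatched filaments affect only the count error, not the length RMSE.
    """
    from .pipeline import PipelineConfig, trace_image

    if not bank:
        raise ValueError("validation bank must be nonempty")
    config = config or PipelineConfig()
    template_bank = config.build_template_bank()

    rows = []
    for idx, (image, truth) in enumerate(bank):
        result = trace_image(image, config=config, template_bank=template_bank)
        n_true = len(truth)
        n_pred = len(result.paths)
        matches = match_filaments(
            [p.pixels for p in result.paths], truth, max_match_dist_px
        )
        rmse = length_rmse(matches, result.lengths_px, truth.lengths_px)
        rows.append(
            {
                "image": idx,
                "n_true": n_true,
                "n_pred": n_pred,
                "count_rel_error": count_relative_error(n_pred, n_true)
                if n_true
                else float("nan"),
                "n_matched": len(matches),
                "length_rmse_px": rmse,
            }
        )
    per_image = pd.DataFrame(rows)
    return ValidationReport(
        per_image=per_image,
        max_count_rel_error=float(per_image["count_rel_error"].max()),
        max_length_rmse_px=float(per_image["length_rmse_px"].max()),
        config=config.to_dict(),
    )
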