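"""Combination-efficacy prediction under independent drug action and Bliss.

Independent drug action (IDA) assumes a combination's effect on a cell line
equals the effect of its single best constituent drug: on a viability-
oriented panel the per-line prediction is the minimum of the component
monotherapy viabilities (the maximum for effect-oriented metrics such as
viability reduction).  Bliss independence assumes the drugs kill
independently, so the per-line predicted survival is the product of the
component survival probabilities, each clamped to [0, 1] first; IDA uses
the raw (possibly <0 or >1) viabilities unclamped.

The population summary is the arithmetic mean of the per-line predictions
over the complete-case cell-line set — the lines with a usable estimate
for every component of the treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, OrientationError
from .panel import MonotherapyPanel, Treatment

Model = Literal["IDA", "Bliss"]

#: Conventional complete-case minima: 50 cell lines for pan-cancer
#: analyses, 3 for cancer-type/subtype-specific analyses.
MIN_LINES_PAN_CANCER = 50
MIN_LINES_SUBTYPE = 3


@dataclass
class ComboPrediction:
    """Per-line and population-mean predicted efficacy for one treatment."""

    treatment: Treatment
    model: Model
    per_line: pd.Series
    mean: float
    n_lines: int
    cell_line_set: tuple[str, ...]


def _component_positions(panel: MonotherapyPanel, treatment: Treatment) -> list[int]:
    return [panel.column_position(d, c) for d, c in treatment.components]


def complete_case_lines(
    panel: MonotherapyPanel,
    treatments: Treatment | Sequence[Treatment],
    min_lines: int = MIN_LINES_PAN_CANCER,
) -> pd.Index:
    """Cell lines with non-missing estimates for every component.

    Accepts one treatment or several (for comparisons that must share a
    cell-line set).  Raises :class:`InsufficientDataError` if fewer than
    ``min_lines`` lines survive.
    """
    if isinstance(treatments, Treatment):
        treatments = [treatments]
    positions = sorted({p for t in treatments for p in _component_positions(panel, t)})
    values = panel.means.iloc[:, positions]
    mask = values.notna().all(axis=1)
    lines = panel.means.index[mask]
    if len(lines) < min_lines:
        labels = ", ".join(t.label for t in treatments)
        raise InsufficientDataError(
            f"only {len(lines)} complete-case cell line(s) for [{labels}]; "
            f"{min_lines} required",
            n_available=len(lines), min_lines=min_lines,
        )
    return lines


def ida_per_line(values: np.ndarray, orientation: str = "viability") -> np.ndarray:
    """Per-line IDA prediction from an (n_lines, n_components) value matrix."""
    if orientation == "viability":
        return values.min(axis=1)
    return values.max(axis=1)


def bliss_per_line(values: np.ndarray) -> np.ndarray:
    """Per-line Bliss prediction: product of component survivals clamped to [0, 1]."""
    return np.clip(values, 0.0, 1.0).prod(axis=1)


def _predict(
    panel: MonotherapyPanel,
    treatment: Treatment,
    model: Model,
    min_lines: int,
    lines: pd.Index | None,
) -> ComboPrediction:
    if lines is None:
        lines = complete_case_lines(panel, treatment, min_lines)
    positions = _component_positions(panel, treatment)
    values = panel.means.loc[lines].to_numpy(float)[:, positions]
    if model == "IDA":
        per = ida_per_line(values, panel.orientation)
    else:
        if panel.orientation != "viability":
            raise OrientationError(
                "Bliss independence is defined on survival probabilities; the panel "
                f"orientation is {panel.orientation!r}, not 'viability'"
            )
        per = bliss_per_line(values)
    per_line = pd.Series(per, index=lines, name=treatment.label)
    return ComboPrediction(
        treatment=treatment, model=model, per_line=per_line,
        mean=float(per.mean()), n_lines=len(lines),
        cell_line_set=tuple(lines),
    )


def ida_combo(
    panel: MonotherapyPanel,
    treatment: Treatment,
    min_lines: int = MIN_LINES_PAN_CANCER,
    lines: pd.Index | None = None,
) -> ComboPrediction:
    """Predicted combination efficacy under independent drug action.

    Per line the prediction is the best (minimum viability / maximum
    effect) component monotherapy value, using raw unclamped viabilities;
    the population mean is taken over the complete-case line set (or the
    explicit ``lines`` when a shared set is enforced externally).
    """
    return _predict(panel, treatment, "IDA", min_lines, lines)


def bliss_combo(
    panel: MonotherapyPanel,
    treatment: Treatment,
    min_lines: int = MIN_LINES_PAN_CANCER,
    lines: pd.Index | None = None,
) -> ComboPrediction:
    """Predicted combination efficacy under Bliss independence.

    Component viabilities are clamped to [0, 1] (Bliss is only defined for
    probabilities) before the per-line product is taken.
    """
    return _predict(panel, treatment, "Bliss", min_lines, lines)


def compare_models(
    panel: MonotherapyPanel,
    treatment: Treatment,
    min_lines: int = MIN_LINES_PAN_CANCER,
) -> tuple[ComboPrediction, ComboPrediction, float]:
    """IDA and Bliss predictions on the identical cell-line set.

    Returns (ida_prediction, bliss_prediction, mean_difference) with
    ``mean_difference = ida.mean - bliss.mean``.
    """
    lines = complete_case_lines(panel, treatment, min_lines)
    ida = ida_combo(panel, treatment, lines=lines)
    bliss = bliss_combo(panel, treatment, lines=lines)
    return ida, bliss, ida.mean - bliss.mean


def predictions_to_frame(predictions: Sequence[ComboPrediction]) -> pd.DataFrame:
    """Summarize predictions as a tidy frame (one row per treatment x model)."""
    return pd.DataFrame(
        [
            {
                "treatment": p.treatment.label,
                "model": p.model,
                "n_lines": p.n_lines,
                "mean": p.mean,
            }
            for p in predictions
        ]
    )
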