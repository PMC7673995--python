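"""Clinical translation: hazards, hazard ratios, trial power, IDAcomboscores.

Mean predicted viability is treated as an estimate of clinical hazard on
the fraction scale — 100% viability is a hazard of 1 (all cancer cells
alive relative to untreated) and 0% viability a hazard of 0 — so the
hazard ratio of a test therapy against a control is simply the ratio of
their mean predicted viabilities.  That HR drives a Freedman-type log-rank
power approximation given a trial's event count, allocation ratio and
significance level.

For prospective ranking of combinations against their best constituent (or
backbone) therapy the IDAcomboscore is

    score = delta_via - delta_via * HR_C/Mbest = delta_via * (1 - HR_C/Mbest)

where delta_via is the best-reference mean viability minus the combination
mean and HR_C/Mbest their ratio.  It rewards combinations that both lower
mean viability and beat their own best monotherapy by a wide margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations as _pairs
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .combo import ComboPrediction, complete_case_lines, ida_combo, MIN_LINES_PAN_CANCER
from .dose_response import LogLogisticFit, ll4
from .errors import (
    ConsistencyError,
    InputError,
    InsufficientDataError,
    RangeError,
    UndefinedHazardRatioError,
)
from .io import ConcentrationMap
from .panel import MonotherapyPanel, Treatment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialDesign:
    """Log-rank power inputs: total events, allocation ratio, alpha.

    ``total_events`` is the number of PFS/TTP or OS events observed;
    ``allocation_ratio`` is experimental:control participants (k).
    """

    total_events: int
    allocation_ratio: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.total_events < 1:
            raise InputError(f"total_events must be >= 1, got {self.total_events}")
        if not (self.allocation_ratio > 0):
            raise InputError(f"allocation_ratio must be > 0, got {self.allocation_ratio}")
        if not (0 < self.alpha < 1):
            raise InputError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class HazardRatioEstimate:
    hr: float
    se: float | None = None
    ci95: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.hr > 0) and self.hr != 0:
            raise InputError(f"hazard ratio must be >= 0, got {self.hr}")
        if self.ci95 is not None and not (self.ci95[0] <= self.hr <= self.ci95[1]):
            raise InputError("hr must lie inside its 95% CI")


@dataclass
class PowerEstimate:
    """Estimated log-rank power with an optional bootstrap SE.

    ``se`` is bounded on report so power +/- se stays in [0, 1].
    """

    power: float
    se: float | None = None
    predicted_success: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.power <= 1.0):
            raise InputError(f"power must be in [0, 1], got {self.power}")

    def bounded_interval(self) -> tuple[float, float] | None:
        if self.se is None:
            return None
        return (max(self.power - self.se, 0.0), min(self.power + self.se, 1.0))


@dataclass
class IDAcomboscoreResult:
    """Prospective ranking score for one combination vs its best reference."""

    treatment: Treatment
    best_reference: str
    delta_via: float
    hr_c_mbest: float
    score: float
    n_lines: int
    se: float | None = None
    null_p: float | None = None
    fdr: float | None = None


# ---------------------------------------------------------------------------
# Viability -> hazard -> power
# ---------------------------------------------------------------------------

def viability_to_hazard(mean_viability: float) -> float:
    """Map mean viability to hazard: identity on the fraction scale, floored at 0."""
    v = float(mean_viability)
    if not np.isfinite(v):
        raise InputError(f"mean viability must be finite, got {v}")
    if v < 0:
        logger.info("negative mean viability %g floored to hazard 0", v)
        return 0.0
    return v


def hazard_ratio(test: ComboPrediction, control: ComboPrediction) -> HazardRatioEstimate:
    """HR = hazard(test mean viability) / hazard(control mean viability).

    Both predictions must have been computed on the same cell-line set.
    """
    if test.cell_line_set != control.cell_line_set:
        raise ConsistencyError(
            "test and control predictions were computed on different cell-line sets "
            f"({test.n_lines} vs {control.n_lines} lines); recompute on a shared "
            "complete-case set"
        )
    h_control = viability_to_hazard(control.mean)
    if h_control == 0:
        raise UndefinedHazardRatioError(
            f"control treatment {control.treatment.label!r} has mean hazard 0; HR undefined"
        )
    hr = viability_to_hazard(test.mean) / h_control
    if hr > 1:
        logger.info("hazard ratio %g > 1 (test therapy predicted worse than control)", hr)
    return HazardRatioEstimate(hr=hr)


def logrank_power(hr: float, design: TrialDesign) -> PowerEstimate:
    """Freedman-type log-rank power approximation.

    power = Phi( sqrt(k*m) * |hr - 1| / (k*hr + 1) - z_{1 - alpha/2} )

    with m total events, k the experimental:control allocation ratio and
    Phi the standard normal CDF.  At hr = 1 this reduces to alpha/2.
    """
    hr = float(hr)
    if not (np.isfinite(hr) and hr > 0):
        raise InputError(f"hazard ratio must be finite and > 0, got {hr}")
    m, k, alpha = design.total_events, design.allocation_ratio, design.alpha
    z_alpha = norm.ppf(1.0 - alpha / 2.0)
    power = float(norm.cdf(np.sqrt(k * m) * abs(hr - 1.0) / (k * hr + 1.0) - z_alpha))
    return PowerEstimate(power=power)


def classify_trial(power_estimate: PowerEstimate, threshold: float = 0.80) -> bool:
    """Predicted-success flag at the configured power threshold (>= counts as success)."""
    if not (0 < threshold < 1):
        raise InputError(f"threshold must be in (0, 1), got {threshold}")
    flag = power_estimate.power >= threshold
    power_estimate.predicted_success = flag
    return flag


# ---------------------------------------------------------------------------
# IDAcomboscore (prospective ranking)
# ---------------------------------------------------------------------------

def idacomboscore(
    panel: MonotherapyPanel,
    combination: Treatment,
    references: Sequence[Treatment] | None = None,
    min_lines: int = MIN_LINES_PAN_CANCER,
) -> IDAcomboscoreResult:
    """Score a combination against the best of its reference therapies.

    ``references`` default to the single-drug components of the
    combination; a multi-drug backbone may be passed as a single reference
    Treatment, in which case it is treated as one monotherapy.  All
    treatments are evaluated under IDA on one shared complete-case line
    set.  best_reference is the reference with the lowest mean viability;
    delta_via = mean(best_reference) - mean(combination);
    score = delta_via * (1 - mean(combination)/mean(best_reference)).
    """
    if references is None:
        references = [Treatment(((d, c),)) for d, c in combination.components]
    if not references:
        raise InputError("at least one reference treatment is required")
    lines = complete_case_lines(panel, [combination, *references], min_lines)
    combo_pred = ida_combo(panel, combination, lines=lines)
    ref_preds = [ida_combo(panel, ref, lines=lines) for ref in references]
    best = min(ref_preds, key=lambda p: p.mean)
    best_hazard = viability_to_hazard(best.mean)
    if best_hazard == 0:
        raise UndefinedHazardRatioError(
            f"best reference {best.treatment.label!r} has mean hazard 0; "
            "HR_C/Mbest undefined"
        )
    hr = viability_to_hazard(combo_pred.mean) / best_hazard
    delta_via = best.mean - combo_pred.mean
    score = delta_via - delta_via * hr
    return IDAcomboscoreResult(
        treatment=combination, best_reference=best.treatment.label,
        delta_via=delta_via, hr_c_mbest=hr, score=score, n_lines=len(lines),
    )


def comboscore_matrix(
    panel: MonotherapyPanel,
    drugs: Sequence[str],
    conc_map: ConcentrationMap,
    min_lines: int = MIN_LINES_PAN_CANCER,
    display_cutoff: float | None = None,
    extrapolation_limit: float = 2.0,
) -> pd.DataFrame:
    """IDAcomboscores for all unordered pairs of drugs at their Csustained doses.

    Each drug is evaluated at its stored clinical concentration, capped at
    ``extrapolation_limit`` x its maximum tested concentration when the
    clinical level exceeds the tested range.  Pairs with too few
    complete-case lines are explicit missing (NaN) entries.  With
    ``display_cutoff`` set, drugs with no score >= cutoff are dropped
    (the readability filter for large heatmaps; 0.004 in pan-cancer use).
    """
    doses: dict[str, float] = {}
    for drug in drugs:
        if drug not in conc_map.csustained:
            raise InputError(f"no clinical concentration for drug {drug!r}")
        cap = extrapolation_limit * conc_map.max_tested[drug]
        dose = conc_map.csustained[drug]
        if dose > cap:
            logger.info("capping %s at %g uM (csustained %g beyond tested range)", drug, cap, dose)
            dose = cap
        doses[drug] = dose
    names = sorted(doses)
    mat = pd.DataFrame(np.nan, index=pd.Index(names, name="drug"), columns=pd.Index(names, name="drug"))
    for a, b in _pairs(names, 2):
        combo = Treatment(((a, doses[a]), (b, doses[b])))
        try:
            res = idacomboscore(panel, combo, min_lines=min_lines)
        except InsufficientDataError as err:
            logger.info("pair (%s, %s) skipped: %s", a, b, err)
            continue
        mat.loc[a, b] = res.score
        mat.loc[b, a] = res.score
    if display_cutoff is not None:
        keep = [d for d in names if (mat.loc[d] >= display_cutoff).any()]
        mat = mat.loc[keep, keep]
    return mat


def dose_grid_scan(
    fits: Mapping[tuple[str, str], LogLogisticFit],
    drug_pair: tuple[str, str],
    grids: tuple[Sequence[float], Sequence[float]],
    extrapolation_limit: float = 2.0,
) -> pd.DataFrame:
    """Mean IDA viability over a 2-drug concentration grid (0 .. Csustained).

    Returns a long frame (conc_a, conc_b, mean_viability, n_lines,
    best_monotherapy_plane) over complete-case lines (lines with fits for
    both drugs).  Concentration 0 maps to the upper asymptote of each
    curve.  The best-monotherapy plane is the lower of the two single-drug
    means at their maximal grid doses.
    """
    drug_a, drug_b = drug_pair
    grid_a = np.asarray(grids[0], dtype=float)
    grid_b = np.asarray(grids[1], dtype=float)
    if grid_a.size == 0 or grid_b.size == 0:
        raise InputError("both concentration grids must be non-empty")
    lines = sorted(
        {line for line, drug in fits if drug == drug_a}
        & {line for line, drug in fits if drug == drug_b}
    )
    if not lines:
        raise InsufficientDataError(
            f"no cell line has fits for both {drug_a} and {drug_b}", 0, 1
        )
    for drug, grid in ((drug_a, grid_a), (drug_b, grid_b)):
        for line in lines:
            cap = extrapolation_limit * fits[(line, drug)].max_tested
            over = grid[grid > cap]
            if over.size:
                raise RangeError(
                    f"grid concentration {over[0]:g} uM for {drug} exceeds "
                    f"{extrapolation_limit:g} x max tested ({cap:g} uM) in line {line}"
                )
    # (n_lines, n_grid) response matrices per drug
    va = np.stack([fits[(line, drug_a)](grid_a) for line in lines])
    vb = np.stack([fits[(line, drug_b)](grid_b) for line in lines])
    mono_a = va[:, np.argmax(grid_a)].mean()
    mono_b = vb[:, np.argmax(grid_b)].mean()
    best_plane = min(mono_a, mono_b)
    rows = []
    for i, ca in enumerate(grid_a):
        for j, cb in enumerate(grid_b):
            mean_v = np.minimum(va[:, i], vb[:, j]).mean()
            rows.append(
                {
                    "conc_a_uM": ca, "conc_b_uM": cb,
                    "mean_viability": float(mean_v), "n_lines": len(lines),
                    "best_monotherapy_plane": float(best_plane),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["drugs"] = (drug_a, drug_b)
    return out


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    trial_id: str
    endpoint: str
    design: TrialDesign
    control: Treatment
    test: Treatment


def read_trial_table(path) -> list[TrialRecord]:
    """Read a trial-design CSV.

    Columns: trial_id, endpoint (PFS/TTP/OS), events, allocation_ratio,
    alpha, control, test — the last two in ``drugA@concA+drugB@concB``
    spec syntax (concentrations in uM).  A missing/blank allocation ratio
    defaults to 1 (equal arms) and a missing alpha to 0.05.
    """
    df = pd.read_csv(path)
    required = {"trial_id", "endpoint", "events", "control", "test"}
    missing = required - set(df.columns)
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"trial table is missing column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        k = row.get("allocation_ratio", 1.0)
        alpha = row.get("alpha", 0.05)
        design = TrialDesign(
            total_events=int(row["events"]),
            allocation_ratio=1.0 if pd.isna(k) else float(k),
            alpha=0.05 if pd.isna(alpha) else float(alpha),
        )
        records.append(
            TrialRecord(
                trial_id=str(row["trial_id"]), endpoint=str(row["endpoint"]),
                design=design,
                control=Treatment.parse(str(row["control"])),
                test=Treatment.parse(str(row["test"])),
            )
        )
    return records
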