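"""Semi-parametric bootstrap for combination-efficacy statistics.

The scheme combines a parametric perturbation of the measured viabilities
with a nonparametric resampling of cell lines.  Per simulation:

1. every panel cell's viability is redrawn as v* = v_hat + z * se with a
   standard-normal z — one z per (cell line, drug, concentration) cell, so
   two therapies sharing a compound at the same concentration see the SAME
   draw and move together (the shared-compound coupling);
2. per-line therapy efficacies are computed from the simulated viabilities
   under the relevant null-interaction model;
3. cell lines are resampled with replacement;
4. mean therapy efficacies are taken over the resampled lines;
5. the statistic of interest (HR, power, IDAcomboscore) is evaluated.

The standard deviation of the simulated statistics estimates the standard
error; confidence intervals are normal-approximation by default with a
percentile option.  The conventional simulation counts are 10,000 for
trial control/experimental comparisons and 1,000 per combination in
prospective scans.  Only random measurement error and cell-line sampling
are modeled — systematic screen errors are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .clinical import TrialDesign, logrank_power, viability_to_hazard
from .combo import complete_case_lines, ida_combo, MIN_LINES_PAN_CANCER
from .errors import BootstrapFailureError, InputError, UndefinedHazardRatioError
from .panel import MonotherapyPanel, Treatment

logger = logging.getLogger(__name__)

#: Conventional simulation counts.
N_SIMS_TRIAL = 10_000
N_SIMS_PROSPECTIVE = 1_000


@dataclass(frozen=True)
class BootstrapConfig:
    n_sims: int = N_SIMS_TRIAL
    seed: int = 0
    ci_level: float = 0.95
    couple_shared_drugs: bool = True
    ci_method: str = "normal"  # or "percentile"

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise InputError(f"n_sims must be >= 1, got {self.n_sims}")
        if not (0 < self.ci_level < 1):
            raise InputError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.ci_method not in ("normal", "percentile"):
            raise InputError(f"ci_method must be 'normal' or 'percentile', got {self.ci_method!r}")


@dataclass
class BootstrapResult:
    point: float
    se: float
    ci: tuple[float, float]
    null_p: float
    n_sims: int
    seed: int
    n_failed: int = 0
    simulated: np.ndarray | None = field(default=None, repr=False)


def _sim_rng(seed: int, sim_index: int) -> np.random.Generator:
    # counter-derived substream: one generator per simulation, so results
    # cannot depend on evaluation order or parallel chunking
    return np.random.default_rng([int(seed), int(sim_index)])


def draw_coupled_panel(
    panel: MonotherapyPanel, rng: np.random.Generator, couple_shared_drugs: bool = True
) -> MonotherapyPanel:
    """One simulated panel: v* = v_hat + z*se, one z per panel cell.

    Because a (drug, concentration) component is one column, every
    treatment referencing it sees the same draw — shared compounds are
    coupled by construction.  ``couple_shared_drugs=False`` is handled at
    the statistic level (independent panels per therapy), not here.
    """
    z = rng.standard_normal(panel.means.shape)
    means = panel.means + z * panel.ses
    return panel.with_means(means)


def resample_lines(lines: Sequence[str], rng: np.random.Generator) -> np.ndarray:
    """A size-n multiset of cell lines drawn uniformly with replacement."""
    lines = np.asarray(lines)
    if lines.size == 0:
        raise InputError("cannot resample from an empty cell-line set")
    return lines[rng.integers(0, lines.size, lines.size)]


def bootstrap_statistic(
    stat: Callable[[np.ndarray, np.ndarray], float],
    panel: MonotherapyPanel,
    config: BootstrapConfig,
    n_panels: int = 1,
) -> BootstrapResult:
    """Bootstrap any statistic of a panel and a resampled line multiset.

    ``stat(values, line_idx)`` receives the simulated viability matrix
    (same row/column order as ``panel.means``; a tuple of ``n_panels``
    matrices when ``n_panels > 1``, for uncoupled comparisons) and the
    integer row indices of the resampled cell-line multiset, and returns a
    scalar.  The point estimate is the statistic on the unperturbed panel
    with every line once.  Fully reproducible given ``config.seed``; a
    statistic failing in more than half the simulations raises
    :class:`BootstrapFailureError`.
    """
    means = panel.means.to_numpy(float)
    ses = panel.ses.to_numpy(float)
    n = means.shape[0]
    identity = np.arange(n)
    try:
        point = float(stat(means if n_panels == 1 else tuple([means] * n_panels), identity))
    except Exception as err:  # noqa: BLE001
        raise BootstrapFailureError(
            f"statistic failed on the unperturbed panel: {err}",
            n_failed=config.n_sims, n_sims=config.n_sims,
        ) from err

    sims = np.empty(config.n_sims)
    n_failed = 0
    errors: list[str] = []
    for i in range(config.n_sims):
        rng = _sim_rng(config.seed, i)
        draws = tuple(
            means + rng.standard_normal(means.shape) * ses for _ in range(n_panels)
        )
        line_idx = rng.integers(0, n, n)
        try:
            sims[i] = stat(draws[0] if n_panels == 1 else draws, line_idx)
        except Exception as err:  # noqa: BLE001 - survival of individual sims is the contract
            sims[i] = np.nan
            n_failed += 1
            if len(errors) < 5:
                errors.append(str(err))
    if n_failed > config.n_sims / 2:
        raise BootstrapFailureError(
            f"statistic failed in {n_failed}/{config.n_sims} simulations; "
            f"first errors: {errors}",
            n_failed=n_failed, n_sims=config.n_sims,
        )
    ok = sims[~np.isnan(sims)]
    # exactly-invariant statistics get an exact zero, not summation dust
    if ok.size and np.ptp(ok) == 0.0:
        se = 0.0
    else:
        se = float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0
    z = float(-_norm_ppf((1.0 - config.ci_level) / 2.0))
    if config.ci_method == "normal":
        ci = (point - z * se, point + z * se)
    else:
        lo, hi = np.quantile(ok, [(1 - config.ci_level) / 2, (1 + config.ci_level) / 2])
        ci = (float(lo), float(hi))
    return BootstrapResult(
        point=point, se=se, ci=ci, null_p=empirical_null_probability(ok),
        n_sims=config.n_sims, seed=config.seed, n_failed=n_failed, simulated=ok,
    )


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


# ---------------------------------------------------------------------------
# Prebuilt statistics
# ---------------------------------------------------------------------------

def _mean_stat(panel: MonotherapyPanel, treatment: Treatment, model: str):
    positions = [panel.column_position(d, c) for d, c in treatment.components]
    orientation = panel.orientation

    def mean_efficacy(values: np.ndarray, line_idx: np.ndarray) -> float:
        sub = values[line_idx][:, positions]
        if model == "IDA":
            per = sub.min(axis=1) if orientation == "viability" else sub.max(axis=1)
        else:
            per = np.clip(sub, 0.0, 1.0).prod(axis=1)
        return float(per.mean())

    return mean_efficacy


def bootstrap_combo_mean(
    panel: MonotherapyPanel,
    treatment: Treatment,
    config: BootstrapConfig,
    model: str = "IDA",
    min_lines: int = MIN_LINES_PAN_CANCER,
) -> BootstrapResult:
    """Bootstrap SE/CI for a treatment's mean predicted efficacy."""
    lines = complete_case_lines(panel, treatment, min_lines)
    sub = panel.subset_lines(lines)
    return bootstrap_statistic(_mean_stat(sub, treatment, model), sub, config)


def bootstrap_hazard_ratio(
    panel: MonotherapyPanel,
    test: Treatment,
    control: Treatment,
    config: BootstrapConfig,
    model: str = "IDA",
    min_lines: int = MIN_LINES_PAN_CANCER,
    design: TrialDesign | None = None,
) -> dict[str, BootstrapResult]:
    """Bootstrap the test-vs-control HR (and trial power, given a design).

    Both therapies are evaluated on one shared complete-case line set.
    With coupling on (default), shared compounds at matching concentrations
    see identical viability draws in every simulation; with coupling off,
    the two therapies draw independent panels.
    """
    lines = complete_case_lines(panel, [test, control], min_lines)
    sub = panel.subset_lines(lines)
    stat_test = _mean_stat(sub, test, model)
    stat_control = _mean_stat(sub, control, model)

    if config.couple_shared_drugs:
        def hr_stat(values: np.ndarray, line_idx: np.ndarray) -> float:
            return _safe_hr(stat_test(values, line_idx), stat_control(values, line_idx))

        n_panels = 1
    else:
        def hr_stat(values: tuple[np.ndarray, np.ndarray], line_idx: np.ndarray) -> float:
            return _safe_hr(stat_test(values[0], line_idx), stat_control(values[1], line_idx))

        n_panels = 2

    out = {"hr": bootstrap_statistic(hr_stat, sub, config, n_panels=n_panels)}
    if design is not None:
        def power_stat(values, line_idx):
            return logrank_power(hr_stat(values, line_idx), design).power

        out["power"] = bootstrap_statistic(power_stat, sub, config, n_panels=n_panels)
    return out


def _safe_hr(mean_test: float, mean_control: float) -> float:
    h_control = viability_to_hazard(mean_control)
    if h_control == 0:
        raise UndefinedHazardRatioError("control mean hazard 0 in simulation")
    return viability_to_hazard(mean_test) / h_control


def bootstrap_comboscore(
    panel: MonotherapyPanel,
    combination: Treatment,
    config: BootstrapConfig,
    references: Sequence[Treatment] | None = None,
    min_lines: int = MIN_LINES_PAN_CANCER,
) -> BootstrapResult:
    """Bootstrap an IDAcomboscore; null_p is the fraction of simulated scores <= 0."""
    if references is None:
        references = [Treatment(((d, c),)) for d, c in combination.components]
    lines = complete_case_lines(panel, [combination, *references], min_lines)
    sub = panel.subset_lines(lines)
    combo_stat = _mean_stat(sub, combination, "IDA")
    ref_stats = [_mean_stat(sub, ref, "IDA") for ref in references]

    def score_stat(values: np.ndarray, line_idx: np.ndarray) -> float:
        mean_combo = combo_stat(values, line_idx)
        best = min(s(values, line_idx) for s in ref_stats)
        best_hazard = viability_to_hazard(best)
        if best_hazard == 0:
            raise UndefinedHazardRatioError("best reference mean hazard 0 in simulation")
        hr = viability_to_hazard(mean_combo) / best_hazard
        delta = best - mean_combo
        return delta - delta * hr

    return bootstrap_statistic(score_stat, sub, config)


# ---------------------------------------------------------------------------
# Null probabilities and FDR
# ---------------------------------------------------------------------------

def empirical_null_probability(simulated_scores: Sequence[float]) -> float:
    """Fraction of simulated scores <= 0 (the null probability that score <= 0)."""
    scores = np.asarray(simulated_scores, dtype=float)
    if scores.size == 0:
        raise InputError("empty list of simulated scores")
    return float((scores <= 0).sum() / scores.size)


def format_null_probability(raw: float, n_sims: int) -> str:
    """Human-readable null probability; a raw 0 is reported as '< 1/n_sims'."""
    if raw == 0.0:
        return f"<{1.0 / n_sims:g}"
    return f"{raw:g}"


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR-adjusted values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Cell-line-count stability
# ---------------------------------------------------------------------------

def subsample_stability(
    panel: MonotherapyPanel,
    treatment: Treatment,
    sizes: Sequence[int],
    reps: int = 100,
    seed: int = 0,
    model: str = "IDA",
) -> pd.DataFrame:
    """Dispersion of the mean prediction under cell-line subsampling.

    For each size, draws ``reps`` subsets without replacement, recomputes
    the mean predicted efficacy, and reports the standard deviation across
    repetitions — the stability diagnostic behind minimum-line
    requirements (prediction dispersion grows quickly below ~50 lines).
    """
    lines = complete_case_lines(panel, treatment, min_lines=1)
    sub = panel.subset_lines(lines)
    stat = _mean_stat(sub, treatment, model)
    values = sub.means.to_numpy(float)
    n = len(lines)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > n:
            raise InputError(f"subset size {size} exceeds available lines ({n})")
        means = np.array(
            [
                stat(values, np.sort(rng.choice(n, size=size, replace=False)))
                for _ in range(reps)
            ]
        )
        if reps <= 1 or np.ptp(means) == 0.0:
            dispersion = 0.0
        else:
            dispersion = float(np.std(means, ddof=1))
        rows.append(
            {
                "size": int(size), "reps": int(reps),
                "mean_of_means": float(means.mean()),
                "dispersion": dispersion,
            }
        )
    return pd.DataFrame(rows)
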