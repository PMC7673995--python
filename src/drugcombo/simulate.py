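"""Synthetic monotherapy screens and combination measurements with known truth.

Emulates the shape of large pharmacogenomic viability screens: per
(cell line, drug) sigmoid dose-response with replicate-level Gaussian
noise, optional heteroskedasticity, multi-site replicate structure, and
combination measurements generated under a named null-interaction model
with an optional interaction offset (negative = synergy, positive =
antagonism).  Every generator is reproducible from its seed and returns
the ground truth alongside the data, so parameter-recovery and
self-consistency tests need no external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import ll4
from .errors import InputError
from .panel import MonotherapyPanel, Treatment, ViabilityEstimate

#: Default true-parameter distributions: upper asymptote anchored at the
#: untreated level, partial-kill floors, inflection spread over ~1.5
#: decades around 1 uM, slopes from shallow to steep.
DEFAULT_MU_LOG_E = 0.0
DEFAULT_SIGMA_LOG_E = 1.0


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Study conditions for a synthetic monotherapy screen.

    Defaults mirror a typical large-screen design: 8 log-spaced doses
    covering ~3 decades, 3 replicates, homoskedastic viability noise of
    0.05 fractional units.
    """

    n_lines: int = 30
    drugs: tuple[str, ...] = ("drugA", "drugB")
    n_doses: int = 8
    n_replicates: int = 3
    dose_min: float = 0.01
    dose_max: float = 10.0
    noise_sd: float = 0.05
    heteroskedastic: bool = False
    mu_log_e: float = DEFAULT_MU_LOG_E
    sigma_log_e: float = DEFAULT_SIGMA_LOG_E
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise InputError(f"n_lines must be >= 1, got {self.n_lines}")
        if self.n_doses < 2:
            raise InputError(f"n_doses must be >= 2, got {self.n_doses}")
        if self.noise_sd < 0:
            raise InputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0 < self.dose_min < self.dose_max):
            raise InputError("need 0 < dose_min < dose_max")

    @property
    def doses(self) -> np.ndarray:
        return np.geomspace(self.dose_min, self.dose_max, self.n_doses)


@dataclass(frozen=True)
class SyntheticComboConfig:
    """How synthetic combination measurements are generated.

    ``interaction_offset`` shifts the measured value away from the named
    null model: negative values inject synergy (combinations kill more
    than the null predicts), positive values antagonism.
    """

    truth_model: str = "IDA"
    interaction_offset: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.truth_model not in ("IDA", "Bliss"):
            raise InputError(f"truth_model must be 'IDA' or 'Bliss', got {self.truth_model!r}")
        if self.noise_sd < 0:
            raise InputError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _line_names(n: int) -> list[str]:
    return [f"CL{i:03d}" for i in range(n)]


def generate_screen(config: SyntheticScreenConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a monotherapy screen and its ground-truth parameter table.

    For each (cell line, drug): true parameters are drawn as d = 1.0,
    c ~ Uniform(0, 0.6), ln e ~ Normal(mu_log_e, sigma_log_e),
    b ~ Uniform(0.5, 3); the curve is evaluated at the log-spaced dose
    design and Gaussian noise of sd ``noise_sd`` (scaled by the true
    viability in heteroskedastic mode) is added per replicate.

    Returns (observations, truth) — observations in the canonical tidy
    dialect, truth with one row per (cell line, drug) and columns
    b, c, d, e.
    """
    rng = np.random.default_rng(config.seed)
    doses = config.doses
    lines = _line_names(config.n_lines)
    obs_rows = []
    truth_rows = []
    for line in lines:
        for drug in config.drugs:
            b = rng.uniform(0.5, 3.0)
            c = rng.uniform(0.0, 0.6)
            d = 1.0
            e = float(np.exp(rng.normal(config.mu_log_e, config.sigma_log_e)))
            truth_rows.append({"cell_line": line, "drug": drug, "b": b, "c": c, "d": d, "e": e})
            clean = ll4(doses, b, c, d, e)
            for rep in range(config.n_replicates):
                sd = config.noise_sd * (np.abs(clean) if config.heteroskedastic else 1.0)
                noisy = clean + sd * rng.standard_normal(doses.size)
                for dose, v in zip(doses, noisy):
                    obs_rows.append(
                        {
                            "cell_line": line, "drug": drug,
                            "concentration_uM": float(dose), "viability": float(v),
                            "replicate": f"r{rep}", "site": "site0",
                        }
                    )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


def truth_panel(
    truth: pd.DataFrame, doses: Sequence[tuple[str, float]], se: float = 0.0
) -> MonotherapyPanel:
    """Noise-free monotherapy panel evaluated from a ground-truth table.

    ``se`` sets every cell's standard error (0 for exact-truth panels;
    a positive value emulates measurement uncertainty for bootstrap and
    coverage experiments).
    """
    estimates = {}
    for _, row in truth.iterrows():
        for drug, conc in doses:
            if drug != row["drug"]:
                continue
            v = float(ll4(conc, row["b"], row["c"], row["d"], row["e"]))
            estimates[(row["cell_line"], drug, float(conc))] = ViabilityEstimate(
                mean=v, se=se, source="fitted"
            )
    return MonotherapyPanel.from_estimates(
        estimates,
        cell_lines=sorted(truth["cell_line"].unique()),
        doses=[(d, float(c)) for d, c in doses],
    )


def generate_combo_measurements(
    truth_viabilities: pd.DataFrame,
    treatment: Treatment,
    config: SyntheticComboConfig,
) -> pd.DataFrame:
    """Simulated per-line measured viability for one drug combination.

    ``truth_viabilities`` is a frame with columns cell_line, drug,
    concentration_uM, viability holding the true monotherapy viabilities
    of every component at its treatment dose.  The per-line measurement is
    the null-model value (min for IDA; clamped product for Bliss) plus the
    interaction offset plus Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    component_cols = []
    lines: pd.Index | None = None
    for drug, conc in treatment.components:
        sub = truth_viabilities[
            (truth_viabilities["drug"] == drug)
            & (truth_viabilities["concentration_uM"] == float(conc))
        ].set_index("cell_line")["viability"]
        if sub.empty:
            raise InputError(f"truth table lacks component {drug}@{conc:g}")
        component_cols.append(sub)
        lines = sub.index if lines is None else lines.intersection(sub.index)
    mat = np.column_stack([col.loc[lines].to_numpy(float) for col in component_cols])
    if config.truth_model == "IDA":
        null_value = mat.min(axis=1)
    else:
        null_value = np.clip(mat, 0.0, 1.0).prod(axis=1)
    measured = null_value + config.interaction_offset
    if config.noise_sd > 0:
        measured = measured + config.noise_sd * rng.standard_normal(measured.size)
    return pd.DataFrame(
        {
            "cell_line": list(lines),
            "treatment": treatment.label,
            "viability": measured,
            "null_value": null_value,
        }
    )
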