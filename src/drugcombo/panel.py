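"""Monotherapy viability panels and treatment specifications.

The :class:`MonotherapyPanel` is the substrate of every combination
prediction: a cell-line x (drug @ concentration) matrix of viability point
estimates with matched standard errors.  Viability is a fraction relative
to an untreated control (1.0 = untreated level, 0.0 = complete kill); the
panel's ``orientation`` records whether lower values mean more effective
treatment (``"viability"``, the default) or higher values do
(``"effect"``, for viability-reduction-type metrics).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ComponentLookupError, InputError

Orientation = Literal["viability", "effect"]

#: Columns of the canonical panel CSV serialization.
_COLUMN_SEP = "@"


@dataclass(frozen=True)
class ViabilityEstimate:
    """A viability point estimate with its standard error.

    Parameters
    ----------
    mean : float
        Viability fraction (1.0 = untreated level).
    se : float
        Standard error of the mean viability, >= 0.
    source : str
        ``"fitted"`` if predicted from a dose-response curve,
        ``"measured"`` if taken directly from screen observations.
    extrapolated : bool
        True when the estimate lies beyond the maximum tested concentration.
    """

    mean: float
    se: float
    source: str = "fitted"
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise InputError(f"viability mean must be finite, got {self.mean}")
        if not (np.isfinite(self.se) and self.se >= 0):
            raise InputError(f"standard error must be finite and >= 0, got {self.se}")


@dataclass(frozen=True)
class Treatment:
    """One therapy: a non-empty set of (drug, concentration in uM) components.

    A multi-drug backbone (e.g. cisplatin + gemcitabine used as the control
    arm of a trial) is simply a Treatment with several components; the
    combination engine treats it as a single therapy.
    """

    components: tuple[tuple[str, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise InputError("a treatment needs at least one (drug, concentration) component")
        comps = tuple((str(d), float(c)) for d, c in self.components)
        # duplicates collapse (min(x, x) = x), keeping first-seen order
        comps = tuple(dict.fromkeys(comps))
        object.__setattr__(self, "components", comps)
        if not self.label:
            object.__setattr__(self, "label", format_treatment(comps))

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.components)

    @classmethod
    def parse(cls, spec: str) -> "Treatment":
        """Parse a ``"drugA@concA+drugB@concB"`` spec (concentrations in uM)."""
        components = []
        for part in spec.split("+"):
            part = part.strip()
            m = re.fullmatch(r"(?P<drug>[^@]+)@(?P<conc>[0-9.eE+-]+)", part)
            if m is None:
                raise InputError(
                    f"cannot parse treatment component {part!r}; expected 'drug@conc_uM'"
                )
            components.append((m.group("drug").strip(), float(m.group("conc"))))
        return cls(tuple(components), label=spec)


def format_treatment(components: Iterable[tuple[str, float]]) -> str:
    return "+".join(f"{d}{_COLUMN_SEP}{c:g}" for d, c in components)


class MonotherapyPanel:
    """Cell-line x (drug @ concentration) matrix of viability estimates.

    Parameters
    ----------
    means, ses : pandas.DataFrame
        Aligned frames indexed by cell line with a two-level column index
        ``(drug, concentration_uM)``.  ``NaN`` in ``means`` marks an
        explicitly missing cell (no usable estimate for that line/drug).
    orientation : {"viability", "effect"}
        Whether lower (viability) or higher (effect) values indicate a more
        effective treatment.  One orientation applies to the whole panel.
    sources : pandas.DataFrame, optional
        Per-cell provenance ("fitted" / "measured"); informational only.
    """

    def __init__(
        self,
        means: pd.DataFrame,
        ses: pd.DataFrame,
        orientation: Orientation = "viability",
        sources: pd.DataFrame | None = None,
    ):
        if orientation not in ("viability", "effect"):
            raise InputError(f"unknown orientation {orientation!r}")
        if means.shape != ses.shape:
            raise InputError("means and ses must have identical shape")
        if not means.index.equals(ses.index) or not means.columns.equals(ses.columns):
            raise InputError("means and ses must share index and columns")
        if means.columns.nlevels != 2:
            raise InputError("panel columns must be a (drug, concentration) MultiIndex")
        se_vals = ses.to_numpy(float)
        if np.nanmin(se_vals, initial=0.0) < 0:
            raise InputError("standard errors must be >= 0")
        self.means = means.astype(float)
        self.ses = ses.astype(float)
        self.orientation: Orientation = orientation
        self.sources = sources

    # -- introspection -------------------------------------------------
    @property
    def cell_lines(self) -> pd.Index:
        return self.means.index

    @property
    def columns(self) -> pd.MultiIndex:
        return self.means.columns

    @property
    def n_lines(self) -> int:
        return len(self.means.index)

    def has_column(self, drug: str, concentration: float) -> bool:
        return (drug, float(concentration)) in self.means.columns

    def column_position(self, drug: str, concentration: float) -> int:
        """Integer position of a (drug, concentration) column, for array kernels."""
        key = (drug, float(concentration))
        try:
            return self.means.columns.get_loc(key)
        except KeyError:
            raise ComponentLookupError(
                f"treatment component {drug}@{concentration:g} uM is not in the panel; "
                f"available drugs: {sorted(set(self.means.columns.get_level_values(0)))}"
            ) from None

    def column(self, drug: str, concentration: float) -> pd.Series:
        return self.means.iloc[:, self.column_position(drug, concentration)]

    def column_se(self, drug: str, concentration: float) -> pd.Series:
        return self.ses.iloc[:, self.column_position(drug, concentration)]

    def subset_lines(self, lines: Sequence[str]) -> "MonotherapyPanel":
        return MonotherapyPanel(
            self.means.loc[list(lines)], self.ses.loc[list(lines)], self.orientation
        )

    def with_means(self, means: pd.DataFrame) -> "MonotherapyPanel":
        """A panel sharing this panel's SEs/orientation but new mean values."""
        return MonotherapyPanel(means, self.ses, self.orientation)

    # -- construction / serialization ---------------------------------
    @classmethod
    def from_estimates(
        cls,
        estimates: dict[tuple[str, str, float], ViabilityEstimate],
        cell_lines: Sequence[str] | None = None,
        doses: Sequence[tuple[str, float]] | None = None,
        orientation: Orientation = "viability",
    ) -> "MonotherapyPanel":
        """Build a panel from ``{(cell_line, drug, concentration): estimate}``.

        Cells absent from ``estimates`` become explicit missing markers.
        """
        if not estimates and not (cell_lines and doses):
            raise InputError("no estimates and no explicit panel frame given")
        if cell_lines is None:
            cell_lines = sorted({k[0] for k in estimates})
        if doses is None:
            doses = sorted({(k[1], k[2]) for k in estimates})
        cols = pd.MultiIndex.from_tuples(
            [(d, float(c)) for d, c in doses], names=["drug", "concentration_uM"]
        )
        means = pd.DataFrame(np.nan, index=pd.Index(cell_lines, name="cell_line"), columns=cols)
        ses = means.copy()
        srcs = pd.DataFrame("", index=means.index, columns=cols)
        for (line, drug, conc), est in estimates.items():
            key = (drug, float(conc))
            if key in cols and line in means.index:
                means.loc[line, key] = est.mean
                ses.loc[line, key] = est.se
                srcs.loc[line, key] = est.source
        return cls(means, ses, orientation, sources=srcs)

    def to_csv(self, means_path, ses_path) -> None:
        """Serialize to a wide CSV pair (values + SEs), columns ``drug@conc``."""
        flat = [f"{d}{_COLUMN_SEP}{c:g}" for d, c in self.means.columns]
        m = self.means.copy()
        m.columns = flat
        m.to_csv(means_path, index_label="cell_line")
        s = self.ses.copy()
        s.columns = flat
        s.to_csv(ses_path, index_label="cell_line")

    @classmethod
    def read_csv(cls, means_path, ses_path, orientation: Orientation = "viability"):
        m = pd.read_csv(means_path, index_col="cell_line")
        s = pd.read_csv(ses_path, index_col="cell_line")
        tuples = []
        for col in m.columns:
            drug, _, conc = col.rpartition(_COLUMN_SEP)
            tuples.append((drug, float(conc)))
        cols = pd.MultiIndex.from_tuples(tuples, names=["drug", "concentration_uM"])
        m.columns = cols
        s.columns = cols
        return cls(m, s, orientation)
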