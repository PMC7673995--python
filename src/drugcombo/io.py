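"""Reading, validating, harmonizing and de-duplicating monotherapy screen data.

The canonical in-memory observation table is a tidy :class:`pandas.DataFrame`
with columns ``cell_line``, ``drug``, ``concentration_uM``, ``viability`` and
optional ``replicate`` / ``site`` columns.  Viability is stored as a fraction
relative to an untreated control (1.0 = untreated level); percent-scale input
requires an explicit flag and is never guessed from the data.  Values below 0
or above 1 are preserved at ingestion — any clamping is model-specific and
happens downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, SchemaError

logger = logging.getLogger(__name__)

#: Canonical observation-table columns, in serialization order.
CANONICAL_COLUMNS = ["cell_line", "drug", "concentration_uM", "viability", "replicate", "site"]
_MANDATORY = {"cell_line", "drug", "concentration_uM", "viability"}


def validate_observations(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy observation table against the canonical contract.

    Requires the four mandatory columns, non-empty identifiers, finite
    non-negative concentrations and finite viabilities.  Returns the table
    unchanged on success.
    """
    missing = _MANDATORY - set(table.columns)
    if missing:
        raise SchemaError(f"observation table is missing mandatory column(s): {sorted(missing)}")
    if len(table) == 0:
        raise InputError("observation table is empty")
    for col in ("cell_line", "drug"):
        ids = table[col].astype(str)
        if (ids.str.len() == 0).any() or ids.isna().any():
            raise InputError(f"empty {col} identifier after harmonization")
    conc = table["concentration_uM"].to_numpy(float)
    if not np.all(np.isfinite(conc)) or (conc < 0).any():
        raise InputError("concentrations must be finite and >= 0")
    if not np.all(np.isfinite(table["viability"].to_numpy(float))):
        raise InputError("viabilities must be finite")
    return table


def read_monotherapy_screen(
    path,
    schema_map: dict[str, str] | None = None,
    viability_scale: str = "fraction",
) -> pd.DataFrame:
    """Read a monotherapy screen CSV into the canonical observation table.

    Parameters
    ----------
    path : path-like
        CSV file (UTF-8, header row).
    schema_map : dict, optional
        Maps canonical names (``cell_line``, ``drug``, ``concentration_uM``,
        ``viability``, optionally ``replicate``/``site``) to the column names
        used in the file.  Omit for files already in the canonical dialect.
    viability_scale : {"fraction", "percent"}
        Declared scale of the viability column.  ``"percent"`` divides by
        100 on ingestion; the scale is never guessed from the data.

    Returns
    -------
    pandas.DataFrame
        Canonical observation table.  Rows with unparseable numerics are
        dropped with a logged count.
    """
    if viability_scale not in ("fraction", "percent"):
        raise InputError(f"viability_scale must be 'fraction' or 'percent', got {viability_scale!r}")
    raw = pd.read_csv(path)
    schema_map = schema_map or {}
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = schema_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in _MANDATORY:
            raise SchemaError(
                f"screen file {path} lacks mandatory column {source!r} (for {canonical!r})"
            )
    table = raw.rename(columns=rename)
    table = table[[c for c in CANONICAL_COLUMNS if c in table.columns]].copy()

    for col in ("concentration_uM", "viability"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    bad = table[["concentration_uM", "viability"]].isna().any(axis=1)
    if bad.any():
        logger.warning("dropped %d row(s) with unparseable numerics from %s", int(bad.sum()), path)
        table = table.loc[~bad].reset_index(drop=True)
    if len(table) == 0:
        raise InputError(f"screen file {path} contains no parseable observations")
    if viability_scale == "percent":
        table["viability"] = table["viability"] / 100.0
    table["cell_line"] = table["cell_line"].astype(str)
    table["drug"] = table["drug"].astype(str)
    return validate_observations(table)


def write_observations(table: pd.DataFrame, path) -> None:
    """Write an observation table in the canonical CSV dialect (round-trip safe)."""
    cols = [c for c in CANONICAL_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Identifier harmonization
# ---------------------------------------------------------------------------

def read_identifier_mapping(path) -> pd.DataFrame:
    """Read a 3-column (source, canonical, kind) identifier-mapping CSV."""
    mapping = pd.read_csv(path)
    missing = {"source", "canonical", "kind"} - set(mapping.columns)
    if missing:
        raise SchemaError(f"identifier mapping is missing column(s): {sorted(missing)}")
    return mapping


def _mapping_dict(mapping: pd.DataFrame, kind: str) -> dict[str, str]:
    sub = mapping[mapping["kind"] == kind]
    dup = sub.groupby("source")["canonical"].nunique()
    conflicts = dup[dup > 1].index.tolist()
    if conflicts:
        raise ConfigurationError(
            f"identifier mapping is not functional for kind={kind!r}: "
            f"source(s) {conflicts} map to multiple canonical names"
        )
    return dict(zip(sub["source"].astype(str), sub["canonical"].astype(str)))


def harmonize_identifiers(table: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Replace drug / cell-line names by canonical names.

    Unmapped names pass through unchanged and are reported via logging, so
    single-dataset runs need no mapping at all.  Row count is preserved.
    """
    out = table.copy()
    for col, kind in (("drug", "drug"), ("cell_line", "cell_line")):
        lut = _mapping_dict(mapping, kind)
        if not lut:
            continue
        unmapped = sorted(set(out[col]) - set(lut))
        if unmapped:
            logger.info("%d unmapped %s name(s) retained as-is: %s", len(unmapped), kind, unmapped[:10])
        out[col] = out[col].map(lambda name: lut.get(name, name))
    return out


# ---------------------------------------------------------------------------
# Replicate / multi-site policy
# ---------------------------------------------------------------------------

def apply_replicate_policy(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict each (cell line, drug) unit to its majority site, then average replicates.

    For every (cell_line, drug) unit measured at several sites, only rows
    from the site with the greatest experiment count are retained; ties are
    broken deterministically by lexicographic site id (and logged).
    Remaining replicate rows for the same (cell line, drug, concentration)
    are averaged into one.  Idempotent.
    """
    validate_observations(table)
    out = table.copy()

    if "site" in out.columns and out["site"].notna().any():
        keep = []
        for (line, drug), grp in out.groupby(["cell_line", "drug"], sort=False):
            counts = grp.groupby("site").size()
            best = counts.max()
            tied = sorted(counts[counts == best].index.astype(str))
            if len(tied) > 1:
                logger.info(
                    "site tie for (%s, %s): %s each with %d experiment(s); keeping %s",
                    line, drug, tied, best, tied[0],
                )
            keep.append(grp[grp["site"].astype(str) == tied[0]])
        out = pd.concat(keep, ignore_index=True)

    group_cols = ["cell_line", "drug", "concentration_uM"]
    if "site" in out.columns:
        group_cols.append("site")
    averaged = out.groupby(group_cols, as_index=False, sort=True)["viability"].mean()
    return averaged


# ---------------------------------------------------------------------------
# Clinical concentration table
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationMap:
    """Per-drug clinical (Csustained) and maximum-tested concentrations, in uM.

    Csustained is the maximum plasma concentration sustained at least six
    hours after administration — the concentration at which predictions are
    clinically relevant.  When a drug has several published clinical
    concentrations the highest is stored, matching the prospective-analysis
    convention.
    """

    csustained: dict[str, float] = field(default_factory=dict)
    max_tested: dict[str, float] = field(default_factory=dict)
    dose_note: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vals in (("csustained", self.csustained), ("max_tested", self.max_tested)):
            for drug, v in vals.items():
                if not (np.isfinite(v) and v > 0):
                    raise InputError(f"{name} for {drug!r} must be finite and > 0, got {v}")

    def drugs(self) -> list[str]:
        return sorted(self.csustained)


def read_concentration_table(path) -> ConcentrationMap:
    """Read a CSV with columns drug, csustained_uM, max_tested_uM.

    Several rows for one drug are collapsed to the maximum of each value.
    """
    df = pd.read_csv(path)
    missing = {"drug", "csustained_uM", "max_tested_uM"} - set(df.columns)
    if missing:
        raise SchemaError(f"concentration table is missing column(s): {sorted(missing)}")
    for col in ("csustained_uM", "max_tested_uM"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col] <= 0).any() or not np.all(np.isfinite(df[col])):
            raise InputError(f"non-positive or non-finite value in {col}")
    agg = df.groupby("drug").agg(
        csustained=("csustained_uM", "max"), max_tested=("max_tested_uM", "max")
    )
    notes = {}
    if "dose_note" in df.columns:
        notes = df.groupby("drug")["dose_note"].first().dropna().astype(str).to_dict()
    return ConcentrationMap(
        csustained=agg["csustained"].to_dict(),
        max_tested=agg["max_tested"].to_dict(),
        dose_note=notes,
    )
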