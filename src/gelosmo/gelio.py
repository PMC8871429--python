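"""Readers and writers for osmotic tables and reduced SANS profiles.

Osmotic tables are self-describing CSV: the pressure-like column names carry
their unit suffix (``pressure_Pa`` or ``pressure_kPa``, likewise ``G_s_*``
and ``uncertainty_*``), salt columns are in mM (== mol/m^3) and temperature
in K.  SANS profiles are the conventional 3-column whitespace ASCII
(q [1/A], I [1/cm], dI [1/cm]) with '#' comment lines.

Readers reject malformed input with the offending line number rather than
silently coercing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .osmotics import OsmoticCurve
from .scattering import SANSProfile

__all__ = [
    "SchemaError",
    "read_osmotic_table",
    "write_osmotic_table",
    "read_sans_profile",
    "write_sans_profile",
    "write_json_report",
]

logger = logging.getLogger("gelosmo")

_CONDITION_COLUMNS = ("c_NaCl_mM", "c_CaCl2_mM", "T_K")
_PRESSURE_UNITS = {"Pa": 1.0, "kPa": 1000.0}


class SchemaError(ValueError):
    """The file does not match the expected table schema."""


def _unit_column(df: pd.DataFrame, stem: str) -> tuple[Optional[str], float]:
    """Find '<stem>_Pa' or '<stem>_kPa' and its SI conversion factor."""
    for suffix, factor in _PRESSURE_UNITS.items():
        name = f"{stem}_{suffix}"
        if name in df.columns:
            return name, factor
    return None, 1.0


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad]]
        raise SchemaError(
            f"{path}: non-numeric value in column {col!r} at line(s) {lines}"
        )
    if vals.isna().any():
        lines = [int(i) + 2 for i in df.index[vals.isna()]]
        raise SchemaError(f"{path}: missing value in column {col!r} at line(s) {lines}")
    return vals.to_numpy(dtype=float)


def read_osmotic_table(path: Union[str, Path]) -> list[OsmoticCurve]:
    """Read a deswelling-series CSV, grouped into curves by condition.

    Mandatory columns: ``phi`` and a pressure column (``pressure_Pa`` or
    ``pressure_kPa``).  Optional: ``pressure_kind``, ``G_s_Pa``/``G_s_kPa``,
    ``uncertainty_Pa``/``uncertainty_kPa`` and the condition columns
    ``c_NaCl_mM``, ``c_CaCl2_mM``, ``T_K``.  All values are converted to SI.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("osmotic table %s is empty", path)
        return []
    if df.empty:
        logger.warning("osmotic table %s has a header but no rows", path)
        return []
    if "phi" not in df.columns:
        raise SchemaError(f"{path}: mandatory column 'phi' is missing")
    pcol, pfactor = _unit_column(df, "pressure")
    if pcol is None:
        raise SchemaError(f"{path}: mandatory column 'pressure_Pa' (or _kPa) is missing")
    phi = _numeric(df, "phi", path)
    pressure = _numeric(df, pcol, path) * pfactor
    gcol, gfactor = _unit_column(df, "G_s")
    g = _numeric(df, gcol, path) * gfactor if gcol else None
    ucol, ufactor = _unit_column(df, "uncertainty")
    unc = _numeric(df, ucol, path) * ufactor if ucol else None
    kinds = (df["pressure_kind"].astype(str).str.strip()
             if "pressure_kind" in df.columns
             else pd.Series(["total"] * len(df)))

    cond_cols = [c for c in _CONDITION_COLUMNS if c in df.columns]
    for c in cond_cols:
        _numeric(df, c, path)
    key = df[cond_cols].astype(float) if cond_cols else None

    curves: list[OsmoticCurve] = []
    if key is not None:
        groups = df.groupby(cond_cols, sort=True).indices
        items = sorted(groups.items())
    else:
        items = [((), np.arange(len(df)))]
    for cond_key, idx in items:
        idx = np.asarray(sorted(idx))
        kind = kinds.iloc[idx[0]]
        if not (kinds.iloc[idx] == kind).all():
            raise SchemaError(
                f"{path}: mixed pressure_kind values within one condition group"
            )
        if not isinstance(cond_key, tuple):
            cond_key = (cond_key,)
        condition = dict(zip(cond_cols, (float(v) for v in cond_key)))
        meta = {}
        if g is not None:
            meta["G_s_Pa"] = g[idx]
        curves.append(OsmoticCurve(
            phi=phi[idx], pressure=pressure[idx], pressure_kind=str(kind),
            condition=condition,
            uncertainty=None if unc is None else unc[idx],
            metadata=meta,
        ))
    return curves


def write_osmotic_table(curves: Sequence[OsmoticCurve], path: Union[str, Path],
                        units: str = "Pa") -> Path:
    """Write curves to CSV in the schema :func:`read_osmotic_table` consumes."""
    if units not in _PRESSURE_UNITS:
        raise ValueError(f"units must be one of {sorted(_PRESSURE_UNITS)}")
    factor = _PRESSURE_UNITS[units]
    path = Path(path)
    rows = []
    for curve in curves:
        g = curve.metadata.get("G_s_Pa")
        for i in range(len(curve)):
            row = {"phi": curve.phi[i],
                   f"pressure_{units}": curve.pressure[i] / factor,
                   "pressure_kind": curve.pressure_kind}
            if g is not None:
                row[f"G_s_{units}"] = np.asarray(g, float)[i] / factor
            if curve.uncertainty is not None:
                row[f"uncertainty_{units}"] = curve.uncertainty[i] / factor
            for c in _CONDITION_COLUMNS:
                if c in curve.condition:
                    row[c] = curve.condition[c]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# SANS ASCII
# ---------------------------------------------------------------------------

def read_sans_profile(path: Union[str, Path], sort: bool = False) -> SANSProfile:
    """Read a reduced SANS profile from 2- or 3-column ASCII.

    Lines starting with '#' are comments.  Rows with q <= 0 are rejected
    with their line number; unsorted q is an error unless ``sort=True``
    (then sorted with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[float, ...]] = []
    ncols = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.replace(",", " ").split()
        try:
            vals = tuple(float(p) for p in parts)
        except ValueError as exc:
            raise SchemaError(f"{path}: non-numeric value at line {lineno}") from exc
        if len(vals) < 2:
            raise SchemaError(f"{path}: fewer than 2 columns at line {lineno}")
        if vals[0] <= 0:
            raise SchemaError(f"{path}: nonpositive q at line {lineno}")
        if ncols is None:
            ncols = min(len(vals), 3)
        rows.append(vals[:ncols])
    if not rows:
        raise SchemaError(f"{path}: no data rows (header-only or empty file)")
    arr = np.asarray(rows, dtype=float)
    q, I = arr[:, 0], arr[:, 1]
    dI = arr[:, 2] if arr.shape[1] >= 3 else None
    if np.any(np.diff(q) <= 0):
        if not sort:
            raise SchemaError(f"{path}: q values are not strictly increasing "
                              "(pass sort=True to sort)")
        logger.warning("sorting unsorted SANS profile %s", path)
        order = np.argsort(q)
        q, I = q[order], I[order]
        if dI is not None:
            dI = dI[order]
    return SANSProfile(q=q, I=I, dI=dI)


def write_sans_profile(profile: SANSProfile, path: Union[str, Path]) -> Path:
    """Write a profile as 3-column ASCII (q, I, dI) with a '#' header."""
    path = Path(path)
    dI = profile.dI if profile.dI is not None else np.zeros_like(profile.q)
    header = "q_invA I_invcm dI_invcm"
    np.savetxt(path, np.column_stack([profile.q, profile.I, dI]),
               header=header, fmt="%.10e")
    return path


class _ReportEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        return super().default(obj)


def write_json_report(report: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, cls=_ReportEncoder) + "\n")
    return path
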