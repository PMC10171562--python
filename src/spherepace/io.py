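"""Long-format readers and writers for longitudinal compositional tables.

Expected layout: one row per scan with columns ``subject_id, age, csf, gm,
wm`` and an optional ``group`` column, comma- or tab-delimited with a
header.  Ages are years by default (``unit="months"`` divides by 12 on
read).  In ``mode="volumes"`` each row holds raw tissue volumes and is
normalized by its row sum; in ``mode="proportions"`` rows must already sum
to 1 within 1e-6.  Validation failures carry 1-based data row numbers
(header excluded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geometry as geo
from .exceptions import DataValidationError
from .rfpca import LongitudinalSample

__all__ = ["read_longitudinal_table", "write_longitudinal_table", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("subject_id", "age", "csf", "gm", "wm")
TISSUES = ("csf", "gm", "wm")


def read_longitudinal_table(
    path,
    unit: str = "years",
    mode: str = "proportions",
    sum_tol: float = 1e-6,
) -> LongitudinalSample:
    """Read a delimited long-format table into a :class:`LongitudinalSample`."""
    if unit not in ("years", "months"):
        raise DataValidationError(f"unknown age unit {unit!r} (use 'years' or 'months')")
    if mode not in ("proportions", "volumes"):
        raise DataValidationError(f"unknown mode {mode!r} (use 'proportions' or 'volumes')")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as e:
        raise DataValidationError(f"cannot parse {path}: {e}") from e
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required columns {missing}")

    errors: list[str] = []
    rows = np.arange(1, len(df) + 1)

    age = pd.to_numeric(df["age"], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(age) | (age <= 0)
    for r in rows[bad]:
        errors.append(f"row {r}: age must be finite and positive")
    if unit == "months":
        age = age / 12.0

    tissue = np.column_stack(
        [pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float) for c in TISSUES]
    )
    bad = ~np.isfinite(tissue).all(axis=1) | (tissue < 0).any(axis=1)
    for r in rows[bad]:
        errors.append(f"row {r}: tissue values must be finite and nonnegative")

    good = np.isfinite(tissue).all(axis=1) & (tissue >= 0).all(axis=1)
    if mode == "volumes":
        s = tissue.sum(axis=1)
        zero = good & (s <= 0)
        for r in rows[zero]:
            errors.append(f"row {r}: zero row sum, cannot normalize volumes")
        with np.errstate(invalid="ignore", divide="ignore"):
            comp = np.where(s[:, None] > 0, tissue / np.where(s[:, None] > 0, s[:, None], 1), np.nan)
    else:
        s = tissue.sum(axis=1)
        off = good & (np.abs(s - 1.0) > sum_tol)
        for r in rows[off]:
            errors.append(f"row {r}: proportions sum to {s[r - 1]:.6g}, expected 1")
        with np.errstate(invalid="ignore"):
            comp = tissue / s[:, None]

    subj = df["subject_id"].astype(str).to_numpy()
    dup = df.assign(_r=rows).duplicated(subset=["subject_id", "age"], keep=False)
    if dup.any():
        for r in rows[dup.to_numpy()]:
            errors.append(f"row {r}: duplicate (subject_id, age) pair")
    if errors:
        raise DataValidationError(f"{path}: " + "; ".join(errors[:20]))

    groups_col = df["group"].astype(str).to_numpy() if "group" in df.columns else None
    ids, times, values, groups = [], [], [], []
    for sid in pd.unique(subj):
        rows_s = np.where(subj == sid)[0]
        order = rows_s[np.argsort(age[rows_s], kind="stable")]
        ids.append(sid)
        times.append(age[order])
        values.append(geo.comp_to_sphere(comp[order], renormalize=True))
        if groups_col is not None:
            g = set(groups_col[rows_s])
            if len(g) > 1:
                raise DataValidationError(
                    f"{path}: subject {sid!r} has inconsistent group labels {sorted(g)}"
                )
            groups.append(groups_col[rows_s[0]])
    return LongitudinalSample(
        ids=ids, times=times, values=values, groups=groups if groups_col is not None else None
    )


def write_longitudinal_table(sample: LongitudinalSample, path, unit: str = "years") -> None:
    """Write a sample back to CSV (proportions mode, ages in the given unit)."""
    if unit not in ("years", "months"):
        raise DataValidationError(f"unknown age unit {unit!r}")
    factor = 12.0 if unit == "months" else 1.0
    records = []
    for i in range(sample.n_subjects):
        comp = geo.sphere_to_comp(sample.values[i])
        for j, t in enumerate(sample.times[i]):
            rec = {
                "subject_id": sample.ids[i],
                "age": t * factor,
                "csf": comp[j, 0],
                "gm": comp[j, 1],
                "wm": comp[j, 2],
            }
            if sample.groups is not None:
                rec["group"] = sample.groups[i]
            records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False, float_format="%.17g")
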