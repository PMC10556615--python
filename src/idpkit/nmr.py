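"""NMR-side statistics: isomer ratios, secondary shifts, titration profiles.

Inputs are already-tabulated peak heights and chemical shifts (peak picking
and lineshape fitting are upstream of this package):

- a *peak table* holds rows of (residue, residue code, isomer tag in
  {cis, trans, none}, height) from e.g. HSQC cross peaks;
- a *shift table* holds rows of (residue, residue code, atom, shift/ppm,
  optional isomer tag).

From these the module computes cis:trans proline isomer ratios from peak
heights of reporter residues, Ca-Cb secondary chemical-shift differentials
against a random-coil reference (positive = helical tendency, negative =
beta tendency), the upfield cis-proline Ca signature, and per-residue
percentage intensity changes on titration with a -100 % noise floor.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "read_peak_table",
    "read_shift_table",
    "validate_peak_table",
    "validate_shift_table",
    "load_random_coil_shifts",
    "IsomerRatio",
    "isomer_ratio",
    "secondary_shift_differential",
    "cis_pro_signature",
    "titration_change",
]

PEAK_COLUMNS = ["residue", "code", "isomer", "height"]
SHIFT_COLUMNS = ["residue", "code", "atom", "shift"]
ISOMER_TAGS = {"cis", "trans", "none"}


def validate_peak_table(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table lacks columns: {sorted(missing)}")
    bad = set(peaks["isomer"]) - ISOMER_TAGS
    if bad:
        raise ValueError(f"unknown isomer tags: {sorted(bad)}")
    if (peaks["height"] < 0).any():
        raise ValueError("peak heights must be non-negative")
    if peaks.duplicated(["residue", "isomer"]).any():
        raise ValueError("duplicate (residue, isomer) rows in peak table")
    return peaks


def validate_shift_table(shifts: pd.DataFrame) -> pd.DataFrame:
    missing = set(SHIFT_COLUMNS) - set(shifts.columns)
    if missing:
        raise ValueError(f"shift table lacks columns: {sorted(missing)}")
    if not np.all(np.isfinite(shifts["shift"])):
        raise ValueError("non-finite chemical shifts")
    key = ["residue", "atom"] + (["isomer"] if "isomer" in shifts.columns else [])
    if shifts.duplicated(key).any():
        raise ValueError("duplicate (residue, atom, isomer) rows in shift table")
    return shifts


def read_peak_table(path) -> pd.DataFrame:
    """Read a TSV peak table with columns residue, code, isomer, height."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "isomer" not in df.columns:
        df["isomer"] = "none"
    df["isomer"] = df["isomer"].fillna("none")
    return validate_peak_table(df)


def read_shift_table(path) -> pd.DataFrame:
    """Read a TSV shift table with columns residue, code, atom, shift[, isomer]."""
    return validate_shift_table(pd.read_csv(path, sep="\t", comment="#"))


def load_random_coil_shifts() -> pd.DataFrame:
    """Random-coil Ca/Cb reference shifts shipped with the package.

    Indexed by 1-letter residue code with columns ``ca`` and ``cb`` (ppm);
    glycine's ``cb`` is NaN and contributes 0 to differentials.  Users with
    a preferred reference set can pass their own frame of the same shape to
    :func:`secondary_shift_differential`.
    """
    ref = importlib.resources.files("idpkit").joinpath("data/random_coil_shifts.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("code")


@dataclass
class IsomerRatio:
    """cis:trans ratio averaged over reporter residues."""

    cis_percent: float
    trans_percent: float
    per_residue: pd.DataFrame  # residue, cis %, trans %
    sd: float                  # dispersion (SD over reporter residues)


def isomer_ratio(peaks: pd.DataFrame, residues) -> IsomerRatio:
    """cis:trans ratio from cis/trans-split peak heights of reporter residues.

    Per residue, cis % = h_cis / (h_cis + h_trans) * 100; the reported ratio
    is the unweighted mean over reporter residues with their SD as the
    dispersion.  Residues lacking either isomer peak are skipped with a
    warning; the ratio is invariant under common rescaling of all heights.
    """
    validate_peak_table(peaks)
    rows = []
    for res in residues:
        sub = peaks[peaks["residue"] == res].set_index("isomer")["height"]
        if "cis" not in sub.index or "trans" not in sub.index:
            warnings.warn(f"residue {res}: missing cis or trans peak, skipped")
            continue
        total = sub["cis"] + sub["trans"]
        if total == 0:
            warnings.warn(f"residue {res}: zero total height, skipped")
            continue
        rows.append((res, 100.0 * sub["cis"] / total, 100.0 * sub["trans"] / total))
    if not rows:
        raise ValueError("no residue had both cis and trans peaks")
    table = pd.DataFrame(rows, columns=["residue", "cis_percent", "trans_percent"])
    return IsomerRatio(
        cis_percent=float(table["cis_percent"].mean()),
        trans_percent=float(table["trans_percent"].mean()),
        per_residue=table,
        sd=float(table["cis_percent"].std(ddof=1)) if len(table) > 1 else 0.0,
    )


def secondary_shift_differential(shifts: pd.DataFrame,
                                 reference: pd.DataFrame | None = None,
                                 isomer: str | None = None) -> pd.DataFrame:
    """Per-residue Ca-Cb secondary-shift differential against random coil.

    delta(i) = (dCa(i) - dCa_rc(type)) - (dCb(i) - dCb_rc(type)), with the
    Cb term taken as 0 for glycine.  Positive values indicate helical
    tendency, negative values beta tendency.  Residues without both Ca and
    Cb observations or without a reference for their type are skipped and
    flagged with a warning.
    """
    validate_shift_table(shifts)
    if reference is None:
        reference = load_random_coil_shifts()
    df = shifts
    if isomer is not None and "isomer" in df.columns:
        df = df[df["isomer"].isin([isomer, "none"])]
    rows = []
    for res, grp in df.groupby("residue"):
        code = grp["code"].iloc[0]
        atoms = grp.set_index("atom")["shift"]
        if code not in reference.index:
            warnings.warn(f"residue {res} ({code}): no random-coil reference, skipped")
            continue
        if "CA" not in atoms.index:
            warnings.warn(f"residue {res}: no Ca shift, skipped")
            continue
        d_ca = atoms["CA"] - reference.loc[code, "ca"]
        if code == "G":
            d_cb = 0.0
        else:
            if "CB" not in atoms.index:
                warnings.warn(f"residue {res}: no Cb shift, skipped")
                continue
            d_cb = atoms["CB"] - reference.loc[code, "cb"]
        rows.append((res, code, d_ca - d_cb))
    return pd.DataFrame(rows, columns=["residue", "code", "delta_delta"])


def cis_pro_signature(shifts: pd.DataFrame, proline_residue: int,
                      window: tuple[float, float] = (0.1, 1.0)) -> tuple[float, bool]:
    """Upfield Ca offset of a proline's cis state relative to trans.

    Returns (offset, call): offset = dCa(trans) - dCa(cis) in ppm (positive
    when the cis peak is upfield of the trans peak) and a boolean call that
    is true when the offset lies in the expected window, by default 0.1 to
    1.0 ppm around the characteristic ~0.3-0.5 ppm cis-proline signature.
    """
    validate_shift_table(shifts)
    if "isomer" not in shifts.columns:
        raise ValueError("shift table carries no isomer tags")
    sub = shifts[(shifts["residue"] == proline_residue) & (shifts["atom"] == "CA")]
    sub = sub.set_index("isomer")["shift"]
    if "cis" not in sub.index or "trans" not in sub.index:
        raise ValueError(
            f"residue {proline_residue}: need both cis and trans Ca shifts"
        )
    offset = float(sub["trans"] - sub["cis"])
    lo, hi = window
    return offset, bool(lo <= offset <= hi)


def titration_change(free: pd.DataFrame, bound: pd.DataFrame,
                     noise_floor: float = 0.0) -> pd.DataFrame:
    """Percentage peak-intensity change on titration, with a -100 % floor.

    change % = (h_bound - h_free) / h_free * 100, clamped to exactly -100
    when the bound peak is at or below the noise floor (the peak has
    vanished into the noise).  Rows present in only one table, or whose free
    peak is itself at or below the floor, are flagged in the ``status``
    column rather than dropped.
    """
    if noise_floor < 0:
        raise ValueError("noise floor must be non-negative")
    validate_peak_table(free)
    validate_peak_table(bound)
    f = free.set_index(["residue", "isomer"])
    b = bound.set_index(["residue", "isomer"])
    rows = []
    for key in f.index.union(b.index):
        res, iso = key
        if key not in f.index or key not in b.index:
            rows.append((res, iso, np.nan, "missing"))
            continue
        h_free = f.loc[key, "height"]
        h_bound = b.loc[key, "height"]
        if h_free <= noise_floor:
            rows.append((res, iso, np.nan, "free_below_floor"))
            continue
        if h_bound <= noise_floor:
            rows.append((res, iso, -100.0, "ok"))
        else:
            rows.append((res, iso, 100.0 * (h_bound - h_free) / h_free, "ok"))
    return pd.DataFrame(rows, columns=["residue", "isomer", "change_percent", "status"])
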