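"""Anthropometric z-scores and four-state nutritional classification.

Children and adolescents are classified each round into one of four
nutritional states from WHO-standard z-scores:

* ``stunted``     — height-for-age z-score (HAZ) below -2 SD;
* ``overweight``  — weight index above the age-appropriate cutoff:
  weight-for-height z-score (WHZ) > 2 SD under 5 years, BMI-for-age
  z-score (BAZ) > 1 SD from 5 to 19 years, and BMI > 25 kg/m^2 above
  19 years;
* ``cso``         — concurrent stunting and overweight (both criteria met
  in the same round);
* ``normal``      — neither criterion met.

All cutoffs are strict inequalities; HAZ exactly -2 is not stunted and
BAZ exactly 1 is not overweight.  Age bands are half-open: [0, 5) uses
WHZ, [5, 19] uses BAZ (the WHO growth reference covers 5-19 inclusive),
and (19, inf) uses BMI.

z-scores may be computed from raw measurements with user-supplied LMS
reference tables (``lms_zscore``, ``load_lms_table``); WHO tables are not
bundled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical state labels, in display order.
STATES = ("normal", "stunted", "overweight", "cso")

#: Age-band edges (years) for the overweight index: [0,5) WHZ, [5,19] BAZ, (19,inf) BMI.
WHZ_MAX_AGE = 5.0
BAZ_MAX_AGE = 19.0

HAZ_CUTOFF = -2.0
WHZ_CUTOFF = 2.0
BAZ_CUTOFF = 1.0
BMI_CUTOFF = 25.0


class ClassificationError(ValueError):
    """A record lacks the index required for its age band."""


def lms_zscore(x, L, M, S):
    """z-score of measurement ``x`` under the LMS (lambda-mu-sigma) transform.

    z = ((x/M)**L - 1) / (L*S), with the limiting log form
    z = ln(x/M)/S used when |L| < 1e-8 so the transform is continuous
    in L at zero.

    Parameters
    ----------
    x : float or array
        Measurement (same units as ``M``); must be positive.
    L : float or array
        Box-Cox power.
    M : float or array
        Reference median; must be positive.
    S : float or array
        Reference coefficient of variation; must be positive.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0):
        raise ValueError("measurement x must be positive")
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("LMS reference requires M > 0 and S > 0")
    ratio = x / M
    log_form = np.log(ratio) / S
    with np.errstate(divide="ignore", invalid="ignore"):
        power_form = (ratio**L - 1.0) / (L * S)
    z = np.where(np.abs(L) < 1e-8, log_form, power_form)
    return float(z) if z.ndim == 0 else z


def load_lms_table(path) -> pd.DataFrame:
    """Read an LMS reference CSV with columns ``key, L, M, S``.

    ``key`` is the lookup variable (age in years, or length/height in cm
    for weight-for-height tables) and must be strictly increasing.
    """
    table = pd.read_csv(path)
    required = {"key", "L", "M", "S"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"LMS table missing columns: {sorted(missing)}")
    if (table["M"] <= 0).any() or (table["S"] <= 0).any():
        raise ValueError("LMS table requires M > 0 and S > 0")
    if not table["key"].is_monotonic_increasing:
        table = table.sort_values("key").reset_index(drop=True)
    return table


def zscore_from_table(x, key, table: pd.DataFrame):
    """z-score of ``x`` at lookup value ``key``, interpolating L, M, S linearly
    between tabulated rows.  ``key`` outside the table range is an error."""
    keys = table["key"].to_numpy(dtype=float)
    key = np.asarray(key, dtype=float)
    if np.any(key < keys[0]) or np.any(key > keys[-1]):
        raise ValueError("lookup key outside LMS reference range")
    L = np.interp(key, keys, table["L"].to_numpy(dtype=float))
    M = np.interp(key, keys, table["M"].to_numpy(dtype=float))
    S = np.interp(key, keys, table["S"].to_numpy(dtype=float))
    return lms_zscore(x, L, M, S)


def weight_index_name(age_years: float) -> str:
    """Name of the overweight index column for an age: whz, baz or bmi."""
    if age_years < 0:
        raise ValueError("age_years must be non-negative")
    if age_years < WHZ_MAX_AGE:
        return "whz"
    if age_years <= BAZ_MAX_AGE:
        return "baz"
    return "bmi"


def _overweight_cutoff(index: str) -> float:
    return {"whz": WHZ_CUTOFF, "baz": BAZ_CUTOFF, "bmi": BMI_CUTOFF}[index]


def classify_state(age_years, haz, whz=None, baz=None, bmi=None) -> str:
    """Classify a single subject-round into one of the four states.

    HAZ and the weight index matching the age band must be present
    (non-missing); otherwise a :class:`ClassificationError` names the
    missing index and the band.
    """
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        raise ClassificationError("age_years is missing")
    if age_years < 0:
        raise ClassificationError("age_years must be non-negative")
    if haz is None or np.isnan(haz):
        raise ClassificationError("haz missing; required for all ages")
    index = weight_index_name(age_years)
    value = {"whz": whz, "baz": baz, "bmi": bmi}[index]
    if value is None or np.isnan(value):
        band = {"whz": "<5 years", "baz": "5-19 years", "bmi": ">19 years"}[index]
        raise ClassificationError(f"{index} missing; required for age band {band}")
    stunted = haz < HAZ_CUTOFF
    overweight = value > _overweight_cutoff(index)
    if stunted and overweight:
        return "cso"
    if stunted:
        return "stunted"
    if overweight:
        return "overweight"
    return "normal"


def classify_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Add ``state`` and ``state_missing`` columns to a long-format panel.

    Rows with insufficient anthropometry for their age band are flagged
    (``state_missing=True``, ``state=NaN``) rather than dropped; dropping
    is the complete-case filter's job.  Vectorised over rows.
    """
    out = panel.copy()
    age = out["age_years"].to_numpy(dtype=float)
    haz = out["haz"].to_numpy(dtype=float) if "haz" in out else np.full(len(out), np.nan)

    idx_value = np.full(len(out), np.nan)
    cutoff = np.full(len(out), np.nan)
    band_masks = {
        "whz": age < WHZ_MAX_AGE,
        "baz": (age >= WHZ_MAX_AGE) & (age <= BAZ_MAX_AGE),
        "bmi": age > BAZ_MAX_AGE,
    }
    for name, mask in band_masks.items():
        if name in out:
            idx_value[mask] = out[name].to_numpy(dtype=float)[mask]
        cutoff[mask] = _overweight_cutoff(name)

    missing = np.isnan(age) | (age < 0) | np.isnan(haz) | np.isnan(idx_value)
    stunted = haz < HAZ_CUTOFF
    over = idx_value > cutoff
    state = np.select(
        [stunted & over, stunted, over],
        ["cso", "stunted", "overweight"],
        default="normal",
    ).astype(object)
    state[missing] = np.nan
    out["state"] = state
    out["state_missing"] = missing
    return out
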