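"""Body condition (scaled mass index) and EURING age classes.

The scaled mass index standardizes each bird's body mass to the cohort's
arithmetic mean wing length via the allometric power implied by the
standardized major axis (SMA) of ln(mass) on ln(wing):

    SMI_i = M_i * (L0 / L_i) ** b,     b = sign(r) * sd(ln M) / sd(ln L)

Because raptors are strongly sexually dimorphic, the index is computed
separately per sex; mixed-sex input is refused.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def assign_age(euring_age: int) -> str:
    """EURING code 5 (first-year) -> juvenile; >= 6 (second-year+) -> adult."""
    code = int(euring_age)
    if code < 5:
        raise ValueError(f"EURING age code {code} not used in this scheme (expected >= 5)")
    return "juvenile" if code == 5 else "adult"


def sma_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized major axis slope of y on x (OLS slope / Pearson r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0:
        raise ValueError("zero variance in x: SMA slope undefined")
    r = np.corrcoef(x, y)[0, 1]
    if r == 0 or np.isnan(r):
        raise ValueError("zero correlation: SMA slope sign undefined")
    return float(np.sign(r) * sy / sx)


def smi(
    records: pd.DataFrame,
    mass_col: str = "mass_g",
    wing_col: str = "wing_mm",
    sex_col: str = "sex",
    out_col: str = "smi_g",
) -> pd.DataFrame:
    """Fill the scaled mass index for a single-sex cohort.

    Requires at least 3 records with positive mass and wing length; wing
    lengths must vary (the allometric slope is otherwise undefined).
    """
    if sex_col in records.columns and records[sex_col].nunique() > 1:
        raise ValueError("smi must be computed per sex; mixed-sex input refused")
    if len(records) < 3:
        raise ValueError("smi needs at least 3 records")
    mass = records[mass_col].to_numpy(dtype=float)
    wing = records[wing_col].to_numpy(dtype=float)
    if np.any(mass <= 0) or np.any(wing <= 0):
        raise ValueError("mass and wing must be positive")
    out = records.copy()
    if np.ptp(wing) == 0:
        # every bird already at the reference size: (L0/L)^b = 1 for any b
        out[out_col] = mass.astype(float)
        return out
    b = sma_slope(np.log(wing), np.log(mass))
    l0 = wing.mean()
    out[out_col] = mass * (l0 / wing) ** b
    return out


def smi_by_sex(records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply :func:`smi` within each sex and reassemble in input order."""
    parts = [smi(g, **kwargs) for _, g in records.groupby("sex", sort=False)]
    return pd.concat(parts).loc[records.index]
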