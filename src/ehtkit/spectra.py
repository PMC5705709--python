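"""Packaged hemoglobin extinction spectra shared by the phantom forward model
and the unmixing inverse model."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_ASSET = "hb_extinction_v1.csv"


def load_extinction_table() -> pd.DataFrame:
    """Return the packaged extinction table (wavelength_nm, eps_hbo2, eps_hb)."""
    with resources.files("ehtkit.data").joinpath(_ASSET).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def extinction_at(wavelengths) -> tuple[np.ndarray, np.ndarray]:
    """Extinction coefficients (eps_HbO2, eps_Hb) at the given wavelengths (nm).

    Values are linearly interpolated within the tabulated 500-600 nm range;
    wavelengths outside that range raise ``ValueError``.
    """
    wl = np.asarray(wavelengths, dtype=float)
    table = load_extinction_table()
    lo, hi = table["wavelength_nm"].min(), table["wavelength_nm"].max()
    if wl.min() < lo or wl.max() > hi:
        raise ValueError(
            f"wavelengths must lie within the tabulated range [{lo}, {hi}] nm"
        )
    eps1 = np.interp(wl, table["wavelength_nm"], table["eps_hbo2"])
    eps2 = np.interp(wl, table["wavelength_nm"], table["eps_hb"])
    return eps1, eps2
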