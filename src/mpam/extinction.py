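"""Hemoglobin extinction coefficients used for dual-wavelength sO2 unmixing.

The bundled table holds molar extinction coefficients of oxy- and
deoxyhemoglobin at the two excitation wavelengths (532 and 559 nm).
532 nm is near an isosbestic point (HbO2 and Hb absorb similarly), so it
carries total-hemoglobin / structural contrast; at 559 nm deoxyhemoglobin
absorbs much more strongly, which provides the oxygenation contrast.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

_TABLE_RESOURCE = "hemoglobin_extinction.csv"


class ExtinctionTable:
    """Extinction coefficients eps(lambda) for HbO2 and Hb.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``wavelength_nm``, ``eps_hbo2``, ``eps_hb``.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"wavelength_nm", "eps_hbo2", "eps_hb"}
        if not required.issubset(table.columns):
            raise ValueError(f"extinction table needs columns {sorted(required)}")
        self._table = table.set_index(table["wavelength_nm"].astype(int))

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(int(w) for w in self._table.index)

    def eps(self, wavelength_nm: int) -> tuple[float, float]:
        """Return ``(eps_hbo2, eps_hb)`` at a wavelength, in cm^-1/M."""
        wl = int(wavelength_nm)
        if wl not in self._table.index:
            raise KeyError(f"no extinction coefficients tabulated at {wl} nm")
        row = self._table.loc[wl]
        return float(row["eps_hbo2"]), float(row["eps_hb"])

    def absorption(self, wavelength_nm: int, so2) -> np.ndarray:
        """Relative blood absorption coefficient at unit total hemoglobin.

        mu(lambda) = sO2 * eps_HbO2(lambda) + (1 - sO2) * eps_Hb(lambda)
        """
        e_oxy, e_deoxy = self.eps(wavelength_nm)
        so2 = np.asarray(so2, dtype=float)
        return so2 * e_oxy + (1.0 - so2) * e_deoxy

    def design_matrix(self, wavelengths, fluence=None) -> np.ndarray:
        """2x2 system matrix mapping (cHbO2, cHb) to amplitudes at each wavelength."""
        rows = []
        fluence = np.ones(len(wavelengths)) if fluence is None else np.asarray(fluence, float)
        for f, wl in zip(fluence, wavelengths):
            e_oxy, e_deoxy = self.eps(wl)
            rows.append([f * e_oxy, f * e_deoxy])
        mat = np.asarray(rows, dtype=float)
        if abs(np.linalg.det(mat)) < 1e-12 * np.abs(mat).max() ** 2:
            raise ValueError("extinction spectra are collinear at these wavelengths")
        return mat


def load_extinction_table() -> ExtinctionTable:
    """Load the bundled 532/559 nm hemoglobin extinction table."""
    ref = importlib.resources.files("mpam.data").joinpath(_TABLE_RESOURCE)
    with ref.open("r") as fh:
        df = pd.read_csv(fh, comment="#")
    return ExtinctionTable(df)
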