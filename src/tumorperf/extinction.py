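"""Hemoglobin molar extinction spectra for the visible fit range.

This module provides a *synthetic* analytic approximation of the tabulated
molar extinction coefficients of oxy- and deoxyhemoglobin, built from a
Soret-band exponential tail plus Gaussian Q-band components:

* HbO2 shows the characteristic double Q-band (maxima near 542 and 577 nm);
* Hb shows a single broad band near 555 nm and exceeds HbO2 in the red
  (>600 nm), which is what makes StO2 spectrally identifiable.

The curves are qualitatively correct (positive everywhere on 450-650 nm,
double-dip reflectance signature, crossings between the Q-bands) but are not
a published compilation; inversion is always performed against the same
table used by the forward model, so perfusion estimates are self-consistent.
A user-supplied table can be loaded with :func:`load_extinction_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Molar mass of the hemoglobin tetramer, g/mol (standard convention).
HEMOGLOBIN_MOLAR_MASS = 64500.0

#: Default wavelength support of the synthetic table, nm.
WL_MIN, WL_MAX = 420.0, 700.0


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients on a wavelength grid.

    Attributes
    ----------
    wavelengths : ndarray, nm, strictly increasing
    eps_hbo2, eps_hb : ndarray, L mol^-1 cm^-1, positive
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing 1-D")
        for name in ("eps_hbo2", "eps_hb"):
            eps = np.asarray(getattr(self, name), float)
            if eps.shape != wl.shape:
                raise ValueError(f"{name} length mismatch")
            if np.any(eps <= 0):
                raise ValueError(f"{name} must be positive")

    def interp(self, wavelengths) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolate both spectra onto `wavelengths`.

        Raises ValueError outside the table support.
        """
        wl = np.asarray(wavelengths, float)
        if wl.min() < self.wavelengths[0] or wl.max() > self.wavelengths[-1]:
            raise ValueError(
                f"wavelengths [{wl.min():g}, {wl.max():g}] nm outside extinction "
                f"support [{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        e1 = np.interp(wl, self.wavelengths, self.eps_hbo2)
        e2 = np.interp(wl, self.wavelengths, self.eps_hb)
        return e1, e2


def _gauss(wl, center, width):
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def synthetic_extinction(wavelengths=None) -> ExtinctionTable:
    """Build the synthetic analytic hemoglobin extinction table.

    Parameters
    ----------
    wavelengths : array-like, nm, optional
        Grid to evaluate on; defaults to 1-nm spacing over 420-700 nm.
    """
    if wavelengths is None:
        wavelengths = np.arange(WL_MIN, WL_MAX + 1.0, 1.0)
    wl = np.asarray(wavelengths, float)
    # HbO2: Soret tail + 542/577 nm Q-bands, small red floor.
    eps_hbo2 = (
        300.0
        + 70000.0 * np.exp(-np.clip(wl - 450.0, 0.0, None) / 22.0)
        + 33000.0 * _gauss(wl, 542.0, 11.0)
        + 31000.0 * _gauss(wl, 577.0, 9.0)
    )
    # Hb: heavier Soret tail + single broad 555 nm band, higher red floor.
    eps_hb = (
        2500.0
        + 90000.0 * np.exp(-np.clip(wl - 450.0, 0.0, None) / 30.0)
        + 42000.0 * _gauss(wl, 555.0, 22.0)
    )
    return ExtinctionTable(wl, eps_hbo2, eps_hb)


def load_extinction_csv(path) -> ExtinctionTable:
    """Load a table from CSV with columns wavelength_nm, eps_hbo2, eps_hb."""
    df = pd.read_csv(path)
    return ExtinctionTable(
        df["wavelength_nm"].to_numpy(float),
        df["eps_hbo2"].to_numpy(float),
        df["eps_hb"].to_numpy(float),
    )
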