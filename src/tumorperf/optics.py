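"""Diffuse reflectance calibration, artifact rejection and spectral inversion.

Raw endoscopic spectra are calibrated against a dark measurement and a 5%
reflectance standard, screened for acquisition artifacts, and inverted to
tissue perfusion parameters (total hemoglobin tHb, oxygen saturation StO2,
reduced-scattering amplitude ``a`` and power ``b``) by bounded least squares
against a forward reflectance model.  The forward model is a closed-form
surrogate R(mu_a, mu_s') that is monotone decreasing in absorption and
increasing in reduced scattering; it can be evaluated directly or through a
precomputed lookup table (LUT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import least_squares

from .extinction import HEMOGLOBIN_MOLAR_MASS, ExtinctionTable, synthetic_extinction

log = logging.getLogger(__name__)

#: Default wavelength fit range, nm: covers the Soret shoulder and both
#: Q-bands (500-575 nm) while avoiding the deep-UV and NIR edges.
DEFAULT_FIT_RANGE = (450.0, 650.0)

#: Scattering reference wavelength, nm.
LAMBDA0 = 630.0

#: Detector saturation level, counts (16-bit ADC).
SATURATION_LEVEL = 65535.0


@dataclass
class Spectrum:
    """One reflectance measurement on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "intensity": self.intensities}
        )

    @classmethod
    def from_csv(cls, path, **meta) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(), meta)


@dataclass(frozen=True)
class OpticalModelParams:
    """Tissue model parameters.

    thb : total hemoglobin, g/L (>= 0)
    sto2 : oxygen saturation fraction in [0, 1]
    a : reduced scattering at 630 nm, 1/cm (> 0)
    b : scattering power (>= 0)
    """

    thb: float
    sto2: float
    a: float
    b: float

    def __post_init__(self):
        if self.thb < 0:
            raise ValueError("thb must be >= 0")
        if not 0.0 <= self.sto2 <= 1.0:
            raise ValueError("sto2 must lie in [0, 1]")
        if self.a <= 0:
            raise ValueError("scattering amplitude a must be > 0")
        if self.b < 0:
            raise ValueError("scattering power b must be >= 0")


def derive_perfusion(params: OpticalModelParams) -> dict:
    """Perfusion metrics from fitted parameters; HbO2 + HbO = tHb exactly."""
    hbo2 = params.sto2 * params.thb
    hbo = (1.0 - params.sto2) * params.thb
    return {"StO2": params.sto2, "tHb": params.thb, "HbO2": hbo2, "HbO": hbo}


def mu_a(params: OpticalModelParams, wavelengths, ext: ExtinctionTable) -> np.ndarray:
    """Absorption coefficient, 1/cm, from hemoglobin content and saturation."""
    eps_hbo2, eps_hb = ext.interp(wavelengths)
    conc = params.thb / HEMOGLOBIN_MOLAR_MASS  # mol/L
    return np.log(10.0) * conc * (
        params.sto2 * eps_hbo2 + (1.0 - params.sto2) * eps_hb
    )


def mu_s_prime(params: OpticalModelParams, wavelengths) -> np.ndarray:
    """Reduced scattering, 1/cm: power law a * (lambda/630 nm)^(-b)."""
    wl = np.asarray(wavelengths, float)
    return params.a * (wl / LAMBDA0) ** (-params.b)


@dataclass(frozen=True)
class SurrogateModel:
    """Closed-form diffuse reflectance surrogate.

    R(mu_a, mu_s') = mu_s' / (mu_s' + k1 * mu_a) * exp(-k2 * sqrt(mu_a mu_s') * d)

    The albedo-like first factor carries most of the absorption contrast; the
    exponential is a weak pathlength correction.  With the default constants
    R is strictly decreasing in mu_a and strictly increasing in mu_s' over
    mu_a in [0.01, 50] and mu_s' in [1, 50] 1/cm.  d is in cm.
    """

    k1: float = 8.0
    k2: float = 0.4
    d: float = 0.01

    def __call__(self, mua, musp):
        mua = np.asarray(mua, float)
        musp = np.asarray(musp, float)
        albedo = musp / (musp + self.k1 * mua)
        return albedo * np.exp(-self.k2 * np.sqrt(mua * musp) * self.d)


def forward_reflectance(
    params: OpticalModelParams, wavelengths, ext: ExtinctionTable, model
) -> np.ndarray:
    """Model reflectance at `wavelengths` for tissue parameters `params`.

    `model` is any callable R(mu_a, mu_s') — the surrogate or a LUT.
    """
    return np.asarray(model(mu_a(params, wavelengths, ext), mu_s_prime(params, wavelengths)))


# ---------------------------------------------------------------------------
# Lookup table


@dataclass(frozen=True)
class LUTGridSpec:
    mua_range: tuple = (0.01, 50.0)
    musp_range: tuple = (1.0, 50.0)
    n_mua: int = 64
    n_musp: int = 48


class LUT:
    """Reflectance lookup table over (mu_a, mu_s'), bilinear in (log10 mu_a, mu_s').

    Construction verifies the physical monotonicity invariants on the nodes:
    reflectance strictly decreasing in mu_a at fixed mu_s' and strictly
    increasing in mu_s' at fixed mu_a.
    """

    def __init__(self, mua_grid, musp_grid, values):
        self.mua_grid = np.asarray(mua_grid, float)
        self.musp_grid = np.asarray(musp_grid, float)
        self.values = np.asarray(values, float)  # shape (n_mua, n_musp)
        if self.values.shape != (self.mua_grid.size, self.musp_grid.size):
            raise ValueError("LUT value shape mismatch")
        if np.any(self.values <= 0):
            raise ValueError("LUT reflectance must be positive")
        if np.any(np.diff(self.values, axis=0) >= 0):
            raise ValueError("surrogate not strictly decreasing in mu_a on grid")
        if np.any(np.diff(self.values, axis=1) <= 0):
            raise ValueError("surrogate not strictly increasing in mu_s' on grid")
        self._interp = RegularGridInterpolator(
            (np.log10(self.mua_grid), self.musp_grid),
            self.values,
            method="linear",
            bounds_error=True,
        )

    def __call__(self, mua, musp):
        mua = np.asarray(mua, float)
        musp = np.asarray(musp, float)
        pts = np.stack([np.log10(mua), np.broadcast_to(musp, mua.shape)], axis=-1)
        return self._interp(pts)


def build_lut(grid_spec: LUTGridSpec = LUTGridSpec(), surrogate=None) -> LUT:
    """Tabulate the forward surrogate on a log-spaced mu_a x linear mu_s' grid."""
    surrogate = surrogate or SurrogateModel()
    mua = np.logspace(
        np.log10(grid_spec.mua_range[0]), np.log10(grid_spec.mua_range[1]), grid_spec.n_mua
    )
    musp = np.linspace(*grid_spec.musp_range, grid_spec.n_musp)
    vals = surrogate(mua[:, None], musp[None, :])
    return LUT(mua, musp, vals)


# ---------------------------------------------------------------------------
# Calibration and artifact rejection


def _common_grid(sample: Spectrum, other: Spectrum) -> np.ndarray:
    """Interpolate `other` onto the sample wavelength grid."""
    return np.interp(sample.wavelengths, other.wavelengths, other.intensities)


def calibrate(
    sample: Spectrum,
    dark: Spectrum,
    reference: Spectrum,
    ref_reflectivity: float = 0.05,
    fit_range: tuple = DEFAULT_FIT_RANGE,
) -> Spectrum:
    """Convert raw counts to calibrated reflectance.

    R(lambda) = ref_reflectivity * (I_sample - I_dark) / (I_ref - I_dark),
    restricted to `fit_range`.  The reference measurement is of a standard of
    known reflectivity (default 5%).
    """
    lo, hi = fit_range
    keep = (sample.wavelengths >= lo) & (sample.wavelengths <= hi)
    wl = sample.wavelengths[keep]
    i_sample = sample.intensities[keep]
    i_dark = _common_grid(sample, dark)[keep]
    i_ref = _common_grid(sample, reference)[keep]
    denom = i_ref - i_dark
    if np.any(denom <= 0):
        bad = wl[np.argmin(denom)]
        raise ValueError(
            f"reference minus dark non-positive at {bad:.1f} nm; cannot calibrate"
        )
    refl = ref_reflectivity * (i_sample - i_dark) / denom
    meta = dict(sample.meta)
    meta["raw_max"] = float(np.max(sample.intensities))
    meta["calibrated"] = True
    return Spectrum(wl, refl, meta)


@dataclass(frozen=True)
class ArtifactThresholds:
    """Screening thresholds for acquisition artifacts.

    saturation_level : raw counts at/above which the detector clipped
    low_signal_floor : minimum acceptable median calibrated reflectance
    rmse_max : post-fit residual cap (applied after inversion)
    """

    saturation_level: float = SATURATION_LEVEL
    low_signal_floor: float = 0.005
    rmse_max: float = 0.02


def reject_artifacts(spectra, thresholds: ArtifactThresholds = ArtifactThresholds()):
    """Split calibrated spectra into (retained, rejected-with-reason) lists.

    Rejection reasons: "saturation" if any raw count reached the detector
    ceiling, "low signal" if the median calibrated reflectance sits below the
    floor.  The residual-based criterion is applied downstream, after
    inversion.  An empty retained set is legal and logged.
    """
    retained, rejected = [], []
    for sp in spectra:
        raw_max = sp.meta.get("raw_max", 0.0)
        if raw_max >= thresholds.saturation_level:
            rejected.append((sp, "saturation"))
        elif np.median(sp.intensities) < thresholds.low_signal_floor:
            rejected.append((sp, "low signal"))
        else:
            retained.append(sp)
    if not retained:
        log.warning("artifact screening rejected all %d spectra", len(rejected))
    return retained, rejected


def average_spectra(spectra) -> Spectrum:
    """Mean of calibrated spectra on a shared grid (per tumor-visit pooling)."""
    if not spectra:
        raise ValueError("cannot average an empty spectrum collection")
    wl = spectra[0].wavelengths
    stack = [spectra[0].intensities]
    for sp in spectra[1:]:
        stack.append(np.interp(wl, sp.wavelengths, sp.intensities))
    meta = dict(spectra[0].meta)
    meta["n_averaged"] = len(spectra)
    return Spectrum(wl, np.mean(stack, axis=0), meta)


# ---------------------------------------------------------------------------
# Inversion


@dataclass(frozen=True)
class FitBounds:
    thb: tuple = (0.1, 100.0)  # g/L
    sto2: tuple = (0.0, 1.0)
    a: tuple = (1.0, 60.0)  # 1/cm at 630 nm
    b: tuple = (0.0, 3.0)

    @property
    def lower(self):
        return np.array([self.thb[0], self.sto2[0], self.a[0], self.b[0]])

    @property
    def upper(self):
        return np.array([self.thb[1], self.sto2[1], self.a[1], self.b[1]])


#: Small fixed multi-start grid (thb, sto2, a, b) — coarse coverage of the
#: physiological range to avoid local minima of the spectral misfit.
DEFAULT_INITS = (
    (5.0, 0.3, 10.0, 1.0),
    (15.0, 0.6, 20.0, 1.2),
    (30.0, 0.9, 30.0, 0.8),
    (10.0, 0.5, 40.0, 2.0),
)


@dataclass
class PerfusionEstimate:
    """Inversion result for one (averaged) calibrated spectrum."""

    params: OpticalModelParams | None
    rmse: float
    n_points: int
    converged: bool
    rejected: bool = False
    reason: str | None = None
    meta: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "tumor_id": self.meta.get("tumor_id"),
            "group": self.meta.get("group"),
            "week": self.meta.get("week"),
            "rmse": self.rmse,
            "n_points": self.n_points,
            "converged": self.converged,
            "rejected": self.rejected,
            "reason": self.reason,
        }
        if self.params is not None:
            row.update(derive_perfusion(self.params))
            row["scatter_a"] = self.params.a
            row["scatter_b"] = self.params.b
        else:
            row.update({"StO2": np.nan, "tHb": np.nan, "HbO2": np.nan, "HbO": np.nan,
                        "scatter_a": np.nan, "scatter_b": np.nan})
        return row


def invert_spectrum(
    calibrated: Spectrum,
    ext: ExtinctionTable | None = None,
    model=None,
    bounds: FitBounds = FitBounds(),
    inits=DEFAULT_INITS,
    rmse_max: float | None = None,
) -> PerfusionEstimate:
    """Bounded least-squares inversion of a calibrated reflectance spectrum.

    Minimizes sum over wavelengths of [R_meas - R_model(theta)]^2 for
    theta = (tHb, StO2, a, b), restarting from a small fixed grid of initial
    values and keeping the best fit.  If `rmse_max` is given, fits whose
    residual exceeds it are flagged rejected (artifact criterion applied
    post-fit).
    """
    ext = ext or synthetic_extinction()
    model = model or SurrogateModel()
    wl = calibrated.wavelengths
    r_meas = calibrated.intensities
    eps_hbo2, eps_hb = ext.interp(wl)
    ln10_over_m = np.log(10.0) / HEMOGLOBIN_MOLAR_MASS
    wl_pow = wl / LAMBDA0

    def residuals(theta):
        thb, sto2, a, b = theta
        mua = ln10_over_m * thb * (sto2 * eps_hbo2 + (1.0 - sto2) * eps_hb)
        musp = a * wl_pow ** (-b)
        return np.asarray(model(mua, musp)) - r_meas

    best = None
    for x0 in inits:
        x0 = np.clip(np.asarray(x0, float), bounds.lower, bounds.upper)
        try:
            sol = least_squares(
                residuals, x0, bounds=(bounds.lower, bounds.upper),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return PerfusionEstimate(
            params=None, rmse=np.inf, n_points=wl.size, converged=False,
            rejected=True, reason="non-convergence", meta=dict(calibrated.meta),
        )
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    params = OpticalModelParams(*best.x)
    est = PerfusionEstimate(
        params=params, rmse=rmse, n_points=wl.size, converged=True,
        meta=dict(calibrated.meta),
    )
    if rmse_max is not None and rmse > rmse_max:
        est.rejected = True
        est.reason = "high residual"
        est.params = None
    return est


def fold_change(perfusion: pd.DataFrame, baseline_week: int = 1,
                metrics=("StO2", "tHb", "HbO2", "HbO")) -> pd.DataFrame:
    """Per-tumor fold change of each perfusion metric relative to baseline week.

    Tumors missing a positive baseline value are excluded (and logged).
    Returns a tidy frame (tumor_id, group, week, metric, value).
    """
    rows = []
    for tumor, sub in perfusion.groupby("tumor_id"):
        base = sub[sub["week"] == baseline_week]
        if base.empty:
            log.info("tumor %s excluded from fold change: no week-%d baseline",
                     tumor, baseline_week)
            continue
        for metric in metrics:
            b = float(base[metric].iloc[0])
            if not np.isfinite(b) or b <= 0:
                log.info("tumor %s metric %s excluded: non-positive baseline %g",
                         tumor, metric, b)
                continue
            for _, rec in sub.iterrows():
                v = rec[metric]
                if not np.isfinite(v):
                    continue
                rows.append({
                    "tumor_id": tumor, "group": rec["group"], "week": rec["week"],
                    "metric": metric, "value": float(v) / b,
                })
    return pd.DataFrame(rows, columns=["tumor_id", "group", "week", "metric", "value"])
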