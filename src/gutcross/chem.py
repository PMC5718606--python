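"""Intestinal-environment chemistry: DOM spectral indices, IEC calibration, fingerprints.

Dissolved organic matter (DOM) chemistry works on microtiter absorbance
spectra of fecal supernatants. Absorbance A is converted to the Napierian
absorption coefficient a = 2.303*A/l (beam length l = 2/3 cm through a
microtiter well), and five indices are computed per sample:

* indole level indices a(217)/a(365) and a(287)/a(365) (pure ratios),
* SUVA254 = A(254)/TSOC (aromaticity),
* SViA420 = A(420)/TSOC (non-aromatic, colored fraction),
* cDOM = a(350)/TSOC (tannin-like anaerobic degradation products),
* TDLP9, the modeled sum of nine p-hydroxy/vanillyl/syringyl lignin phenols:
  ln(TDLP9) = -2.282*ln a(350) - 8.209*ln a(275) + 11.365*ln a(295) + 2.909.

TSOC is total soluble organic carbon per gram fecal dry matter and is taken
as a given input column. Undefined indices (non-positive absorption at a
required wavelength) propagate as NaN, never as silent zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NAPIERIAN_FACTOR = 2.303
DEFAULT_PATH_LENGTH_CM = 2.0 / 3.0

TDLP9_COEF_A350 = -2.282
TDLP9_COEF_A275 = -8.209
TDLP9_COEF_A295 = 11.365
TDLP9_INTERCEPT = 2.909


@dataclass
class AbsorbanceSpectrum:
    """One sample/dilution spectrum on a strictly increasing wavelength grid."""

    sample_id: str
    dilution: int
    wavelengths: np.ndarray
    absorbance: np.ndarray
    path_length: float = DEFAULT_PATH_LENGTH_CM
    tsoc: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.absorbance.size:
            raise ValueError("wavelength/absorbance grids must be 1-D and aligned")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")

    def at(self, wavelength: float) -> float:
        """Absorbance at the grid point nearest the requested wavelength."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.absorbance[i])


def napierian_spectrum(
    spectrum: AbsorbanceSpectrum, dilution_correct: bool = False
) -> np.ndarray:
    """Napierian absorption coefficients a(lambda) = 2.303 * A(lambda) / l.

    With ``dilution_correct`` the coefficients are multiplied by the dilution
    factor, i.e. returned on the undiluted-supernatant basis (per cm).
    """
    a = NAPIERIAN_FACTOR * spectrum.absorbance / spectrum.path_length
    if dilution_correct:
        a = a * spectrum.dilution
    return a


def select_dilution(
    spectra: list[AbsorbanceSpectrum],
    window: tuple[float, float] = (217.0, 420.0),
    target_range: tuple[float, float] = (0.05, 1.0),
) -> AbsorbanceSpectrum:
    """Pick the least-diluted spectrum whose peak absorbance over 217-420 nm
    falls in the photometrically reliable range [0.05, 1.0].

    Falls back to the spectrum nearest the range (with a warning) when no
    dilution qualifies.
    """
    if not spectra:
        raise ValueError("no spectra supplied")
    lo, hi = target_range

    def max_in_window(s: AbsorbanceSpectrum) -> float:
        mask = (s.wavelengths >= window[0]) & (s.wavelengths <= window[1])
        return float(s.absorbance[mask].max())

    in_range = [s for s in spectra if lo <= max_in_window(s) <= hi]
    if in_range:
        return min(in_range, key=lambda s: s.dilution)
    warnings.warn("no dilution in absorbance range; using nearest-to-range spectrum")

    def dist(s: AbsorbanceSpectrum) -> float:
        m = max_in_window(s)
        return lo - m if m < lo else m - hi

    return min(spectra, key=dist)


def tdlp9(a350: float, a275: float, a295: float) -> float:
    """Lignin-phenol sum from three Napierian absorption coefficients (per cm)."""
    if min(a350, a275, a295) <= 0:
        return float("nan")
    return float(
        np.exp(
            TDLP9_COEF_A350 * np.log(a350)
            + TDLP9_COEF_A275 * np.log(a275)
            + TDLP9_COEF_A295 * np.log(a295)
            + TDLP9_INTERCEPT
        )
    )


def dom_indices(
    spectrum: AbsorbanceSpectrum, tsoc: float | None = None, dilution_correct: bool = True
) -> pd.Series:
    """The five DOM indices for one spectrum.

    Ratio indices (indole, TDLP9 inputs) are computed on the Napierian
    coefficients; TSOC-normalized indices use the dilution-corrected values so
    all dilutions of a sample agree up to noise. Non-positive denominators
    yield NaN with a warning.
    """
    tsoc = spectrum.tsoc if tsoc is None else tsoc
    a = napierian_spectrum(spectrum, dilution_correct=dilution_correct)

    def a_at(w: float) -> float:
        i = int(np.argmin(np.abs(spectrum.wavelengths - w)))
        return float(a[i])

    A_at = spectrum.at
    dil = spectrum.dilution if dilution_correct else 1

    a365 = a_at(365.0)
    out = {}
    for name, num in (("indole_217_365", a_at(217.0)), ("indole_287_365", a_at(287.0))):
        if a365 <= 0 or num <= 0:
            warnings.warn(f"{name} undefined (non-positive absorption)")
            out[name] = float("nan")
        else:
            out[name] = num / a365
    if tsoc is None or tsoc <= 0:
        warnings.warn("TSOC missing or non-positive; SUVA/SViA/cDOM undefined")
        out["suva"] = out["svia"] = out["cdom"] = float("nan")
    else:
        out["suva"] = A_at(254.0) * dil / tsoc
        out["svia"] = A_at(420.0) * dil / tsoc
        out["cdom"] = a_at(350.0) / tsoc
    val = tdlp9(a_at(350.0), a_at(275.0), a_at(295.0))
    if np.isnan(val):
        warnings.warn("tdlp9 undefined (non-positive absorption coefficient)")
    out["tdlp9"] = val
    return pd.Series(out)


def dom_indices_table(
    spectra_long: pd.DataFrame,
    tsoc: pd.Series | pd.DataFrame,
    path_length: float = DEFAULT_PATH_LENGTH_CM,
) -> pd.DataFrame:
    """Per-sample DOM indices from a long-format spectra table.

    For each sample the working dilution is chosen by :func:`select_dilution`
    and indices are computed on the dilution-corrected coefficients.
    """
    if isinstance(tsoc, pd.DataFrame):
        tsoc = tsoc.iloc[:, 0]
    rows = {}
    for sample, grp in spectra_long.groupby("sample", sort=False):
        spectra = []
        for dil, sub in grp.groupby("dilution"):
            sub = sub.sort_values("wavelength_nm")
            spectra.append(
                AbsorbanceSpectrum(
                    sample_id=str(sample),
                    dilution=int(dil),
                    wavelengths=sub["wavelength_nm"].to_numpy(),
                    absorbance=sub["absorbance"].to_numpy(),
                    path_length=path_length,
                )
            )
        chosen = select_dilution(spectra)
        rows[sample] = dom_indices(chosen, tsoc=float(tsoc.get(sample, np.nan)))
    out = pd.DataFrame(rows).T
    out.index.name = "sample"
    return out


@dataclass
class CalibrationResult:
    slope: float
    intercept: float
    r_squared: float
    calibrated: pd.Series
    drift: pd.DataFrame
    flagged_batches: list[int]


def calibrate_conductivity(
    samples: pd.DataFrame,
    standards: pd.DataFrame,
    r2_warn: float = 0.99,
    drift_flag: float = 0.05,
) -> CalibrationResult:
    """Map raw conductivity readings through a linear standards fit; report drift.

    ``standards`` needs columns batch/nominal/reading (1 M KCl and its 10-fold
    dilutions, triplicate per batch); ``samples`` needs sample_id/batch/reading.
    Drift per batch is the relative change of the mean repeated-standard
    reading versus the first batch, flagged above ``drift_flag``.
    """
    if standards["nominal"].nunique() < 2:
        raise ValueError("need standards at >= 2 concentration levels")
    fit = stats.linregress(standards["nominal"], standards["reading"])
    r2 = float(fit.rvalue**2)
    if r2 < r2_warn:
        warnings.warn(f"standards fit R^2 = {r2:.4f} below {r2_warn}")
    calibrated = (samples["reading"] - fit.intercept) / fit.slope
    calibrated = pd.Series(calibrated.to_numpy(), index=samples["sample_id"].to_numpy(), name="iec")

    # drift: per-batch mean reading of each standard level, relative to batch 0
    per_batch = standards.groupby(["nominal", "batch"])["reading"].mean().unstack("batch")
    rel = per_batch.div(per_batch.iloc[:, 0], axis=0) - 1.0
    drift = rel.abs().max(axis=0).rename("max_rel_drift").reset_index()
    flagged = drift.loc[drift["max_rel_drift"] > drift_flag, "batch"].astype(int).tolist()
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        calibrated=calibrated,
        drift=drift,
        flagged_batches=flagged,
    )


def fingerprint_profile(peaks: pd.Series | np.ndarray) -> tuple[float, pd.Series]:
    """Total content and relative peak-abundance profile of one HPLC fingerprint.

    The profile is a composition vector and feeds the alpha-diversity suite
    (profile mode) exactly as a community vector would.
    """
    areas = pd.Series(peaks, dtype=float)
    if (areas < 0).any():
        raise ValueError("peak areas must be non-negative")
    total = float(areas.sum())
    if total == 0:
        raise ValueError("all-zero peak table")
    return total, areas / total


def fingerprint_table(peaks: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample totals and profiles for a samples x peaks area table."""
    totals = peaks.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero peak row(s)")
    return totals, peaks.div(totals, axis=0)
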