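"""Survival-Yield and breakdown curves from energy-resolved spectra.

The Survival Yield at one collision voltage is the precursor peak's share
of the total ion current,

    SY = I_precursor / (I_precursor + sum I_fragment),

so SY = 1 means no fragmentation and SY -> 0 means complete precursor
depletion.  A breakdown curve applies the same TIC-normalised measure to a
chosen fragment m/z across the voltage ramp.  Peak intensity at a target
m/z is the sum of all centroids within a tolerance window (default
0.05 Th); the absence of a peak is meaningful data (fraction 0), since a
diagnostic ion's absence in the other isomers is what makes it diagnostic.

Replicates at a voltage are averaged after TIC normalisation so unequal
total ion currents do not weight them (SY itself is scale-invariant, so
this only matters for raw exports).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSeries

__all__ = [
    "survival_yield",
    "SurvivalYieldCurve",
    "BreakdownCurve",
    "sy_curve",
    "breakdown_curve",
    "fit_sigmoid",
]


def _window_fraction(s: Spectrum, target_mz: float, tol: float) -> float:
    if len(s) == 0:
        raise ValueError("empty spectrum")
    total = s.tic
    if total <= 0:
        raise ValueError("spectrum has zero total ion current")
    sel = np.abs(s.mz - target_mz) <= tol
    return float(s.intensity[sel].sum() / total)


def survival_yield(s: Spectrum, precursor_mz: float, tol: float = 0.05) -> float:
    """Precursor intensity over TIC; isotope peaks beyond ``tol`` of the
    precursor m/z count as fragments (explicit, configurable policy)."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    return _window_fraction(s, precursor_mz, tol)


@dataclass
class SurvivalYieldCurve:
    voltages: np.ndarray
    values: np.ndarray
    peptide_id: str

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("SY values must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"voltage": self.voltages, "value": self.values})

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class BreakdownCurve(SurvivalYieldCurve):
    target_mz: float = float("nan")
    tol: float = float("nan")


def _per_voltage(series: SpectrumSeries, target_mz: float, tol: float):
    seen: set[tuple[float, int]] = set()
    for s in series.spectra:
        key = (s.meta.voltage, s.meta.replicate)
        if key in seen:
            raise ValueError(f"duplicate voltage/replicate pair {key}")
        seen.add(key)
    voltages = series.voltages
    values = []
    for v in voltages:
        fractions = [
            _window_fraction(s, target_mz, tol) for s in series.at_voltage(v)
        ]
        values.append(float(np.mean(fractions)))
    return np.array(voltages), np.array(values)


def sy_curve(series: SpectrumSeries, tol: float = 0.05) -> SurvivalYieldCurve:
    """One SY point per voltage (replicates averaged), sorted by voltage."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    v, y = _per_voltage(series, series.precursor_mz, tol)
    return SurvivalYieldCurve(v, y, series.peptide_id)


def breakdown_curve(
    series: SpectrumSeries, target_mz: float, tol: float = 0.05
) -> BreakdownCurve:
    """TIC-normalised intensity of one fragment m/z across the voltage ramp."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    v, y = _per_voltage(series, target_mz, tol)
    return BreakdownCurve(v, y, series.peptide_id, target_mz=target_mz, tol=tol)


def fit_sigmoid(curve: SurvivalYieldCurve) -> tuple[float, float]:
    """Fit SY(V) = 1/(1+exp((V-V50)/w)); returns (V50, w).

    A convenience for summarising depletion curves; the diagnostic workflow
    itself reads curves directly.
    """
    from scipy.optimize import curve_fit

    def logistic(v, v50, w):
        return 1.0 / (1.0 + np.exp((v - v50) / w))

    v50_guess = float(np.interp(0.5, curve.values[::-1], curve.voltages[::-1]))
    popt, _ = curve_fit(
        logistic, curve.voltages, curve.values, p0=[v50_guess, 2.0], maxfev=10000
    )
    return float(popt[0]), float(popt[1])
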