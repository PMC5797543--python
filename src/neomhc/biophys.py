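"""Peptide masses and Boltzmann melt-curve fitting.

Theoretical peptide masses come from the standard residue-mass tables
(average and monoisotopic) plus one water; they are the expected values
against which LC-MS observed masses of peptide/MHC preparations are
checked.

Differential scanning fluorimetry (DSF) melt curves are fitted with the
Boltzmann sigmoid

    F(T) = F_min + (F_max - F_min) / (1 + exp((Tm - T) / k))

where Tm is the melting temperature (curve midpoint, degC) and k the slope
parameter (degC). The default scan emulates a 25-95 degC ramp.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

from neomhc.chemdata import (RESIDUE_MASS_AVERAGE, RESIDUE_MASS_MONO,
                             WATER_AVERAGE, WATER_MONO)


def peptide_mass(sequence: str, kind: str = "average") -> float:
    """Theoretical peptide mass in Da (sum of residue masses + water),
    rounded to 2 decimals."""
    if not sequence:
        raise ValueError("empty sequence")
    if kind == "average":
        table, water = RESIDUE_MASS_AVERAGE, WATER_AVERAGE
    elif kind == "monoisotopic":
        table, water = RESIDUE_MASS_MONO, WATER_MONO
    else:
        raise ValueError(f"unknown mass kind {kind!r}")
    try:
        total = sum(table[a] for a in sequence) + water
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None
    return round(total, 2)


@dataclasses.dataclass
class MeltCurve:
    temperatures: np.ndarray  # degC, strictly increasing
    fluorescence: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence lengths differ")
        if len(self.temperatures) < 10:
            raise ValueError("need at least 10 points to fit a melt curve")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclasses.dataclass
class BoltzmannFit:
    f_min: float
    f_max: float
    tm: float  # degC
    slope: float  # degC
    rss: float
    converged: bool


def boltzmann(t: np.ndarray, f_min: float, f_max: float, tm: float,
              k: float) -> np.ndarray:
    return f_min + (f_max - f_min) / (1.0 + np.exp((tm - t) / k))


class FitError(RuntimeError):
    pass


def fit_boltzmann(curve: MeltCurve,
                  initial_guess: tuple[float, float, float, float] | None
                  = None) -> BoltzmannFit:
    """Least-squares Boltzmann sigmoid fit.

    The automatic initial guess uses (min F, max F, T at max dF/dT, 2 degC).
    Non-convergence or a Tm outside the scanned range raises FitError with
    diagnostics.
    """
    t, f = curve.temperatures, curve.fluorescence
    if initial_guess is None:
        df = np.gradient(f, t)
        tm0 = float(t[np.argmax(df)])
        initial_guess = (float(f.min()), float(f.max()), tm0, 2.0)
    span = float(f.max() - f.min())
    if span <= 0 or span < 1e-9 * max(1.0, abs(float(f.max()))):
        raise FitError("flat curve: no unfolding transition to fit")
    try:
        popt, _ = curve_fit(boltzmann, t, f, p0=initial_guess, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    f_min, f_max, tm, k = (float(x) for x in popt)
    if f_min > f_max:  # equivalent parametrisation; normalise
        f_min, f_max, k = f_max, f_min, -k
    resid = f - boltzmann(t, f_min, f_max, tm, k)
    rss = float(np.sum(resid ** 2))
    if not (t.min() <= tm <= t.max()):
        raise FitError(
            f"fitted Tm {tm:.2f} degC outside the scanned range "
            f"[{t.min():.1f}, {t.max():.1f}]")
    if abs(f_max - f_min) < 1e-12:
        raise FitError("fit collapsed to a flat curve")
    return BoltzmannFit(f_min=f_min, f_max=f_max, tm=tm, slope=k, rss=rss,
                        converged=True)


def simulate_melt_curve(f_min: float, f_max: float, tm: float, k: float,
                        t_start: float = 25.0, t_end: float = 95.0,
                        step: float = 0.5, noise_sd: float = 0.0,
                        seed: int = 0) -> MeltCurve:
    """Seeded synthetic melt curve from the Boltzmann model plus Gaussian
    noise; Tm must lie inside the scanned range."""
    if not (t_start < tm < t_end):
        raise ValueError(f"Tm {tm} outside scan range ({t_start}, {t_end})")
    if f_min >= f_max:
        raise ValueError("F_min must be below F_max")
    t = np.arange(t_start, t_end + step / 2, step)
    f = boltzmann(t, f_min, f_max, tm, k)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return MeltCurve(temperatures=t, fluorescence=f)
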