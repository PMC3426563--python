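"""Sequential three-state thermodynamics (N <-> I <-> U) and deconvolution of
temperature-series spectra into pure state spectra.

Populations follow from the two transition free energies: with
K1 = exp(-dG1/RT) and K2 = exp(-dG2/RT),
X_N = 1/(1 + K1 + K1*K2), X_I = K1*X_N, X_U = K1*K2*X_N. Free energies are in
kJ/mol, temperatures in Kelvin. The observed matrix Y(lambda, T) is modelled
as a population-weighted combination of the state spectra, solved wavelength
by wavelength in least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "R_KJ",
    "ThreeStateModel",
    "SpectraSeries",
    "StateSpectra",
    "gibbs_helmholtz",
    "populations",
    "deconvolute_spectra",
]

R_KJ = 8.314462618e-3  # gas constant, kJ/(mol K)


def gibbs_helmholtz(T, dH: float, Tm: float, dCp: float = 0.0):
    """dG(T) = dH (1 - T/Tm) - dCp (Tm - T + T ln(T/Tm)), all in kJ/mol."""
    T = np.asarray(T, dtype=float)
    return dH * (1.0 - T / Tm) - dCp * (Tm - T + T * np.log(T / Tm))


@dataclass
class ThreeStateModel:
    """dG1 (N<->I) and dG2 (I<->U) versus temperature.

    Either tabulated: ``temperatures`` (K, strictly increasing) with matching
    ``dG1``/``dG2`` arrays (kJ/mol, linearly interpolated), or parametric:
    ``gh1``/``gh2`` as (dH, Tm[, dCp]) Gibbs-Helmholtz tuples.
    """

    temperatures: np.ndarray | None = None
    dG1: np.ndarray | None = None
    dG2: np.ndarray | None = None
    gh1: tuple | None = None
    gh2: tuple | None = None

    def __post_init__(self) -> None:
        tabulated = self.temperatures is not None
        parametric = self.gh1 is not None and self.gh2 is not None
        if not tabulated and not parametric:
            raise ValueError("give either tabulated dG arrays or Gibbs-Helmholtz parameters")
        if tabulated:
            self.temperatures = np.asarray(self.temperatures, dtype=float)
            if np.any(self.temperatures <= 0) or np.any(np.diff(self.temperatures) <= 0):
                raise ValueError("temperatures must be positive and strictly increasing")
            self.dG1 = np.asarray(self.dG1, dtype=float)
            self.dG2 = np.asarray(self.dG2, dtype=float)
            if self.dG1.shape != self.temperatures.shape or self.dG2.shape != self.temperatures.shape:
                raise ValueError("dG arrays must match the temperature grid")

    def free_energies(self, T) -> tuple[np.ndarray, np.ndarray]:
        T = np.atleast_1d(np.asarray(T, dtype=float))
        if self.gh1 is not None and self.gh2 is not None:
            return gibbs_helmholtz(T, *self.gh1), gibbs_helmholtz(T, *self.gh2)
        if np.any(T < self.temperatures[0] - 1e-9) or np.any(T > self.temperatures[-1] + 1e-9):
            raise ValueError("temperature outside the tabulated model range")
        g1 = np.interp(T, self.temperatures, self.dG1)
        g2 = np.interp(T, self.temperatures, self.dG2)
        return g1, g2


def populations(model: ThreeStateModel, T) -> np.ndarray:
    """State populations (X_N, X_I, X_U) at temperature(s) T (K).

    Returns shape (3,) for a scalar T, else (len(T), 3); rows sum to 1.
    Computed in log space, so arbitrarily large |dG| values are safe.
    """
    scalar = np.isscalar(T)
    T = np.atleast_1d(np.asarray(T, dtype=float))
    g1, g2 = model.free_energies(T)
    if not (np.all(np.isfinite(T)) and np.all(T > 0)):
        raise ValueError("temperatures must be positive and finite")
    with np.errstate(invalid="ignore"):
        w = np.column_stack([np.zeros_like(T), -g1 / (R_KJ * T), -(g1 + g2) / (R_KJ * T)])
    if np.any(np.isnan(w)):
        raise ValueError("non-finite free energy")
    # +/- inf log-weights encode fully (de)populated states
    pos_inf = np.isposinf(w)
    x = np.where(pos_inf, 1.0, np.exp(np.where(pos_inf, -np.inf, w)
                                      - logsumexp(np.where(pos_inf, -np.inf, w),
                                                  axis=1, keepdims=True)))
    rows_inf = pos_inf.any(axis=1)
    if rows_inf.any():
        x[rows_inf] = pos_inf[rows_inf].astype(float)
    x = x / x.sum(axis=1, keepdims=True)
    return x[0] if scalar else x


@dataclass
class SpectraSeries:
    wavelengths: np.ndarray        # nm
    temperatures: np.ndarray       # K
    Y: np.ndarray                  # (n_wavelengths, n_temperatures)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (len(self.wavelengths), len(self.temperatures)):
            raise ValueError("Y must be (n_wavelengths, n_temperatures)")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("Y contains non-finite values")


@dataclass
class StateSpectra:
    wavelengths: np.ndarray
    Y_native: np.ndarray
    Y_intermediate: np.ndarray
    Y_unfolded: np.ndarray
    populations: np.ndarray            # (n_temperatures, 3)
    baseline_slopes: np.ndarray | None  # (n_wavelengths, 3) for linear_T
    residual: np.ndarray               # (n_wavelengths, n_temperatures)
    condition_number: float

    def reconstruct(self, temperatures: np.ndarray) -> np.ndarray:
        """Population-weighted model spectra at the fitted temperatures."""
        x = self.populations
        states = np.column_stack([self.Y_native, self.Y_intermediate, self.Y_unfolded])
        y = states @ x.T
        if self.baseline_slopes is not None:
            y = y + self.baseline_slopes @ (x * temperatures[:, None]).T
        return y


def deconvolute_spectra(series: SpectraSeries, model: ThreeStateModel,
                        baseline: str = "constant",
                        max_condition: float = 1e8) -> StateSpectra:
    """Resolve a temperature series into pure N/I/U spectra.

    Solves, per wavelength, Y(lambda, .) = X @ y_states(lambda) where X is the
    (n_T, 3) population matrix from the model. ``baseline='linear_T'`` adds a
    per-state linear temperature term (6 parameters per wavelength).
    Rank-deficient population matrices (collinear populations) raise, naming
    the condition number.
    """
    T = series.temperatures
    if len(T) < 3:
        raise ValueError("need >= 3 temperatures for a three-state deconvolution")
    x = populations(model, T)
    if baseline == "constant":
        design = x
    elif baseline == "linear_T":
        if len(T) < 6:
            raise ValueError("linear_T baseline needs >= 6 temperatures")
        design = np.hstack([x, x * T[:, None]])
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    cond = float(np.linalg.cond(design))
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(
            f"population design matrix is rank deficient (condition number {cond:.3g}); "
            "the temperature series does not separate the three states"
        )
    coef, *_ = np.linalg.lstsq(design, series.Y.T, rcond=None)
    coef = coef.T  # (n_wavelengths, n_params)
    slopes = coef[:, 3:6] if baseline == "linear_T" else None
    fitted = (design @ coef.T).T
    return StateSpectra(
        wavelengths=series.wavelengths,
        Y_native=coef[:, 0],
        Y_intermediate=coef[:, 1],
        Y_unfolded=coef[:, 2],
        populations=x,
        baseline_slopes=slopes,
        residual=series.Y - fitted,
        condition_number=cond,
    )
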