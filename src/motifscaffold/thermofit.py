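"""Thermal-unfolding analysis: MRE, two-state melts, nanoDSF fits, DSC.

Temperatures cross the public interface in degrees Celsius (melt curves are
recorded that way) and are converted to Kelvin internally for all
thermodynamics; R = 8.314 J/mol/K, enthalpies in kJ/mol.

Models
------
* Mean residue ellipticity:  MRE = theta * MW / (10 * n * c * d), with
  theta the observed CD signal (mdeg), MW the molecular weight (Da), n the
  number of residues, c the concentration (g/L) and d the path length (cm).
* Two-state van't Hoff melt:  K(T) = exp[-(dH/R)(1/T - 1/Tm)];
  y(T) = [(yN + mN*T) + (yD + mD*T) * K] / (1 + K) with linear baselines.
* Heat-capacity-corrected (nanoDSF) melt:
  dG(T) = dH*(1 - T/Tm) - dCp*[(Tm - T) + T*ln(T/Tm)]  (Gibbs-Helmholtz),
  folded fraction f = 1 / (1 + exp(-dG/RT)), with a quadratic native
  baseline a0 + a1*dT^2 and constant denatured baseline b1 (dT = T - Tref).
  The baseline assignment is a documented reconstruction; fix parameters to
  change it.
* DSC excess heat capacity: Cp(T) = dH^2/(R T^2) * K/(1+K)^2, peaking at Tm
  with integrated area dH.

A synthetic melt-curve generator (`simulate_melt`) produces model curves
plus i.i.d. Gaussian noise; published DSC parameter sets for the designed
proteins and the wild-type enzyme ship as `DSC_PARAMS` for round-trip
studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "R_KJ",
    "CELSIUS_OFFSET",
    "MREParams",
    "TwoStateParams",
    "StabilityParams",
    "MeltCurve",
    "FitResult",
    "DenaturantSeries",
    "DSC_PARAMS",
    "mre",
    "two_state_signal",
    "fit_two_state",
    "dsc_excess_cp",
    "stability_signal",
    "gibbs_energy",
    "fit_stability",
    "extrapolate_tm0",
    "simulate_melt",
]

R_KJ = 8.314462618e-3  # gas constant, kJ/mol/K
CELSIUS_OFFSET = 273.15

#: Published DSC unfolding parameters (residue count, Tm degC, dH kJ/mol)
#: for the four characterised designs and the wild-type enzyme.
DSC_PARAMS: dict[str, tuple[int, float, float]] = {
    "dEngBF4": (300, 81.1, 193.0),
    "dEngBF5": (300, 99.9, 251.0),
    "dEngBF8": (300, 64.5, 410.0),
    "dEngBF9": (300, 68.0, 356.0),
    "EngBF": (1363, 68.2, 1120.0),
}


@dataclass
class MREParams:
    """Normalisation constants for mean residue ellipticity."""

    mw: float  # molecular weight, Da
    n_residues: int
    concentration: float  # g/L (= mg/mL)
    path_length: float  # cm

    def __post_init__(self) -> None:
        if min(self.mw, self.n_residues, self.concentration, self.path_length) <= 0:
            raise ValueError("all MRE parameters must be positive")


def mre(theta_mdeg, p: MREParams, mean_residue_weight: str = "n") -> np.ndarray | float:
    """Mean residue ellipticity (deg cm^2 dmol^-1) from a CD signal in mdeg.

    ``mean_residue_weight`` selects MW/n (default) or MW/(n-1) for the mean
    residue weight (peptide-bond counting); both conventions circulate.
    """
    n = p.n_residues if mean_residue_weight == "n" else p.n_residues - 1
    return np.asarray(theta_mdeg, float) * p.mw / (10.0 * n * p.concentration * p.path_length)


@dataclass
class TwoStateParams:
    """Two-state van't Hoff melt parameters (Tm in K, dH in kJ/mol)."""

    tm: float
    dh: float
    y_n: float = 0.0
    m_n: float = 0.0
    y_d: float = 1.0
    m_d: float = 0.0

    def __post_init__(self) -> None:
        if self.tm <= 0:
            raise ValueError("Tm must be > 0 K")

    @property
    def tm_celsius(self) -> float:
        return self.tm - CELSIUS_OFFSET

    @classmethod
    def from_celsius(cls, tm_c: float, dh: float, **baselines) -> "TwoStateParams":
        return cls(tm=tm_c + CELSIUS_OFFSET, dh=dh, **baselines)


def _vant_hoff_exponent(t_kelvin: np.ndarray, tm: float, dh: float) -> np.ndarray:
    """ln K(T) of the two-state van't Hoff equilibrium."""
    return -(dh / R_KJ) * (1.0 / t_kelvin - 1.0 / tm)


def two_state_signal(t_kelvin, p: TwoStateParams) -> np.ndarray | float:
    """Observed signal of a two-state unfolding transition at T (K).

    Evaluated through the logistic form for numerical stability at extreme
    K (the denatured fraction is expit(ln K)).
    """
    t = np.asarray(t_kelvin, float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be > 0 K")
    fd = special.expit(_vant_hoff_exponent(t, p.tm, p.dh))  # denatured fraction
    return (p.y_n + p.m_n * t) * (1.0 - fd) + (p.y_d + p.m_d * t) * fd


@dataclass
class MeltCurve:
    """Temperature/signal table; temperatures in degC, strictly increasing."""

    temperature_c: np.ndarray
    signal: np.ndarray
    technique: str = "CD222"  # CD222 | DSC | nanoDSF-ratio

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, float)
        self.signal = np.asarray(self.signal, float)
        if self.temperature_c.shape != self.signal.shape:
            raise ValueError("temperature and signal lengths differ")
        if np.any(np.diff(self.temperature_c) <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperature_c)

    @property
    def temperature_k(self) -> np.ndarray:
        return self.temperature_c + CELSIUS_OFFSET

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"temperature_c": self.temperature_c, "signal": self.signal}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, technique: str = "CD222") -> "MeltCurve":
        df = pd.read_csv(path)
        cols = list(df.columns[:2])
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), technique=technique)


@dataclass
class FitResult:
    """Fitted parameters with standard errors from the fit covariance."""

    converged: bool
    params: dict[str, float] = field(default_factory=dict)
    stderr: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    message: str = ""

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _init_two_state(curve: MeltCurve) -> TwoStateParams:
    """Heuristic initialisation: Tm at max |dy/dT| (finite differences),
    dH = 300 kJ/mol, baselines from linear fits to the terminal 15%."""
    t = curve.temperature_k
    y = curve.signal
    dy = np.gradient(y, t)
    tm0 = float(t[np.argmax(np.abs(dy))])
    n_edge = max(2, len(t) // 7)
    mn, yn = np.polyfit(t[:n_edge], y[:n_edge], 1)
    md, yd = np.polyfit(t[-n_edge:], y[-n_edge:], 1)
    return TwoStateParams(tm=tm0, dh=300.0, y_n=yn, m_n=mn, y_d=yd, m_d=md)


_TWO_STATE_NAMES = ("tm", "dh", "y_n", "m_n", "y_d", "m_d")


def _finalize_fit(names, popt, pcov, resid, extra_params=None) -> FitResult:
    stderr = {}
    ok = bool(np.all(np.isfinite(popt)))
    if pcov is not None and np.all(np.isfinite(np.diag(pcov))) and np.all(np.diag(pcov) >= 0):
        err = np.sqrt(np.diag(pcov))
        stderr = dict(zip(names, err))
    params = dict(zip(names, popt))
    if extra_params:
        params.update(extra_params)
    return FitResult(
        converged=ok,
        params=params,
        stderr=stderr,
        residual_norm=float(np.linalg.norm(resid)),
    )


def _check_transition(result: FitResult, t: np.ndarray, y: np.ndarray, amplitude: float) -> None:
    """Demote fits with no credible transition: Tm outside the data range,
    non-positive enthalpy, or transition amplitude buried in the signal."""
    tm, dh = result.params["tm"], result.params["dh"]
    span = float(np.ptp(y))
    if not (t[0] <= tm <= t[-1]) or dh <= 0 or span == 0 or abs(amplitude) < 0.05 * span:
        result.converged = False
        result.message = "degenerate fit: no transition in the scanned range"


def fit_two_state(curve: MeltCurve, init: TwoStateParams | None = None) -> FitResult:
    """Nonlinear least-squares fit of the two-state model (six parameters).

    Reports Tm both in K (``tm``) and degC (``tm_celsius``).  Non-converged
    fits (optimizer failure, Tm outside the data range, non-positive dH, or
    a singular covariance) are flagged with ``converged=False``.
    """
    if len(curve) < 10:
        raise ValueError("need >= 10 points spanning the transition")
    p0 = init or _init_two_state(curve)
    x0 = [getattr(p0, name) for name in _TWO_STATE_NAMES]
    t = curve.temperature_k
    y = curve.signal

    def model(tk, tm, dh, y_n, m_n, y_d, m_d):
        return two_state_signal(
            tk, TwoStateParams(tm=tm, dh=dh, y_n=y_n, m_n=m_n, y_d=y_d, m_d=m_d)
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(model, t, y, p0=x0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return FitResult(converged=False, message=str(exc))
    resid = y - model(t, *popt)
    result = _finalize_fit(_TWO_STATE_NAMES, popt, pcov, resid)
    tm = result.params["tm"]
    amplitude = (result.params["y_d"] + result.params["m_d"] * tm) - (
        result.params["y_n"] + result.params["m_n"] * tm
    )
    _check_transition(result, t, y, amplitude)
    result.params["tm_celsius"] = tm - CELSIUS_OFFSET
    if "tm" in result.stderr:
        result.stderr["tm_celsius"] = result.stderr["tm"]
    return result


def dsc_excess_cp(t_kelvin, tm: float, dh: float) -> np.ndarray | float:
    """Two-state van't Hoff excess heat capacity (kJ/mol/K).

    Cp(T) = dH^2/(R T^2) * K/(1+K)^2; maximum at Tm, integral dH.
    """
    if tm <= 0 or dh <= 0:
        raise ValueError("Tm and dH must be positive")
    t = np.asarray(t_kelvin, float)
    x = _vant_hoff_exponent(t, tm, dh)
    # K/(1+K)^2 = expit(x) * expit(-x), overflow-free
    return dh**2 / (R_KJ * t**2) * special.expit(x) * special.expit(-x)


@dataclass
class StabilityParams:
    """Heat-capacity-corrected unfolding with quadratic baseline correction.

    dH (kJ/mol) at Tm, dCp (kJ/mol/K, temperature-independent), Tm (K);
    a0, a1 parameterise the native baseline a0 + a1*dT^2 and b1 the
    denatured baseline, with dT = T - Tref (Tref arbitrary, default
    298.15 K).
    """

    tm: float
    dh: float
    dcp: float = 0.0
    a0: float = 0.0
    a1: float = 0.0
    b1: float = 1.0
    tref: float = 298.15

    def __post_init__(self) -> None:
        if self.tm <= 0:
            raise ValueError("Tm must be > 0 K")

    @property
    def tm_celsius(self) -> float:
        return self.tm - CELSIUS_OFFSET

    @classmethod
    def from_celsius(cls, tm_c: float, dh: float, **rest) -> "StabilityParams":
        return cls(tm=tm_c + CELSIUS_OFFSET, dh=dh, **rest)


def gibbs_energy(t_kelvin, tm: float, dh: float, dcp: float = 0.0) -> np.ndarray | float:
    """Gibbs-Helmholtz unfolding free energy (kJ/mol) at T (K).

    dG(T) = dH*(1 - T/Tm) - dCp*[(Tm - T) + T*ln(T/Tm)].
    """
    t = np.asarray(t_kelvin, float)
    return dh * (1.0 - t / tm) - dcp * ((tm - t) + t * np.log(t / tm))


def stability_signal(t_kelvin, p: StabilityParams) -> np.ndarray | float:
    """Observed signal of the heat-capacity-corrected two-state model."""
    t = np.asarray(t_kelvin, float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be > 0 K")
    dg = gibbs_energy(t, p.tm, p.dh, p.dcp)
    f = special.expit(dg / (R_KJ * t))
    dt = t - p.tref
    native = p.a0 + p.a1 * dt**2
    denatured = p.b1
    return native * f + denatured * (1.0 - f)


_STABILITY_NAMES = ("tm", "dh", "dcp", "a0", "a1", "b1")


def fit_stability(
    curve: MeltCurve,
    fix_dcp: float | None = None,
    init: StabilityParams | None = None,
    tref: float = 298.15,
) -> FitResult:
    """Fit the heat-capacity-corrected model; dCp optionally held fixed.

    dCp is weakly determined by a single curve, so fixing it (e.g. to a
    per-residue estimate) typically tightens the Tm standard error.
    """
    if len(curve) < 10:
        raise ValueError("need >= 10 points spanning the transition")
    t = curve.temperature_k
    y = curve.signal
    if init is None:
        ts = _init_two_state(curve)
        amp_n = float(np.mean(y[: max(2, len(y) // 7)]))
        amp_d = float(np.mean(y[-max(2, len(y) // 7):]))
        init = StabilityParams(
            tm=ts.tm, dh=300.0, dcp=0.0 if fix_dcp is None else fix_dcp,
            a0=amp_n, a1=0.0, b1=amp_d, tref=tref,
        )
    names = [n for n in _STABILITY_NAMES if not (n == "dcp" and fix_dcp is not None)]
    x0 = [getattr(init, n) for n in names]

    def model(tk, *args):
        kw = dict(zip(names, args))
        if fix_dcp is not None:
            kw["dcp"] = fix_dcp
        return stability_signal(tk, StabilityParams(tref=tref, **kw))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(model, t, y, p0=x0, maxfev=40000)
    except (RuntimeError, ValueError) as exc:
        return FitResult(converged=False, message=str(exc))
    resid = y - model(t, *popt)
    extra = {"dcp": fix_dcp} if fix_dcp is not None else None
    result = _finalize_fit(names, popt, pcov, resid, extra_params=extra)
    tm = result.params["tm"]
    dt_tm = tm - tref
    amplitude = result.params["b1"] - (result.params["a0"] + result.params["a1"] * dt_tm**2)
    _check_transition(result, t, y, amplitude)
    result.params["tm_celsius"] = tm - CELSIUS_OFFSET
    if "tm" in result.stderr:
        result.stderr["tm_celsius"] = result.stderr["tm"]
    return result


@dataclass
class DenaturantSeries:
    """Fitted Tm (degC) as a function of denaturant concentration (M)."""

    concentration: np.ndarray  # [GuHCl], M
    tm_c: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, float)
        self.tm_c = np.asarray(self.tm_c, float)
        if self.concentration.shape != self.tm_c.shape:
            raise ValueError("length mismatch")
        if len(np.unique(self.concentration)) < 2:
            raise ValueError("need >= 2 distinct denaturant concentrations")


def extrapolate_tm0(series: DenaturantSeries) -> tuple[float, float]:
    """Tm at zero denaturant by ordinary least squares.

    Returns (intercept degC, standard error of the intercept); the standard
    error is 0 for an exactly linear series and NaN with only 2 points.
    """
    fit = stats.linregress(series.concentration, series.tm_c)
    return float(fit.intercept), float(fit.intercept_stderr)


def simulate_melt(
    params: TwoStateParams | StabilityParams,
    grid_celsius: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    technique: str | None = None,
) -> MeltCurve:
    """Synthetic melt curve: model signal on a degC grid + Gaussian noise."""
    grid_celsius = np.asarray(grid_celsius, float)
    t = grid_celsius + CELSIUS_OFFSET
    if isinstance(params, TwoStateParams):
        y = two_state_signal(t, params)
        technique = technique or "CD222"
    else:
        y = stability_signal(t, params)
        technique = technique or "nanoDSF-ratio"
    if noise_sd > 0:
        if isinstance(rng, (int, np.integer)) or rng is None:
            rng = np.random.default_rng(rng)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return MeltCurve(temperature_c=grid_celsius, signal=np.asarray(y), technique=technique)
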