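"""Two-state thermal-denaturation analysis of CD melt curves.

A folded⇌unfolded equilibrium with van't Hoff enthalpy ``dH_vh`` and midpoint
``Tm`` (ΔCp = 0 by default) is fitted to an ellipticity-versus-temperature
trace.  Raw CD baselines drift with temperature, so linear pre- and
post-transition baselines are fitted alongside the thermodynamic parameters:

    θ(T) = f(T)·(aF + bF·T) + (1 − f(T))·(aU + bU·T)
    f(T) = 1 / (1 + exp(−ΔG(T)/(R·T))),   ΔG(T) = dH_vh·(1 − T/Tm)

Model/Results layout follows statsmodels: :class:`TwoStateMeltModel` wraps a
:class:`MeltCurve`; :meth:`~TwoStateMeltModel.fit` returns a
:class:`MeltFitResults` carrying Tm, dH_vh, their standard errors and a
``summary()`` table.  :func:`compare_melts` implements the
"identical-within-measurement-error" stability comparison between variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

R_GAS = 8.314462618  # J mol^-1 K^-1

__all__ = [
    "MeltCurve",
    "TwoStateMeltModel",
    "MeltFitResults",
    "MeltComparison",
    "NoTransitionError",
    "two_state_signal",
    "folded_fraction",
    "fit_melt",
    "compare_melts",
]


class NoTransitionError(ValueError):
    """No unfolding transition detected in the melt curve."""


@dataclass
class MeltCurve:
    """Ellipticity vs. temperature; stored in kelvin, ingested as °C."""

    T: np.ndarray      # kelvin, strictly increasing
    theta: np.ndarray  # ellipticity (mdeg or arbitrary)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.T.ndim != 1 or self.T.shape != self.theta.shape:
            raise ValueError("T and theta must be 1-D vectors of equal length")
        if len(self.T) < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperature must be strictly increasing")

    @classmethod
    def from_celsius(cls, T_celsius: np.ndarray, theta: np.ndarray) -> "MeltCurve":
        return cls(T=np.asarray(T_celsius, dtype=float) + 273.15, theta=theta)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeltCurve":
        """Read a two-column CSV with ``temperature_C`` and ``signal``."""
        df = pd.read_csv(path)
        if not {"temperature_C", "signal"}.issubset(df.columns):
            raise ValueError("melt CSV needs columns temperature_C, signal")
        return cls.from_celsius(df["temperature_C"].to_numpy(), df["signal"].to_numpy())


def folded_fraction(T: np.ndarray, Tm: float, dH_vh: float) -> np.ndarray:
    """Two-state folded fraction f(T); exactly 0.5 at T = Tm."""
    T = np.asarray(T, dtype=float)
    dG = dH_vh * (1.0 - T / Tm)
    return 1.0 / (1.0 + np.exp(-dG / (R_GAS * T)))


def two_state_signal(
    T: np.ndarray,
    Tm: float,
    dH_vh: float,
    aF: float,
    bF: float,
    aU: float,
    bU: float,
) -> np.ndarray:
    """Two-state melt signal with linear folded/unfolded baselines."""
    T = np.asarray(T, dtype=float)
    f = folded_fraction(T, Tm, dH_vh)
    return f * (aF + bF * T) + (1.0 - f) * (aU + bU * T)


def _transition_guess(curve: MeltCurve, peak_threshold: float = 3.0) -> float:
    """Initial Tm from the maximum of the smoothed |dθ/dT|.

    Raises :class:`NoTransitionError` when the derivative peak does not stand
    out from the baseline drift (peak below ``peak_threshold`` times the
    median absolute derivative).
    """
    n = len(curve.T)
    window = min(21, n if n % 2 == 1 else n - 1)
    theta_s = savgol_filter(curve.theta, window, 3) if window >= 5 else curve.theta
    dtheta = np.gradient(theta_s, curve.T)
    mag = np.abs(dtheta)
    med = np.median(mag)
    peak = int(np.argmax(mag))
    if med > 0 and mag[peak] < peak_threshold * med:
        raise NoTransitionError(
            f"derivative peak ({mag[peak]:.3g}) below {peak_threshold} x median "
            f"({med:.3g}); no unfolding transition detected"
        )
    if med == 0 and mag[peak] == 0:
        raise NoTransitionError("flat melt curve; no transition")
    return float(curve.T[peak])


def _count_derivative_peaks(curve: MeltCurve, rel_height: float = 0.5) -> int:
    """Number of separated |dθ/dT| peaks above ``rel_height`` of the maximum.

    More than one flags a multistep melt (the two-state fit is then suspect);
    no multi-state model is fitted.
    """
    from scipy.signal import find_peaks

    n = len(curve.T)
    window = min(21, n if n % 2 == 1 else n - 1)
    theta_s = savgol_filter(curve.theta, window, 3) if window >= 5 else curve.theta
    mag = np.abs(np.gradient(theta_s, curve.T))
    if mag.max() <= 0:
        return 0
    span = max(curve.T[-1] - curve.T[0], 1e-9)
    dist = max(int(5.0 / (span / n)), 1)  # peaks at least ~5 K apart
    peaks, _ = find_peaks(mag, height=rel_height * mag.max(), distance=dist)
    return max(len(peaks), 1)


class TwoStateMeltModel:
    """Two-state unfolding model for one CD melt curve.

    ``dCp`` (J mol⁻¹ K⁻¹) extends ΔG(T) with a heat-capacity term when
    nonzero; the default 0 is the pure van't Hoff analysis.
    """

    def __init__(self, curve: MeltCurve, dCp: float = 0.0):
        self.curve = curve
        self.dCp = float(dCp)

    def predict(self, params: lmfit.Parameters, T: np.ndarray | None = None) -> np.ndarray:
        T = self.curve.T if T is None else np.asarray(T, dtype=float)
        v = params.valuesdict()
        f = self._folded_fraction(T, v["Tm"], v["dH_vh"])
        return f * (v["aF"] + v["bF"] * T) + (1.0 - f) * (v["aU"] + v["bU"] * T)

    def _folded_fraction(self, T: np.ndarray, Tm: float, dH: float) -> np.ndarray:
        dG = dH * (1.0 - T / Tm)
        if self.dCp != 0.0:
            dG = dG + self.dCp * (T - Tm - T * np.log(T / Tm))
        return 1.0 / (1.0 + np.exp(-np.clip(dG / (R_GAS * T), -500, 500)))

    def _initial_params(self) -> lmfit.Parameters:
        c = self.curve
        Tm0 = _transition_guess(c)
        k = max(len(c.T) // 10, 3)
        # baseline guesses from the end segments
        bF0, aF0 = np.polyfit(c.T[:k], c.theta[:k], 1)
        bU0, aU0 = np.polyfit(c.T[-k:], c.theta[-k:], 1)
        p = lmfit.Parameters()
        p.add("Tm", value=Tm0, min=c.T[0], max=c.T[-1])
        p.add("dH_vh", value=3e5, min=1e3, max=5e6)
        p.add("aF", value=aF0)
        p.add("bF", value=bF0)
        p.add("aU", value=aU0)
        p.add("bU", value=bU0)
        return p

    def fit(self, params: lmfit.Parameters | None = None) -> "MeltFitResults":
        params = params or self._initial_params()

        def resid(p: lmfit.Parameters) -> np.ndarray:
            return self.predict(p) - self.curve.theta

        out = lmfit.minimize(resid, params, method="leastsq")
        return MeltFitResults(model=self, minimizer_result=out)


@dataclass
class MeltFitResults:
    """Fitted two-state melt: Tm, van't Hoff enthalpy, baselines, SEs."""

    model: TwoStateMeltModel
    minimizer_result: lmfit.minimizer.MinimizerResult

    def __post_init__(self) -> None:
        r = self.minimizer_result
        v = r.params.valuesdict()
        self.Tm: float = float(v["Tm"])
        self.dH_vh: float = float(v["dH_vh"])
        self.baselines: dict[str, float] = {
            k: float(v[k]) for k in ("aF", "bF", "aU", "bU")
        }
        self.loss: float = float(np.sum(np.asarray(r.residual) ** 2))
        self.converged: bool = bool(r.success)
        se = r.params["Tm"].stderr
        self.Tm_se: float = float(se) if se is not None else math.nan
        se = r.params["dH_vh"].stderr
        self.dH_vh_se: float = float(se) if se is not None else math.nan
        self.n_transition_peaks: int = _count_derivative_peaks(self.model.curve)
        self.multistep_flag: bool = self.n_transition_peaks > 1

    @property
    def Tm_celsius(self) -> float:
        return self.Tm - 273.15

    def predict(self, T: np.ndarray | None = None) -> np.ndarray:
        return self.model.predict(self.minimizer_result.params, T=T)

    def summary(self) -> str:
        lines = [
            "Two-state thermal unfolding fit",
            "=" * 46,
            f"n = {len(self.model.curve.T)}   SSR = {self.loss:.4e}   "
            f"converged: {self.converged}",
            f"Tm     = {self.Tm:8.2f} K ({self.Tm_celsius:.2f} degC)  +/- {self.Tm_se:.3f}",
            f"dH_vh  = {self.dH_vh / 1e3:8.1f} kJ/mol          +/- {self.dH_vh_se / 1e3:.2f}",
            f"baselines: folded {self.baselines['aF']:.3g} + {self.baselines['bF']:.3g}*T; "
            f"unfolded {self.baselines['aU']:.3g} + {self.baselines['bU']:.3g}*T",
        ]
        if self.multistep_flag:
            lines.append(
                f"warning: {self.n_transition_peaks} derivative peaks — "
                "multistep melting; two-state fit is suspect"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "Tm_K": self.Tm,
            "Tm_celsius": self.Tm_celsius,
            "Tm_se": self.Tm_se,
            "dH_vh_J_per_mol": self.dH_vh,
            "dH_vh_se": self.dH_vh_se,
            "baselines": self.baselines,
            "loss": self.loss,
            "converged": self.converged,
            "multistep_flag": self.multistep_flag,
        }


def fit_melt(curve: MeltCurve, dCp: float = 0.0) -> MeltFitResults:
    """Fit a two-state unfolding model (functional front door)."""
    return TwoStateMeltModel(curve, dCp=dCp).fit()


@dataclass
class MeltComparison:
    """ΔTm between two fitted melts with propagated uncertainty."""

    delta_Tm: float
    se: float
    indistinguishable: bool


def compare_melts(a: MeltFitResults, b: MeltFitResults) -> MeltComparison:
    """Compare midpoints: ΔTm = Tm_a − Tm_b with joint SE.

    Two variants are flagged "indistinguishable" (stability preserved) when
    |ΔTm| < 2·SE, the measurement-error criterion used for variant pairs.
    """
    if not (a.converged and b.converged):
        raise ValueError("both melt fits must have converged")
    delta = a.Tm - b.Tm
    se = math.hypot(
        a.Tm_se if math.isfinite(a.Tm_se) else 0.0,
        b.Tm_se if math.isfinite(b.Tm_se) else 0.0,
    )
    return MeltComparison(delta_Tm=delta, se=se, indistinguishable=abs(delta) < 2.0 * se)
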