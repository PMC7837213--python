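"""Global fitting of the integrated rate law to normalized ThT traces.

The workflow mirrors the standard chemical-kinetics analysis of inhibitor
screens: fit the uninhibited (reference) aggregation curve to extract the
combined rate products ``k+kn`` and ``k+k2``, then refit each inhibited
condition to obtain *apparent* products and report their ratios to the
reference.  A suppressed ``ratio_kn`` with unchanged ``ratio_k2`` indicates a
primary-nucleation-specific inhibitor, and vice versa — the mechanism
decoupling that distinguishes this analysis from potency-only readouts.

Model/Results layout follows statsmodels: build an
:class:`AggregationKineticsModel` from data, call :meth:`~AggregationKineticsModel.fit`,
get an :class:`AggregationFitResults` with estimates, standard errors and a
``summary()`` table.

The optimisation works in ``(log10 λ, log10 κ)`` space, where
``λ = sqrt(2 k+kn m0^nc)`` and ``κ = sqrt(2 k+k2 m0^(n2+1))`` are the primary
and secondary pathway rate scales in s⁻¹.  This is a bijection of the rate
products at fixed ``m0`` and orders, but keeps the search box scale-free:
the bounds [1e-8, 1e-1] s⁻¹ span half-times from under a minute to years
regardless of the concentration unit.  Products and their uncertainties are
reported on the natural scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import KineticParameters, fibril_mass_analytic, half_time
from .traces import (
    Condition,
    FlatTraceError,
    NormalizedTrace,
    ThTTrace,
    average_replicates,
    normalize_trace,
)

__all__ = [
    "AggregationKineticsModel",
    "AggregationFitResults",
    "ApparentRates",
    "FitConvergenceError",
    "fit_reference",
    "fit_apparent",
    "censored_apparent",
    "inhibition_profile",
    "run_screen",
]

LOG10_RATE_BOUNDS = (-8.0, -1.0)  # log10 of λ, κ in s^-1


class FitConvergenceError(RuntimeError):
    """No optimisation start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[dict] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class AggregationKineticsModel:
    """Integrated-rate-law model for one or more normalized aggregation traces.

    Parameters
    ----------
    traces : NormalizedTrace or sequence of NormalizedTrace
        Replicate-averaged normalized traces (unseeded).  Multiple traces are
        fitted jointly with shared parameters.
    m0 : float, optional
        Initial monomer concentration (molar); defaults to the traces' value.
    nc, n2 : float
        Reaction orders, fixed during the fit (default 2).
    weights : {"uniform", "sd"}
        Residual weighting; "sd" uses replicate standard deviations where
        available (uniform is the default — no error model is assumed).
    """

    def __init__(
        self,
        traces: NormalizedTrace | Sequence[NormalizedTrace],
        m0: float | None = None,
        nc: float = 2.0,
        n2: float = 2.0,
        weights: str = "uniform",
        log_bounds: tuple[float, float] = LOG10_RATE_BOUNDS,
    ):
        if isinstance(traces, NormalizedTrace):
            traces = [traces]
        if not traces:
            raise ValueError("at least one trace is required")
        self.traces = list(traces)
        m0s = {tr.condition.m0 for tr in self.traces}
        if m0 is None:
            if len(m0s) != 1:
                raise ValueError(f"traces disagree on m0: {sorted(m0s)}")
            m0 = m0s.pop()
        self.m0 = float(m0)
        self.nc = float(nc)
        self.n2 = float(n2)
        self.log_bounds = log_bounds
        if weights not in ("uniform", "sd"):
            raise ValueError("weights must be 'uniform' or 'sd'")
        self._w = []
        for tr in self.traces:
            if weights == "sd" and tr.y_sd is not None and np.all(tr.y_sd > 0):
                self._w.append(1.0 / tr.y_sd)
            else:
                self._w.append(np.ones_like(tr.y))
        self.nobs = int(sum(len(tr.t) for tr in self.traces))

    # -- model evaluation ---------------------------------------------------

    def params_from_log(self, log10_lam: float, log10_kappa: float) -> KineticParameters:
        return KineticParameters.from_rate_scales(
            lam=10.0**log10_lam, kappa=10.0**log10_kappa, m0=self.m0, nc=self.nc, n2=self.n2
        )

    def predict(self, params: KineticParameters, t: np.ndarray | None = None) -> np.ndarray:
        if t is not None:
            return fibril_mass_analytic(t, params).M_norm
        return np.concatenate(
            [fibril_mass_analytic(tr.t, params).M_norm for tr in self.traces]
        )

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        params = self.params_from_log(x[0], x[1])
        res = []
        for tr, w in zip(self.traces, self._w):
            res.append(w * (tr.y - fibril_mass_analytic(tr.t, params).M_norm))
        return np.concatenate(res)

    def loss(self, log10_lam: float, log10_kappa: float) -> float:
        """Sum of squared (weighted) residuals at the given rate scales."""
        r = self._residuals(np.array([log10_lam, log10_kappa]))
        return float(r @ r)

    # -- starting values ----------------------------------------------------

    def _data_half_time(self) -> float | None:
        """Crude half-time of the pooled data by first upward 0.5-crossing."""
        tr = self.traces[0]
        above = np.nonzero(tr.y >= 0.5)[0]
        if len(above) == 0 or above[0] == 0:
            return None
        i = above[0]
        t0, t1 = tr.t[i - 1], tr.t[i]
        y0, y1 = tr.y[i - 1], tr.y[i]
        if y1 == y0:
            return float(t1)
        return float(t0 + (0.5 - y0) * (t1 - t0) / (y1 - y0))

    def _starts(self, n_starts: int, seed: int, extra: list[np.ndarray]) -> list[np.ndarray]:
        lo, hi = self.log_bounds
        starts = [np.clip(np.asarray(s, dtype=float), lo, hi) for s in extra]
        t_half = self._data_half_time()
        if t_half is not None and t_half > 0:
            # secondary-dominated heuristic: κ·t½ ≈ 10, λ ≈ κ/10
            k0 = math.log10(10.0 / t_half)
            starts.append(np.clip(np.array([k0 - 1.0, k0]), lo, hi))
        rng = np.random.default_rng(seed)
        while len(starts) < n_starts:
            starts.append(rng.uniform(lo, hi, size=2))
        return starts[:n_starts]

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_starts: int = 8,
        seed: int = 0,
        start: tuple[float, float] | None = None,
    ) -> "AggregationFitResults":
        """Least-squares fit with deterministic multi-start.

        ``start`` (log10 λ, log10 κ) is prepended to the start list when
        given (used by the apparent-rate refits).  The best-loss solution is
        returned; ties within 1e-9 relative loss are broken by proximity to
        the first start.  All starts' losses are kept in the results.
        """
        lo, hi = self.log_bounds
        extra = [np.asarray(start, dtype=float)] if start is not None else []
        starts = self._starts(n_starts, seed, extra)
        attempts: list[dict] = []
        for x0 in starts:
            try:
                sol = least_squares(
                    self._residuals,
                    x0,
                    bounds=([lo, lo], [hi, hi]),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
                attempts.append(
                    {
                        "x0": x0,
                        "x": sol.x,
                        "loss": float(2.0 * sol.cost),
                        "success": bool(sol.success),
                        "nfev": int(sol.nfev),
                        "jac": sol.jac,
                        "message": sol.message,
                    }
                )
            except Exception as exc:  # pathological corner of the box
                attempts.append({"x0": x0, "success": False, "message": str(exc)})
        converged = [a for a in attempts if a.get("success")]
        if not converged:
            raise FitConvergenceError("no optimisation start converged", attempts)
        best_loss = min(a["loss"] for a in converged)
        anchor = starts[0]
        best = min(
            converged,
            key=lambda a: (
                0 if a["loss"] <= best_loss * (1 + 1e-9) + 1e-300 else 1,
                float(np.linalg.norm(a["x"] - anchor)),
                a["loss"],
            ),
        )
        return AggregationFitResults(model=self, _best=best, _attempts=attempts)


@dataclass
class AggregationFitResults:
    """Results of an integrated-rate-law fit.

    Exposes the fitted :class:`KineticParameters`, the loss (SSR), approximate
    standard errors of the log10 rate products from the Jacobian at the
    optimum, convergence diagnostics and the residual curve.
    """

    model: AggregationKineticsModel
    _best: dict
    _attempts: list[dict]

    def __post_init__(self) -> None:
        x = self._best["x"]
        self._log10_lam, self._log10_kappa = float(x[0]), float(x[1])
        self.params: KineticParameters = self.model.params_from_log(*x)
        self.loss: float = self._best["loss"]
        self.converged: bool = True
        self.n_iterations: int = self._best["nfev"]
        self.residual_curve: np.ndarray = self.model._residuals(x)
        self.start_losses: list[float] = [
            a["loss"] for a in self._attempts if a.get("success")
        ]
        self.at_bound: bool = any(
            abs(v - b) < 1e-6
            for v in (self._log10_lam, self._log10_kappa)
            for b in self.model.log_bounds
        )
        self._compute_bse()

    def _compute_bse(self) -> None:
        J = self._best["jac"]
        dof = max(self.model.nobs - 2, 1)
        s2 = self.loss / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.array([np.nan, np.nan])
        # log10 k+kn = 2 log10 λ + const; log10 k+k2 = 2 log10 κ + const
        self.bse_log10: dict[str, float] = {
            "log10_k_plus_kn": 2.0 * float(se[0]),
            "log10_k_plus_k2": 2.0 * float(se[1]),
        }

    @property
    def log10_k_plus_kn(self) -> float:
        return math.log10(self.params.k_plus_kn)

    @property
    def log10_k_plus_k2(self) -> float:
        return math.log10(self.params.k_plus_k2)

    def half_time(self) -> float:
        return half_time(self.params)

    def predict(self, t: np.ndarray | None = None) -> np.ndarray:
        return self.model.predict(self.params, t=t)

    def summary(self) -> str:
        lines = [
            "Integrated rate law fit (combined nucleation/elongation products)",
            "=" * 66,
            f"observations: {self.model.nobs}   traces: {len(self.model.traces)}",
            f"m0 = {self.model.m0:.3e} M   nc = {self.model.nc:g}   n2 = {self.model.n2:g}",
            f"SSR = {self.loss:.4e}   starts converged: {len(self.start_losses)}",
            "-" * 66,
            f"{'parameter':<16}{'estimate':>14}{'log10':>10}{'se(log10)':>12}",
            f"{'k+kn':<16}{self.params.k_plus_kn:>14.4e}"
            f"{self.log10_k_plus_kn:>10.3f}{self.bse_log10['log10_k_plus_kn']:>12.3f}",
            f"{'k+k2':<16}{self.params.k_plus_k2:>14.4e}"
            f"{self.log10_k_plus_k2:>10.3f}{self.bse_log10['log10_k_plus_k2']:>12.3f}",
        ]
        if self.at_bound:
            lines.append("warning: a parameter sits at a search bound")
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        return {
            "k_plus_kn": self.params.k_plus_kn,
            "k_plus_k2": self.params.k_plus_k2,
            "m0": self.model.m0,
            "nc": self.model.nc,
            "n2": self.model.n2,
            "loss": self.loss,
            "bse_log10": self.bse_log10,
            "at_bound": self.at_bound,
            "n_iterations": self.n_iterations,
        }


@dataclass
class ApparentRates:
    """Condition-specific apparent rate products and their fold-changes.

    ``ratio_kn`` and ``ratio_k2`` are apparent/reference; ``censored`` marks
    flat traces whose ratios are upper bounds at the fit floor, not
    estimates.  ``mechanism_note`` records whether a single-pathway
    perturbation (kn-only or k2-only refit) explains the curve within 5% of
    the two-parameter loss.
    """

    condition: Condition
    app_k_plus_kn: float
    app_k_plus_k2: float
    ratio_kn: float
    ratio_k2: float
    censored: bool = False
    mechanism_note: str = ""
    loss: float = math.nan
    fit: AggregationFitResults | None = field(default=None, repr=False)

    @property
    def log10_ratio_kn(self) -> float:
        return math.log10(self.ratio_kn)

    @property
    def log10_ratio_k2(self) -> float:
        return math.log10(self.ratio_k2)


def fit_reference(
    traces: NormalizedTrace | Sequence[NormalizedTrace],
    nc: float = 2.0,
    n2: float = 2.0,
    n_starts: int = 8,
    seed: int = 0,
    weights: str = "uniform",
) -> AggregationFitResults:
    """Fit the uninhibited reference condition (functional front door).

    Equivalent to ``AggregationKineticsModel(traces, ...).fit(...)``.
    """
    model = AggregationKineticsModel(traces, nc=nc, n2=n2, weights=weights)
    return model.fit(n_starts=n_starts, seed=seed)


def _single_pathway_losses(
    model: AggregationKineticsModel, reference: AggregationFitResults, full_x: np.ndarray
) -> dict[str, float]:
    """Best loss when only one pathway is allowed to move off the reference."""
    lo, hi = model.log_bounds
    ref_lam, ref_kap = reference._log10_lam, reference._log10_kappa
    out = {}
    for name, fixed_idx, fixed_val in (("kn_only", 1, ref_kap), ("k2_only", 0, ref_lam)):
        free_idx = 1 - fixed_idx

        def res1(z: np.ndarray) -> np.ndarray:
            x = np.empty(2)
            x[fixed_idx] = fixed_val
            x[free_idx] = z[0]
            return model._residuals(x)

        best = math.inf
        for z0 in {full_x[free_idx], ref_lam if free_idx == 0 else ref_kap}:
            try:
                sol = least_squares(res1, [z0], bounds=([lo], [hi]), method="trf")
                if sol.success:
                    best = min(best, float(2.0 * sol.cost))
            except Exception:
                pass
        out[name] = best
    return out


def fit_apparent(
    trace: NormalizedTrace,
    reference: AggregationFitResults,
    n_starts: int = 8,
    seed: int = 0,
) -> ApparentRates:
    """Refit both rate products for one condition against the reference fit.

    Starts from the reference parameters, a half-time-rescaled variant of
    them (both rate scales multiplied by t½_ref/t½_obs, which lands near the
    optimum even for strong inhibition) and the usual multistart.
    """
    if trace.condition.m0 != reference.model.m0:
        raise ValueError("apparent fit requires the same m0 as the reference")
    model = AggregationKineticsModel(
        trace, m0=reference.model.m0, nc=reference.model.nc, n2=reference.model.n2
    )
    ref_x = np.array([reference._log10_lam, reference._log10_kappa])
    extra_starts = [ref_x]
    t_half_obs = model._data_half_time()
    if t_half_obs is not None and t_half_obs > 0:
        shift = math.log10(reference.half_time() / t_half_obs)
        extra_starts.append(ref_x + shift)
    lo, hi = model.log_bounds
    starts = [np.clip(s, lo, hi) for s in extra_starts]
    res = model.fit(n_starts=n_starts, seed=seed, start=tuple(starts[0]))
    # try the half-time-shifted start explicitly and keep the better fit
    if len(starts) > 1:
        res2 = model.fit(n_starts=2, seed=seed, start=tuple(starts[1]))
        if res2.loss < res.loss:
            res = res2
    single = _single_pathway_losses(model, reference, res._best["x"])
    # 5% of the two-parameter loss, with an absolute floor so that
    # numerically-zero losses (noise-free data) compare sanely
    threshold = res.loss * 1.05 + 1e-10 * model.nobs
    within = {k: v <= threshold for k, v in single.items()}
    if within["kn_only"] and within["k2_only"]:
        note = "either single-pathway perturbation suffices"
    elif within["kn_only"]:
        note = "kn-only perturbation explains the curve"
    elif within["k2_only"]:
        note = "k2-only perturbation explains the curve"
    else:
        note = "both pathways perturbed"
    return ApparentRates(
        condition=trace.condition,
        app_k_plus_kn=res.params.k_plus_kn,
        app_k_plus_k2=res.params.k_plus_k2,
        ratio_kn=res.params.k_plus_kn / reference.params.k_plus_kn,
        ratio_k2=res.params.k_plus_k2 / reference.params.k_plus_k2,
        censored=False,
        mechanism_note=note,
        loss=res.loss,
        fit=res,
    )


def censored_apparent(
    condition: Condition, reference: AggregationFitResults
) -> ApparentRates:
    """Censored record for a flat (fully inhibited) trace.

    Ratios are *upper bounds* at the fit floor — the smallest rate scales the
    search box allows — never point estimates.
    """
    lo, _ = reference.model.log_bounds
    floor = reference.model.params_from_log(lo, lo)
    return ApparentRates(
        condition=condition,
        app_k_plus_kn=floor.k_plus_kn,
        app_k_plus_k2=floor.k_plus_k2,
        ratio_kn=floor.k_plus_kn / reference.params.k_plus_kn,
        ratio_k2=floor.k_plus_k2 / reference.params.k_plus_k2,
        censored=True,
        mechanism_note="flat trace: complete inhibition at this horizon; ratios are upper bounds",
    )


def inhibition_profile(apparent: Sequence[ApparentRates]) -> pd.DataFrame:
    """Ranked per-variant inhibition table across the dilution series.

    One row per (variant, ratio); sorted so the most potent
    primary-nucleation inhibitor (most negative ``log10_ratio_kn`` at the
    highest antibody:monomer ratio) comes first.  Censored (flat-trace)
    conditions keep their upper-bound ratios and a flag.  The
    (ratio_kn, ratio_k2) columns are the scatterplot-ready pairs.
    """
    if not apparent:
        raise ValueError("no apparent-rate records; reference missing?")
    rows = []
    for ap in apparent:
        rows.append(
            {
                "variant": ap.condition.variant,
                "inhibitor_ratio": ap.condition.inhibitor_ratio,
                "ratio_kn": ap.ratio_kn,
                "ratio_k2": ap.ratio_k2,
                "log10_ratio_kn": ap.log10_ratio_kn,
                "log10_ratio_k2": ap.log10_ratio_k2,
                "censored": ap.censored,
                "mechanism_note": ap.mechanism_note,
            }
        )
    df = pd.DataFrame(rows)
    top = df.groupby("variant").apply(  # rank by potency at the highest dilution
        lambda g: g.loc[g["inhibitor_ratio"].idxmax(), "log10_ratio_kn"],
        include_groups=False,
    )
    df["rank_key"] = df["variant"].map(top)
    df = df.sort_values(
        ["rank_key", "variant", "inhibitor_ratio"], ascending=[True, True, False]
    ).drop(columns="rank_key")
    df["rank"] = pd.factorize(df["variant"])[0] + 1
    return df.reset_index(drop=True)


def run_screen(
    traces: Sequence[ThTTrace],
    reference_variant: str = "reference",
    nc: float = 2.0,
    n2: float = 2.0,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[AggregationFitResults, list[ApparentRates], pd.DataFrame]:
    """Full screen analysis: normalize, average, fit reference, fit apparents.

    Raw traces are grouped by condition; replicates are normalized and
    averaged; the reference variant is fitted first and every other condition
    refitted against it.  Flat wells (no dynamic range at this horizon, i.e.
    complete inhibition) and wells that never plateau become censored
    records.  Returns (reference fit, apparent-rate records, ranked table).
    """
    groups: dict[tuple, list[ThTTrace]] = {}
    for tr in traces:
        groups.setdefault(tr.condition.key(), []).append(tr)

    def averaged(trs: list[ThTTrace]) -> NormalizedTrace:
        return average_replicates([normalize_trace(tr) for tr in trs])

    ref_groups = [k for k in groups if k[0] == reference_variant]
    if not ref_groups:
        raise ValueError(f"no wells for reference variant {reference_variant!r}")
    reference = fit_reference(
        averaged(groups[ref_groups[0]]), nc=nc, n2=n2, n_starts=n_starts, seed=seed
    )

    apparents: list[ApparentRates] = []
    for key, trs in sorted(groups.items()):
        if key[0] == reference_variant:
            continue
        try:
            avg = averaged(trs)
        except (FlatTraceError, ValueError) as exc:
            ap = censored_apparent(trs[0].condition, reference)
            if not isinstance(exc, FlatTraceError):
                ap.mechanism_note = f"censored: {exc}"
            apparents.append(ap)
            continue
        apparents.append(fit_apparent(avg, reference, n_starts=n_starts, seed=seed))
    table = inhibition_profile(apparents) if apparents else pd.DataFrame()
    return reference, apparents, table
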