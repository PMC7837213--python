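"""Synthetic ThT plate-reader datasets with the study's screening design.

Emulates the inhibitor-screen layout used throughout the analysis: 1.5 µM
Aβ42, antibody:monomer ratios 1:2, 1:4 and 1:8, triplicates, one reading
every 2 min, plus strongly seeded (30% monomer-equivalent) reactions for the
elongation assay.  Each simulated well maps a normalized mass curve from the
forward models to raw fluorescence via a per-well affine transform (gain and
baseline jitter force the normalization path to be exercised), then applies
multiplicative signal noise and additive baseline noise.  A ground-truth
manifest records every input so recovery studies need nothing else.

Reference kinetic parameters default to rate scales λ = 2e-4 s⁻¹ and
κ = 2e-3 s⁻¹ at 1.5 µM (an uninhibited half-time of about 40 min on a
multi-hour run — a realistic timescale for this assay, fixed arbitrarily,
not fitted to any experiment).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    DEFAULT_K_PLUS,
    KineticParameters,
    SeededState,
    fibril_mass_analytic,
    fibril_mass_ode,
)
from .traces import Condition, NormalizedTrace, ThTTrace, METADATA_COLUMNS

__all__ = [
    "ScreenDesign",
    "NoiseModel",
    "InhibitorEffect",
    "SimulatedScreen",
    "default_reference_parameters",
    "simulate_screen",
    "simulate_seeded_pair",
]

def default_reference_parameters(m0: float = 1.5e-6) -> KineticParameters:
    """Uninhibited Aβ42-like parameters (half-time ≈ 40 min at 1.5 µM).

    Secondary-nucleation dominated (κ/λ = 10), as is characteristic of Aβ42.
    """
    return KineticParameters.from_rate_scales(lam=2.3e-4, kappa=2.3e-3, m0=m0)


@dataclass(frozen=True)
class ScreenDesign:
    """Plate design: concentrations, dilution series, cadence and horizon."""

    m0: float = 1.5e-6
    ratios: tuple[float, ...] = (0.5, 0.25, 0.125)
    replicates: int = 3
    cadence: float = 120.0
    horizon: float = 43200.0  # 12 h: an overnight plate run
    seed_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if list(self.ratios) != sorted(self.ratios, reverse=True):
            raise ValueError("ratios must be sorted descending (1:2 before 1:8)")
        if self.cadence <= 0 or self.horizon <= self.cadence:
            raise ValueError("invalid cadence/horizon")

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.horizon + 0.5 * self.cadence, self.cadence)


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader noise: multiplicative on signal, additive on baseline (AU)."""

    sigma_mult: float = 0.01
    sigma_add: float = 2.0
    gain_range: tuple[float, float] = (800.0, 1200.0)
    baseline_range: tuple[float, float] = (80.0, 120.0)

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(sigma_mult=0.0, sigma_add=0.0)


@dataclass(frozen=True)
class InhibitorEffect:
    """Per-dilution multiplicative suppression of the rate products.

    ``kn_factor``/``k2_factor``/``elong_factor`` map an antibody:monomer
    ratio to the factor applied to k+kn, k+k2 and k+ respectively.  All
    factors are positive and tend to 1 as the ratio tends to 0.
    """

    variant: str
    kn_factor: Callable[[float], float]
    k2_factor: Callable[[float], float]
    elong_factor: Callable[[float], float] = field(default=lambda r: 1.0)

    @classmethod
    def from_top_dilution(
        cls,
        variant: str,
        kn_factor: float,
        k2_factor: float = 1.0,
        elong_factor: float = 1.0,
        top_ratio: float = 0.5,
    ) -> "InhibitorEffect":
        """Effect whose log-suppression scales linearly with the ratio.

        ``factor(r) = factor_top ** (r / top_ratio)`` — a simple stoichiometric
        dose-response that is monotone across the dilution series and tends
        to 1 at vanishing antibody.
        """

        def scale(top: float) -> Callable[[float], float]:
            return lambda r, top=top: float(top) ** (r / top_ratio)

        return cls(
            variant=variant,
            kn_factor=scale(kn_factor),
            k2_factor=scale(k2_factor),
            elong_factor=scale(elong_factor),
        )

    def apply(self, reference: KineticParameters, ratio: float) -> KineticParameters:
        return KineticParameters(
            k_plus_kn=reference.k_plus_kn * self.kn_factor(ratio) * self.elong_factor(ratio),
            k_plus_k2=reference.k_plus_k2 * self.k2_factor(ratio) * self.elong_factor(ratio),
            m0=reference.m0,
            nc=reference.nc,
            n2=reference.n2,
        )


@dataclass
class SimulatedScreen:
    """In-memory plate dataset: raw traces, well metadata and ground truth."""

    traces: list[ThTTrace]
    metadata: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write canonical long CSV, metadata sidecar and ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "plate": out / "plate_long.csv",
            "metadata": out / "well_metadata.csv",
            "manifest": out / "ground_truth.json",
        }
        frames = [
            pd.DataFrame({"well": tr.well, "time": tr.t, "value": tr.F})
            for tr in self.traces
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            paths["plate"], index=False, float_format=lambda x: repr(float(x))
        )
        self.metadata.to_csv(paths["metadata"], index=False)
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return paths


def _well_name(i: int) -> str:
    return f"{'ABCDEFGH'[i // 12]}{i % 12 + 1}"


def simulate_screen(
    reference: KineticParameters | None = None,
    effects: Sequence[InhibitorEffect] = (),
    design: ScreenDesign = ScreenDesign(),
    noise: NoiseModel = NoiseModel(),
) -> SimulatedScreen:
    """Simulate a full unseeded inhibitor screen in plate format.

    One reference condition plus every (effect, ratio) combination, each with
    ``design.replicates`` wells.  Normalized mass curves come from the
    analytic rate law under condition-scaled parameters; raw AU values are
    ``baseline + gain*M`` with per-well gain/baseline draws, multiplicative
    Gaussian signal noise (sd fraction ``sigma_mult``) and additive baseline
    noise.  Identical ``design.rng_seed`` gives bit-identical output.
    """
    reference = reference or default_reference_parameters(design.m0)
    if reference.m0 != design.m0:
        raise ValueError("reference parameters and design disagree on m0")
    rng = np.random.default_rng(design.rng_seed)
    t = design.time_grid()

    conditions: list[tuple[str, float, KineticParameters]] = [
        ("reference", 0.0, reference)
    ]
    truth_effects: dict[str, dict] = {}
    for eff in effects:
        truth_effects[eff.variant] = {}
        for ratio in design.ratios:
            params = eff.apply(reference, ratio)
            conditions.append((eff.variant, ratio, params))
            truth_effects[eff.variant][str(ratio)] = {
                "kn_factor": eff.kn_factor(ratio) * eff.elong_factor(ratio),
                "k2_factor": eff.k2_factor(ratio) * eff.elong_factor(ratio),
                "true_k_plus_kn": params.k_plus_kn,
                "true_k_plus_k2": params.k_plus_k2,
            }

    traces: list[ThTTrace] = []
    meta_rows = []
    well_idx = 0
    for variant, ratio, params in conditions:
        M = fibril_mass_analytic(t, params).M_norm
        for rep in range(1, design.replicates + 1):
            gain = rng.uniform(*noise.gain_range)
            base = rng.uniform(*noise.baseline_range)
            signal = gain * M
            F = (
                base
                + signal * (1.0 + noise.sigma_mult * rng.standard_normal(t.shape))
                + noise.sigma_add * rng.standard_normal(t.shape)
            )
            well = _well_name(well_idx)
            well_idx += 1
            cond = Condition(
                m0=design.m0,
                inhibitor_ratio=ratio,
                seed_fraction=design.seed_fraction,
                replicate_id=f"r{rep}",
                variant=variant,
            )
            traces.append(ThTTrace(t=t.copy(), F=F, condition=cond, well=well))
            meta_rows.append(
                dict(
                    zip(
                        METADATA_COLUMNS,
                        [well, variant, design.m0, ratio, design.seed_fraction, f"r{rep}"],
                    )
                )
            )

    manifest = {
        "design": {
            "m0": design.m0,
            "ratios": list(design.ratios),
            "replicates": design.replicates,
            "cadence": design.cadence,
            "horizon": design.horizon,
            "seed_fraction": design.seed_fraction,
            "rng_seed": design.rng_seed,
        },
        "reference": {
            "k_plus_kn": reference.k_plus_kn,
            "k_plus_k2": reference.k_plus_k2,
            "lam": reference.lam,
            "kappa": reference.kappa,
            "nc": reference.nc,
            "n2": reference.n2,
        },
        "noise": {
            "sigma_mult": noise.sigma_mult,
            "sigma_add": noise.sigma_add,
            "gain_range": list(noise.gain_range),
            "baseline_range": list(noise.baseline_range),
        },
        "effects": truth_effects,
        "n_wells": len(traces),
    }
    return SimulatedScreen(
        traces=traces, metadata=pd.DataFrame(meta_rows), manifest=manifest
    )


def simulate_seeded_pair(
    reference: KineticParameters | None = None,
    elong_factor: float = 1.0,
    design: ScreenDesign = ScreenDesign(seed_fraction=0.30, cadence=5.0, horizon=3600.0),
    noise_sd: float = 0.0,
    mean_fibril_length: float = 500.0,
    k_plus: float = DEFAULT_K_PLUS,
) -> tuple[NormalizedTrace, NormalizedTrace, dict]:
    """Simulate a seeded control/sample pair with the elongation rate scaled.

    Both reactions start from the same preformed-fibril seed (mass
    ``design.seed_fraction * m0`` in monomer equivalents; number via the mean
    fibril length).  The sample's elongation constant is ``k_plus *
    elong_factor`` with the nucleation constants kn, k2 unchanged, realised
    through the explicit product split.  Returns (control, sample, manifest);
    traces carry the normalized fibril mass M/(m0+M0) with optional additive
    Gaussian noise of sd ``noise_sd``.
    """
    if design.seed_fraction <= 0:
        raise ValueError("seeded simulation requires seed_fraction > 0")
    if elong_factor <= 0:
        raise ValueError("elong_factor must be positive")
    reference = reference or default_reference_parameters(design.m0)
    seed_state = SeededState.from_mass_fraction(
        design.seed_fraction, design.m0, mean_length=mean_fibril_length
    )
    t = design.time_grid()
    rng = np.random.default_rng(design.rng_seed)

    def one(factor: float, label: str, rep: str) -> NormalizedTrace:
        scaled = KineticParameters(
            k_plus_kn=reference.k_plus_kn * factor,
            k_plus_k2=reference.k_plus_k2 * factor,
            m0=reference.m0,
            nc=reference.nc,
            n2=reference.n2,
        )
        curve = fibril_mass_ode(t, scaled, seed=seed_state, k_plus=k_plus * factor)
        y = curve.M_norm + noise_sd * rng.standard_normal(t.shape)
        cond = Condition(
            m0=design.m0,
            inhibitor_ratio=0.0,
            seed_fraction=design.seed_fraction,
            replicate_id=rep,
            variant=label,
        )
        return NormalizedTrace(
            t=t.copy(), y=y, baseline=0.0, plateau=1.0, condition=cond, well=label
        )

    control = one(1.0, "control", "r1")
    sample = one(elong_factor, "sample", "r1")
    manifest = {
        "M0": seed_state.M0,
        "P0": seed_state.P0,
        "k_plus": k_plus,
        "elong_factor": elong_factor,
        "mean_fibril_length": mean_fibril_length,
        "expected_initial_slope_control": 2.0
        * k_plus
        * seed_state.P0
        * design.m0
        / (design.m0 + seed_state.M0),
        "seed_fraction": design.seed_fraction,
        "m0": design.m0,
    }
    return control, sample, manifest
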