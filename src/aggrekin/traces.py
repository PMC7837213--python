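"""Reading, validation, normalization and replicate-averaging of ThT plate data.

ThT (thioflavin T) fluorescence reports amyloid fibril mass, so each well's
time series is a proxy for M(t).  Raw traces carry an arbitrary baseline and
gain; comparison with the dimensionless rate law requires normalization to
[0, 1] between the pre-growth baseline and the final plateau.

On-disk formats
---------------
Canonical long format (CSV): columns ``well,time,value``.  Wide format
(import only): one time column plus one column per well.  A sidecar metadata
CSV maps wells to conditions: ``well,variant,m0_molar,ratio,seed_fraction,
replicate``.  Inhibitor ratio is stored as the antibody:monomer fraction
(1:2 -> 0.5) so dilution series are numerically ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "ThTTrace",
    "NormalizedTrace",
    "FlatTraceError",
    "PlateLayoutError",
    "read_plate_timeseries",
    "write_plate",
    "read_metadata",
    "normalize_trace",
    "average_replicates",
]

METADATA_COLUMNS = ["well", "variant", "m0_molar", "ratio", "seed_fraction", "replicate"]


class FlatTraceError(ValueError):
    """Dynamic range below the floor — typical of complete inhibition.

    Callers must branch: flat wells are censored, not fitted.
    """


class PlateLayoutError(ValueError):
    """File does not match the declared plate layout; lists offending rows/wells."""


@dataclass(frozen=True)
class Condition:
    """Per-well experimental condition.

    ``inhibitor_ratio`` is the antibody:monomer fraction (1:2 → 0.5);
    ``seed_fraction`` the monomer-equivalent seed fraction of ``m0``.
    """

    m0: float = 1.5e-6
    inhibitor_ratio: float = 0.0
    seed_fraction: float = 0.0
    replicate_id: str = "r1"
    variant: str = "reference"

    def key(self) -> tuple:
        """Identity of the condition ignoring the replicate label."""
        return (self.variant, self.m0, self.inhibitor_ratio, self.seed_fraction)


@dataclass
class ThTTrace:
    """One well's raw fluorescence time series (t in seconds, F in AU)."""

    t: np.ndarray
    F: np.ndarray
    condition: Condition = field(default_factory=Condition)
    well: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.F.shape:
            raise ValueError("t and F must be 1-D vectors of equal length")
        if len(self.t) < 10:
            raise ValueError("a trace needs at least 10 time points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("fluorescence values must be finite")


@dataclass
class NormalizedTrace:
    """Baseline/plateau-normalized signal with the windows' AU levels retained."""

    t: np.ndarray
    y: np.ndarray
    baseline: float
    plateau: float
    condition: Condition = field(default_factory=Condition)
    well: str = ""
    y_sd: np.ndarray | None = None
    n_replicates: int = 1


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise PlateLayoutError(f"metadata file missing columns: {missing}")
    meta["well"] = meta["well"].astype(str)
    return meta.set_index("well", drop=False)


def _condition_from_row(row: pd.Series) -> Condition:
    return Condition(
        m0=float(row["m0_molar"]),
        inhibitor_ratio=float(row["ratio"]),
        seed_fraction=float(row["seed_fraction"]),
        replicate_id=str(row["replicate"]),
        variant=str(row["variant"]),
    )


def read_plate_timeseries(
    path: str | Path,
    metadata: str | Path | pd.DataFrame,
    layout: str = "long",
    time_unit: str = "s",
) -> list[ThTTrace]:
    """Read a plate file (long or wide layout) into per-well traces.

    Times are converted to seconds (``time_unit`` in {"s", "min", "h"}).
    Wells missing from the metadata, duplicate (well, time) rows and
    non-monotone times are rejected with a report naming the offenders.
    """
    factor = {"s": 1.0, "min": 60.0, "h": 3600.0}.get(time_unit)
    if factor is None:
        raise ValueError(f"unknown time unit {time_unit!r}")
    meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)

    df = pd.read_csv(path, float_precision="round_trip")
    if layout == "long":
        required = {"well", "time", "value"}
        if not required.issubset(df.columns):
            raise PlateLayoutError(f"long layout requires columns {sorted(required)}")
        dup = df.duplicated(subset=["well", "time"])
        if dup.any():
            raise PlateLayoutError(
                f"duplicate (well, time) rows at indices {df.index[dup].tolist()[:20]}"
            )
        long = df
    elif layout == "wide":
        time_col = df.columns[0]
        long = df.melt(id_vars=[time_col], var_name="well", value_name="value").rename(
            columns={time_col: "time"}
        )
    else:
        raise ValueError(f"unknown layout {layout!r}")

    long = long.assign(well=long["well"].astype(str))
    unmapped = sorted(set(long["well"]) - set(meta.index))
    if unmapped:
        raise PlateLayoutError(f"wells absent from metadata: {unmapped}")

    traces = []
    for well, grp in long.groupby("well", sort=True):
        grp = grp.sort_values("time")
        t = grp["time"].to_numpy(dtype=float) * factor
        if np.any(np.diff(t) <= 0):
            raise PlateLayoutError(f"non-monotone or duplicate times in well {well}")
        traces.append(
            ThTTrace(
                t=t,
                F=grp["value"].to_numpy(dtype=float),
                condition=_condition_from_row(meta.loc[str(well)]),
                well=str(well),
            )
        )
    return traces


def write_plate(traces: Iterable[ThTTrace], path: str | Path) -> None:
    """Write traces to the canonical long CSV (times in seconds)."""
    frames = [
        pd.DataFrame({"well": tr.well, "time": tr.t, "value": tr.F}) for tr in traces
    ]
    # shortest-roundtrip float text keeps the long format bit-exact
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def normalize_trace(
    trace: ThTTrace,
    baseline_window: int = 5,
    plateau_window: int = 10,
    range_floor: float = 0.2,
    plateau_slope_tol: float = 0.05,
) -> NormalizedTrace:
    """Normalize a raw trace to [0, 1] between baseline and plateau means.

    baseline = mean of the first ``baseline_window`` points, plateau = mean of
    the last ``plateau_window`` points; ``y = (F − baseline)/(plateau −
    baseline)``.  The result is invariant to affine transforms of F.

    Raises
    ------
    FlatTraceError
        If the dynamic range is below ``range_floor`` times the signal
        magnitude — the expected outcome for fully inhibited wells.
    ValueError
        If the trace has not plateaued (relative drift across the last
        window exceeds ``plateau_slope_tol`` of the dynamic range).
    """
    n = len(trace.t)
    bw = min(baseline_window, n // 3)
    pw = min(plateau_window, n // 3)
    baseline = float(np.mean(trace.F[:bw]))
    plateau = float(np.mean(trace.F[-pw:]))
    dyn = plateau - baseline
    # flat test must be affine-invariant: compare the baseline→plateau climb
    # against the trace's full excursion, which for a flat well is pure noise
    span = float(np.max(trace.F) - np.min(trace.F))
    if span <= 0.0 or dyn <= range_floor * span:
        raise FlatTraceError(
            f"baseline-to-plateau climb {dyn:.3g} below {range_floor:g} of the "
            f"signal excursion {span:.3g}; flat trace — complete inhibition at "
            "this horizon?"
        )
    # plateau check: linear drift over the last window, relative to range
    tw, Fw = trace.t[-pw:], trace.F[-pw:]
    slope = float(np.polyfit(tw, Fw, 1)[0]) if pw >= 3 else 0.0
    drift = abs(slope) * (tw[-1] - tw[0]) / dyn
    if drift > plateau_slope_tol:
        raise ValueError(
            f"trace has not plateaued: relative drift {drift:.3f} over the last "
            f"{pw} points exceeds {plateau_slope_tol}"
        )
    return NormalizedTrace(
        t=trace.t.copy(),
        y=(trace.F - baseline) / dyn,
        baseline=baseline,
        plateau=plateau,
        condition=trace.condition,
        well=trace.well,
    )


def average_replicates(traces: Sequence[NormalizedTrace]) -> NormalizedTrace:
    """Pointwise mean and sd of replicate traces sharing a grid and condition.

    Grids must match exactly — no resampling happens at this layer.
    """
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for tr in traces[1:]:
        if tr.t.shape != first.t.shape or not np.allclose(tr.t, first.t, rtol=0, atol=1e-9):
            raise ValueError("replicate time grids differ; resample upstream")
        if tr.condition.key() != first.condition.key():
            raise ValueError(
                f"conditions differ: {tr.condition.key()} vs {first.condition.key()}"
            )
    Y = np.vstack([tr.y for tr in traces])
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1) if len(traces) > 1 else np.zeros_like(mean)
    cond = replace(first.condition, replicate_id="mean")
    return NormalizedTrace(
        t=first.t.copy(),
        y=mean,
        baseline=float(np.mean([tr.baseline for tr in traces])),
        plateau=float(np.mean([tr.plateau for tr in traces])),
        condition=cond,
        well=",".join(tr.well for tr in traces),
        y_sd=sd,
        n_replicates=len(traces),
    )
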