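"""Plate I/O, normalization and replicate aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggrekin import (
    Condition,
    FlatTraceError,
    PlateLayoutError,
    ThTTrace,
    average_replicates,
    fibril_mass_analytic,
    normalize_trace,
    read_plate_timeseries,
    write_plate,
)
from aggrekin.traces import read_metadata

from conftest import model_trace


def _metadata_csv(tmp_path, wells):
    rows = [
        {"well": w, "variant": "reference", "m0_molar": 1.5e-6,
         "ratio": 0.0, "seed_fraction": 0.0, "replicate": f"r{i+1}"}
        for i, w in enumerate(wells)
    ]
    path = tmp_path / "meta.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestReadPlate:
    def test_long_format_counts(self, tmp_path):
        t = np.arange(5)
        rows = []
        for w in ("A1", "A2", "A3"):
            for ti in t:
                rows.append({"well": w, "time": ti * 120.0, "value": 100.0 + ti})
        plate = tmp_path / "plate.csv"
        pd.DataFrame(rows).to_csv(plate, index=False)
        # short traces are permitted at the I/O layer? no — ThTTrace needs 10
        with pytest.raises(ValueError):
            read_plate_timeseries(plate, _metadata_csv(tmp_path, ["A1", "A2", "A3"]))

    def test_long_format_three_wells(self, tmp_path):
        t = np.arange(12)
        rows = [
            {"well": w, "time": ti * 120.0, "value": 100.0 + ti}
            for w in ("A1", "A2", "A3")
            for ti in t
        ]
        plate = tmp_path / "plate.csv"
        pd.DataFrame(rows).to_csv(plate, index=False)
        traces = read_plate_timeseries(plate, _metadata_csv(tmp_path, ["A1", "A2", "A3"]))
        assert len(traces) == 3
        assert all(len(tr.t) == 12 for tr in traces)

    def test_wide_format_minutes_to_seconds(self, tmp_path):
        # a 2-minute cadence must land on 120 s steps after unit conversion
        t_min = np.arange(0, 24, 2.0)
        df = pd.DataFrame({"time": t_min, "A1": np.linspace(100, 1100, len(t_min))})
        plate = tmp_path / "wide.csv"
        df.to_csv(plate, index=False)
        traces = read_plate_timeseries(
            plate, _metadata_csv(tmp_path, ["A1"]), layout="wide", time_unit="min"
        )
        assert traces[0].t[1] - traces[0].t[0] == 120.0

    def test_unmapped_well_named_in_error(self, tmp_path):
        rows = [
            {"well": w, "time": float(ti), "value": 1.0}
            for w in ("A1", "B9")
            for ti in range(12)
        ]
        plate = tmp_path / "plate.csv"
        pd.DataFrame(rows).to_csv(plate, index=False)
        with pytest.raises(PlateLayoutError, match="B9"):
            read_plate_timeseries(plate, _metadata_csv(tmp_path, ["A1"]))

    def test_duplicate_well_time_rejected(self, tmp_path):
        rows = [{"well": "A1", "time": float(ti), "value": 1.0} for ti in range(12)]
        rows.append({"well": "A1", "time": 3.0, "value": 2.0})
        plate = tmp_path / "plate.csv"
        pd.DataFrame(rows).to_csv(plate, index=False)
        with pytest.raises(PlateLayoutError, match="duplicate"):
            read_plate_timeseries(plate, _metadata_csv(tmp_path, ["A1"]))

    def test_metadata_missing_columns(self, tmp_path):
        path = tmp_path / "meta.csv"
        pd.DataFrame({"well": ["A1"]}).to_csv(path, index=False)
        with pytest.raises(PlateLayoutError, match="missing columns"):
            read_metadata(path)

    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        t = np.arange(12) * 120.0
        traces = [
            ThTTrace(t=t, F=100 + 1000 * rng.random(12), well=w)
            for w in ("A1", "A2")
        ]
        out = tmp_path / "out.csv"
        write_plate(traces, out)
        back = read_plate_timeseries(out, _metadata_csv(tmp_path, ["A1", "A2"]))
        for orig, rt in zip(traces, back):
            np.testing.assert_array_equal(orig.t, rt.t)
            np.testing.assert_array_equal(orig.F, rt.F)


class TestNormalize:
    def _raw_sigmoid(self, baseline=100.0, gain=1000.0):
        p = __import__("aggrekin").default_reference_parameters()
        t = np.arange(0.0, 10800.0, 120.0)
        M = fibril_mass_analytic(t, p).M_norm
        return ThTTrace(t=t, F=baseline + gain * M)

    def test_recovers_known_affine_transform(self):
        tr = self._raw_sigmoid(baseline=100.0, gain=1000.0)
        nt = normalize_trace(tr)
        assert float(np.mean(nt.y[-10:])) == pytest.approx(1.0, abs=0.005)
        assert float(np.mean(nt.y[:5])) == pytest.approx(0.0, abs=0.005)
        # windows average over the first points of the rise, so the recovered
        # levels sit within a few AU of the true affine parameters
        assert nt.baseline == pytest.approx(100.0, abs=5.0)
        assert nt.plateau == pytest.approx(1100.0, abs=5.0)

    def test_idempotent_on_normalized_input(self):
        tr = self._raw_sigmoid(baseline=0.0, gain=1.0)
        once = normalize_trace(tr)
        twice = normalize_trace(ThTTrace(t=tr.t, F=once.y))
        np.testing.assert_allclose(twice.y, once.y, atol=0.01)

    def test_constant_trace_is_flat(self):
        tr = ThTTrace(t=np.arange(12) * 120.0, F=np.full(12, 250.0))
        with pytest.raises(FlatTraceError):
            normalize_trace(tr)

    def test_unfinished_trace_rejected(self):
        # still rising at the end of the run: no plateau to normalize to
        t = np.arange(0.0, 3600.0, 120.0)
        tr = ThTTrace(t=t, F=100.0 + t)
        with pytest.raises(ValueError, match="plateau"):
            normalize_trace(tr)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 1000.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        tr = self._raw_sigmoid()
        base = normalize_trace(tr)
        scaled = normalize_trace(ThTTrace(t=tr.t, F=a * tr.F + b))
        np.testing.assert_allclose(scaled.y, base.y, atol=1e-9)


class TestAverageReplicates:
    def test_identical_replicates_zero_sd(self, reference_params, two_hour_grid):
        tr = model_trace(reference_params, two_hour_grid)
        avg = average_replicates([tr, tr, tr])
        np.testing.assert_allclose(avg.y, tr.y, rtol=1e-15)
        np.testing.assert_allclose(avg.y_sd, 0.0, atol=1e-15)
        assert avg.n_replicates == 3

    def test_symmetric_offsets_give_closed_form_sd(self, reference_params, two_hour_grid):
        tr = model_trace(reference_params, two_hour_grid)
        hi = model_trace(reference_params, two_hour_grid)
        lo = model_trace(reference_params, two_hour_grid)
        hi.y = tr.y + 0.1
        lo.y = tr.y - 0.1
        avg = average_replicates([tr, hi, lo])
        np.testing.assert_allclose(avg.y, tr.y, atol=1e-12)
        np.testing.assert_allclose(avg.y_sd, 0.1, atol=1e-12)

    def test_mismatched_grids_rejected(self, reference_params, two_hour_grid):
        a = model_trace(reference_params, two_hour_grid)
        b = model_trace(reference_params, two_hour_grid + 1.0)
        with pytest.raises(ValueError, match="grids"):
            average_replicates([a, b])

    def test_mismatched_conditions_rejected(self, reference_params, two_hour_grid):
        a = model_trace(reference_params, two_hour_grid, variant="x")
        b = model_trace(reference_params, two_hour_grid, variant="y")
        with pytest.raises(ValueError, match="conditions"):
            average_replicates([a, b])
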