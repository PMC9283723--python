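"""Plate QC formulas, control normalization anchors, stack correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypselect.config import CorrectionUnavailableWarning, DegenerateControlsError
from cypselect.plates import (
    ControlStats,
    assemble_concentration_series,
    compute_plate_qc,
    control_stats,
    correct_plate_stack,
    normalize_stack,
    percent_activity,
    qc_report,
)
from cypselect.synthetic import (
    ArtifactModel,
    PlateSpec,
    RawPlate,
    generate_library,
    generate_plate_stack,
)


def _plate(dmso_vals, pos_vals, compound_vals=(500.0,)) -> RawPlate:
    """Build a minimal one-row plate from explicit control well values."""
    n = len(dmso_vals) + len(pos_vals) + len(compound_vals)
    reads = np.array([list(dmso_vals) + list(pos_vals) + list(compound_vals)])
    roles = np.array(
        [["dmso"] * len(dmso_vals) + ["positive"] * len(pos_vals)
         + ["compound"] * len(compound_vals)], dtype=object
    )
    ids = np.array([[None] * (n - len(compound_vals))
                    + [f"C{i}" for i in range(len(compound_vals))]], dtype=object)
    return RawPlate("P1", "CYP3A7", reads, roles, ids, 0, 1.0, 0)


class TestPlateQC:
    def test_hand_computed_example(self):
        # means 1000/100, population SDs 20/10: Z' = 1 - 90/900 = 0.9,
        # S/B = 10, CV = 2 %
        plate = _plate([980.0, 1020.0] * 8, [90.0, 110.0] * 8)
        qc = compute_plate_qc(plate)
        assert qc.z_prime == pytest.approx(0.9, abs=1e-12)
        assert qc.s_b == pytest.approx(10.0, abs=1e-12)
        assert qc.cv_pct == pytest.approx(2.0, abs=1e-12)
        assert qc.passed

    def test_zero_variance_gives_z_prime_one(self):
        qc = compute_plate_qc(_plate([1000.0] * 16, [100.0] * 16))
        assert qc.z_prime == 1.0

    def test_sb_below_threshold_fails(self):
        qc = compute_plate_qc(_plate([289.0, 291.0] * 8, [99.5, 100.5] * 8))
        assert qc.s_b == pytest.approx(2.9)
        assert qc.pass_cv and qc.pass_z_prime and not qc.pass_s_b
        assert not qc.passed

    def test_degenerate_controls_raise(self):
        with pytest.raises(DegenerateControlsError):
            compute_plate_qc(_plate([100.0] * 16, [100.0] * 16))

    def test_synthetic_plates_pass_at_five_percent_noise(self):
        """With CV 5 % noise and a 10x control separation, the published QC
        thresholds pass for (at least) 20/20 seeds."""
        spec = PlateSpec(
            n_rows=16, n_cols=24,
            concentration_series=np.array([0.01, 0.1, 1.0, 10.0]),
            noise_cv=0.05, n_dmso_plates_leading=0, n_dmso_plates_trailing=0,
        )
        lib = generate_library(10, 1, 0.0, seed=0, n_bits=8)
        n_pass = 0
        for seed in range(20):
            stack = generate_plate_stack(lib, spec, "CYP3A7",
                                         mu_dmso=1000.0, mu_pos=100.0, seed=seed)
            report = qc_report(stack)
            n_pass += int(report["passed"].all())
        assert n_pass == 20


class TestNormalization:
    def test_anchor_points(self):
        ctrl = ControlStats(v_dmso=1000.0, v_pos=100.0, sd_dmso=20.0, sd_pos=10.0)
        assert percent_activity(1000.0, ctrl) == 0.0
        assert percent_activity(100.0, ctrl) == -100.0
        assert percent_activity(550.0, ctrl) == -50.0

    def test_degenerate_controls_error(self):
        with pytest.raises(DegenerateControlsError):
            ControlStats(v_dmso=100.0, v_pos=100.0, sd_dmso=0.0, sd_pos=0.0)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_affine_invariance(self, scale):
        """Rescaling every read on a plate leaves % activity unchanged."""
        plate = _plate([980.0, 1020.0] * 8, [90.0, 110.0] * 8, (550.0, 300.0))
        ctrl = control_stats(plate)
        base = percent_activity(plate.reads[plate.roles == "compound"], ctrl)
        scaled = RawPlate("P1", "CYP3A7", plate.reads * scale, plate.roles,
                          plate.compound_ids, 0, 1.0, 0)
        ctrl2 = control_stats(scaled)
        again = percent_activity(scaled.reads[scaled.roles == "compound"], ctrl2)
        assert np.allclose(base, again, atol=1e-9)


def _stack(artifact=None, seed=0, lead=2, trail=2):
    spec = PlateSpec(
        n_rows=16, n_cols=24,
        concentration_series=np.geomspace(0.01, 10.0, 5),
        n_dmso_cols=1, n_pos_cols=1, noise_cv=0.0,
        n_dmso_plates_leading=lead, n_dmso_plates_trailing=trail,
        artifact=artifact,
    )
    lib = generate_library(30, 3, 0.5, seed=3, n_bits=16)
    return generate_plate_stack(lib, spec, "CYP3A7", seed=seed)


class TestStackCorrection:
    def test_identity_on_clean_data(self):
        stack = _stack()
        corrected = correct_plate_stack(stack)
        for raw, cor in zip(stack, corrected):
            assert np.allclose(cor.reads, raw.reads, rtol=1e-9)

    def test_removes_planted_gradient(self):
        """A +/-20 % corner-to-corner separable gradient must be removed to
        < 1 % per-well bias."""
        clean = _stack()
        warped = _stack(artifact=ArtifactModel(row_amp=0.2, col_amp=0.2))
        corrected = correct_plate_stack(warped)
        for ref, cor in zip(clean, corrected):
            if ref.concentration_index is None:
                continue
            mask = ref.reads > 0  # fully-inhibited wells clip to zero signal
            rel = np.abs(cor.reads[mask] / ref.reads[mask] - 1.0)
            assert rel.max() < 0.01

    def test_tracks_gradient_drifting_across_stack(self):
        clean = _stack()
        warped = _stack(artifact=ArtifactModel(row_amp=0.2, col_amp=0.2, drift=0.5))
        corrected = correct_plate_stack(warped)
        mid = len(clean) // 2
        ref, cor = clean[mid], corrected[mid]
        mask = ref.reads > 0
        rel = np.abs(cor.reads[mask] / ref.reads[mask] - 1.0)
        assert rel.max() < 0.02

    def test_no_dmso_plates_warns_and_passes_through(self):
        stack = _stack(lead=0, trail=0)
        with pytest.warns(CorrectionUnavailableWarning):
            out = correct_plate_stack(stack)
        assert all(not p.corrected for p in out)


class TestSeriesAssembly:
    def test_full_titration_makes_one_series(self, clean_plate_spec):
        lib = generate_library(5, 1, 1.0, seed=2, n_bits=8)
        stack = generate_plate_stack(lib, clean_plate_spec, "CYP3A7", seed=0)
        wells = normalize_stack(stack)
        series = assemble_concentration_series(wells)
        assert len(series) == 5
        assert all(len(s) == 11 and s.fittable for s in series)
        for s in series:
            assert np.all(np.diff(s.concentrations_um) > 0)

    def test_duplicate_concentrations_average(self):
        import pandas as pd

        wells = pd.DataFrame(
            {
                "compound_id": ["A"] * 5,
                "enzyme": ["CYP3A7"] * 5,
                "concentration_um": [0.1, 1.0, 1.0, 10.0, 58.0],
                "activity_pct": [0.0, -40.0, -60.0, -80.0, -90.0],
            }
        )
        (s,) = assemble_concentration_series(wells)
        assert len(s) == 4
        assert s.activities_pct[1] == pytest.approx(-50.0)

    def test_three_points_flagged_unfittable(self):
        import pandas as pd

        wells = pd.DataFrame(
            {
                "compound_id": ["A"] * 3,
                "enzyme": ["CYP3A7"] * 3,
                "concentration_um": [0.1, 1.0, 10.0],
                "activity_pct": [0.0, -50.0, -90.0],
            }
        )
        (s,) = assemble_concentration_series(wells)
        assert not s.fittable
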