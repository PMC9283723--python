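"""Generator round trips: the latent truth must be recoverable exactly when
noise is switched off, and every draw must be reproducible from the seed."""

import numpy as np
import pandas as pd
import pytest

from cypselect.config import ConfigurationError
from cypselect.plates import normalize_stack
from cypselect.synthetic import (
    EnzymeTruth,
    GroundTruthCompound,
    PlateSpec,
    generate_depletion_panel,
    generate_descriptor_table,
    generate_library,
    generate_plate_stack,
    ground_truth_table,
)


def _single_compound_library(truth_3a7: EnzymeTruth) -> list[GroundTruthCompound]:
    return [
        GroundTruthCompound(
            compound_id="CPD-00000",
            cluster_label=0,
            fingerprint=np.zeros(16, dtype=np.uint8),
            truth={"CYP3A7": truth_3a7, "CYP3A4": EnzymeTruth()},
        )
    ]


class TestLibrary:
    def test_same_seed_is_byte_identical(self):
        a = generate_library(60, 5, 0.3, seed=42, n_bits=64)
        b = generate_library(60, 5, 0.3, seed=42, n_bits=64)
        pd.testing.assert_frame_equal(ground_truth_table(a), ground_truth_table(b))
        assert all(np.array_equal(x.fingerprint, y.fingerprint) for x, y in zip(a, b))

    def test_uniform_plan_yields_expected_active_count(self):
        lib = generate_library(100, 5, 0.2, seed=1)
        reg = ground_truth_table(lib)
        assert len(lib) == 100
        assert set(reg["cluster_label"]) <= set(range(5))
        n_active = sum(1 for c in lib if c.truth["CYP3A7"].direction != "inactive")
        # binomial(100, 0.2): 3 sigma around 20
        assert 8 <= n_active <= 32

    def test_zero_flip_probability_gives_identical_fingerprints(self):
        lib = generate_library(10, 1, 0.5, seed=0, n_bits=32, bit_flip_prob=0.0)
        fps = np.vstack([c.fingerprint for c in lib])
        assert (fps == fps[0]).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_compounds": 3, "n_clusters": 5},
            {"n_compounds": 10, "n_clusters": 2, "enrichment_plan": {7: 0.5}},
            {"n_compounds": 10, "n_clusters": 2, "enrichment_plan": {0: 1.5}},
        ],
    )
    def test_inconsistent_plans_raise(self, kwargs):
        with pytest.raises(ConfigurationError):
            generate_library(seed=0, **kwargs)


class TestSignalMap:
    def test_half_inhibition_at_ac50_maps_to_550(self):
        # a(ac50) = efficacy/2 exactly; with mu 1000/100 the read is 550
        truth = EnzymeTruth("inhibitor", ac50_um=1.0, hill=1.0, efficacy_pct=-100.0)
        spec = PlateSpec(
            n_rows=16, n_cols=24,
            concentration_series=np.array([0.01, 0.1, 1.0, 10.0]),
            n_dmso_cols=1, n_pos_cols=1, noise_cv=0.0,
            n_dmso_plates_leading=1, n_dmso_plates_trailing=1,
        )
        stack = generate_plate_stack(
            _single_compound_library(truth), spec, "CYP3A7",
            mu_dmso=1000.0, mu_pos=100.0, seed=0,
        )
        plate_at_ac50 = next(p for p in stack if p.concentration_um == 1.0)
        well = plate_at_ac50.reads[plate_at_ac50.compound_ids == "CPD-00000"]
        assert well[0] == pytest.approx(550.0, abs=1e-9)

    def test_full_inhibition_reaches_positive_control_level(self):
        truth = EnzymeTruth("inhibitor", ac50_um=1e-6, hill=1.0, efficacy_pct=-100.0)
        spec = PlateSpec(
            n_rows=16, n_cols=24,
            concentration_series=np.array([1.0, 10.0, 100.0, 1000.0]),
            n_dmso_cols=1, n_pos_cols=1, noise_cv=0.0,
        )
        stack = generate_plate_stack(
            _single_compound_library(truth), spec, "CYP3A7",
            mu_dmso=1000.0, mu_pos=100.0, seed=0,
        )
        top = next(p for p in stack if p.concentration_um == 1000.0)
        well = top.reads[top.compound_ids == "CPD-00000"][0]
        assert well == pytest.approx(100.0, rel=1e-6)

    def test_inactive_compound_sits_at_dmso_level(self):
        spec = PlateSpec(
            n_rows=16, n_cols=24,
            concentration_series=np.array([0.01, 1.0, 10.0, 58.0]),
            n_dmso_cols=1, n_pos_cols=1, noise_cv=0.0,
        )
        stack = generate_plate_stack(
            _single_compound_library(EnzymeTruth()), spec, "CYP3A7",
            mu_dmso=1000.0, mu_pos=100.0, seed=0,
        )
        for p in stack:
            assert np.allclose(p.reads[p.compound_ids == "CPD-00000"], 1000.0)

    def test_empty_library_raises(self, clean_plate_spec):
        with pytest.raises(ConfigurationError):
            generate_plate_stack([], clean_plate_spec, "CYP3A7", seed=0)

    def test_noise_free_normalization_round_trip(self, clean_plate_spec):
        """With no noise and no artifact, normalization must return the true
        Hill-curve activity at every well to 1e-9."""
        lib = generate_library(30, 3, 0.7, seed=5, n_bits=32)
        stack = generate_plate_stack(lib, clean_plate_spec, "CYP3A7", seed=0)
        wells = normalize_stack(stack)
        truth = {c.compound_id: c.truth["CYP3A7"] for c in lib}
        for _, row in wells.iterrows():
            expected = float(truth[row.compound_id].activity_at(row.concentration_um))
            assert row.activity_pct == pytest.approx(expected, abs=1e-9)


class TestDepletionPanel:
    def test_closed_form_half_life(self):
        truth = EnzymeTruth(k_per_min=np.log(2) / 13.8)
        panel = generate_depletion_panel(
            _single_compound_library(truth),
            time_points_min=(0.0, 13.8, 27.6), noise_cv=0.0, seed=0,
        )
        row = panel[(panel.enzyme == "CYP3A7") & (panel.time_min == 13.8)]
        assert row.pct_remaining.iloc[0] == pytest.approx(50.0, rel=1e-12)

    def test_stable_compound_is_flat_and_t0_is_exact(self):
        panel = generate_depletion_panel(
            _single_compound_library(EnzymeTruth()), noise_cv=0.3, seed=1
        )
        p7 = panel[panel.enzyme == "CYP3A7"]
        assert p7.loc[p7.time_min == 0, "pct_remaining"].iloc[0] == 100.0
        noise_free = generate_depletion_panel(
            _single_compound_library(EnzymeTruth()), noise_cv=0.0, seed=1
        )
        assert (noise_free.pct_remaining == 100.0).all()

    def test_negative_time_raises(self):
        with pytest.raises(ConfigurationError):
            generate_depletion_panel(
                _single_compound_library(EnzymeTruth()),
                time_points_min=(0.0, -5.0), seed=0,
            )


class TestDescriptors:
    def test_zero_sd_pins_values_to_group_mean(self):
        lib = generate_library(20, 2, 1.0, seed=3, n_bits=16)
        profiles = {
            g: {"slogp": (3.0, 0.0), "flag": (1.0, None)}
            for g in ("common", "CYP3A4", "CYP3A7", "other")
        }
        table = generate_descriptor_table(lib, profiles, seed=0)
        assert (table["slogp"] == 3.0).all()
        assert set(table["flag"]) <= {0.0, 1.0}

    def test_group_means_track_published_profile(self):
        # CYP3A7-selective profile has SlogP 3 +/- 2: sample mean within
        # 3*SD/sqrt(n) of 3 for a large library
        lib = generate_library(3000, 4, 0.5, seed=9, n_bits=16)
        table = generate_descriptor_table(lib, seed=9)
        grp = table[table.group == "CYP3A7"]
        n = len(grp)
        assert n > 100
        assert abs(grp["slogp"].mean() - 3.0) < 3.0 * 2.0 / np.sqrt(n)

    def test_negative_sd_raises(self):
        lib = generate_library(4, 2, 0.5, seed=0, n_bits=8)
        bad = {g: {"x": (0.0, -1.0)} for g in ("common", "CYP3A4", "CYP3A7", "other")}
        with pytest.raises(ConfigurationError):
            generate_descriptor_table(lib, bad, seed=0)

    def test_inconsistent_profiles_raise(self):
        lib = generate_library(4, 2, 0.5, seed=0, n_bits=8)
        bad = {
            "common": {"x": (0.0, 1.0)},
            "CYP3A4": {"y": (0.0, 1.0)},
        }
        with pytest.raises(ConfigurationError):
            generate_descriptor_table(lib, bad, seed=0)
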