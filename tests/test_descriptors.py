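"""Descriptor construction, feature assembly and dataset I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoyield.descriptors import (
    ELECTRONIC_COLUMNS,
    ElectronicDescriptors,
    FeatureSpec,
    ReactionDataset,
    SensitizerRecord,
    assemble_features,
    read_dataset,
    scale_rates,
    write_dataset,
)
from photoyield.kinetics import RateConstantSet


class TestScaleRates:
    def test_equal_rates_split_evenly(self):
        s = scale_rates(RateConstantSet(1e6, 1e6, 1e6, 1e6, 1e6))
        assert all(v == pytest.approx(0.2, rel=1e-12) for v in s.as_tuple())

    def test_ops1_printed_scaled_descriptors(self):
        """Theoretical OPS1 rates reproduce its published scaled ratios.

        s_k_r = 0.431 and s_k_ic = 9.6e-4 are printed; s_k_risc ~ 1.2e-6
        follows from the printed k_risc = 5.3e1 against the rate sum.
        """
        s = scale_rates(RateConstantSet(2.0e7, 4.46e4, 2.6e7, 5.3e1, 3.6e5))
        assert s.s_k_r_S1S0 == pytest.approx(0.431, rel=0.10)
        assert s.s_k_ic_S1S0 == pytest.approx(9.6e-4, rel=0.10)
        assert s.s_k_risc_T1S1 == pytest.approx(1.2e-6, rel=0.10)

    def test_zero_rate_scales_to_zero(self):
        s = scale_rates(RateConstantSet(k_r_S1S0=1e7, k_risc_T1S1=0.0))
        assert s.s_k_risc_T1S1 == 0.0

    def test_all_zero_rates_unconstructible(self):
        with pytest.raises(ValueError):
            RateConstantSet(0, 0, 0, 0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        logs=st.lists(st.floats(min_value=-2, max_value=9), min_size=5, max_size=5),
        log_c=st.floats(min_value=-6, max_value=6),
    )
    def test_scale_invariance_and_sum_to_one(self, logs, log_c):
        """Multiplying all rates by a positive constant leaves s_RC unchanged."""
        ks = 10.0 ** np.array(logs)
        c = 10.0 ** log_c
        s1 = scale_rates(RateConstantSet(*ks))
        s2 = scale_rates(RateConstantSet(*(c * ks)))
        assert sum(s1.as_tuple()) == pytest.approx(1.0, abs=1e-9)
        for a, b in zip(s1.as_tuple(), s2.as_tuple()):
            assert a == pytest.approx(b, rel=1e-9, abs=1e-15)

    def test_component_ratios_equal_rate_ratios(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ks = 10.0 ** rng.uniform(0, 9, 5)
            s = scale_rates(RateConstantSet(*ks)).as_tuple()
            for i in range(5):
                for j in range(5):
                    assert s[i] / s[j] == pytest.approx(ks[i] / ks[j], rel=1e-9)


class TestElectronicDescriptors:
    def test_gap_consistency_enforced(self):
        with pytest.raises(ValueError):
            ElectronicDescriptors(
                E_HOMO_eV=-5.8, E_LUMO_eV=-1.8, E_S1_eV=3.0, E_T1_eV=2.7, dEST_eV=0.5
            )

    def test_gap_autofilled(self):
        e = ElectronicDescriptors(
            E_HOMO_eV=-5.8, E_LUMO_eV=-1.8, E_S1_eV=3.0, E_T1_eV=2.7
        )
        assert e.dEST_eV == pytest.approx(0.3)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ElectronicDescriptors(
                E_HOMO_eV=-1.0, E_LUMO_eV=-2.0, E_S1_eV=3.0, E_T1_eV=2.7
            )
        with pytest.raises(ValueError):
            ElectronicDescriptors(
                E_HOMO_eV=-5.8, E_LUMO_eV=-1.8, E_S1_eV=2.0, E_T1_eV=2.7
            )


def _record(i, k_risc=1e5):
    rates = RateConstantSet(1e7 * (i + 1), 1e5, 2e7, k_risc, 1e4)
    elec = ElectronicDescriptors(
        E_HOMO_eV=-5.8 + 0.01 * i, E_LUMO_eV=-1.8, E_S1_eV=3.0, E_T1_eV=2.8
    )
    return SensitizerRecord(
        sensitizer_id=f"S{i}", rates=rates, electronic=elec,
        lifetime_columns={"LT_t_s": 1e-6 * (i + 1)},
    )


def _reactions(n_sens, reaction_ids, rng):
    rows = [
        {"sensitizer_id": f"S{i}", "reaction_id": r,
         "yield_percent": float(rng.uniform(0, 100))}
        for i in range(n_sens)
        for r in reaction_ids
    ]
    return ReactionDataset(pd.DataFrame(rows))


class TestAssembleFeatures:
    def test_default_campaign_shape(self, default_data, full_spec):
        """60 x 5 with s_RC + 4 auxiliaries + one-hot -> 300 x 14 matrix."""
        dataset, sensitizers = default_data
        spec = FeatureSpec(
            base_set="s_RC",
            auxiliary=("E_HOMO_eV", "f_S1", "dEST_eV", "dDM_debye"),
        )
        m = assemble_features(dataset, sensitizers, spec)
        assert len(m) == 300
        assert len(m.feature_names) == 5 + 4 + 5

    def test_counting_without_auxiliaries(self):
        rng = np.random.default_rng(0)
        sens = [_record(i) for i in range(4)]
        ds = _reactions(4, ["A", "B"], rng)
        m = assemble_features(ds, sens, FeatureSpec(base_set="s_RC"))
        assert len(m.feature_names) == 5 + 2

    def test_duplicate_pair_rejected(self):
        frame = pd.DataFrame(
            {
                "sensitizer_id": ["S0", "S0"],
                "reaction_id": ["A", "A"],
                "yield_percent": [10.0, 20.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            ReactionDataset(frame)

    def test_unknown_sensitizer_listed(self):
        rng = np.random.default_rng(0)
        ds = _reactions(3, ["A"], rng)
        with pytest.raises(KeyError, match="S2"):
            assemble_features(ds, [_record(0), _record(1)], FeatureSpec())

    def test_rc_log_transform_default_and_raw_mode(self):
        rng = np.random.default_rng(0)
        sens = [_record(i) for i in range(3)]
        ds = _reactions(3, ["A"], rng)
        logm = assemble_features(ds, sens, FeatureSpec(base_set="RC"))
        raw = assemble_features(
            ds, sens, FeatureSpec(base_set="RC", rate_transform="raw")
        )
        assert "log10_k_r_S1S0" in logm.feature_names
        assert logm.X.loc[("S0", "A"), "log10_k_r_S1S0"] == pytest.approx(7.0)
        assert raw.X.loc[("S0", "A"), "k_r_S1S0"] == pytest.approx(1e7)

    def test_underflowing_rate_floored_before_log(self):
        sens = [_record(0, k_risc=6.8e-5), _record(1)]
        rng = np.random.default_rng(0)
        ds = _reactions(2, ["A"], rng)
        m = assemble_features(ds, sens, FeatureSpec(base_set="RC"))
        assert m.X.loc[("S0", "A"), "log10_k_risc_T1S1"] == pytest.approx(
            np.log10(6.8e-5)
        )
        zero = [_record(0, k_risc=0.0), _record(1)]
        m0 = assemble_features(ds, zero, FeatureSpec(base_set="RC"))
        assert m0.X.loc[("S0", "A"), "log10_k_risc_T1S1"] == -12.0

    def test_deterministic_column_order(self, tiny_data, full_spec):
        dataset, sensitizers = tiny_data
        a = assemble_features(dataset, sensitizers, full_spec)
        b = assemble_features(dataset, sensitizers, full_spec)
        assert a.feature_names == b.feature_names
        pd.testing.assert_frame_equal(a.X, b.X)

    def test_unknown_auxiliary_rejected(self):
        with pytest.raises(ValueError, match="E_HOMO"):
            FeatureSpec(auxiliary=("E_HOMO",))  # must use the _eV column name


class TestDatasetIO:
    def test_round_trip_exact(self, tmp_path, tiny_data):
        dataset, sensitizers = tiny_data
        sp, rp = tmp_path / "s.csv", tmp_path / "r.csv"
        write_dataset(sensitizers, dataset, sp, rp)
        ds2, sens2 = read_dataset(sp, rp)
        pd.testing.assert_frame_equal(dataset.frame, ds2.frame)
        for a, b in zip(sensitizers, sens2):
            assert a.sensitizer_id == b.sensitizer_id
            assert a.rates.as_tuple() == b.rates.as_tuple()
            assert a.electronic.as_dict() == b.electronic.as_dict()

    def test_out_of_range_yield_rejected_with_row(self):
        frame = pd.DataFrame(
            {
                "sensitizer_id": ["S0", "S1"],
                "reaction_id": ["A", "A"],
                "yield_percent": [50.0, 101.0],
            }
        )
        with pytest.raises(ValueError, match=r"\[1\]"):
            ReactionDataset(frame)

    def test_lifetime_columns_pass_through(self, tmp_path):
        rng = np.random.default_rng(1)
        sens = [_record(i) for i in range(3)]
        ds = _reactions(3, ["A"], rng)
        sp, rp = tmp_path / "s.csv", tmp_path / "r.csv"
        write_dataset(sens, ds, sp, rp)
        _, sens2 = read_dataset(sp, rp)
        for a, b in zip(sens, sens2):
            assert b.lifetime_columns["LT_t_s"] == a.lifetime_columns["LT_t_s"]

    def test_missing_mandatory_column_reported(self, tmp_path, tiny_data):
        dataset, sensitizers = tiny_data
        sp, rp = tmp_path / "s.csv", tmp_path / "r.csv"
        write_dataset(sensitizers, dataset, sp, rp)
        frame = pd.read_csv(sp).drop(columns=["E_HOMO_eV"])
        frame.to_csv(sp, index=False)
        with pytest.raises(ValueError, match="E_HOMO_eV"):
            read_dataset(sp, rp)
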