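"""Neutral-loss prediction, attribution and relative fragment intensities."""

import numpy as np
import pytest

from domfrag.chem import ElementalFormula, ion_mass, neutral_mass, parse_formula
from domfrag.fragmentation import (
    ALL_LOSSES,
    MAJOR_LOSSES,
    FragmentProfile,
    IsolationWindow,
    apply_common_detection_limit,
    attribute_fragments,
    calibrate_fragment_spectrum,
    common_detection_limit,
    predict_fragments,
    relative_intensities,
)
from domfrag.peaks import CalibrationError, Peak, PeakList


PRINTED_LOSS_MASSES = {
    "H2O": 18.01056,
    "CO2": 43.98983,
    "CO2+H2O": 62.00039,
    "2CO2": 87.97966,
    "2CO2+H2O": 105.99022,
    "3CO2": 131.96949,
}


class TestLossTable:
    def test_major_set_is_exactly_the_nine(self):
        assert {l.label for l in MAJOR_LOSSES} == {
            "CO2", "2CO2", "3CO2", "H2O", "CO2+H2O", "2CO2+H2O",
            "CH3OH", "CO2+CH3OH", "2CO2+CH3OH",
        }
        assert all(l.is_major for l in MAJOR_LOSSES)

    @pytest.mark.parametrize("label,mass", PRINTED_LOSS_MASSES.items())
    def test_exact_masses_match_calibration_list(self, label, mass):
        loss = next(l for l in ALL_LOSSES if l.label == label)
        assert round(loss.exact_mass, 5) == mass

    def test_exact_mass_consistent_with_formula(self):
        for loss in ALL_LOSSES:
            assert loss.exact_mass == pytest.approx(
                neutral_mass(loss.formula), abs=1e-6
            )


class TestPredict:
    def test_co2_loss_of_c18h22o8(self, c18h22o8):
        frags = dict(predict_fragments(c18h22o8))
        co2 = next(l for l in ALL_LOSSES if l.label == "CO2")
        assert frags[co2] == pytest.approx(321.13436, abs=1e-5)

    def test_3co2_from_benzenetricarboxylic_gives_benzene(self, btc):
        frags = {l.label: mz for l, mz in predict_fragments(btc)}
        assert frags["3CO2"] == pytest.approx(77.03967, abs=1e-5)
        loss3 = next(l for l in ALL_LOSSES if l.label == "3CO2")
        assert btc - loss3.formula == ElementalFormula(c=6, h=6)

    def test_insufficient_atoms_skipped(self):
        ch4 = ElementalFormula(c=1, h=4)
        labels = {l.label for l, _ in predict_fragments(ch4)}
        assert "CO2" not in labels and "H2O" not in labels

    def test_round_trip_fragment_plus_loss(self, c18h22o8):
        for loss, _ in predict_fragments(c18h22o8):
            assert (c18h22o8 - loss.formula) + loss.formula == c18h22o8


def _frag_spectrum(precursor, profile, total=1e6, offset_ppm=0.0, noise=100.0):
    mz_by_label = {"precursor": ion_mass(precursor)}
    mz_by_label.update({l.label: mz for l, mz in predict_fragments(precursor)})
    peaks = [
        Peak(
            mz=mz_by_label[lbl] * (1 + offset_ppm / 1e6),
            intensity=total * share,
            snr=total * share / noise,
        )
        for lbl, share in profile.items()
        if share > 0
    ]
    return PeakList(
        sample_id="f", peaks=peaks, scan_type="fragmentation",
        isolation_center=round(ion_mass(precursor)),
    )


class TestCalibrateFragmentSpectrum:
    PROFILE = {"precursor": 0.5, "CO2": 0.2, "2CO2": 0.1, "H2O": 0.1, "CO2+H2O": 0.1}

    def test_recovers_injected_offset(self, c18h22o8):
        pl = _frag_spectrum(c18h22o8, self.PROFILE, offset_ppm=0.4)
        _, result = calibrate_fragment_spectrum(pl, [c18h22o8])
        assert result.max_abs_ppm < 0.02
        assert result.offset_ppm == pytest.approx(0.4, abs=0.02)

    def test_identity_on_calibrated_input(self, c18h22o8):
        pl = _frag_spectrum(c18h22o8, self.PROFILE, offset_ppm=0.0)
        corrected, result = calibrate_fragment_spectrum(pl, [c18h22o8])
        assert abs(result.offset_ppm) < 1e-9
        np.testing.assert_allclose(corrected.mz, pl.mz, rtol=1e-12)

    def test_zero_matches_errors(self, c18h22o8):
        pl = PeakList(
            sample_id="junk",
            peaks=[Peak(mz=111.111, intensity=1, snr=9)],
            scan_type="fragmentation",
        )
        with pytest.raises(CalibrationError):
            calibrate_fragment_spectrum(pl, [c18h22o8])


class TestAttribution:
    def test_close_precursors_resolved_by_exact_mass(self):
        # window-381-style pair separated by the CH4/O spacing (0.0364 Da)
        a = parse_formula("C19H26O7")
        b = parse_formula("C18H22O8")
        assert abs(ion_mass(a) - ion_mass(b)) == pytest.approx(0.03639, abs=1e-4)
        co2 = next(l for l in ALL_LOSSES if l.label == "CO2")
        frag_mz = ion_mass(a) - co2.exact_mass
        pl = PeakList(
            sample_id="w",
            peaks=[Peak(mz=frag_mz, intensity=100.0, snr=50.0)],
            scan_type="fragmentation",
        )
        records, unattributed = attribute_fragments(pl, [a, b], tol_ppm=1.0)
        assert not unattributed
        assert {r.precursor_formula for r in records} == {a}
        assert records[0].loss.label == "CO2"

    def test_degenerate_explanations_flagged_ambiguous(self):
        # two precursors 18.01056 Da apart: A - (CO2+H2O) == B - CO2 exactly
        b = parse_formula("C18H22O8")
        a = b + parse_formula("H2O")
        co2 = next(l for l in ALL_LOSSES if l.label == "CO2")
        frag_mz = ion_mass(b) - co2.exact_mass
        pl = PeakList(
            sample_id="w",
            peaks=[Peak(mz=frag_mz, intensity=100.0, snr=50.0)],
            scan_type="fragmentation",
        )
        records, _ = attribute_fragments(pl, [a, b], tol_ppm=1.0)
        assert len(records) == 2
        assert all(r.ambiguous for r in records)
        split, _ = attribute_fragments(pl, [a, b], tol_ppm=1.0, ambiguous_policy="split")
        assert sum(r.intensity for r in split) == pytest.approx(100.0)

    def test_empty_spectrum(self, c18h22o8):
        pl = PeakList(sample_id="w", peaks=[], scan_type="fragmentation")
        records, unattributed = attribute_fragments(pl, [c18h22o8])
        assert records == [] and unattributed == []


class TestRelativeIntensities:
    def test_forced_arithmetic(self, c18h22o8):
        profile_in = {"precursor": 0.8, "CO2": 0.15, "H2O": 0.05}
        pl = _frag_spectrum(c18h22o8, profile_in, total=100.0)
        records, _ = attribute_fragments(pl, [c18h22o8])
        prof = relative_intensities(records, c18h22o8, 80.0)
        assert prof.rel["CO2"] == pytest.approx(0.15)
        assert prof.rel["H2O"] == pytest.approx(0.05)
        assert prof.precursor_share == pytest.approx(0.80)

    def test_shares_sum_to_one(self, c18h22o8):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0, 1, 10)
        labels = ["precursor"] + [l.label for l in MAJOR_LOSSES]
        profile = dict(zip(labels, raw / raw.sum()))
        pl = _frag_spectrum(c18h22o8, profile, total=1e5)
        records, _ = attribute_fragments(pl, [c18h22o8])
        prec_int = profile["precursor"] * 1e5
        prof = relative_intensities(records, c18h22o8, prec_int)
        assert prof.precursor_share + sum(prof.rel.values()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_no_fragments_means_precursor_share_one(self, c18h22o8):
        prof = relative_intensities([], c18h22o8, 500.0)
        assert prof.precursor_share == 1.0
        assert all(v == 0.0 for v in prof.rel.values())

    def test_absent_precursor_errors(self, c18h22o8):
        with pytest.raises(ValueError, match="I_Tot"):
            relative_intensities([], c18h22o8, 0.0)


class TestCommonDetectionLimit:
    def test_minimum_across_samples(self):
        assert common_detection_limit({"a": 120.0, "b": 85.0, "c": 210.0}) == 85.0
        assert common_detection_limit({"solo": 42.0}) == 42.0

    def test_symmetric_censoring(self, c18h22o8):
        def prof(rel_co2):
            rel = {l.label: 0.0 for l in MAJOR_LOSSES}
            rel["CO2"] = rel_co2
            rel["H2O"] = 0.3
            return FragmentProfile(
                precursor_formula=c18h22o8,
                precursor_share=1 - rel_co2 - 0.3,
                rel=rel,
                precursor_snr=100.0,
            )

        # threshold_rel = 1/100; CO2 below it in sample b only
        out = apply_common_detection_limit({"a": prof(0.05), "b": prof(0.005)})
        assert out["a"].rel["CO2"] == 0.0 and out["b"].rel["CO2"] == 0.0
        assert out["a"].rel["H2O"] == 0.3  # untouched


class TestIsolationWindow:
    def test_contains_and_validation(self):
        w = IsolationWindow(center=381.2)
        assert w.width == 0.4
        assert w.contains(381.35) and not w.contains(381.45)
        with pytest.raises(ValueError):
            IsolationWindow(center=381.0, width=0.0)
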