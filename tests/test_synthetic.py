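"""The synthetic-spectrum generator: determinism, truth traceability and
the statistical structure the pipeline is meant to detect."""

import numpy as np
import pytest

from domfrag.chem import ion_mass
from domfrag.fragmentation import IsolationWindow, MAJOR_LOSSES, PRECURSOR_LABEL
from domfrag.stats import paired_regression
from domfrag.synthetic import (
    GeneratorConfig,
    generate_fragmentation,
    generate_fullrange,
    make_model_compound_fixture,
    windows_for_formulas,
)
from domfrag.synthetic import _sample_profile  # noqa: PLC2701  (white-box checks)


class TestFullRange:
    def test_bit_identical_under_same_seed(self):
        cfg = GeneratorConfig(seed=3, n_formulae=60, noise_peak_rate=0.1,
                              emit_isotopologues=True)
        s1, _ = generate_fullrange(cfg)
        s2, _ = generate_fullrange(cfg)
        for k in s1:
            assert [(p.mz, p.intensity, p.snr) for p in s1[k].peaks] == [
                (p.mz, p.intensity, p.snr) for p in s2[k].peaks
            ]

    def test_zero_formulae_gives_empty_spectra(self):
        spectra, truth = generate_fullrange(GeneratorConfig(seed=0, n_formulae=0))
        assert all(len(pl) == 0 for pl in spectra.values())
        assert truth.formulas == []

    def test_isotopologue_companions_present(self):
        cfg = GeneratorConfig(seed=4, n_formulae=40, emit_isotopologues=True,
                              ppm_jitter_sd=0.01)
        spectra, truth = generate_fullrange(cfg)
        for s, pl in spectra.items():
            mz = pl.mz
            for f in truth.membership[s]:
                target = ion_mass(f) + 1.0033548
                d = np.min(np.abs(mz - target))
                assert d / target * 1e6 < 0.5, f.hill()

    def test_mz_inside_window_and_intensities_positive(self):
        cfg = GeneratorConfig(seed=5, n_formulae=80)
        spectra, _ = generate_fullrange(cfg)
        for pl in spectra.values():
            assert (pl.intensity > 0).all()
            assert (pl.mz >= cfg.mass_min - 0.01).all()
            assert (pl.mz <= cfg.mass_max + 0.01).all()

    def test_every_emitted_peak_traces_to_truth(self):
        cfg = GeneratorConfig(seed=6, n_formulae=50, noise_peak_rate=0.2,
                              ppm_jitter_sd=0.01)
        spectra, truth = generate_fullrange(cfg)
        for s, pl in spectra.items():
            true_mz = np.array(sorted(ion_mass(f) for f in truth.membership[s]))
            noise = np.array(sorted(truth.noise_mz[s])) if truth.noise_mz[s] else np.empty(0)
            for p in pl.peaks:
                near_true = np.min(np.abs(true_mz - p.mz)) < 0.001
                near_noise = noise.size and np.min(np.abs(noise - p.mz)) < 0.001
                assert near_true or near_noise

    def test_injected_offset_is_recorded(self):
        cfg = GeneratorConfig(seed=7, n_formulae=30, calibration_offset_ppm=0.4,
                              ppm_jitter_sd=0.0)
        spectra, truth = generate_fullrange(cfg)
        assert truth.calibration_offset_ppm == 0.4
        s = cfg.sample_ids[0]
        f = sorted(truth.membership[s], key=ion_mass)[0]
        mz = ion_mass(f)
        measured = spectra[s].mz[np.argmin(np.abs(spectra[s].mz - mz))]
        assert (measured - mz) / mz * 1e6 == pytest.approx(0.4, abs=1e-6)


@pytest.fixture(scope="module")
def scenario():
    cfg = GeneratorConfig(seed=8, n_formulae=60, sample_ids=("A", "B"),
                          profile_divergence=0.0, isomers_per_formula=5)
    spectra, truth = generate_fullrange(cfg)
    window = windows_for_formulas(truth.formulas)[3]
    scans = generate_fragmentation(cfg, window, truth)
    return cfg, truth, window, scans


class TestFragmentation:
    def test_zero_divergence_profiles_identical_across_samples(self, scenario):
        cfg, truth, window, _ = scenario
        for f in truth.formulas[:5]:
            pa = _sample_profile(truth, "A", f)
            pb = _sample_profile(truth, "B", f)
            assert pa == pb

    def test_zero_divergence_regression_slope_near_one(self, scenario):
        cfg, truth, window, scans = scenario
        rel = {}
        for s, pl in scans.items():
            precursors = [f for f in truth.membership[s] if window.contains(ion_mass(f))]
            vec = {}
            for f in precursors:
                prof = _sample_profile(truth, s, f)
                for lbl, share in prof.items():
                    if lbl != PRECURSOR_LABEL and share > 0:
                        vec[(f.hill(), lbl)] = share
            rel[s] = vec
        keys = sorted(set(rel["A"]) & set(rel["B"]))
        res = paired_regression(
            {k: rel["A"][k] for k in keys}, {k: rel["B"][k] for k in keys}
        )
        assert res.slope == pytest.approx(1.0, abs=1e-9)

    def test_empty_window_errors(self, scenario):
        cfg, truth, _, _ = scenario
        with pytest.raises(ValueError, match="no precursor"):
            generate_fragmentation(cfg, IsolationWindow(center=1999.0), truth)

    def test_isomer_averaging_shrinks_cfrag_variance(self):
        """Among formulas with the same oxygen count (same expected
        carboxyl number), the spread of the true carboxyl estimate
        shrinks roughly like 1/sqrt(n_isomers)."""
        from domfrag.synthetic import _ensure_isomers

        def pooled_sd(n_isomers, seed):
            cfg = GeneratorConfig(
                seed=seed, n_formulae=200, sample_ids=("A",),
                isomers_per_formula=n_isomers,
            )
            _, truth = generate_fullrange(cfg)
            _ensure_isomers(truth, truth.formulas)
            by_o = {}
            for f in truth.formulas:
                by_o.setdefault(f.o, []).append(truth.true_c_frag(f))
            variances = [np.var(v, ddof=1) for v in by_o.values() if len(v) > 3]
            return float(np.sqrt(np.mean(variances)))

        sd1 = pooled_sd(1, 21)
        sd25 = pooled_sd(25, 21)
        assert sd25 < sd1 / 2.5  # ~5x shrinkage expected, allow slack

    def test_precursor_only_profile_gives_fragment_free_spectrum(self):
        cfg = GeneratorConfig(seed=9, n_formulae=20, sample_ids=("A",),
                              carboxyl_mean_slope=0.0, co2_loss_prob=0.0)
        _, truth = generate_fullrange(cfg)
        f = truth.formulas[0]
        prof = _sample_profile(truth, "A", f)
        # with q=0 nothing decarboxylates: all CO2-series shares vanish
        assert all(
            prof[l.label] == 0 for l in MAJOR_LOSSES if l.co2_multiplicity > 0
        )


class TestModelCompoundFixture:
    def test_three_isomers_share_precursor_mass(self):
        spectra, profiles = make_model_compound_fixture()
        assert len(spectra) == 3
        for pl in spectra.values():
            assert np.min(np.abs(pl.mz - 209.00916)) < 1e-4

    def test_distinct_profiles_give_large_slope_deviation(self):
        _, profiles = make_model_compound_fixture()
        names = sorted(profiles)
        labels = sorted({k for p in profiles.values() for k in p})
        a = {k: profiles[names[0]].get(k, 0.0) for k in labels}
        b = {k: profiles[names[1]].get(k, 0.0) for k in labels}
        res = paired_regression(a, b)
        assert res.delta_sl > 0.3

    def test_fixture_vs_itself_is_exact(self):
        _, profiles = make_model_compound_fixture()
        name = sorted(profiles)[0]
        p = {k: v for k, v in profiles[name].items()}
        res = paired_regression(p, p)
        assert res.delta_sl == pytest.approx(0.0, abs=1e-12)
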