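# domfrag

Molecular universality analysis of dissolved organic matter (DOM) from
ultrahigh-resolution mass spectrometry.

Natural DOM is one of the most complex molecular mixtures known: a single
negative-mode FT-ICR-MS spectrum resolves thousands of elemental
compositions, and each molecular formula hides an unknown number of
structural isomers. `domfrag` implements the complete computational chain
needed to ask whether DOM from different aquatic environments is not just
*compositionally* but *structurally* alike:

1. **Formula assignment** — exhaustive enumeration of CHNOSP compositions
   for each calibrated peak under the standard DOM criteria
   (C₀–₆₀, N₀–₄, S₀–₂, P₀–₁, O/C ≤ 1, H/C ≥ 0.3, integer DBE ≥ 0, [M−H]⁻
   ions), ¹³C₁/¹⁵N₁ isotopologue verification, and compound-class labels
   from the modified aromaticity index
   AI_mod = (1 + C − ½O − S − ½(N+P+H)) / (C − ½O − S − N − P).
2. **Neutral-loss fragmentation analysis** — precursor ions isolated in
   0.4 Da windows lose CO₂, H₂O, CH₃OH and combinations thereof; fragments
   are predicted by exact mass arithmetic, used for internal calibration of
   the fragmentation spectra, attributed back to their precursor, and
   quantified as relative intensities I_F/I_Tot (fragment intensity over
   precursor + the nine major-loss fragments).
3. **Universality statistics** — paired OLS regression of relative
   fragment intensities between samples (slope deviation Δsl = |1 − slope|)
   and Bray–Curtis dissimilarity BC = Σ|x−y| / Σ(x+y) at three
   compositional levels: all assigned formulas, the common-formula
   intersection, and fragments of common formulas.
4. **Isomeric diversity** — carboxyl counts per formula estimated two
   independent ways (intensity-weighted CO₂-loss multiplicity
   c_frag = Σₖ k·Iₖ / Σₖ Iₖ, and a composition model); their correlation is
   a diversity index, and central-limit averaging over isomers gives a
   minimum isomer number n_min = ⌈(σ_single/σ_residual)²⌉, hence a minimum
   compound count n_min × |common formulas|.
5. **Synthetic spectra** — a ground-truth generator emulating DOM spectra
   (bell-shaped intensity envelope, CH₂ homologous series, class mixture,
   isotopologues, ppm offsets and jitter, noise peaks, Dirichlet
   fragmentation profiles with a single between-sample divergence knob δ
   and a configurable isomers-per-formula multiplicity), so every stage is
   testable against known answers without instrument data.

## Worked example

Two synthetic samples ("deep_sea", "lake") share 70% of their formulas and
*all* fragmentation structure (divergence δ = 0), but differ in formula
abundances:

```python
from domfrag import (GeneratorConfig, PipelineSettings,
                     generate_fullrange, generate_fragmentation, run_arrays)
from domfrag.synthetic import windows_for_formulas

config = GeneratorConfig(
    seed=42, sample_ids=("deep_sea", "lake"), n_formulae=150,
    shared_fraction=0.7, abundance_divergence=0.4, profile_divergence=0.0,
)
spectra, truth = generate_fullrange(config)
ranked = sorted(truth.common_formulas(),
                key=lambda f: -truth.intensities["deep_sea"][f])
windows = windows_for_formulas(ranked[:30])[:8]
frag_scans = {(s, w.center): pl
              for w in windows
              for s, pl in generate_fragmentation(config, w, truth).items()}
report = run_arrays(spectra, frag_scans,
                    PipelineSettings(sigma_single=truth.sigma_single_c_frag()))
```

which prints, via the report object:

```
common formulas: 105 shares: {'deep_sea': 83.3333, 'lake': 81.3953}
regression lake~deep_sea: slope=1.015 delta_sl=0.015 r=0.998 n=107
Bray-Curtis all_formulae: 0.376
Bray-Curtis common_formulae: 0.220
Bray-Curtis fragments: 0.028
deep_sea: r_estimates=0.928 n_min_isomers=11 n_min_compounds=1155
lake: r_estimates=0.925 n_min_isomers=11 n_min_compounds=1155
```

Reading: the two samples look quite different at the whole-spectrum level
(38% dissimilar) and still differ in the abundances of the formulas they
share (22%), yet the fragments of common formulas are nearly identical
(2.8%, at the replicate-noise floor) with a regression slope
indistinguishable from 1 — the signature of a structurally universal
component. The diversity stage recovers ≈ 11 isomers per formula against a
generator truth of 10, giving at least 11 × 105 = 1155 distinct compounds
behind the common formulas.

## Command line

```sh
domfrag simulate --seed 3 --samples AABW,NADW --n-formulae 300 --out scenario/
domfrag run-all --config scenario/manifest.cfg --out run/
domfrag assign --in scenario/AABW_fullrange.tsv --out AABW_assign.tsv
domfrag calibrate --in spectrum.tsv --calib-refs refs.txt --out calibrated.tsv
domfrag fragment --in scenario/AABW_frag_385.1576.tsv \
    --precursors C22H34O4,C18H22O8 --out records.tsv
domfrag stats --config scenario/manifest.cfg --out stats/
domfrag diversity --config scenario/manifest.cfg --out diversity/
```

Peak lists are plain TSV (`mz`, `intensity`, `snr`) with a commented
metadata header; reports are JSON plus TSV tables.

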