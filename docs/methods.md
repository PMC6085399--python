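# Methods

This note documents the models, conventions and numerical choices behind
`domfrag`, and what the synthetic studies do and do not demonstrate.

## Masses and ion convention

All masses derive from CODATA/IUPAC monoisotopic atomic masses
(`domfrag.chem.MASSES`). Ions are singly deprotonated, [M−H]⁻, and by
default the abstracted hydrogen is treated as a proton:
m/z = M − 1.00727646688 Da. A flag switches to the
neutral − 1.00782503207 + mₑ convention; the 0.00055 Da difference is
~1.5 ppm at 370 Da, far above the working tolerance, so the convention in
force is echoed in every peak-list header and report. The six
neutral-loss masses used for fragment-spectrum calibration (H₂O 18.01056,
CO₂ 43.98983, CO₂+H₂O 62.00039, 2CO₂ 87.97966, 2CO₂+H₂O 105.99022,
3CO₂ 131.96949 Da) reproduce from these constants at five decimals;
comparisons to printed five-decimal values use round-half-even.

## DBE, AI_mod and compound classes

DBE = 1 + C − H/2 + N/2 + P/2 with N and P trivalent (the convention for
negative-mode DOM; valences are configurable). The modified aromaticity
index AI_mod returns 0 whenever its numerator or denominator is
non-positive, which prevents oxygen-rich aliphatics from being labelled
aromatic. Classes are assigned first-match: black carbon
(AI_mod ≥ 0.666, no N/S/P), O-rich / O-poor polyphenols
(0.5 ≤ AI_mod < 0.666, split at O/C = 0.5), highly unsaturated
(AI_mod < 0.5, H/C < 1.5, O/C < 0.9), aliphatic
(1.5 ≤ H/C ≤ 2.0, O/C < 0.9, no N), else `other`. The polyphenol bounds
are read as the half-open interval [0.5, 0.666) — the only reading under
which the five classes are disjoint.

## Internal calibration

The correction model is linear on the ppm scale,
measured = true · (1 + (a + b·true)/10⁶), fitted by least squares to
reference masses matched within 1 ppm (configurable; the match window
must exceed the worst expected miscalibration and stay below the peak
spacing). `order=0` drops the slope term. Three matched references are
required (two for `order=0`); a calibration is flagged failed when the
residual max |ppm| exceeds 0.06 ppm. Fragmentation spectra are calibrated
the same way, using as references the predicted fragment ions (precursor
ion m/z minus each applicable neutral-loss mass) plus the precursor ions
themselves. A fallback reference list of CRAM-like C(14+n)H(18+2n)O₈
compositions is provided, but real instruments should supply a curated
list.

## Formula assignment

Candidates are enumerated exhaustively over C 1–60, N 0–4, S 0–2, P 0–1,
O ≤ C, with hydrogen resolved from the residual mass and bounded by
H/C ≥ 0.3 and H ≤ 2C + N + P + 2 (the DBE ≥ 0 closure of the nominally
unbounded H range); the nitrogen rule (H+N+P even, i.e. integer DBE) is
enforced for even-electron [M−H]⁻ ions. Default tolerance is 0.5 ppm.

Among in-tolerance candidates the winner is chosen by (1) a confirming
¹³C₁ companion peak in the same spectrum, (2) fewest heteroatoms N+S+P,
(3) smallest |error|, (4) Hill string. Parsimony ranks *above* mass error
across the whole tolerance window because of the C₅H₅ ↔ N₄PS₂
near-degeneracy: those candidate pairs sit ~0.35 ppm apart near 370 Da,
so a pure nearest-mass rule flips between them on sub-tolerance mass
jitter, while CHO-only compositions dominate real DOM. A `tie_ppm`
parameter restores a narrower tie window if desired.

Isotopologue verification flags unassigned peaks at parent m/z + 1.0033548
(¹³C) or + 0.9970349 Da (¹⁵N) within tolerance; a ¹³C₁ candidate must also
match the binomial abundance expectation c·0.0107/(1−0.0107) of its parent
within a factor of 3 (configurable), otherwise it is left unflagged with a
warning.

## Fragment attribution and relative intensities

The loss table contains the nine major losses (CO₂, 2CO₂, 3CO₂, H₂O,
CO₂+H₂O, 2CO₂+H₂O, CH₃OH, CO₂+CH₃OH, 2CO₂+CH₃OH) plus CO as a minor loss
that never enters I_Tot. A loss applies only when its atoms are available
in the precursor and a hydrogen remains on the fragment. Attribution
matches each fragment peak against every predicted (precursor, loss) m/z
of the window within 1 ppm (default). A peak explicable by two or more
pairs is flagged ambiguous and excluded from statistics (conservative
default); an alternative policy splits its intensity equally. I_Tot is
the precursor intensity plus the attributed major-loss fragment
intensities of that precursor, so relative intensities and the precursor
share sum to exactly 1.

The cross-sample common detection limit of a precursor is the minimum
precursor S/N across the samples compared. It is applied as a relative
threshold, noise_units / (min S/N): a fragment whose relative intensity
falls below the threshold in *any* sample is zeroed in *all* samples, so
the statistics never compare a detected fragment against one that could
not have been detected elsewhere. The sentence defining this limit admits
other readings; this one is logged prominently and the `noise_units`
factor is configurable.

## Comparison statistics

Paired regression fits sample B's relative fragment intensities on
sample A's by OLS (samples ordered lexicographically; the first is the
abscissa). Pearson r and its two-sided p-value accompany the fit; no
multiple-testing correction is applied. At most one outlier — the point
with the largest externally studentized residual, when it exceeds 4 — is
removed and the fit repeated; both raw and screened results are reported,
so no data disappear silently.

Bray–Curtis dissimilarity is computed at three levels: (1) normalized
intensities of all assigned monoisotopic formulas; (2) the common-formula
intersection, renormalized over that subset by default (a flag disables
renormalization — the matrices are then nested sub-vectors of level 1);
(3) normalized relative fragment intensities of fragmented common
formulas. Replicate runs of one sample at level 3 define the analytical
noise floor against which between-sample values are interpreted.

## Isomeric diversity

c_frag weights each major loss by its CO₂ multiplicity (combined losses
count their CO₂ units only — decarboxylation is what reports a carboxyl
group; H₂O- and CH₃OH-only losses carry weight 0, the precursor counts at
0), making it invariant to intensity scaling and bounded by 3. The
composition-only estimate is pluggable; the default is linear,
c_formula = a·O + b·DBE + c₀, either user-supplied, self-calibrated by
least squares against the sample's own c_frag values, or — for generator
studies — the analytic expectation of the generator's carboxyl link
(`TruthLinkCarboxylModel`, the "matched dispersion model"). Every report
prints the model provenance.

The minimum isomer number follows from central-limit averaging: if a
formula is an n-fold mixture of isomers whose individual carboxyl
estimates scatter with dispersion σ_single, the observed residual
dispersion of c_frag − c_formula shrinks like σ_single/√n, so
n_min = ⌈(σ_single/σ_residual)²⌉ (≥ 1; a zero residual returns a
configured cap with a warning). σ_single must be supplied for real data —
for synthetic data it is measured from the ground-truth isomer table as
the pooled within-formula standard deviation times the decarboxylation
probability. Multiplying n_min by the number of common formulas gives the
minimum number of distinct compounds behind the shared component.

## The synthetic generator

The generator emulates the *statistical* structure of DOM spectra, not
instrument physics (no transients, space charge or collision dynamics).
Defaults describe the study conditions throughout the test suite:

* acquisition window 150–2000 Da; log-normal-bell intensity envelope
  centred at 370 Da (σ = 120 Da) with per-formula log-normal
  heterogeneity (SD 0.4);
* formulas drawn from a CHO library (C 4–40, even H, O/C ≤ 1,
  0.3 ≤ H/C ≤ 2.2) as CH₂ homologous series of five members, classes
  mixed 60% highly unsaturated / 15% aliphatic / 10% O-poor polyphenol /
  7% O-rich polyphenol / 5% black carbon / 3% other — the composition of
  a marine-dominated sample set;
* mass error: configurable constant ppm offset plus N(0, 0.05 ppm)
  jitter; intensities carry 5% multiplicative measurement noise; S/N is
  intensity over a constant noise level; optional ¹³C₁ companions at
  binomial abundance and uniform noise peaks flagged in the truth;
* fragmentation: an isomer with k carboxyls (k ~ round-clipped
  N(0.35·O, 1), k ≤ 3, shared across samples) loses each independently
  with probability q = 0.6, so its CO₂-multiplicity distribution is
  Binomial(k, q) and its expected c_frag is exactly q·k; within a
  multiplicity the mass splits 60/25/15 over the pure/+H₂O/+CH₃OH losses
  (75/18/7 over precursor/H₂O/CH₃OH at multiplicity 0). A formula's
  profile is the average over its isomers; the divergence knob δ
  interpolates each sample's isomer profiles between one shared set
  (δ = 0) and independent Dirichlet draws (δ = 1). Replicates redraw only
  measurement noise.

Determinism: every random stream is keyed by the seed plus CRC32 tags of
the sample, window and replicate, so identical configurations yield
bit-identical peak lists and replicate scans are well-defined.

What passing tests show: that the pipeline recovers known compositions,
attributions and isomer multiplicities under realistic mass accuracy and
noise, and that its statistics separate structural divergence from
abundance divergence. What they do not show: performance on real spectra
with unresolved peaks, space-charge m/z distortions, adduct chemistry or
non-CHO-dominated mixtures, nor the absolute isomer numbers of natural
DOM — σ_single is not observable from a single real sample.

## Benchmark problem sizes

The packaged studies (`domfrag.scenarios`) use 500-formula scenarios for
recovery rates, 20 seeded replicates of a 120-formula two-sample study
for the dissimilarity contrast, and 10–20 replicates per grid point for
the diversity statistics — sizes at which every quantity is stable to the
few-percent level while the whole benchmark run stays fast on one core.
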