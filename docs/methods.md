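# Methods

## Mass conventions

Monoisotopic masses are sums of most-abundant-isotope IUPAC atomic masses
over the formula (`constants.ISOTOPE_MASSES`; C, H, N, O, S, Na plus a few
common halogens — extendable per call). Ion m/z values are
electron-corrected: m/z([M+Na]⁺) = M + m(Na) − mₑ, m/z([M−H]⁻) =
M − m(H) + mₑ. This convention reproduces FTICR-printed accurate masses at
the sixth decimal; a flag disables it for instruments calibrated without
the correction. Nominal m/z rounds half away from zero, matching
unit-resolution ion-trap fragment labels. Only |z| = 1 is supported —
electrospray of the compound class here yields singly charged adducts, and
multiply charged species are out of scope.

The mass-shift library pairs each label with a formula delta; construction
verifies the stated Da value against the formula mass to 1e−6 Da, so a
typo in an entry fails fast. MS/MS annotation considers single losses and
combinations of at most two (all assignments needed in practice use ≤ 2;
allowing more inflates false positives combinatorially). The default
matching tolerance is 0.01 Da for 2-decimal printed shifts and 0.5 Da for
unit-resolution fragments; HRAM comparisons use 5–10 ppm.

## Dissociation-yield spectra

Y = ΣI_F/(I_P + ΣI_F) is the default corrected quantity rather than the
first-order depletion form −ln(1−Y): in the one-photon limit both are
proportional to the absorption cross-section, and the bounded form is the
conventional rendering. The log form is available through
`build_spectrum(..., log_yield=True)`. Windows default to
±0.5 m/z around the listed precursor and fragment masses; overlapping
precursor/fragment windows are a validation error.

Replicates (the instrument averages 4–8 mass spectra per wavelength step)
are averaged *before* the yield is computed. For windowed intensity sums
the average of spectra equals the average of the windowed sums, which is
how `build_spectrum` implements it. The linear power correction divides
the yield by the mean pulse energy of the step's replicates; zero or
negative energies abort with the offending step named. Steps with no ion
signal are recorded as gaps and never interpolated — a missing point must
stay visibly missing.

## Candidate enumeration

Transformation rules are substructure rewrites (RDKit reaction SMARTS),
shipped as code-level patterns because the underlying chemistry is
specified structurally, not algorithmically:

* ester cleavage keeps the acid-side product (`C(=O)O–C` → `C(=O)OH`);
* hydroxylation adds OH at each symmetry-distinct sp³ C–H (aromatic
  hydroxylation behind a flag, off by default — in practice oxidation is
  predicted on the aliphatic geranyl moieties);
* epoxidation converts each non-carbonyl C=C to the epoxide;
* E/Z isomerization emits both configurations of each aryl-conjugated
  enoate C=C (the photoactive bond of sinapoyl-type chromophores, matched
  by `c–CH=CH–C(=O)O`). Restricting to that bond is a deliberate default:
  flipping every stereo bond of a terpenoid tail would explode the
  candidate set without diagnostic value;
* sulfonation attaches SO₃ at hydroxyl/carboxyl oxygens (O-sulfation) or
  at alkene C–H (C-sulfonation), each net +SO₃;
* glucuronidation attaches the glucuronyl moiety through the anomeric
  carbon (net +C₆H₈O₆), emitting both anomers when stereo enumeration is
  on.

Products are deduplicated on canonical isomeric SMILES, so symmetric sites
collapse automatically. Site symmetry for hydroxylation and ionization
uses RDKit canonical atom ranks without tie-breaking. Ionization variants
cover every O/N atom for protonation and Na⁺ coordination and every O/N–H
for deprotonation. Mass filtering computes each candidate's formula from
the structure and keeps those whose adduct m/z matches the target within a
ppm tolerance (default 10 ppm), recording the matching ion.

The reference parent structure (`DGSM_SMILES`) is a synthetic
reconstruction from the compound name — sinapic acid esterified to the
malate 2-OH, both malate carboxyls esterified with (2E)-geranyl — since no
machine-readable structure is distributed; its formula (C₃₅H₄₈O₉) and
sodiated mass are verified in tests.

Stereoisomer bookkeeping (for example how many diastereomers a
glucuronidation could generate) is reported as counts under explicit
options (`anomeric_enumeration`, E/Z rule scope) rather than hard-coded
totals, because such totals depend on which stereocenters one chooses to
enumerate.

## Theoretical spectra

Conformer records carry Gibbs free energies (kJ/mol; only differences
matter, so relative and absolute energies are interchangeable), harmonic
frequencies (cm⁻¹) and IR intensities (km/mol). The pipeline:

1. **Deduplication**: records agreeing within 0.1 kJ/mol *and* 1% per
   rotational constant collapse to the lowest-energy representative. The
   energy-plus-fingerprint criterion is our operational definition of a
   duplicate; records without fingerprints compare on energy alone.
2. **Filtering**: relative energy window ≤ 40 kJ/mol (inclusive boundary,
   configurable), then the 20 lowest-energy conformers per ionization-site
   tag. The window is applied before the cap; both are configurable.
   Records flagged invalid (imaginary modes) are dropped first.
3. **Scaling**: 0.975 below 2500 cm⁻¹, 0.955 at/above (the crossover is
   evaluated on the unscaled frequency); modes flagged as S-atom-dominated
   use 1.049 instead of the fingerprint factor, compensating the known
   B3LYP underestimation of sulfonate S–O stretches. When flags are absent
   they may be derived upstream from a mass-weighted displacement fraction
   threshold (0.2 is a reasonable default); the package consumes the flags.
4. **Broadening**: each stick becomes an area-preserving Gaussian with
   FWHM 20 cm⁻¹ (σ = FWHM/(2√(2 ln 2)) ≈ 8.49 cm⁻¹) on a 550–3700 cm⁻¹,
   1 cm⁻¹ grid — oversampling the 3–5 cm⁻¹ experimental steps.
5. **Weighting**: Boltzmann populations exp(−ΔG/RT)/Σ at 298.15 K with
   R = 8.314462618 J mol⁻¹ K⁻¹, min-shifted for overflow safety; the
   weighted sum is max-normalized.

DFT-level free energies on the retained set are assumed for the final
weighting (the cheaper semiempirical energies serve only for the upstream
pre-filter, which is exercised here through its tabulated outputs). The
frequency-block text parser recognizes the common `Frequencies --` /
`IR Inten --` layout and the `Sum of electronic and thermal Free Energies`
line (Hartree → kJ/mol), closing one record per thermochemistry line.

## Matching and ranking

Spectra are max-normalized, linearly resampled onto the densest common
grid over their overlap (extrapolation refused), and compared by cosine
similarity clipped to [0, 1]; Pearson mapped through (r+1)/2 is available.
Cosine was chosen because it is invariant under uniform intensity
rescaling — the one transformation guaranteed meaningless for these
spectra. Region weighting multiplies grid-point weights inside named
intervals (defaults: C=O stretch 1700–1800 cm⁻¹, alkene CH bend 1050–1125
cm⁻¹); all-equal weights reproduce the unweighted score identically.
Ranking sorts by descending score with lexicographic id tie-break, so the
result is independent of input order; the exclusion threshold defaults to
0.8 and is necessarily a package choice — visual spectral matching has no
printed threshold, so ranks on real systems can only be mirrored
qualitatively on synthetic analogues. No baseline subtraction is applied
by default (an optional constant-offset flag exists at the analysis
level); mixture deconvolution is out of scope — an ambiguous assignment
is reported as multiple non-excluded candidates.

## Toxicity aggregation

Binary-endpoint model outputs are converted to [0, 1] (qualitative calls
via a documented default map: yes/active/positive → 1, no/inactive/
negative → 0 — the upstream platforms do not publish a numeric table, so
this mapping is ours) and combined by unweighted arithmetic mean. Zones:
mean > 0.66 reliable positive; 0.5 < mean ≤ 0.66 unreliable positive;
0.33 ≤ mean ≤ 0.5 unreliable negative; mean < 0.33 reliable negative.
The prose intervals overlap at exactly 0.5 and 0.66; we close them on the
negative-unreliable side (configurable), which makes the classification
total and single-valued on [0, 1]. NOAEL estimates from two models are
combined by their arithmetic mean. The QSAR models themselves are never
invoked — their outputs are input files.

## Synthetic data

`make_scan_series` inverts the analysis pipeline: a target spectrum is
converted to per-step yields multiplied by a smooth pulse-energy envelope
(so the power correction actually does something in tests), scaled to a
maximum yield of 0.8, and emitted as 4–8 replicate peak lists per step
with multiplicative Gaussian intensity noise — multiplicative because ion
count fluctuations scale with signal. The default grid is 550–1850 cm⁻¹
at 5 cm⁻¹ (the fingerprint-region scan size keeps the full test suite
fast; the builders accept any grid up to the full 550–3700 cm⁻¹ range).
`make_conformer_set` returns records with exactly known Boltzmann
populations; `make_isomer_pair` returns truth/decoy/noisy-experimental
triples where the decoy's carbonyl band is displaced by a chosen shift.
All generators are driven by `numpy.random.default_rng(seed)` and are
bit-reproducible per seed.

What the synthetic data does *not* emulate: trap space-charge effects,
saturation, laser mode structure, wavelength-calibration error,
chromatographic co-elution, or anharmonicity in the theoretical spectra.
Passing tests therefore demonstrate the correctness of the arithmetic and
the statistical behavior of the pipeline, not instrument-level fidelity.

## Numerical choices and limitations

* Isotope masses are frozen constants; overriding the table changes every
  downstream mass consistently.
* The printed accurate mass of the sulfonated metabolite's deprotonated
  ion in the source data (555.1531) disagrees by ~1 mDa with the value
  computed from its formula (555.1542); the package always computes from
  the formula and never hard-codes that printed value.
* The computed sodiated m/z of C₃₁H₄₀O₁₅ is 675.225941, which rounds to
  675.2259 — one unit in the last printed digit below the commonly quoted
  675.2260.
* Grid detection uses the modal step of consecutive unique wavenumbers;
  irregular series keep their actual support.
* Dissociation yields of exactly 0/1 are legitimate (no dissociation /
  complete dissociation); only a zero-signal step is treated as missing.
* Enumeration is constitutional-plus-flagged-stereo; exhaustive
  stereoisomer expansion of flexible tails is deliberately not attempted.
* All similarity scores are comparable only within one experimental
  spectrum; no cross-spectrum score calibration is claimed.
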