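# iris-elucidate

Structure elucidation of metabolic transformation products from LC–MS with
infrared ion spectroscopy (IRIS), plus downstream in silico toxicity triage.

When a new agrochemical or drug candidate is incubated in metabolically
competent cell lines, LC–MS reveals its transformation products only as
m/z values and retention times — usually compatible with many isomeric
structures. IRIS resolves this by recording an IR spectrum of each
mass-selected ion directly in the ion trap: the ion population is
irradiated with tunable IR light, and on resonance with a vibrational
transition the precursor dissociates. The dissociation yield

    Y(ν̃) = ΣI_F / (I_P + ΣI_F)

(I_P precursor intensity, ΣI_F summed fragment intensity), corrected
linearly for laser pulse energy, traces the vibrational spectrum of the
ion. Comparing it against quantum-chemically predicted spectra of
candidate structures confirms or excludes isomers — which matters because
in silico toxicity (QSAR) predictions depend on the exact structure, and
when isomers cannot be distinguished the most hazardous one must be
assumed.

This package implements the desk side of that workflow:

* **`chem`** — Hill-formula parsing, monoisotopic masses, electron-corrected
  adduct m/z ([M+H]⁺, [M−H]⁻, [M+Na]⁺), ppm errors, and annotation of mass
  shifts (+SO₃ = +79.96 Da, +C₆H₈O₆ = +176.03 Da, …) and MS/MS neutral
  losses (≤ 2 combined).
* **`yield_spectrum`** — dissociation-yield spectra from wavelength-stepped
  scan series: replicate averaging, linear pulse-energy correction, gap
  handling, max-normalization.
* **`biotransform`** — candidate enumeration by phase I rules (ester
  cleavage, hydroxylation, epoxidation, E/Z isomerization of the
  photoactive aryl-conjugated double bond) and phase II rules (sulfonation,
  glucuronidation with anomer enumeration), ionization-site expansion over
  O/N atoms, and exact-mass filtering.
* **`theory`** — Boltzmann-weighted theoretical IR spectra from harmonic
  conformer records: duplicate removal, 40 kJ/mol energy window, 20
  conformers per ionization site, frequency scaling (0.975 fingerprint /
  0.955 above 2500 cm⁻¹ / 1.049 for S-atom modes), 20 cm⁻¹ FWHM Gaussian
  broadening, weighting at 298.15 K. Includes a text parser for
  quantum-chemistry frequency blocks.
* **`matching`** — cosine (or Pearson) similarity of normalized spectra with
  optional weighting of diagnostic regions (C=O stretch 1700–1800 cm⁻¹,
  alkene CH bend 1050–1125 cm⁻¹), deterministic ranking and exclusion
  flags.
* **`tox`** — consensus QSAR aggregation: arithmetic-mean scores, zone
  classification (< 0.33 reliable negative, 0.33–0.5 unreliable negative,
  0.5–0.66 unreliable positive, > 0.66 reliable positive), NOAEL averaging,
  tabular reports.
* **`fixtures`** — seed-deterministic synthetic scan series, conformer
  ensembles, and isomer-pair spectra with known ground truth.

## Worked example

Digeraniol sinapoyl malate (DGSM, C₃₅H₄₈O₉) sodiates to m/z 635.319054. A
metabolite at m/z 499 suggests loss of one geranyl tail:

```
$ elucidate mass --formula C25H32O9 --ion "[M+Na]+"
neutral monoisotopic mass: 476.204633 Da
[M+Na]+ m/z: 499.193853 (nominal 499)
```

Enumerating ester cleavage of DGSM crossed with E/Z isomerization of the
photoactive sinapoyl double bond, filtered to the observed mass:

```
$ elucidate enumerate --parent dgsm.smi --rules ester_cleavage,EZ \
      --target-mz 499.19597 --ion "[M+Na]+" --ppm 10
   id  ...                         history  formula matched_ion         mz
cand0  ...                  ester_cleavage C25H32O9     [M+Na]+ 499.193853
cand1  ...                  ester_cleavage C25H32O9     [M+Na]+ 499.193853
cand2  ... ester_cleavage|EZ_isomerization C25H32O9     [M+Na]+ 499.193853
cand3  ... ester_cleavage|EZ_isomerization C25H32O9     [M+Na]+ 499.193853
```

Exactly four unique candidates survive: the two possible cleavage sites
(the digeraniol tails are inequivalent) times the two configurations of
the double bond. Ranking synthetic candidate spectra against a noisy
measured spectrum (here generated with `elucidate fixtures --kind isomers`,
decoy C=O band shifted 75 cm⁻¹):

```
$ elucidate match --exp experimental.tsv --theo truth.tsv --theo decoy.tsv
   id  score  rank  excluded
truth 0.9954     1     False
decoy 0.5597     2      True
```

The true structure scores 0.995 and ranks first; the decoy falls below the
0.8 exclusion threshold and is excluded — the quantitative version of
ruling out an isomer because its carbonyl band does not fit.

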