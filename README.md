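# irsom — protein secondary structure from Amide I infrared spectra

`irsom` estimates protein secondary-structure fractions — α-helix, β-sheet
and "other" — from the Amide I band (1600–1700 cm⁻¹) of Fourier-transform
infrared (FTIR) absorbance spectra. The Amide I band is dominated by backbone
C=O stretching, and its shape encodes secondary structure: helix-rich proteins
absorb near 1654 cm⁻¹, β-sheets near 1631 cm⁻¹ (with a weaker high-wavenumber
component near 1678 cm⁻¹), and disordered segments in between.

The main estimator is a Kohonen self-organising map (SOM) trained on a
reference library of spectra with known structure fractions (e.g. from DSSP
annotations of crystal structures). The package also provides two classical
band-fitting estimators, ATR↔transmission conversion, Fourier
self-deconvolution, preprocessing utilities, a synthetic-spectrum generator
for validation, and a command-line application.

## How it works

1. **Training.** Reference spectra (baselined and normalised to 1 at the
   Amide I maximum) train a square grid of nodes. Each node stores a synthetic
   spectrum; at every step a random reference spectrum pulls its best-matching
   node and that node's grid neighbours towards itself, with learning rate and
   neighbourhood radius decaying exponentially. Similar spectra end up on
   nearby nodes.
2. **Structure assignment.** Nodes that hold a reference member copy that
   member's fractions exactly; every other node receives an inverse-distance
   weighted average of the reference fractions (weighting power `p`, default
   3, so nearby members dominate).
3. **Prediction.** A test spectrum finds its `k` best-matching nodes (default
   5) and averages their fractions with inverse-distance weights. The same
   weights reconstruct the spectrum from node spectra; the normalised
   root-mean-square deviation (NRMSD) between input and reconstruction is a
   built-in reliability flag — a high NRMSD means the map has never seen
   anything like this spectrum.
4. **Validation.** Leave-one-out validation (LOOV) trains N maps on N−1
   members each and predicts the held-out member, giving per-member helix and
   sheet deviations.

See [docs/methods.md](docs/methods.md) for equations, parameter defaults and
their rationale, and known limitations.

## Worked example (library)

Thirty synthetic reference spectra with known fractions, a 20×20 map, and a
prediction for one member:

```python
from irsom.som import SOMConfig, train
from irsom.synthetic import SyntheticModel, make_reference_set

refset = make_reference_set(30, SyntheticModel(noise_sd=0.005), seed=7)
tmap = train(refset, SOMConfig(map_dim=20, n_steps=5000, seed=7))
print(tmap.summary())

res = tmap.predict(refset.spectrum(0))
print(f"predicted: helix={res.fractions.helix:.3f} "
      f"sheet={res.fractions.sheet:.3f} other={res.fractions.other:.3f} "
      f"NRMSD={res.nrmsd:.4f}")
truth = refset.members[0][2]
print(f"true     : helix={truth.helix:.3f} sheet={truth.sheet:.3f} "
      f"other={truth.other:.3f}")
```

Output (verbatim):

```
Trained self-organising map
---------------------------
map dimension        : 20 x 20 (400 nodes)
spectral grid        : 51 points, 1600.0-1700.0 cm^-1
reference members    : 30
training steps       : 5000
alpha schedule       : 0.25 -> 0.01
sigma schedule       : 10.0 -> 0.5
seed                 : 7
final quantization   : 0.0301392
occupied nodes       : 30

predicted: helix=0.061 sheet=0.740 other=0.199 NRMSD=0.0383
true     : helix=0.053 sheet=0.745 other=0.202
```

## Worked example (command line)

```
$ irsom synth --n 30 --seed 7 --out ref.txt
$ irsom loov --ref ref.txt --map-dim 20 --steps 5000 --seed 7 --out loov.csv
mean |helix deviation| = 0.0594
mean |sheet deviation| = 0.0455
```

`loov.csv` holds the per-member deviation table sorted by true helix content
(columns `label, true_*, pred_*, *_dev, nrmsd, nrmsd_x5`). Other subcommands:
`train` (fit and save a map), `predict` (apply a saved map to test spectra),
`convert` (ATR↔transmission), `bandfit` (Gaussian band-fitting estimators),
`fsd` (Fourier self-deconvolution). Every subcommand writes a
`*.manifest.json` recording the resolved options, seed and package version so
runs can be reproduced exactly. `--config file.yaml` supplies SOM options
declaratively; explicit flags override it.

## Package layout

| module | contents |
| --- | --- |
| `irsom.spectra` | `Spectrum`, `StructureFractions`, `ReferenceSet` value types |
| `irsom.io` | training/test/spectrum file formats, predictions CSV |
| `irsom.preprocess` | interpolation, linear baseline, normalisation, water-vapour handling |
| `irsom.som` | `KohonenSOM` (model) → `TrainedMap` (results), prediction, NRMSD |
| `irsom.validation` | leave-one-out validation and deviation tables |
| `irsom.atr` | penetration depth, ATR↔transmission conversion |
| `irsom.bandfit` | second-derivative peak picking, Gaussian fitting, window quantification |
| `irsom.fsd` | Fourier self-deconvolution |
| `irsom.synthetic` | synthetic Amide I generator with known fractions |
| `irsom.cli` | `irsom` command-line application |
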