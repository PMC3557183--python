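# actipet

Analysis of positron activity induced in tissue by high-energy photon
radiotherapy, measured with dynamic PET.

Photon beams above the photoneutron threshold (~15–18 MeV) activate the
light elements of tissue through (γ,n) reactions: ¹²C → ¹¹C (T½ 20.39 min),
¹⁶O → ¹⁵O (2.04 min), ¹⁴N → ¹³N (9.97 min).  A dynamic PET scan started a
few minutes after beam-off records the superposition of their decays.  For
a volume of interest, the measured count rate is modelled as

    S(t) = S₁·2^(−t/T½,₁) + S₂·2^(−t/T½,₂) + S₃·2^(−t/T½,₃) + K,

with the amplitudes Sₖ ≥ 0 referenced to the end of irradiation and
K ≥ 0 a constant background.  Fitting this model to a time–activity curve
(TAC) in two regimes —

* **fixed**: half-lives pinned to the physical ¹¹C/¹⁵O/¹³N values; the
  non-negative amplitudes are the exact solution of a non-negative linear
  least-squares problem;
* **free**: amplitudes *and* half-lives estimated by bounded nonlinear
  least squares with a deterministic multi-start grid —

yields the relative count-rate fractions Sₖ/ΣSₖ and effective half-lives.
Because each nuclide descends from one element and ¹H yields no positron
emitter, the normalized fractions can be compared directly with
hydrogen-omitted (C/N/O-renormalized) reference tissue compositions.

The package is aimed at medical physicists exploring post-treatment PET
verification and tissue-composition imaging: it provides the forward model,
scikit-learn style fitters with 95% confidence intervals, TAC extraction
from 4-D NIfTI volumes, reference nuclide/composition tables, a synthetic
data generator (Poisson counting noise at configurable count levels), and a
command-line pipeline.

## Worked example

Simulate a noiseless bladder-content acquisition (transport delay 7 min,
15 frames of 2 min), fit both regimes, and compare with the reference
composition:

```python
import actipet as ap

spec = ap.SimulationSpec(tissue="urinary_bladder_filled")
tac = ap.simulate_tac(spec)

fixed = ap.fit_fixed(tac)
print("fractions:", fixed.normalized_fractions.round(4))

free = ap.fit_free(tac)
print("half-lives (min):", free.half_lives.round(3), "identified:", free.identified)

comp = ap.fractions_to_composition(fixed)
print(ap.compare_to_reference(comp, "urinary_bladder_filled").to_text())
```

Output:

```
fractions: [0.0398 0.9432 0.017 ]
half-lives (min): [20.39  9.97  2.04] identified: (True, True, True)
Tissue: urinary_bladder_filled
 element    fitted  reference      diff  CI overlap
       C    0.0398     0.0398   -0.0000           -
       N    0.0170     0.0170   -0.0000           -
       O    0.9432     0.9432   +0.0000           -
```

The fixed fit recovers the generating count-rate fractions (4.0% C,
94.3% O, 1.7% N — the hydrogen-adjusted bladder composition); the free fit
recovers all three physical half-lives exactly from the noiseless curve,
and the element-wise comparison against the bundled reference is zero by
construction.  The same pipeline is available from the shell:

```bash
actipet simulate --tissue urinary_bladder_filled --tac tac.csv
actipet fit --tac tac.csv --mode both --out fit.json
actipet report --fit-report fit.json --tissue urinary_bladder_filled --out cmp.json
```

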