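# lingtract

fMRI-guided white-matter language tractography and naming-outcome
statistics, at desk scale.

After anterior temporal lobe resection for temporal lobe epilepsy, a
quarter to a half of patients operated on the language-dominant side lose
measurable naming ability. One way to stratify that risk preoperatively is
to seed probabilistic tractography from each patient's naming-fMRI
activation maximum in the posterobasal temporal lobe, measure the volume of
the resulting white-matter language tract in the to-be-resected hemisphere,
and relate it to naming change after surgery. `lingtract` implements that
analysis chain end to end for researchers who want to study, extend or
stress-test it without access to patient imaging:

1. **Seeding** — the `k = 100` white-matter voxels nearest (Euclidean mm)
   a cortical activation peak, plus the peak's homotopic mirror for the
   contralateral hemisphere.
2. **Tracking** — bidirectional probabilistic streamlines (1000 per seed,
   step 1 mm, minimum curvature radius 1 mm ⇒ per-step turn ≤ 60°, minimum
   fibre-orientation amplitude 0.1) with five-tissue-type termination:
   accepted streamlines end in grey matter at both ends. Visitation maps
   are binarized at probability 0.01.
3. **Volumetry** — hemispheric tract volumes (intracranial-volume
   corrected), tract laterality index
   `LI = (V_surg − V_contralat)/(V_surg + V_contralat)`, group commonality
   maps; bootstrap fMRI laterality `LI = (L − R)/(L + R)` with the ±0.2
   bilateral band.
4. **Outcome models** — decline scoring (≥ 4 Graded Naming Test items is
   clinically significant), Pearson correlations, multiple regression with
   the standard clinical covariates plus sensitivity/specificity of the
   dichotomized prediction, random-intercept linear mixed models with
   likelihood-ratio tests and marginal R², Fisher r-to-z correlation
   contrasts and the seizure-outcome Fisher exact test.
5. **Synthetic data** — phantom brains (tissue shells + coherent fibre
   bundles with controllable left–right asymmetry) and synthetic cohorts
   with a planted linear volume → decline effect, so every stage above is
   testable and calibratable offline.

See `docs/methods.md` for the model details, parameter defaults and the
limits of what the synthetic data can show.

## Worked example

Run the full pipeline on a synthetic 20-subject cohort (a few seconds):

```sh
lingtract run --out demo --seed 42
```

prints

```
4mo: sensitivity 100%, specificity 94%
12mo: sensitivity 100%, specificity 100%
report bundle written to demo
```

and writes `demo/cohort.csv`, `demo/correlations.csv`, `demo/report.json`,
per-side commonality maps and a `manifest.json` with every parameter,
derived seed and file checksum (rerunning with the same seed reproduces all
of it bit-exactly). Inside `report.json` for this seed:

* the ipsilateral (surgery-side) tract volume correlates with 4-month
  naming decline at r = 0.98 (n = 20) and with 12-month decline at
  r = 0.94 (n = 18) — the generator planted decline as a linear function
  of exactly that volume, so a high correlation is the expected recovery;
* the 4-month multiple regression (volume + preoperative score, age, onset
  age, duration, sex, education, surgery type, fMRI LI) gives
  F(9, 10) = 39.9, R² = 0.97;
* dichotomizing its fitted decline at the ≥ 4-item cutoff yields the
  contingency table {TP 3, FP 1, FN 0, TN 16}: sensitivity 100%,
  specificity 94%;
* the mixed model across both follow-ups prefers the volume model over the
  null at χ²(1) = 60.2, marginal R² = 0.91.

The same stages are available individually (`lingtract simulate`, `seed`,
`track`, `metrics`, `li`, `analyze`) and as library functions
(`lingtract.build_seed`, `lingtract.track`, `lingtract.fit_mixed_model`,
…).

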