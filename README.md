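# vcgmem

Vectorcardiographic quantification of cardiac memory after right-ventricular
pacing.

Cardiac memory is the persistent repolarization change that follows a period
of altered ventricular activation: after days of right-ventricular pacing,
the T wave of the normally conducted beat "remembers" the paced activation,
its spatial vector rotating toward the paced QRS vector. This package
implements the full measurement chain used to quantify that phenomenon on
body-surface ECGs, for electrophysiology researchers who work with
paced/sensed recording pairs:

1. **12-lead → XYZ**: the Kors regression matrix maps the 8 independent
   leads (I, II, V1–V6) to orthogonal X (leftward), Y (inferior),
   Z (posterior) leads.
2. **Median beat**: beats labeled normal (or retained by template
   correlation) are aligned on the maximum |dV/dt| of the X lead and
   reduced to a time-coherent XYZ median beat; the electrically quiet
   origin point — the flattest, lowest window of the vector magnitude
   before the QRS — is the reference for every vector.
3. **Global electrical heterogeneity**: spatial peak and area QRS, T and
   spatial ventricular gradient (SVG) vectors with azimuth, elevation and
   magnitude; SAI QRST (∫|X|+∫|Y|+∫|Z|) and iVMQT (∫√(X²+Y²+Z²)) over
   QRS onset → T offset.
4. **Memory angles**: with four recordings per patient — sensed (AAI) and
   paced (DDD) on day 1 and day 7 — cardiac memory is the 3-D angle between
   the day-7 paced QRS vector and the day-7 sensed T vector
   (QRS_DDD-7–T_AAI-7), measured on same-day recordings so electrode
   placement cancels; eight comparison angles complete the set.
5. **Statistics**: circular descriptives (mean direction, resultant length
   R̄, von Mises κ, circular variance/SD, median, 95% CI), Rayleigh and
   Kuiper uniformity tests, two-sample Kuiper and Watson U², Hotelling's
   paired test, Fisher–Lee circular–circular and Fisher–Mardia–Jupp
   circular–linear correlations, and linear mixed models (random intercept
   + random day slope) on axially transformed angles (2θ+360°, halved for
   reporting).
6. **Synthetic cohort**: a dipole-loop simulator emits paced/sensed
   recording quadruples with known ground truth — configurable memory
   rotation, covariate-dependent saturation, measurement noise and bounded
   day-7 electrode rotation — so every stage is testable against truth.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1   # 80 recordings, 20 patients
python analysis/02_measure_vcg.py                # median beats -> metric table
python analysis/03_circular_analysis.py          # angles -> circular stats
python analysis/04_mixed_models.py               # Models 1 & 2
```

With seed 1 this prints, among other lines:

```
memory angle (QRS_DDD-7 vs T_AAI-7): mean 111.7 deg (95% CI 104.9 to 118.5),
  median 110.5, R 0.964, kappa 14.1
activation difference (QRS_AAI-7 vs QRS_DDD-7): mean 77.0 deg, R 0.976
Fisher-Lee r between the memory angle and the day-7 sensed-vs-paced T
  separation: -0.774
within-mode day-1 vs day-7 QRS angles (electrode-placement error bound):
qrs_aai1_aai7      2.19 deg     qrs_ddd1_ddd7      2.42 deg
```

Reading: the sensed T vector has rotated toward — but not onto — the paced
QRS direction (a memory angle well below the ~150° a memory-free cohort
would show, and strongly anticorrelated with the sensed-vs-paced T
separation, which measures the same alignment from the other side). Paced
and sensed activation differ by ~77°, while the same mode measured on the
two days differs by only ~2°, confirming that day-to-day electrode
placement contributes far less than the effects being measured. The mixed
models then attribute the day-1 → day-7 T-vector change to the memory
rotation and recover its attenuation in female patients.

The same steps are available as a CLI (`vcgmem simulate | ingest |
medianbeat | geh | circstat | models | run-all`); `vcgmem run-all --in
<cohort dir> --out <report dir>` writes the complete report bundle with a
reproducibility manifest.

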