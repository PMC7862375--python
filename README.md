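# octaprof

Directional OCTA vessel-density and choriocapillaris flow-deficit
profiling anchored to the NIR-FAF preserved-autofluorescence border, for
quantifying macular microvascular change in retinitis pigmentosa (RP).

In RP, near-infrared fundus autofluorescence (NIR-FAF) shows a central
area of preserved autofluorescence (APA) whose sharp border marks the
edge of structurally intact outer retina. `octaprof` registers the three
en-face angiograms of a 6 × 6 mm swept-source OCTA scan — superficial
vascular complex (SVC), deep capillary complex (DCC) and choriocapillaris
(CC) — to the NIR-FAF image, binarizes them with the standard dual-branch
chain (top-hat → {Frangi + Huang fuzzy-entropy threshold} ∧ {local median
threshold}; CC by a normative-database global threshold), and quantifies
vessel density VD (SVC, DCC) and flow-deficit fraction FD (CC) in a
series of 0.1 × 0.8 mm sample areas running superiorly, inferiorly and
temporally from the fovea. Profiles are re-indexed so each eye's APA
border sits at offset 0, then compared position-by-position against
1:1 matched controls with a Wilcoxon signed-rank test; a difference
counts as significant only over ≥ 5 consecutive offsets with p < 0.05.

Per metric and direction the result is the familiar report row

    mean ± SD (range) of control − patient beyond the border, in %

plus the extent of the significant runs. A synthetic-data generator
produces paired NIR-FAF + angiogram images with exact per-pixel ground
truth (vessel labels, deficit labels, APA geometry, misalignment), so the
entire pipeline is testable at desk scale; the default study conditions
emulate a 29-pair cohort of RP eyes whose APA border falls inside the
scan — no clinical images are distributed.

## Worked example

Simulate a six-pair cohort and analyze it (about two and a half minutes
at the native 1024-px grid; `--grid 512` is a fast preview):

```bash
octaprof simulate --out cohort --n-cases 6 --seed 42
octaprof analyze --manifest cohort/manifest.csv --out results --pre-registered
octaprof report --results results
```

`report` prints one row per metric and direction; on the run above:

```
VD[SVC]   superior     3.12 +-  3.78% (range -4.92 to 11.79%)  runs: none
VD[SVC]   inferior     2.16 +-  2.33% (range -2.71 to 7.29%)  runs: none
VD[SVC]   temporal     1.33 +-  3.01% (range -3.80 to 7.45%)  runs: none
VD[DCC]   superior    27.42 +-  3.24% (range 20.26 to 33.67%)  runs: [+0.0, +0.7]; [+0.9, +1.9]
VD[DCC]   inferior    25.70 +-  4.43% (range 17.03 to 34.03%)  runs: [+1.0, +1.9]
VD[DCC]   temporal    25.17 +-  4.14% (range 17.74 to 32.18%)  runs: none
FD        superior    -5.64 +-  2.73% (range -9.86 to -0.71%)  runs: none
FD        inferior    -4.91 +-  2.30% (range -8.95 to -0.33%)  runs: none
FD        temporal    -5.32 +-  2.89% (range -10.42 to -0.07%)  runs: none
```

Reading it: the generator injected a 30-point DCC vessel-density deficit
outside the APA (0.42 inside → 0.12 outside) and a 5-point CC
flow-deficit increase; the pipeline reads back a 25–27-point DCC loss
and a ≈ −5-point FD difference (controls have *fewer* deficits, hence
the sign) in every direction, and essentially nothing in the SVC —
while inside the APA (negative offsets) no significant run appears,
mirroring the preserved-retina expectation. With only six pairs the
smallest attainable two-sided Wilcoxon p is 1/32, so the run rule flags
the DCC deficit only patchily and the subtler FD effect not at all; at
the default 29-pair study size the DCC run covers the whole beyond-edge range
(see the acceptance study below). The gap between 30 injected and ~26
recovered DCC points is the documented high-density undercount of the
AND-of-two-branches binarization (see `docs/methods.md`).

`results/` also contains the tidy per-area profiles
(`profiles.csv`), per-offset p-values, profile and p-value figures per
metric/direction, the estimated registration transforms and the exact
run configuration.

The same analysis is available as a library:

```python
from octaprof import SyntheticCaseParams, generate_case, analyze_cohort

cases = [generate_case(SyntheticCaseParams(seed=s), f"P{s}") for s in range(6)]
pairs = [(c.patient.subject_id, c.patient, c.patient_nirfaf,
          c.control, c.control_nirfaf) for c in cases]
ca = analyze_cohort(pairs, slabs=("DCC",), pre_registered=True)
print(ca.results[("VD[DCC]", "inferior")].summary())
```

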