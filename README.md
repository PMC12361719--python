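# mtlseg

Landmark-rule segmentation protocol tools for the **anterior medial temporal
lobe cortices** — entorhinal cortex (ERC) and Brodmann areas 35 and 36
(perirhinal cortex).

The anterior MTL cortices are among the first targets of tau and TDP-43
pathology in Alzheimer's disease and LATE, but their cytoarchitectonic
borders are invisible on MRI. Segmentation protocols for them therefore have
to express every border as a rule anchored to landmarks that *are* visible
on MRI: the anterior tip of the hippocampus, the superior edge and crown of
the parahippocampal gyrus (PHG), the banks and fundus of the collateral
sulcus (CS), and the crown of the fusiform gyrus (FG). `mtlseg` implements
the full life cycle of such a protocol:

1. **Measure** — signed arc-length distances from cytoarchitectonic borders
   to candidate landmarks on coronal pial contours, plus each region's
   anterior-extent distance to candidate anchor structures;
2. **Derive** — summary statistics (n / mean / median / SD per cell), anchor
   selection by between-case SD, quantization of extent medians onto the
   slice grid, whole-millimetre offset rounding, and emission of a
   machine-readable rule table;
3. **Segment** — a deterministic engine that applies the rule table to any
   landmark-tagged slice stack, producing ordered, gap-free labeled
   arc-length intervals per slice (and, optionally, voxel rasters / NIfTI);
4. **Evaluate** — Dice Similarity Index (DSI) overlap, label areas and
   volume proxies, shallow-vs-deep CS and disease-group comparisons, and a
   landmark-perturbation experiment characterizing the engine's sensitivity
   to landmark placement error.

Because the underlying histology cohort is not public, the package ships a
first-class **synthetic phantom generator**: seeded cohorts of cases with
per-case anterior extents (median/SD matched to the published cohort),
coronal pial contours through PHG, CS and FG with a shallow or deep sulcus,
and ground-truth borders placed at configurable landmark offsets with
Gaussian between-case noise. Everything the pipeline claims is demonstrated
end to end on these phantoms.

## The protocol in brief

With slice thickness $t = 1.3$ mm and measured median anterior-extent
distances $\tilde d$ to the hippocampus tip, region starts are

$$\mathrm{start} = t \cdot \mathrm{round}(\tilde d / t)$$

giving ERC $4.75 \to 5.2$ mm, BA35 $9.25 \to 9.1$ mm and BA36
$10.25 \to 10.4$ mm anterior to the hippocampus. Border rules per reference
level (10, 9, 7, 5, 4, 2.5 mm anterior) place each border on a landmark or
at a whole-millimetre arc-length offset from one (e.g. *BA35 medial, 9 mm
level: 7 mm medial to the superior PHG edge*); the BA35 lateral border sits
on the CS fundus throughout, and on the first ERC slice the ERC is wrapped
by a medial flank of BA35. Overlap is scored with the Dice index
$\mathrm{DSI} = 2|A \cap B| / (|A| + |B|)$.

## Worked example

```python
import mtlseg as m

# a 20-case phantom cohort under realistic noise (2 mm border SD)
cohort = m.generate_cohort(m.CohortConfig(n_cases=20, seed=42))

# measure distances and fit the protocol
results = m.ProtocolModel.from_cohort(cohort).fit()
print(results.summary())
```

```
Anchor structure: hippocampus

Anchor ranking (between-case SD of extent distances, mm):
           anchor   ERC  BA35  BA36  sd_sum identifiability
      hippocampus 1.958 2.172 4.160   8.289            easy
         amygdala 2.088 2.223 4.142   8.454            hard
    limen_insulae 2.148 2.333 4.712   9.193            easy
    ...

Region starts (mm anterior to anchor, on the slice grid):
  ERC: 5.2 mm  (median 4.80 mm)
  BA35: 10.4 mm  (median 10.40 mm)
  BA36: 10.4 mm  (median 10.96 mm)
```

The anchor ranking shows why the hippocampus tip is the anchor: it has
nearly the lowest between-case SD and, unlike the amygdala tip, is easy to
identify on MRI. At n = 20 with 2 mm border noise the derived starts and
offsets wobble around the generating truth (BA35 here lands one slice
anterior of its true 9.1 mm start) — exactly the sampling behaviour the
derivation stage is meant to expose. With zero noise the round trip is an
identity, and at n = 200 every offset is recovered within 1 mm (both are
asserted in the test suite).

```python
# segment a case and inspect the slice partition
case = cohort.cases[0]
labelmap = results.segment(cohort.slice_stack(case.case_id))
print(labelmap.to_frame().head(8).to_string(index=False))
```

```
 case_id  slice_distance_mm label      segment  s_start_mm  s_end_mm
case0000                2.6   ERC      primary   14.082728 22.926228
case0000                2.6  BA35      primary   22.926228 31.328622
case0000                2.6  BA36      primary   31.328622 44.526549
...
case0000                5.2  BA35 medial_flank    8.082728 18.504478
case0000                5.2   ERC      primary   18.504478 22.926228
```

Each slice is a gap-free medial-to-lateral partition (adjacent labels share
border positions exactly); on the first ERC slice the BA35 medial flank
appears medial of the ERC.

```python
# landmark-perturbation reliability
report = m.reliability_experiment(cohort, results.rule_table,
                                  sigmas_mm=(0.0, 0.5, 1.0), n_reps=3, seed=0)
print(report.render())
```

```
label         sigma=0       sigma=0.5     sigma=1
BA35          1.000±0.000   0.975±0.006   0.951±0.010
BA36          1.000±0.000   0.961±0.012   0.921±0.020
ERC           1.000±0.000   0.938±0.023   0.885±0.040

mean DSI non-increasing with sigma: BA35=yes, BA36=yes, ERC=yes
```

At zero landmark noise the engine is exactly reproducible (DSI 1.0); DSI
decays monotonically with landmark jitter, and the smallest label (ERC)
is penalized the most — the familiar small-structure behaviour of the Dice
index.

A `mtlseg` console script exposes the same pipeline from the shell
(`generate`, `measure`, `derive-rules`, `segment`, `evaluate`); see
`mtlseg --help`.

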