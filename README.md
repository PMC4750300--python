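# ciliometry

Length morphometry of primary cilia from confocal Z-stacks.

The primary cilium is a single microtubule-based protrusion present on most
cell types; its length modulates the organelle's signalling sensitivity, so
accurate length measurement matters. Confocal imaging samples the cell as a
Z-stack of optical sections, and a cilium is rarely aligned with the imaging
plane: part of its length extends along the optical axis, where standard 2D
measurements cannot see it.

`ciliometry` implements three measurement strategies for straight cilia and
the statistical machinery to compare them:

- **MIP** — the length of the cilium traced on the maximum intensity
  projection. Fast, but a cilium at elevation angle θ to the imaging plane is
  foreshortened to `L·cos θ`.
- **PyT** — the Pythagorean estimate `c = √(a² + b²)`, where `a` is the
  projected (MIP) length and `b = (z_last − z_first)·Δz` is the axial extent
  from the number of Z-slices the cilium appears in. Exact for a straight
  cilium, up to the axial quantisation of the slice grid.
- **DAAS** — measurement on a vertical "side view" built by reslicing the
  volume along the cilium's in-plane direction (bilinear interpolation within
  each slice, columns at the native pixel spacing), with endpoints picked on
  that plane and segment lengths computed with the anisotropic calibration.

Cilia are **classified** as *flat* when their whole signal appears in at most
four Z-slices, otherwise *angled*. Method agreement is quantified with the
two-way absolute-agreement intraclass correlation ICC(A,1) interpreted on the
Landis–Koch scale, Bland–Altman bias and 95% limits of agreement
(bias ± 1.96·SD of the paired differences), and independent Student's
t-tests between populations.

Because real confocal data comes without ground truth, the package includes a
synthetic-stack generator: straight cilia of known length and 3D orientation
rendered with an anisotropic Gaussian PSF, background and noise, plus analytic
annotations. Every measurement method is validated against the two geometric
identities of a straight segment — projected length `L·cos θ` and axial
extent `L·sin θ`.

## Worked example

Simulate a 31 + 31 cohort of flat and angled cilia whose *true* lengths are
drawn from the same distribution, measure every cilium with all three methods
(three replicates each), and compare:

```sh
ciliometry pipeline --out-dir run --seed 0
```

`run/report_ttests.csv` then contains (abridged):

| method | p | mean_flat | mean_angled |
|--------|------|-----------|-------------|
| MIP | 0.0000 | 2.99 ± 0.74 | 1.44 ± 0.59 |
| PYT | 0.1346 | 3.04 ± 0.73 | 2.74 ± 0.85 |
| DAAS | 0.7962 | 2.93 ± 0.74 | 2.88 ± 0.76 |

Although both populations have identical true-length distributions, MIP
reports a wildly significant flat-vs-angled difference — pure projection
artefact — while DAAS correctly reports none. `run/report_agreement.csv`
shows the same story pairwise: for angled cilia the PyT–DAAS ICC is 0.96
("almost perfect") while MIP–DAAS drops to 0.24 ("fair"); for flat cilia all
pairs agree almost perfectly (MIP–DAAS 0.993, PyT–DAAS 0.985). Practical
reading: measure flat cilia on the projection, measure angled cilia with PyT
(or DAAS when a side view is wanted).

The same can be done in Python:

```python
from ciliometry import run_cohort_study
study = run_cohort_study(seed=0)
print(study.report.population_summary)
```

Individual pieces — `read_stack`, `max_projection`, `measure_pyt`,
`reslice`, `daas_from_stack`, `icc_absolute_agreement`, `bland_altman` — are
importable directly from `ciliometry` for use on real annotated data
(OME-TIFF stacks plus a CSV of per-cilium polylines and slice spans).

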