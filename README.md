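# phosphodia

Phosphosite localization, peptide collapse and occupancy estimation for
data-independent acquisition (DIA) phosphoproteomics — with ground-truth
simulators so every stage can be validated without instrument data.

## The problem

DIA co-fragments every precursor inside wide isolation windows (here 48
windows of 14 Da with 1 Da overlap), so a phosphopeptide's MS2 spectrum is
chimeric and its phospho group may sit on any of several Ser/Thr/Tyr
acceptors — often with positional isomers co-eluting in the same window.
This package implements the computational stack that makes site-resolved,
quantitative DIA phosphoproteomics workable at desk scale:

- **Site localization** (`site_localization`): every positional isomer of a
  precursor is enumerated into site candidates; the union of their
  theoretical b/y fragment masses is deduplicated and each unique mass is
  annotated per candidate as *confirming*, *refuting* or *neutral*. Each
  observed mass receives a weight — the product of clamped intensity,
  mass-accuracy, XIC-shape-correlation and isotope-pattern components, with
  low-correlation traces removed as interference. A candidate scores
  Σ confirming − Σ refuting weights (floored at 0); normalized candidate
  scores yield fractional per-residue confidences, with Class I calls at
  ≥ 0.75 (library mode) or ≥ 0.99 (library-free mode).
- **Library-free pseudo-DDA** (`dia_extraction`): 3D MS1 feature detection
  (m/z × rt × intensity) plus precursor–fragment grouping by elution-profile
  correlation turns a DIA map into searchable pseudo-DDA spectra.
- **Peptide collapse** (`collapse`): a precursor-level "normal report" is
  collapsed to modification-specific peptide tables (charge states summed in
  linear space, log2 afterwards) and to MaxQuant-like site tables keyed by
  (protein, position, multiplicity) at a localization cutoff.
- **Occupancy / stoichiometry** (`stoichiometry`): the fraction *a* of a
  protein pool phosphorylated at a site is estimated by the 3D multiple
  regression model (3DMM): fit `Q ≈ α·P + β·N` by nonnegative least squares
  over all condition × replicate triplets of phosphopeptide (P), counterpart
  peptide (N) and protein (Q) intensities, then
  `a_i = α·P_i / (α·P_i + β·N_i)` per condition. The classical two-condition
  closed form and linear-behavior missing-value extrapolation are included.
- **Benchmark statistics** (`stats_bench`): minimum-valid filtering,
  median normalization with downshifted-normal imputation (width 0.3,
  downshift 1.8), SAM s0-moderated testing with permutation FDR, d-score
  ROC curves, and the bias/variance MSE decomposition.
- **Simulators** (`synthetic_data`): DIA runs with co-eluting positional
  isomers at controlled ratios, the mixed-species ratio benchmark
  (0.25/0.5/1.5/2 : 1), and the stoichiometry benchmark
  (1/10/50/90/99% occupancy grid) — all seed-deterministic with truth tables.

## Worked example

Fit an occupancy model for one site measured in two conditions, where the
phospho form responds at half the rate of its counterpart peptide:

```python
from phosphodia.stoichiometry import fit_3dmm

fit = fit_3dmm(P=[[100.0], [180.0]],   # phosphopeptide intensity per condition
               N=[[50.0], [10.0]],     # non-phospho counterpart
               Q=[[100.0], [100.0]])   # protein level
print(fit.summary())
```

```
3DMM phosphosite occupancy fit
==============================================
points: 2    residual norm: 0
alpha (phospho response):     0.5
beta (counterpart response):  1
----------------------------------------------
   condition    occupancy  clipped
           0       0.5000    False
           1       0.9000    False
```

The fitted response factors (α:β = 0.5:1) say each unit of phosphopeptide
signal represents two protein copies relative to the counterpart; condition
0 is 50% phosphorylated and condition 1 is 90%.

The occupancy-grid benchmark end to end, from a shell:

```
$ phosphodia benchmark stoich --seed 1 --n-sites 500
condition 1%: median estimated occupancy 1.0%
condition 10%: median estimated occupancy 10.1%
condition 50%: median estimated occupancy 50.3%
condition 90%: median estimated occupancy 90.0%
condition 99%: median estimated occupancy 99.0%
```

With 10% measurement noise and three replicates the median fitted occupancy
recovers each design value of the five-condition grid to a fraction of a
percentage point.

Simulating and localizing a DIA run:

```bash
phosphodia simulate --n-precursors 20 --seed 4 --mzml run.mzML --truth truth.tsv
phosphodia localize --mzml run.mzML --truth truth.tsv --cutoff 0.75 --out loc.tsv
```

`loc.tsv` carries one row per precursor with the localized probability string
(e.g. `AAS(0.98)LS(0.02)DTK`), the best candidate's positions, and the Class I
calls at the chosen cutoff.

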