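# Methods

This note documents the models and procedures phosphodia implements, the
defaults that matter, what the simulators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Site localization model

For a precursor with `p` phospho groups and `n ≥ p` S/T/Y acceptors, the
C(n, p) placements are enumerated as site candidates. The union of all
candidates' theoretical b/y ion m/z values (charges 1–2 by default, b1 ions
included because the b1 of an N-terminal phospho residue is maximally
site-determining) is deduplicated at 1e-4 Da — below instrument resolution,
above float noise — and each unique mass is annotated per candidate:

* *confirming* — in this candidate's theoretical set but not in every
  candidate's set;
* *refuting* — in at least one other candidate's set but not this one's;
* *neutral* — shared by all candidates (no localization information).

Each unique mass is then looked up in the run over the boundaries of the
selected peak group. Its evidence weight is the product of four components,
each clamped to [0, 1]:

* **intensity** `1 + log10(apex / max_apex) / d` with dynamic range
  `d = 3` decades: 1 for the strongest fragment of the group, 0 for anything
  three orders of magnitude down. The component depends only on the
  intensity *ratio*, so a global rescaling of the run leaves it — and hence
  all confidences — exactly unchanged. A direct `log(apex)/log(max)`
  normalization would not have this property, which the scoring contract
  requires.
* **mass accuracy** `exp(−(ppm/σ)²/2)` with σ = 10 ppm, evaluated on the
  intensity-weighted centroid of matched peaks in the apex scan.
* **XIC correlation** — Pearson r of the fragment trace against the peak
  group's consensus (smoothed summed) profile. Traces with r < 0.25 are
  interference and their weight is forced to zero outright; this is the
  systematic interference removal that distinguishes DIA localization from
  DDA-style spectrum-only scoring.
* **isotope** (optional, on by default) — agreement of the observed M+1/M+0
  ratio with the averagine expectation at the fragment mass,
  `exp(−|log(observed/expected)|)`. A missing isotope peak does not veto the
  fragment (it may simply be below noise).

The product combination means any failing aspect vetoes a fragment; a mean
combination is available as a config option. Fragments below 1% of the
group's strongest fragment apex count as unobserved (weight 0).

A candidate's raw score is the sum of its observed confirming weights minus
its observed refuting weights, floored at zero before normalization — a
fractional confidence must be a share of nonnegative mass. Fractional
candidate confidences sum to 1; per-residue confidences sum the fractions of
all candidates placing a phospho on the residue (and therefore sum to `p`).
Subtraction happens at candidate level only; the site level aggregates
candidate fractions. Residues at or above the threshold are Class I calls:
0.75 with a spectral library, 0.99 in library-free mode. With no usable
evidence the candidate confidences fall back to uniform (1/#candidates)
rather than abstaining, so downstream code always sees a normalized table;
the uniform values sit far below either Class I cutoff.

Ties at the threshold use ≥, so mirrored 0.5/0.5 isomer pairs produce no
Class I call at 0.75 but both residues are retained in the probability
string for downstream collapse.

## DIA extraction

Isolation windows follow the benchmark instrument scheme — 48 windows of
14 Da with 1 Da overlap starting at 350 m/z; window intervals are closed on
both ends so a precursor in an overlap region is assigned to both windows,
which is the point of overlapping schemes. XICs use 20 ppm tolerance for
fragments and 10 ppm for MS1 features (typical Orbitrap values); every scan
contributes a grid point, absent signal is 0, never missing, which keeps
grids aligned across fragments. Retention time is seconds everywhere;
minute-valued mzML scan times are converted on read.

Peak groups are local maxima of the Savitzky–Golay-smoothed (window 5,
order 2) summed fragment trace above a noise floor of 5% of its maximum,
with boundaries at the nearest flanking minima; the quality score is an
equal blend of the spectral contrast angle between integrated fragment areas
and library intensities, and the mean pairwise Pearson correlation of the
fragment traces. This score is a documented stand-in: the commercial peak
group score it emulates is proprietary, and only the ranking matters here.

Library-free pseudo-DDA generation detects 3D MS1 features (per-scan
centroids linked across adjacent scans within 10 ppm, gap limit 1 scan,
minimum span 3 scans) and assigns each fragment m/z in the feature's window
and rt span to the feature whose MS1 elution profile it correlates with best,
requiring r ≥ 0.8. Constant (zero-variance) traces have r defined as 0 and
are excluded.

Window diagnostics report transmission (intensity at the extreme window
position over intensity at the center position of the same precursor,
observed in two half-window-shifted schemes) and centerness (distance from
window center over half width, 0 at center and 1 at the edge); observations
with zero center intensity are skipped with a warning.

## Peptide collapse

Charge states of one modified sequence in one run are summed in linear
intensity space, then log2-transformed; missing means absent, never zero.
Site-level collapse explodes each localized position at or above the cutoff
(default 0.75) into a (protein, 1-based protein position, multiplicity) key —
multiplicity is the phospho count of the contributing peptide, kept in the
key so singly and doubly phosphorylated evidence remains separate, following
the MaxQuant site-table convention. Contributing precursors (charge states,
missed-cleavage variants) are summed per run and the best localization
probability is retained. Protein groups use the first accession as site key.
When two localized sites on one precursor straddle the cutoff with equal
probability, both are retained. De-normalization divides by per-run factors;
quantile normalization maps every column onto the mean sorted profile
(missing entries keep their rank semantics).

## Occupancy model (3DMM)

If a protein pool Q carries a site at occupancy `a`, the phospho form
reports `P ∝ a·Q` and the counterpart `N ∝ (1−a)·Q`, each with its own
response factor. Across conditions and replicates this is a plane through
the origin, `Q_i = α·P_i + β·N_i`, fitted by nonnegative least squares —
response factors are physical and unconstrained least squares would admit
negative occupancies. Occupancies are computed on replicate means,
`a_i = α·P̄_i/(α·P̄_i + β·N̄_i)`; they are invariant to a common rescaling of
(α, β) and hence to the protein intensity scale. Replicates enter the
regression as independent points. Fits with α = 0 or β = 0 are flagged
degenerate; an all-zero counterpart yields occupancy 1, flagged. Estimates
are clipped to [0, 1] with a flag, matching how bounded stoichiometries are
reported. With exactly two noiseless conditions the fit reproduces the
classical two-condition closed form
`a_B = (z−y)/(x−y)`, `a_A = x(z−y)/(z(x−y))` on the condition ratios
x = P_A/P_B, y = N_A/N_B, z = Q_A/Q_B.

Missing-value extrapolation assumes equally regulated peptide forms scale
linearly: for a target form with gaps, the donor form with the highest
Pearson correlation over ≥ 2 shared observations provides a least-squares
line in log space (intensities are multiplicative, so log space is the
natural choice) that predicts the missing entries; filled entries are
flagged imputed, and entries with no eligible donor stay missing.

## Statistics

Minimum-valid filtering keeps features with ≥ 3 valid values in at least one
group (default). Normalization subtracts each sample's median; imputation
draws missing entries from Normal(mean − 1.8·sd, 0.3·sd) of the sample's
valid values — the standard downshifted-normal scheme for left-censored
intensities — and is bit-reproducible under a fixed seed.

The two-class SAM statistic is `d = (m̄₁ − m̄₂)/(s + s0)` with the pooled
standard error `s` and fudge factor s0 = 0.1 by default. The multi-class
statistic is `√(MS_between)/(√(MS_within) + s0)` — an s0-moderated ANOVA
analog chosen here because it reduces to the familiar √F at s0 = 0 and
shares the d-statistic's moderation behavior. q-values come from group-label
permutations (250 by default): at each |statistic| threshold, the expected
exceedance count over permutations divided by the observed count, clipped to
[0, 1] and made monotone so a larger statistic never has a larger q.

MSE against a known truth is decomposed as bias = |mean − truth| and
population variance; the headline mse = bias² + variance is the classical
identity (equal to the mean squared error about the truth to 1e-12), and the
additive report bias + variance is also emitted for comparisons that sum the
two error components directly. |bias| is used rather than a signed or
positive-part bias.

## Simulators: what they emulate and what they do not

`simulate_dia_run` emulates co-eluting phosphopeptide positional isomers at
controlled mixing ratios inside the 14-Da window scheme: Gaussian elution
(σ = 5 s) over a 120-s gradient at a 3-s cycle (one MS1 scan plus one MS2
scan per window), per-fragment relative intensities drawn log-normal (or
uniform for exact-symmetry tests), averagine isotope peaks, multiplicative
log-normal intensity noise with CV = 1/SNR, and Poisson-distributed
interference peaks uniform in m/z with log-normal intensities. Isomers
co-elute at the identical apex by default — the hardest localization case —
with configurable offsets. Desk-scale rosters (≤ a few hundred precursors)
keep test and benchmark runtimes in seconds.

It does **not** emulate: realistic retention-time structure or peak tailing,
charge-state envelopes beyond the configured fragment charges, chimeric
backgrounds with correlated (co-eluting) interference, detector saturation,
or profile-mode peaks. Passing the localization suite therefore shows the
scoring logic is correct under the stated noise model, not that real-data
error rates (which depend on search engine FDR and chromatographic quality)
are reproduced.

`simulate_species_mix` generates the mixed-species ratio design — a constant
background population and a regulated subpopulation scaled by
{0.25, 0.5, 1.5, 2} against a 1:1 reference, log-normal base intensities,
multiplicative replicate noise at 10% CV by default, 3 replicates.
`simulate_stoichiometry_benchmark` generates P/N/Q triplets on the
{1, 10, 50, 90, 99}% occupancy grid (500 sites, 10% CV, 3 replicates by
default) with configurable generative response factors. Both return truth
tables sufficient to score any estimate, and all generators are
seed-deterministic.

## Known limitations

* No decoy-site FDR model for localization; confidence is per precursor.
* Fragment evidence assumes charge 1 for isotope-ratio checks.
* The peak-group quality score is a stand-in blend, not a re-implementation
  of any proprietary score.
* Pseudo-DDA spectra are not searched; the package stops at generation.
* Occupancy fitting assumes the counterpart peptide is observable; sites on
  peptides whose unmodified form is never detected cannot be fitted.
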