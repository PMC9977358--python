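# Methods

This note documents the models, parameters, and numerical choices behind
`cfswm`, and what the synthetic-data studies do and do not establish.

## Trial design and staircase

`design.build_design` returns the printed parameters of the three
experiments: 312 trials (64 conscious / 224 nonconscious / 24 absent, 4
blocks of 78) for experiments 1–2 and 222 trials (60 conscious split 36/24
with/without distractor, 120 nonconscious split 72/48, 42 absent, 3 runs of
74) for experiment 3, together with the per-condition probe allocations,
timing envelopes, and staircase bounds (RGB 182–206, extended to 174–206 in
experiment 3; start 196; step 2; background 210).

`build_schedule` materializes a seeded schedule whose (condition,
distractor, probe-type) tally reproduces those counts exactly. Choices the
printed design leaves open are resolved as follows and are deliberate
package conventions: target quadrants are balanced within condition with
remainders assigned by a seeded draw without replacement; the distractor
occupies one of the two opposite-side quadrants (experiments 1–2) or any of
the three free quadrants (experiment 3); the probe is reduced to the
quadrant it points at, since only quadrant identity enters scoring; delays
(5–15 s) and experiment-3 ITIs (3–9 s) are i.i.d. uniform on a 0.5 s
lattice; onsets accumulate the full response/PAS deadlines and restart per
block. The staircase state carries over between blocks (the final gray
level of one session seeds the next).

**Staircase direction and equilibrium.** "Contrast" is the distance between
the shapes' gray level and the 210 background, so a window with more than 3
of 10 breakthrough reports (PAS > 1) moves the gray level *up* toward 206
(less contrast), and a quiet window moves it down toward the 182/174 bound
(more contrast), clamped at the bounds; the update consumes its window, and
the buffer restarts. A consequence worth documenting: at fine contrast
resolution this rule equilibrates where P(Bin(10, p) ≥ 4) = 0.5, i.e. at a
breakthrough probability p ≈ 0.365, which corresponds to ~64% fully
suppressed (PAS = 1) trials — not the advertised 70% (or experiment 3's
80%). The advertised floors are reached only when the observer's
psychometric function keeps breakthrough probability below ~0.3 across the
whole accessible contrast range, so that the staircase parks at the
maximum-contrast bound. Both the window threshold and the target floor are
therefore exposed as configuration rather than hard-coded guarantees.

## Observer models

`observers.ObserverParams` defines a generative observer: each sample item
is stored with probability `p_enc_target` / `p_enc_distractor`
(nonconscious trials) or `p_enc_conscious` (conscious trials, always
role-tagged since the cue is visible), optionally carrying its
target/distractor role (`tagging`). At probe time, a stored target-tagged or
untagged item matching the probe elicits "yes" with 1 − `lapse`; a stored
distractor-tagged match with `p_yes_distractor_match` (goal-directed
rejection when below the bias); no match falls back on the bias
`p_yes_guess`. The three presets map onto the competing hypotheses: tagged
(hits > distractor FAs), untagged (hits = distractor FAs, both above
guess), and guessing (all rates at the bias).

Visibility on nonconscious trials is logistic in the staircased gray level,
P(PAS > 1) = 1/(1 + exp(slope·(rgb − mid))), with defaults mid = 178,
slope = 0.35: breakthrough ≈ 0.2 at the experiment-1 maximum-contrast bound,
which makes the staircase bound-limited and yields ≈ 80% PAS = 1 trials at
equilibrium — consistent with the ~29% breakthrough exclusion rate the
design anticipates. Conscious trials are rated PAS = 3 except for an
`erroneous_pas_rate` (default 6.3%) of lower ratings, which exercises the
exclusion logic and feeds the contamination control; absent trials report a
false experience at 10%. Default nonconscious encoding probabilities
(p_enc_target 0.08, p_enc_distractor 0.10, bias 0.35, distractor-match
acceptance 0.08) place the tagged observer in the experiment-1 regime of a
few-percent adjusted hit rate; memory decay over the delay is absorbed into
the encoding probability, and RTs are log-normal (median 800 ms, σ = 0.5)
with 1% omissions — enough structure to exercise the RT/omission exclusion
rules, with no claim of psychophysical realism.

## Behavioral statistics

Exclusions: no response, RT < 250 ms, then the visibility rule (PAS = 1
required in absent/nonconscious, PAS = 3 in conscious, relaxed to ≥ 2 by
`include_pas2`). Rates are computed per subject as 100 × yes/denominator per
probe type, with empty denominators recorded as missing rather than zero,
and tested across subjects (random effects). The Wilcoxon implementation
drops zero differences (the common matched-pairs convention; Pratt handling
is deliberately not used), uses midranks for ties, reports the
continuity-corrected normal Z, and switches to exact enumeration for n ≤ 25
tie-free samples. BF01 uses the JZS formulation — Cauchy(0, √2/2) prior on
the standardized effect, inverse-gamma mixture integrated by adaptive
quadrature with a convergence guard — which reproduces the printed
two-decimal BF01 values at their printed inputs to within 0.01; scipy
supplies the frequentist machinery and pingouin serves as an independent
cross-check in the tests, never as the implementation.

## Synthetic beta volumes

The first-level GLM is out of scope; its outputs are emulated directly.
Each trial × phase beta volume is the sum of the patterns whose label
predicates match the trial, times their amplitudes, plus i.i.d. Gaussian
noise (σ = 1), smoothed at 2 mm FWHM on a 24×24×16 grid of 2 mm voxels
(16×16×10 in the quick examples/tests). The mask hierarchy is an
ellipsoidal brain, a slightly eroded gray-matter shell, a posterior
"visuospatial" slab split into hemispheric patches, and an extended mask
adding an anterior slab. Smoothing uses σ = FWHM/(2√(2 ln 2)) per axis and
a zero-padded kernel renormalized by the smoothed indicator (no
wraparound; constants are preserved exactly).

Planted effects: attention to a left/right target drives the contralateral
patch; distractor presence and probe status add fixed random-sign patterns
over the visuospatial mask; any stimulus adds a broad bilateral response
used by the ROI-defining contrast. Amplitudes were calibrated once against
the decoding module and then frozen: 0.08 (conscious target side, → ~63%
decoding at experiment-3 conscious trial counts), 0.05 (nonconscious and
probe-status effects, → ~52–56%), 0.10 (stimulus-vs-absent). These place
the synthetic data in the qualitative accuracy regimes the analysis is
meant to resolve; they are working points, not estimates of real effect
sizes. What passing tests show is that the *procedure* recovers planted
structure at these regimes and stays at chance without it — not that real
BOLD data would behave this way (no hemodynamics, autocorrelation, motion,
or anatomical variability are simulated).

## Decoding engine

**Folds.** Trials are sorted by onset and cut into `n_folds` contiguous
chunks; at each boundary, neighboring trials are greedily removed (from the
currently larger fold) until every temporally adjacent cross-fold pair is
≥ 30 s apart. Chunk boundaries are re-jittered (seeded) until every fold
retains both classes, with an explicit infeasibility error naming the
binding constraint. An exhaustive gap audit runs in the tests on every
seeded plan.

**Classifier.** The decoder is a deterministic linear max-margin
classifier: L2-regularized squared-hinge SVM with unit cost, solved in the
primal by constant-momentum Nesterov descent (step 1/L from the spectral
norm, early stop on the gradient norm). When voxels outnumber trials the
problem is first rotated into the row space of the data (representer
property of the L2 penalty), and the same solver trains an entire batch of
label vectors — all balancing iterations, or all permutation shuffles of a
fold — in one vectorized call, which is what makes literal classifier
refits inside the permutation null affordable. Determinism gives exact
repeatability: with already-balanced input all 50 resampling iterations are
identical by construction. The tests verify convergence against an
independent optimizer and high decision agreement with a reference SVM
implementation.

**Searchlight and ROI.** Sphere searchlights use all integer offsets within
radius 4.2 voxels (305 offsets, the ~300-voxel convention), intersected
with the brain mask at each center of the search mask; accuracy is the
pooled cross-validated fraction correct, and the map is smoothed at 8 mm
FWHM (renormalized within the mapped region) *before* ROI selection. The
ROI keeps gray-matter voxels strictly above 50%, ranked by accuracy and
truncated at 5,000, with ties at the cutoff broken by a seeded draw whose
size is recorded. Orthogonality between the ROI-defining contrast and the
decoded contrast is the caller's responsibility; a dedicated test verifies
that selection on one contrast does not inflate an independent contrast's
accuracy above chance on null data.

**Balancing.** Unbalanced classes are handled by repeated seeded
down-sampling (default 50 iterations, mean reported); a nested nuisance
factor can be equalized across classes per level, or forced to an exactly
uniform label × factor cross-tab for the counterbalanced control. Every
iteration's cross-tab is recorded and audited in the tests. Input balance
for the searchlight is required explicitly — the caller balances, never the
searchlight silently.

**Group inference.** The two-step permutation test shuffles labels within
folds (preserving fold composition), recomputes every subject's accuracy
with full classifier refits per shuffle, and compares the observed
across-subject mean against the null means, one-tailed, with
p = (1 + #{null ≥ observed})/(1 + n_perm). Subjects with unbalanced classes
are reduced once by a seeded balanced subsample for the null (their
observed accuracy remains the 50-iteration mean on the full data); n_perm
is configurable and desk-scale runs use 99–200 in place of 10,000.

**Controls.** `contamination_control` splits the absent trials into two
bins (sizes within one), spikes one with conscious trials at the estimated
erroneous-rating rate (6.3% of the bin), and decodes clean vs contaminated;
`relabel_control` either decodes a nuisance factor directly or re-runs a
decode on exactly counterbalanced subsets.

## Desk-scale study sizes

The package's own simulation studies (tests and acceptance script) use the
following sizes, chosen once as the package's desk-scale working points:
chance anchors run 10 synthetic subjects × 120 pure-noise trials (ROI and
thinned searchlight means, 50% ± 2 pp); null calibration of the permutation
test runs 200 replicates of 6 subjects × 24 trials with 4 folds, a
16-voxel ROI, and n_perm = 200 (expecting p > 0.05 in ≈95% of replicates);
signal recovery runs 12 replicates of 6 subjects at full experiment-3
conscious trial counts on the default grid with n_perm = 99. The behavioral
suites run 20–30 simulated subjects at experiment-1 trial counts.

## Known limitations

* Beta images are condition-coded Gaussians; none of the temporal structure
  of BOLD (hemodynamic overlap, drift, autocorrelation) survives into the
  synthetic data, so the 30 s fold gap is exercised as a contract, not as a
  physiological necessity.
* The group permutation null shuffles within subject and averages across
  subjects; other poolings of the two-step procedure exist, and the choice
  is recorded in run metadata.
* The Bayesian Wilcoxon variant (a BF for the matched-pairs Z) is not
  implemented; BF01 is available for t statistics only.
* Masks are geometric stand-ins; anatomical atlas masks can be supplied as
  volumes for real-data use but are not constructed here.
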