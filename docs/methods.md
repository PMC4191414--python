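# Methods

## The analysis model

The pipeline treats a screen as a set of 96-well assay plates, each
described by a plate map (well → role: library gene, NT negative control,
ATR/CHK1 positive control, or empty) and a raw signal per well, replicate
and condition (treated / untreated). Three stages take signals to calls:

1. **Percent-of-control normalization.** Each well on a plate is divided
   by the arithmetic mean of that plate's NT wells for the same replicate
   and condition. Because the dominant technical artifacts of plate
   assays (reader gain, seeding density, incubation time) act
   multiplicatively and plate-wide, this removes them exactly: the
   package proves this on itself by simulating plate factors of arbitrary
   magnitude and recovering identical viabilities. The arithmetic mean is
   used ("the average of the negative controls"); a median option exists
   but is off by default. No spatial (B-score / loess) correction is
   applied — the simulator can generate edge effects so their impact can
   be measured, but the analysis deliberately mirrors a design that used
   none.

2. **Viability ratio.** Per gene and replicate,
   `R = (T_g/U_g) / (T_NT/U_NT)`. After stage 1 the NT terms are exactly
   1; they are kept so the operation is also correct on raw inputs.
   Treated/untreated pairing is explicit — sister plates share a plate id
   and replicate index — rather than inferred, because silent mispairing
   is the worst failure mode of this design. Knockdowns with untreated
   viability below a floor (default 0.05, chosen as a level at which
   fewer than a tenth of the cells of a healthy well survive transfection
   alone) are flagged toxic; their ratio is a quotient of noise and is
   reported separately, never scored.

3. **Scoring and the joint rule.** Per gene: the mean of R over
   replicates (at least two usable ones required), `log2` of that mean, a
   z-score of the log2 value against the mean and n−1 standard deviation
   of all eligible library genes, and a one-tailed pooled-variance
   Student's t-test of the gene's per-replicate ratios against the
   NT-well ratios pooled across all plates (df = n1+n2−2, tail resolved
   in the direction of the observed deviation, p floored at 1e−300
   before −log10). A sensitization hit requires R < 0.7 AND z < −1.5 AND
   −log10 P > 1, all strict; resistance mirrors the bounds (R > 1.3,
   z > +1.5). No multiple-testing correction enters the calls — the AND
   of three criteria is itself the specificity control; a
   Benjamini–Hochberg adjusted column (`bh_q`) is emitted for information
   only.

Design points that were genuinely open, and how they were resolved:

* The z-score is computed per gene (on the mean over replicates), not per
  replicate — matching a single point per gene in rank and volcano
  summaries. `log2(mean R)` rather than `mean(log2 R)` feeds it; the two
  differ only at second order in the replicate CV (≈0.5·CV² in log), well
  under the criterion width at screen noise levels.
* ATR/CHK1 control wells are normalized and scored like genes but are
  excluded from the z-score population: they are effect-bearing controls,
  not nulls, and would inflate the library spread. They still receive a z
  against the library population (pooled across all plates and
  replicates, so their score aggregates n_plates × n_replicates wells).
* The NT comparison group for the t-test pools every NT well's own ratio
  (each against its plate's NT means) across the screen, maximizing null
  degrees of freedom; a per-plate alternative is a one-line change.
* The minimum eligible population for z-standardization is two genes
  (the n−1 sd then forces z = ±1/√2); a zero-spread library is rejected
  as degenerate rather than silently producing infinities.

## Secondary (deconvolution) validation

Candidates are re-tested with their four siRNAs in individual wells. The
metric is the same normalized ratio; the t-test uses the lower tail only,
since only sensitization is validated. A siRNA is significant when
R < 0.8 and P < 0.05 (strict); a gene is validated when ≥2 of its tested
siRNAs are significant. Genes tested with fewer than four siRNAs are
allowed; the rule applies to the results present.

## The synthetic screen generator

The generator emulates exactly the statistical structure the analysis
assumes: signal = baseline × plate factor × edge factor × knockdown
viability × condition effect × lognormal well noise, where the condition
effect is 1 (untreated) or `nt_treated_fraction × ρ_g` (treated), with
ρ_g the gene's true normalized ratio. Defaults are the study design:
1006 genes × 4 siRNAs, 88 gene wells + 1 ATR + 1 CHK1 + 4 NT wells per
plate (the source design says only "several" NT wells; four is the
parameterized default), 3 replicates, well noise CV 0.10, plate-effect
log-sd 0.10, ATR true ratio 0.7 (anchored to its observed role as the
criterion-level marker) and CHK1 0.55 (arbitrary, below ATR since the
stronger control), NT treated fraction 0.5 (never reported; inert by
construction since only ratios to NT matter — verified by test). Noise
is lognormal because absorbance noise is positive and roughly
proportional to signal.

Randomness uses numpy's PCG64; one `SeedSequence` per screen is spawned
into independent per-plate streams, so enlarging a library extends a
screen without reshuffling existing plates, and results are reproducible
across platforms.

What the generator does **not** model: transfection-efficiency gradients,
cell-cycle composition, pathway structure among genes, siRNA seed-based
off-target signatures (secondary-screen off-targets are simply ρ = 1),
or correlated noise between sister plates. Passing recovery tests on
this generator therefore demonstrates the pipeline's algebra and
statistics, not robustness to every artifact of real screens.

## Calibration notes and known limitations

* **Null p-values from plate data are mildly anti-conservative.** An NT
  well's ratio is computed against an NT mean that contains the well
  itself, shrinking its log-variance by a factor ≈ (1−1/k) for k NT wells
  per plate, while gene wells carry ≈ (1+1/k); with k = 4 the t-test's
  pooled reference underestimates gene variance by ~29% in sd. This is a
  property of control-based normalization with few controls, not of the
  implementation; the t statistic's own calibration is verified against
  its exact null (normal, equal variance, independent groups), where the
  folded one-tailed p passes a Kolmogorov–Smirnov uniformity check on
  2000 null genes. More NT wells per plate shrink the distortion as 1/k.
* **At the default noise level the three criteria are nested.** With CV
  0.10 and 3 replicates the sd of a null gene's mean ratio is ≈0.09, so
  R < 0.7 is a ≈3.3σ event, while z = −1.5 and −log10 P = 1 sit far
  closer to the null bulk; a null gene crossing the ratio bound almost
  surely crosses the other two, so the joint rule's false positives
  coincide with the ratio criterion's. The AND rule's added specificity
  appears when the null widens: at CV 0.25 it strictly reduces false
  positives in every tested seed (roughly halving them).
* **The t-vs-permutation comparison is resolution-limited at n = 3 + 6.**
  The exact permutation distribution has C(9,3) = 84 atoms, so the tests
  compare the t-based p to a 10⁵-resample permutation oracle at its
  floor for extreme effects, and require agreement within 0.01 at n =
  6 + 12 where the discrete oracle is fine enough to be meaningful.
* Problem sizes in the test-suite simulations (40–200 genes for unit
  tests, full 1006-gene screens for recovery and calibration checks,
  25 seeds for the specificity sweep) were chosen to estimate each
  quantity well inside its assertion margin while keeping the whole
  suite interactive.
* Hit thresholds live in a frozen `Thresholds` dataclass (named set
  "primary-screen"); alternates can be supplied as JSON without touching
  code. The thresholds are constants of the assay design, not fitted
  quantities.
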