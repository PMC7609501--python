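# Methods

## Problem setting

A biomarker of food intake (BFI) is a urinary metabolite whose level signals
recent consumption of a food or food group. The package models the discovery
setting of a free-living crossover feeding intervention: participants follow
fixed daily menu plans, collect spot urines at scheduled times, and each
urine yields a non-chromatographic accurate-mass fingerprint — one intensity
per m/z bin. Discovery then proceeds per food: classify baseline vs
post-exposure urines, rank explanatory bins, annotate them to candidate
compounds by accurate mass, and interrogate the rest of the menu "biobank"
for cross-food generality and specificity.

## Study design model

Two studies share one weekly skeleton: a "Pre" day (dinner only), three
experimental days each with breakfast/lunch/snack/dinner slots, and a "Post"
day. Meal windows are 2 h (breakfast 8–10, lunch 12.5–14.5, dinner 18–20)
and 0.5 h for the snack (16.5–17). Urine slots per experimental day are FMV
(7:00), fasting (7:30), post-breakfast (11:00), post-lunch (15:30) and an
evening series (post-dinner 21:00, bed-time 23:00); the Post day contributes
FMV and fasting. Days are abstract indices (Pre = 0 … Post = 4); calendar
anchoring is metadata.

Study 1 (n = 15): menu plans 1–3 in fixed order on two consecutive weeks,
with a two-arm crossover of the Pre-day dinner. Study 2 (n = 36): menu plans
4–6 ordered by the rows of a 3×3 Latin square drawn uniformly from the full
space of 12 (verified by exhaustive enumeration), with the three Pre-day
dinners permuted independently. Square and dinner draws come from separate
`SeedSequence`-spawned streams of the master seed, so both are reproducible
and mutually independent. Whether the original randomization balanced
squares across participants is unknown; a uniform draw is this package's
choice.

Compliance uses the 5-level self-report scale {0, 25, 50, 75, 100 %}. The
default simulation profile puts 88 % of items at fully eaten
(P = {100: .88, 75: .07, 50: .03, 25: .01, 0: .01}), giving an overall
compliance fraction near 0.94 — comfortably above the > 80 % the design
anticipates; the exact probabilities are free parameters of the simulator,
not measured values.

## Cohort model

Defaults reproduce the recruited totals: n = 51 with the female count fixed
by deterministic rounding (29/51 = 57 % exactly, rather than a Bernoulli
draw), and truncated-normal continuous traits — age 46.3 ± 17.5 y on
[19, 77], weight 68.3 ± 11.5 kg, height 168.2 ± 8.0 cm, waist
83.1 ± 9.7 cm. Truncation to the observed age range shifts the realized
mean by about +0.6 y; tests use a 3-SE band that absorbs this. Study-specific
profiles (study 1: n = 15, 53 % female; study 2: n = 36, 58 % female) are
packaged alongside.

## Fingerprint generator

Each participant × feature baseline is log-normal: feature medians
LogNormal(ln 1000, 1) shared across the cohort, times a participant effect
LogNormal(0, 0.3). The default grid holds 2,000 background bins drawn on a
0.01-Da grid over 80–600 Da, plus one bin per ionization product of each
panel compound. Two *different* compounds may not share a bin at the grid
resolution; the generator rejects such panels naming the pair. One packaged
consequence: the ¹³C isotopologue of furaneol sulfate (208.00024) and
2-furoylglycine [M+K]¹⁺ (208.00067) are unresolvable on a combined-polarity
0.01-Da axis, so the simulation panel omits that single isotopologue. A
polarity-split feature axis would lift this limitation.

Biomarker response is lag + first-order decay, acting multiplicatively on
baseline. For an exposure ending at t₀ with consumed fraction f, every ion
bin of the marker is multiplied at sampling time t by

    1 + (m − 1) · f · exp(−(t − t₀ − L) ln2 / h)   for t ≥ t₀ + L,

with peak fold-change m, lag L and half-life h. The additive-excess form is
used (rather than multiplying by the decay term itself) so that the signal
returns to baseline as t → ∞ and m = 1 is exactly a null marker. Multiple
same-day exposures to source foods of one marker stack multiplicatively.
Closed form: at threshold-fold θ the signal stays elevated for
L + h·log₂((m−1)/(θ−1)). The packaged sweetener marker (m = 9, h = 4, L = 0)
therefore holds > 2× baseline for exactly 12 h.

Samples are then multiplied by a log-normal dilution factor (CV 0.3 around
median 1 — the stand-in for the urine-concentration variation that real
protocols measure by refractive index and normalize away; the factor is
recorded in the sample metadata) and by log-normal measurement noise
(CV 0.2). With noise CV = 0, dividing by the recorded factor recovers
pre-dilution intensities exactly. Every run emits a truth table: per sample,
a 0/1 exposure flag per food and per food group (consumed earlier the same
day), enabling exact recall computations downstream.

Kinetic parameters per compound (lag, half-life, fold) are plausible values
for phase-II conjugates cleared over hours, not measured constants; the only
anchored behavior is the sweetener's 12-h elevation window. The exclusive
single-food markers (eugenol conjugates of curry) deliberately share the
generic legume marker's kinetics (h = 3, m = 5) so that specificity
comparisons between "generic" and "exclusive" markers isolate cross-food
sharing rather than decay speed. What the generator does **not** emulate:
inter-individual kinetic variation, correlated background biology (diet-wide
co-variation of non-marker bins), isotope-pattern intensity ratios, missing
samples, or batch drift — so passing recovery tests demonstrate correctness
of the machinery under the stated model, not field performance on real
biobanks.

## Discovery stage

Contrast construction follows the discovery schematic: for a target food,
exposure days are the participant-days on which it was actually consumed;
the exposed class is the bed-time urine of those days, the baseline class
the same days' FMV. Other pairings are configurable.

The classifier is a random forest (default 1,000 trees, √p features per
split, out-of-bag evaluation, seed surfaced). Metrics: OOB accuracy; mean
margin à la Breiman (OOB vote share of the true class minus the other
class); AUC of OOB vote shares. Proximity is the fraction of trees in whose
terminal nodes two samples co-occur, embedded by classical (Torgerson) MDS
on distance = 1 − proximity with a fixed eigen-sign convention
(largest-magnitude loading positive), making the embedding deterministic.

Two OOB caveats are documented because they are easy to misread as bugs:
(i) under the null, OOB accuracy is pessimistically biased by a few percent
(bag composition is anti-correlated with the held-out sample's class);
(ii) duplicated samples carrying opposite labels are systematically
*anti*-predicted out of bag — the identical twin is usually in-bag with the
opposite label — so their margin is strongly negative, not ≈ 0; vote
symmetry holds only pooled over in- and out-of-bag evaluations. Small paired
designs (few participants × one week) can show the same inversion through
distinctive individual baselines; at the packaged scales (≥ 10 participants
× 3 weeks) the effect is negligible.

Feature selection combines three criteria — RF importance (impurity-based),
per-feature Mann–Whitney AUC (ties ½), and Welch's t (two-sided;
pooled-variance switch available) — because no single one dominates: the
combination rule is rank-sum aggregation (average ranks within each
criterion, ties in the total broken by ascending m/z), with a
Benjamini–Hochberg FDR gate on the t-test p-values (default α = 0.05) and a
top-k cutoff (default 25). Constant features score AUC 0.5 / p 1;
zero-within-class-variance features with different means are treated as
infinitely significant. Whether the original analysis used an FDR gate at
all is not documented; the gate is this package's choice.

## Specificity and kinetics

Cross-food consistency intersects the selected bins of every member food of
a group, retaining per-food ranks; groups with fewer than two member foods
present are skipped with a notice. Specificity of a bin for a target food is
the AUC of its normalized intensity, target-exposed post-meal samples vs
post-meal samples following any other food (1 = perfectly specific,
0.5 = uninformative) — chosen as an AUC for consistency with the discovery
stage and because it admits an exact pair-counting oracle. Elevation windows
are measured on a median time course against the same-day FMV baseline
(default threshold fold 2), with crossing times linearly interpolated
between sampled points; hourly sampling recovers a constructed 12-h window
to well within 1 h.

## Numerical and I/O choices

Monoisotopic masses, isotope masses and the electron mass come from the
NIST table shipped with pyteomics. Ion m/z includes the electron mass — at
m/z 200 its omission alone is a 2.7-ppm error, larger than the ~1-ppm
agreement of the worked example (C₆H₆O₆S [M−H]¹⁻ = 204.98123 vs observed
204.98143, +0.98 ppm). Default annotation tolerance is 5 ppm (the worked
example sits at ~1 ppm; 5 ppm is safe without being promiscuous); when
annotating *bin centers* rather than peaks the tolerance widens to cover
half a bin width. One heavy-isotope substitution per ion; masses print to 5
decimals, full precision internally. MSI levels: 1 requires mass + RT + MSn
against an authentic standard, 2 a literature/spectral match, else 3.

Binning uses half-open intervals [k·w, (k+1)·w) (boundary peaks go up), bin
centers at (k+0.5)·w, default w = 0.01 Da. Log transform x → log(x+1) is
applied before classification by default (a switch). All tables are UTF-8
TSV with header; write∘read is an identity on every packaged table. The
pipeline manifest records config, seed and SHA-256 of every artifact, and
contains no timestamps, so identical config + seed reproduces byte-identical
runs.

## Scales used in the shipped analyses

Desk-scale defaults keep every stage interactive: the packaged biobank runs
12 participants × 3 weeks (720 urines × ~2,030 bins), and the marker
recovery scenario 10 participants × 3 weeks with a single shared legume
marker (30 exposed vs 30 baseline urines per food contrast, 2,000 background
bins). These sizes are the package's chosen simulation conditions; the
generator accepts the full recruited sizes unchanged.

## Known limitations

- Single-axis (combined-polarity) m/z grid; see the furaneol-sulfate
  isotopologue note above.
- No dose–response or intake quantification; exposure is binary × consumed
  fraction.
- Annotation is database matching only; no formula generation from mass, no
  MS² interpretation or retention-time modelling.
- The cross-food intersection over *all four* legume foods is recovered in
  the distilled scenario (legumes in the evening meal, mirroring the
  discovery schematic); in the full-panel biobank, lunch-time legume
  exposures are crowded out of the top candidates by same-day co-exposures,
  and the honest output is the partial-sharing report of analysis stage 5 —
  an illustration of why multi-food menus and cross-food checks are needed
  at all.
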