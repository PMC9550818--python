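# Methods

## Coordinate frame and measurement conventions

All landmarks are millimetres on standing long-cassette films: on the
postero-anterior (coronal) film x is positive toward the patient's left and
y positive cranial; on the lateral film x is positive anterior. Reporting
units follow clinical convention (cm for trunk shift and apical vertebral
translation, degrees and mm elsewhere); the conversion happens inside the
measurement functions, never in the geometry.

Signed quantities use "positive = left side elevated" throughout: the
clavicular angle (CA, line through the two clavicle highest points), T1 tilt
(T1 upper endplate), and radiographic shoulder height (RSH = y_left −
y_right of the soft-tissue shoulder points). Shoulder imbalance is
|RSH| ≥ 10 mm at the two-year film. Whether shoulder height should be read
from soft-tissue shadows or bony landmarks is not settled usage; the schema
carries dedicated soft-tissue points and the measurement uses those.

Cobb angles are the unsigned angle between two undirected endplate lines
(upper endplate of the upper end vertebra, lower endplate of the lower),
folded into [0°, 90°]; they are invariant under rigid rotation and
translation of the landmark set. End vertebrae are auto-detected as the pair
maximizing the Cobb angle inside a region window — proximal thoracic (PT)
C7–T6, main thoracic (MT) T4–L2, both configurable — with ties broken
toward the cranial pair, so a straight spine deterministically returns the
most cranial window pair at 0°. The MT apex is the body centroid
horizontally farthest from the C7 plumb line within T4–T12, and apical
vertebral translation is referenced to the C7 plumb line (the standard
thoracic convention). The C7 plumb line is the vertical through the C7 body
centroid; the central sacral vertical line (CSVL) is the vertical through
the S1 upper-endplate centre.

Proximal junctional kyphosis requires the sagittal angle between the lower
endplate of the UIV and the upper endplate of the vertebra two levels
cranial to be strictly greater than 10° *and* at least 10° above its
preoperative value; with a UIV at T1/T2 the supradjacent levels fall off the
film and the result is "not evaluable" (None), which is distinct from
false. Distal adding-on is a ≥ 5° MT Cobb increase with end-vertebra
distalization, or a ≥ 5° change (either direction) of the disc angulation
below the LIV; it is not evaluable without a first-erect film.

## The MSLV rule

The modified Shinshu line (MSL) is the segment from the C7 spinous-process
centre to the LIV spinous-process centre (LIV restricted to T11–L4). A
vertebral body "touches" the segment when its quadrilateral outline comes
within ε = 0.1 mm (configurable) — radiograph digitization noise is
sub-millimetre, so tangency within ε counts.

"First touched proximally" is operationalized as a traversal of the contact
set (all touching levels strictly between C7 and the LIV), decomposed into
maximal runs of consecutive levels:

1. Walking cranially from the LIV, the run contiguous with the LIV is the
   column the line leaves as it ascends; it is discarded.
2. The MSLV is the most caudal level of the next (more cranial) run — the
   body the line first meets again on its way up.
3. If that first proximal contact is at T2 or above and nothing anywhere in
   T3–T8 touches, the line has *deviated* from the column (the severe-PT
   configuration): the MSLV is the most proximal touching body, clamped
   caudally so it is never cranial to T2. An empty contact set above the
   LIV run is also a deviation, with MSLV = T2.
4. A straight spine, whose LIV run extends to T1, clamps to MSLV = T2.

This traversal is one consistent reading of an informally stated rule; it
reproduces the clinically described pattern (mid-thoracic MSLV for mild
proximal curves, T2 for deviated ones) and is checked against an
independent dense-sampling contact oracle on hundreds of random spines. The
output always lies in [T2, one level cranial to the LIV].

Match classification against the actually instrumented UIV: for the MSLV
method, matched / proximal (UIV cranial to MSLV) / distal; for the
comparator methods, set membership, with a "T1 or T2" recommendation
honoured by an actual T2 (T1 UIVs are excluded from analyzable cohorts, so
a T1 recommendation could otherwise never match). The Lenke method's
published rule covers only the left-shoulder-elevated arm (fusion to T2);
the complement set used for unmatched counting defaults to {T3..T6} and is
configurable. Left-shoulder elevation is judged on signed RSH > 0 (RSH is
the imbalance metric itself; RSH = 0 counts as not elevated). In the
Ilharreborde table a zero T1 tilt or RSH routes to the "opposite direction"
column (the least committal cell), and a bending index α − β/2 of exactly
15° to the "< 15°" row.

LIV rules: Lenke 2A takes the vertebra last touched by the CSVL — walking
caudally from the MT apex, the first (most cephalad) body the CSVL touches;
2B/2C take the stable vertebra (SV) if it is caudal to the end vertebra
(EV), the EV if caudal to the SV, and one level below when they coincide.
The result is clamped into T11–L4 so an MSL always exists.

## Statistics

The 2×2 tables are (unmatched, matched) × (imbalanced, balanced), so the
odds ratio (a·d)/(b·c) is the odds of imbalance when the surgeon's UIV did
not follow the method. The CI is Woolf's log-normal interval with
z = 1.959964; zero cells raise an error by default, with an optional +0.5
continuity correction (always flagged in the result and logged). Fisher's
exact test uses the probability-mass two-sided convention (the sum of
hypergeometric probabilities no larger than the observed table's), matching
R's `fisher.test`; note that two-decimal *display* of small p-values in
clinical tables is often truncated rather than rounded (0.0264 shown as
0.02). Group means use Welch's t with Satterthwaite degrees of freedom;
level-ordinal variables (UIV, MSLV) use the Mann–Whitney U test, exact by
enumeration when the combined n ≤ 12 with no ties and otherwise the
tie-corrected normal approximation on the mid-rank statistic (no continuity
correction, so identical samples give p = 1 exactly); the mode used is
recorded in the result. Interobserver agreement is unweighted Cohen's
kappa, undefined (NaN) when chance agreement is 1. No multiple-testing
adjustment is applied anywhere.

Logistic regression (imbalance ~ unmatched-indicator + preoperative CA) is
fitted by iteratively reweighted least squares (statsmodels GLM/binomial;
tolerance 1e-8, at most 25 iterations) with Wald 95% intervals.
Non-convergence or (quasi-)complete separation — diagnosed by diverging
coefficients (|β| > 15) or non-finite standard errors — raises an explicit
error rather than returning a silently unreliable fit; the cohort report
records such failures per method. On a zero-free 2×2 design the
indicator-only fit reproduces the cross-product odds ratio to at least six
significant digits, which is tested.

## The synthetic world

The generator emulates a surgical Lenke-2 cohort at its published summary
statistics; it is a stated world, not a fit to patient data. Defaults:
n = 55; PT Cobb ~ N(42, 10)°, MT Cobb ~ N(56, 9)° (draws clipped to the
geometric model's validity domain); PT apex T3, MT apex T9; deviation
fraction 0.35; surgeon's UIV drawn from {T2: 43/55, T3: 4/55, T4: 6/55,
T5: 1/55, T6: 1/55}; subtype mix 2A:2B:2C = 39:10:6; thoracic kyphosis
~ N(13.5, 8)° and lumbar lordosis ~ N(47, 9)°; age ~ N(14.3, 1.9) years,
45/55 female; PT/MT correction rates ~ N(0.52, 0.17)/N(0.64, 0.13);
landmark noise 0.5 mm.

A spine is built from a per-level endplate-tilt profile: cosine-eased
interpolation through anchors at the PT upper end vertebra (+0.25·PT), the
PT apex (0), the shared end vertebra (0.25·PT − PT), the MT apex (0), the
MT lower end vertebra (0.25·PT − PT + MT), easing back to neutral by L4.
The asymmetric ±(0.25/0.75) split keeps T1 tilt in the clinically observed
single-digit range while both curve windows span exactly the requested Cobb
angles, so measurement round-trips are exact by construction up to noise.
Lateral centroid offsets are the integral of the tilt profile; bodies are
quadrilaterals (width 30–40 mm, height 22–30 mm, growing craniocaudally)
perpendicular to the local centerline, spinous centres on the centerline.
The whole landmark set is rigidly rotated about S1 so the C7 plumb line
lands at a drawn N(0, 7) mm offset from the CSVL. Landmark noise is applied
as *rigid per-vertebra jitter* (0.5 mm) plus a small 0.1° orientation
jitter: independent per-corner noise at the same magnitude would put about
1.7° of standard deviation on a measured Cobb angle and no generator could
then meet a 1° round-trip contract.

Deviated (severe-PT) spines add a lateral-offset modifier — strongest at
T3–T5, slightly rightward at T7–T8, zero at C7 — whose amplitude is
escalated geometrically until the MSL loses all contact in T3–T8. The
modifier translates bodies without re-tilting them, so Cobb measurements
are untouched (translation invariance); its side effect is that the
auto-detected MT apex can latch onto the displaced proximal levels and
inflate the reported MT apical translation for those patients — a known
generator limitation with no bearing on the shoulder-balance analysis.

Two-year shoulder imbalance is generated *conditionally on matched status*
(P = 0.23 if the drawn UIV equals the MSLV, 0.55 otherwise; implied odds
ratio ≈ 4.1), with |RSH| drawn as 10 + Exp(5) mm when imbalanced and
U(0, 9.5) mm otherwise, realized exactly in the two-year film's shoulder
points. Generating the outcome conditionally rather than mechanically from
geometry gives exact control of the coupling the pipeline must detect.
Everything is reproducible: one `numpy` generator seeded from the config
drives every draw, and identical configs serialize to identical bytes.

What a green synthetic test does **not** establish: the generator matches
the published cohort only at summary level (curve magnitudes, deviation
rate, UIV policy, imbalance coupling). It does not emulate per-patient
correlations between curve flexibility, shoulder posture and outcome, rib
cage or 3D axial rotation, real digitization error structure, or the LIV
distribution's concentration on L1/L2; patient-level tables from real
cohorts are therefore out of reach, and the Monte-Carlo calibration claim
is only that the default world's estimated odds-ratio distribution brackets
the published effect size.

## Numerical choices and degenerate inputs

- Contact tolerance ε = 0.1 mm; "touch" includes tangency within ε.
- Undirected line angles fold into [0°, 90°]; a vertical endplate maps to
  +90° in the signed convention, and the signed convention is discontinuous
  there (tests compare line angles on the circle).
- Coincident endplate points raise a degenerate-geometry error; coincident
  rater label sets with a single label make kappa undefined (NaN).
- End-vertebra and apex argmax ties break toward the cranial candidate
  (strict-improvement search in cranial-to-caudal order).
- Welch's t on two identical constant samples returns t = 0, p = 1 rather
  than failing (both-zero-variance with unequal means is an error).
- The per-method 2×2 analysis falls back to the continuity-corrected odds
  ratio on zero cells by default (flagged); the strict error mode is a
  configuration switch.
- Display rounding of ratios: two decimals below 10, three significant
  figures at or above 10; percentages as integers; full precision always
  retained in `report.json`.

## Known limitations

- The MSLV traversal is one formalization of an informally stated
  geometric rule; alternative readings could differ for contact patterns
  with multiple proximal runs.
- The stable vertebra used for synthetic 2B/2C LIV selection is a
  centroid-proximity surrogate, not a pedicle-based definition.
- SRS-22r scores are opaque covariates drawn from fixed normals; they carry
  no structural relation to the radiographic outcome.
- Interobserver reliability (kappa) is implemented and tested against its
  formula, but no second-rater data exist in the synthetic world, so no
  reliability figure is reported by the pipeline.
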