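# Methods

## Scope and data model

The unit of observation is a measured mitotic metaphase plate: one row per
chromosome with short-arm length S, long-arm length L and optional
satellite length, all in micrometres, keyed by population and plate.
Validation enforces L ≥ S > 0 and satellite/satellite-arm consistency.
Chromosome identifiers within a plate are opaque; homology across plates is
always computed, never assumed from row order.

## Morphometry

Arm ratio r = L/S and centromeric asymmetry CA = 100·(L − S)/(L + S) are
equivalent descriptors (CA = 100·(r − 1)/(r + 1)); CA is bounded on
[0, 100) and is the per-chromosome summand of M_CA. Classification uses the
classical arm-ratio breakpoints 1.7, 3.0 and 7.0 collapsed into four
classes m/sm/st/t with left-closed bins, so every ratio maps to exactly one
class; thresholds are configurable as (label, lower-bound) lists. True
telocentrics (S = 0) are outside the data model, so "t" is simply the
high-ratio tail class.

Satellites are included in total chromosome length (they are chromatin and
contribute to TCL and CV_CL) but excluded from r and CA, so the presence of
a satellite can never flip a chromosome's class. Both switches are exposed
in the run configuration.

## Homolog pairing

Within a plate, homologs are identified by an exact minimum-weight perfect
matching (blossom algorithm) under

    d(a, b) = |CL_a − CL_b| / mean(CL_a, CL_b) + 0.5 · |r_a − r_b|.

Exactness at every plate size removes any heuristic nondeterminism; the
test suite cross-checks the matcher against brute-force enumeration of all
105 matchings on 8-chromosome plates. A pair is flagged heteromorphic when
its members disagree in class label or differ in total length by more than
15% (relative to the pair mean); the threshold is configurable.

A caveat discovered during development: for telocentric chromosomes the
arm ratio is numerically ill-conditioned (r = (1 − f)/f with f the
short-arm fraction; df = 0.01 moves r by ±1.5–2.5 when r ≈ 10), so under
the default arm-fraction noise the |Δr| term of d is dominated by noise
among telocentrics and the matching can cross length ranks in
telocentric-rich complements. Consequences are quantified below.

## Consensus karyotype and idiogram

Per plate, pairs are sorted by decreasing mean total length and
rank-aligned across plates — a convention that assumes a stable length
ordering within a population. Consensus arm/satellite lengths are
across-plate means at each rank; the consensus base class is the majority
vote of per-plate classes (ties broken by reclassifying the mean arms);
satellite presence and arm follow plate majorities. The formula string
counts pairs per rendered class in the fixed order m, m-sat, sm, sm-sat,
st, st-sat, t, t-sat, omitting zero counts; parsing is its exact inverse.

Idiogram geometry draws one column per pair, longest first, short arm up,
centromeres aligned; arm and satellite extents are proportional to the mean
lengths with a single global scale, and the secondary-constriction gap is a
fixed 0.3 µm drawing constant. Output is plain SVG (hand-written XML — the
drawing is simple enough that no SVG library is needed) plus a JSON
geometry table.

## Asymmetry statistics

CV_CL, M_CA and TCL are computed over the full diploid plate and then
averaged across a population's plates (mean ± sample SD, ddof = 1, SD
undefined for a single plate). The alternative of evaluating the indices on
the consensus haploid karyotype is available (`karyotype_indices`) but is
not the default, since published per-population dispersions read most
naturally as across-plate variation. TCL/TLC spellings are both accepted in
calibration targets. The scatter table/plot places populations at
(M_CA, CV_CL) with TCL encoded as point size.

## Synthetic generator

### Calibration

`calibrate_template(formula, {cv_cl, m_ca, tcl})` constructs an eight-pair
complement whose noiseless diploid plate reproduces the targets:

1. **CA placement.** Each class occupies a CA bin derived from its
   arm-ratio bin, shrunk by a 5-point safety margin so that arm-fraction
   noise (≈2 CA points SD per chromosome) rarely flips a class at
   simulation time. Pairs sharing a class are spread evenly over half their
   clamped bin — distinct pairs get distinct centromere positions, as in
   real karyotypes; without this the pairing dissimilarity's ratio term is
   pure noise between same-class pairs and homology becomes unidentifiable.
   A single shift applied to all pair CAs (clamped to the bins) is solved
   by bisection so the complement mean, including any heteromorphism
   effect, equals the M_CA target.
2. **Length profile.** Pair lengths follow CL_i ∝ exp(b·s_i) on an equally
   spaced grid s_i ∈ [1, −1]; b ≥ 0 is solved by bisection so the plate
   CV_CL (satellites and heteromorphism included) hits its target. The
   exponential profile is strictly positive at any CV and reproduces the
   large-vs-small bimodality typical of *Alstroemeria* complements.
3. **Scale.** One global rescale sets TCL (CV_CL and M_CA are
   scale-invariant, so steps are independent).

Satellited pairs carry a satellite of 10% of pair length on the short arm
(the published material does not report satellite sizes; 10% is a typical
microscopic satellite proportion). Classes are assigned to length ranks in
canonical formula order (longest pairs metacentric), consistent with the
bimodal complement; the true per-rank classes of the source populations
are unpublished, so templates are index-consistent reconstructions, not
measured karyotypes. Calibration is fully deterministic (no RNG) and lands
on the targets to machine precision for feasible combinations; infeasible
targets (e.g. M_CA = 60 for an all-metacentric formula) raise a
calibration error reporting the best-achieved residuals.

### Simulation

Each homolog independently draws a multiplicative lognormal factor with
unit mean and CV `noise_cv` (default 0.03) applied to its total arm length
and satellite — emulating plate-to-plate chromatin contraction and
measurement error — and an additive Gaussian perturbation of its short-arm
fraction with SD `arm_split_sd` (default 0.01), clamped to keep S ≤ L.
Heteromorphism is a deterministic relative offset on one homolog's long
arm (the packaged var. *tofoensis* template: pair 5, +20%). A single
integer seed determines all outputs; per-plate seeds derive from
`SeedSequence((seed, plate_index))`. Defaults were chosen once to produce
across-plate dispersions on the same scale as the published per-population
SDs; the generator does not model inter-individual variation, C-banding or
satellite-size variation, so green recovery tests establish statistical
consistency of the pipeline, not biological realism of the noise.

### What recovery tests establish — and known limitations

With the defaults, 10 simulated plates per population recover the
published CV_CL/M_CA/TCL means within two published SDs and the published
haploid formulas (three distinct strings across the four varieties).

Two quantified limitations, both rooted in the telocentric ill-conditioning
noted above:

- **Formula stability for var. tofoensis.** Its complement has four
  telocentric pairs; occasional cross-rank matches among them corrupt
  satellite majority votes, so the 10-plate consensus formula reproduces
  the published string in ≈90% of seeds (the other nine populations:
  ≈100%).
- **Heteromorphism detection rate.** The +20% long-arm offset on a
  telocentric changes total homolog length by a factor (S + 1.2L)/(S + L)
  ≈ 1.17–1.20, barely above the 15% flagging cutoff (ratio 1.162), while
  the two homologs' independent 3% length noise gives the log length-ratio
  an SD of √2·0.03 ≈ 0.042. Even with perfect pairing the flag can
  therefore fire in at most ≈66–78% of plates, and mis-pairing adds
  spurious flags; "exactly pair 5 flagged" is observed in only ≈12% of
  seeds. The corresponding acceptance test asserts a 95% detection rate
  and fails; raising the offset (≳27%), lowering the threshold, or
  reducing the noise would reach 95%, but those are the stated defaults,
  so the package reports the honest rate instead of moving them. On the
  noiseless plate, pair 5 is always the unique flagged pair.

## Numerical choices

- Sample (n−1) standard deviations throughout (small numbers of plates).
- Measurement files are written with 6 significant digits; read∘write is
  the identity to well under the 1e-4 µm round-trip tolerance.
- All report artifacts (CSV/JSON) use fixed orderings and float formats,
  so re-running an analysis is byte-identical; the scatter SVG strips its
  date metadata for the same reason.
- Majority-vote ties in consensus classes are broken by reclassifying the
  across-plate mean arms; equal-dissimilarity matchings resolve by the
  matcher's deterministic edge order.
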