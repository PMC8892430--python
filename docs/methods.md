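# Methods

This note documents the models, algorithms and numerical choices behind
`tracerscreen`, in the order the pipeline runs, and states what the
synthetic-data studies do and do not demonstrate.

## Data model and units

Retention time is seconds everywhere inside the package; the CLI and the
TSV report use minutes because that is how chromatographic methods are
usually quoted. m/z tolerances are relative (ppm). Only centroided MS1
scans are processed; MS2 scans and scans of the non-selected polarity are
dropped on read. mzXML is the primary input dialect (32- or 64-bit
network-order peak arrays, indexed or not); mzML is read through a compact
cvParam-level parser. A heuristic flags probable profile-mode input (very
dense, near-contiguous m/z sampling) with a warning rather than an error,
since dense centroided spectra can look similar.

Within a ±ppm window, per-scan lookup returns the **most intense** centroid
(ties break toward the smaller mass error): noise centroids are weak, and
this choice is stable against split centroids. EIC extraction, by contrast,
**sums** all centroids in the window, which conserves total ion current and
is the right aggregation for areas. The choice sum-vs-max for EICs is
genuinely open; summation is the default and the only mode used by the
pipeline.

## Rules and the built-in rule sets

A rule set is an ordered tuple of predicate objects evaluated against an
`offset → intensity` map; the first violation is reported. The same pure
function is applied to scan intensities and, later, to chromatographic peak
areas — areas carry an extra factor of peak width in seconds, which leaves
every ratio rule unchanged and only loosens absolute intensity thresholds
(a peak wider than ~1 s has area larger than its apex intensity; the
scan-level check has already enforced the thresholds on intensities).

The built-in sets encode the published screening parameterization for
malonate-derived C2 ladders: required offsets {0…+4} (standard) or
{0…−6} (reversed), forbidden offsets {−1,−2} / {+1,+2} at a 5 % noise
tolerance, 10–300 % windows chaining each even satellite to its lighter
even neighbour, 10–200 % windows checking each odd satellite against
*both* of its even neighbours separately (the conservative reading of
"relative to A and B"), and the odd/even ratio-constancy identity at ±10 %.
Two open readings were settled as follows:

- the 10–300 % windows are read distributively (X+2 vs X, X+4 vs X+2),
  matching the unambiguous phrasing of the reversed set;
- equality of group ratios uses the symmetric, strict metric
  `|r_i − r_j| / min(r_i, r_j) ≤ tol` over all pairs.

The relative-abundance windows are represented as range-mode `RatioRule`s
(the class the published description itself assigns them to); this also
gives the stepwise-attrition log a clean partition into intensity →
absence → ratio stages. Any object with an `evaluate` method and offset
properties participates in evaluation, so user-defined rule subtypes need
no engine changes. Rule sets serialize to YAML/JSON so thresholds can be
edited without code. The carbon mass difference is the exact
13C−12C value, 1.0033548378 Da; the engine accepts a different Δm for
other elements, but no non-carbon rule set is built in.

## Scan screening and clustering

Every centroid of every scan is provisionally X. A centroid whose intensity
is below the hard X-intensity bound implied by the rules (1e5 counts for
the built-in sets) is skipped before satellite lookup; this is an exact
shortcut, not an approximation, and the test suite checks bit-equality
against a brute-force evaluator with no such shortcut.

Survivors are clustered on X m/z with complete linkage on log(m/z) and the
dendrogram cut at the inter-scan mass deviation (8 ppm), which bounds every
cluster's relative m/z diameter by the cut — the reason complete linkage
was chosen over single or average linkage. Each m/z cluster is then split
wherever consecutive members are more than `max_scan_gap` (default 3) scans
apart, and groups with fewer than `min_cluster_size` (default 3) members
are discarded: a real chromatographic peak of 5–25 s width sampled every
~0.5 s must appear in several consecutive scans, while isolated passes are
either noise or pathological crossings (see the shifted-satellite decoy
below). Scan-level compliance is required of cluster members but not of
every scan across the final peak — low-abundance satellites drop out at
the peak tails; the final arbitration is chromatographic.

## Chromatographic verification

Peak picking follows the centWave idea, reimplemented: a Mexican-hat CWT
over 10 log-spaced scales covering σ = width/4 for widths 5–25 s, per-scale
local maxima linked into ridge lines (largest scale first, matching window
proportional to scale), ridges of at least 3 scales kept. The apex is
refined on the raw trace near the ridge position; boundaries descend from
the apex to the nearest local minima (or zero); the area is the trapezoidal
integral between the boundaries. The width filter uses the
Gaussian-equivalent width 4σ estimated from the interpolated half-maximum
crossings — unlike the best-responding scale, this estimate keeps growing
for humps wider than the scale grid, so a 60 s hump is rejected rather
than aliased onto the largest scale. SNR is apex over 1.4826 × MAD of the
trace outside the peak in a local window, floored at 1 count (so a
noiseless baseline never vetoes a peak); default threshold 3. The original
algorithm publication fixes neither the scale count nor the SNR cut; both
are parameters here.

A candidate is accepted when (i) an X peak lies in its rt window, (ii)
every required offset has a picked peak whose apex falls inside the X peak
bounds, (iii) all pairwise Pearson correlations of the coelution-checked
EICs, restricted to the X peak bounds, reach 0.85 (restricting to the X
bounds keeps neighbouring isomers from depressing r), and (iv) the rule
set holds on the peak areas, with forbidden offsets contributing the area
of a coeluting peak or zero. Multiple X peaks in one candidate window are
verified independently, so coeluting-window isomers yield separate
features. Zero-variance traces make the correlation undefined and count as
coelution failure.

## Bracketing, convolution, reintegration

Bracketing is greedy and deterministic: features ordered by descending
summed isotopologue area seed brackets and absorb, per sample, the nearest
unassigned feature within ±0.1 min and ±5 ppm; a sample contributes at most
one feature per bracket. Greedy-by-intensity is a design choice (the
upstream software this stage mirrors does not document its algorithm);
it is idempotent and order-stable. Convolution connects brackets whose
consensus rt agree within the bracketing tolerance and whose X EICs
correlate at r ≥ 0.85 (the same threshold as coelution — no separate value
is published) in at least one shared sample; connected components become
feature groups. Reintegration fills non-detected samples by integrating
the EICs over the mean X peak bounds of the detected members, flagging the
values `reintegrated`; detected members are never altered.

## The synthetic incorporation model

The generator's pattern model has two layers:

1. **Even envelope.** Each of the `n_units` C2 units is tracer-derived
   independently with probability `q`, so the number of incorporated units
   is Binomial(n_units, q) and the even offsets ±2m carry its weights: a
   strictly decreasing staircase iff `q < 1/(n_units+1)`, otherwise a hill
   — both shapes are observed in real cultures, depending on tracer supply
   and the timing of biosynthesis.
2. **Odd satellites.** Isotopic defects (natural 13C in the light pool,
   residual 12C in the labelled pool) displace a molecule by ±1. The
   expected number of defects is
   `λ = (1 − tracer_purity)·2·n_units·q + ε_b·(n_carbons − 2·n_units·q)`
   with `ε_b = nat_13c` (standard) or `1 − label_purity` (reversed); the
   probability of carrying a defect is the Poisson `1 − exp(−λ)`, split
   evenly between the two directions: each odd offset 2m+1 receives
   `δ·(S_m + S_{m+1})` with `δ = (1 − exp(−λ))/2`.

The symmetric split is a deliberate idealization. Physically, up-defects
weight the lighter neighbour and down-defects the heavier one, with weights
that drift slowly with m; the symmetric form makes the diagnostic identity
`(I_{2m} + I_{2m+2}) / I_{2m+1} = (1 − 2δ')/δ'` **exactly** independent of
m (and keeps odd satellites strictly below the mean of their even
neighbours for every parameterization, since δ < 1/2). That exact constancy
is the property the ratio rules are designed around, and the package
asserts it at 1e−9 relative over random parameterizations. A fully
per-carbon binomial treatment does not share the exact identity — its
odd/even ratios drift by several percent to tens of percent across m, and
it would also place a spurious X−1 satellite on the monoisotopic species —
which is why the layered model above was chosen for the generator.
Mirroring the labelling parameters (swapping which pool is "dirty")
negates every offset exactly, which is asserted to 1e−12.

Defaults: `tracer_purity = 0.99`, `nat_13c = 0.0107` (natural 13C
abundance), `label_purity = 0.99` (a uniformly labelled carbon source is
never perfectly pure), scan interval 0.5 s, peak σ 3 s, intensity noise CV
5 % when noise is requested.

Planted compounds in the bundled demo studies use carbon skeletons of
18–30 atoms with `q ∈ {0.10, 0.12, 0.15}` and apex heights 1.2–3 × 10⁶
counts — conditions under which the full theoretical pattern satisfies
both built-in rule sets with margin, i.e. the compounds are genuinely
detectable, continuous-biosynthesis cases. Decoys violate exactly one rule
each: a deleted required satellite, a forbidden satellite at 10 % of X, a
threefold-inflated first odd satellite (breaking ratio constancy), a
pattern scaled below the X intensity threshold, an X±2 trace shifted 15 s
(failing coelution; it can pass the scan rules in one or two crossing
scans, which the minimum cluster size removes), and a half-width first odd
satellite (scan-compliant at the apex but failing the area re-check).

## What the synthetic studies show — and what they do not

On noiseless synthetic runs the pipeline attains 100 % recall of planted
compliant compounds and zero decoy leakage, for both approaches, and the
logged attrition of candidates across the cumulative intensity → absence →
ratio stages is monotone. These are correctness statements about the
implementation against a known truth. They do not bound recall or
false-discovery rates on real chromatograms, where peak shapes are not
Gaussian, backgrounds drift, coeluting isobars overlap within the mass
tolerance, patterns deviate from the symmetric-defect idealization, and
carry-over between injections can plant true patterns in blank samples.
The generator also does not simulate a full metabolome, adduct chemistry
beyond a simple co-eluting companion, or detector saturation.

## Problem sizes

The bundled studies use single-digit-minute synthetic runs (≈1 300 scans
at 0.5 s intervals) with 40 planted compounds for the recovery studies,
three jittered replicates for bracketing, and 50 random five-scan runs for
the brute-force oracle comparison; the complete test suite and the
acceptance script each run in well under a minute on one CPU.
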