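# Methods

## Scope

`apascreen` implements a targeted dereplication pipeline for 3-alkyl
pyridine alkaloids (3-APAs) in sponge extracts analyzed by two-function
(MS^E) LC-MS: an exact-mass formula engine, a combinatorial compound
library, diagnostic-fragment screening, drift-time (ion-mobility)
resolution of coeluting isobars with pseudo-MS3 association, and
PCA-based prioritization of specimens against cell-viability data. A
synthetic-data module generates cohorts with the statistical structure
the analysis assumes, so every stage is testable end to end without
instrument files.

## Mass convention

All ion m/z values are computed as the plain monoisotopic formula mass
of the charged species divided by the charge, with added protons
counted as H atoms and **no electron-mass correction**
(C = 12.0 exactly, H = 1.0078250319, N = 14.0030740052,
O = 15.9949146221 Da). This convention reproduces the published
reference values for this compound class to four decimals — e.g. the
tetrahydropyridine diagnostic C6H12N+ at 98.0970, where an
electron-corrected mass would be 98.0964. Reported values are rounded
half-even to 4 decimals; full precision is kept internally.

Natively charged species follow class rules: cyclostellettamine
dications and viscosamine trications are the intact cation formula
divided by 2 or 3; their "singly charged molecular ion" is formula
plus one H. Haliclamines are neutral and observed as [M+H]+ and
[M+2H]2+; viscosalines are native monocations with an additional
(M+H)/2 doubly charged species.

## Compound library

Formula rules per class (n, m chain carbons):

| class              | intact species             | formula                       | F1/F2 fragment rule   |
|--------------------|----------------------------|-------------------------------|-----------------------|
| cyclostellettamine | cyclic dimer, 2+ cation    | C(10+n+m) H(2(n+m)+8) N2      | C(5+k) H(2k+4) N (Pyr)|
| haliclamine        | cyclic dimer, neutral      | C(10+n+m) H(2(n+m)+14) N2     | C(5+k) H(2k+8) N (THP)|
| viscosamine        | cyclic trimer, 3+ cation   | C(15+S) H(2S+12) N3           | — (diagnostic only)   |
| viscosaline        | linear + beta-alanine, 1+  | C(13+n+m) H(2(n+m)+14) N3 O2  | — (curated 2+ frags)  |

Thirteen curated reference compounds are shipped (five
cyclostellettamines, five haliclamines, one viscosamine, two
viscosalines). Where a published reference value is internally
inconsistent with its own printed formula (several doubly charged
values, the viscosamine trication, one viscosaline formula that is one
H heavier than its printed mass), the entry stores both the printed
and the recomputed value; **matching uses the recomputed,
self-consistent value by default**, switchable to printed values at
library construction. Haliclamine A does not satisfy the THP–THP
hydrogen rule — its reference fragments follow the pyridinium rule
with 9- and 12-carbon chains — so it is stored as a curated-only entry
with both moiety diagnostics attached rather than regenerated from a
rule the data do not support.

Homolog expansion enumerates all unordered chain combinations per
class over a configurable range (default 8–14 carbons, covering every
curated species); generated entries matching a curated (class, chains)
pair are replaced by the curated entry.

## Synthetic data generator

The generator emulates a screening cohort, not an instrument:

- **Cohort**: 28 samples, 3 alkaloid carriers (defaults S1, S5, S8).
  Carriers receive all 13 curated compounds scaled by per-sample
  abundance profiles: carriers 1 and 2 share a profile with carrier 1
  richer in cyclostellettamine Q and the haliclamines; carrier 3 is
  divergent (most compounds higher, five depleted). Profiles are
  ordinal mimics only — no absolute concentration scale is implied.
- **Runs**: 21-minute retention grid at 0.05 min steps, m/z 50–1200.
  Each compound elutes at a deterministic hash-derived retention time
  (2–16 min) with a narrow Gaussian profile (sd 0.06 min) plus
  per-sample Gaussian rt jitter (sd 0.05 min). Function 1 receives all
  ion species with 3-peak carbon isotope envelopes (binomial over
  carbon count, per-carbon heavy probability 0.0107; N/O isotopes are
  below matching tolerance and ignored); function 2 receives the
  moiety diagnostics, F1/F2 fragments and an attenuated precursor at
  the same retention time. All m/z values carry Gaussian jitter
  (default sd 3 ppm, within the 1–10 ppm deviations typical for this
  instrument class).
- **Background**: 2100 shared features, m/z uniform over the
  acquisition range, intensities log-normal(mu=10, sigma=1), with
  per-sample multiplicative log10-normal noise (sd 0.15, ~35–40% CV —
  an ordinary LC-MS run-to-run variability), plus Poisson shot-noise
  peaks (rate 50 per function). Alkaloid ion intensities default to
  1e6 (abundance 1), making the 13 compounds a substantial fraction of
  a carrier's total ion current, as expected for dominant secondary
  metabolites; this matters because sum normalization then imprints a
  small carrier-specific shift on every background feature, which is
  exactly how such compounds drive real PCA separations.
- **Viability**: carriers are drawn around reference anchors (8, 31,
  22% of control) truncated below 50%; five designated non-carrier
  actives around (29, 51, 18, 31, 13); the remainder uniform 55–100%.
- **TAP dataset**: a precursor at m/z 218.19 with two Gaussian drift
  populations (defaults 4.0 and 5.5 ms, sd 0.35 ms): the lower-drift
  population's secondary spectrum carries the ring-opening fragment
  (singly charged molecular ion minus C2H6N, 44.0500 Da → m/z 393.34),
  the higher-drift population carries both onium fragments (204.18,
  232.21). Drift times are arbitrary model values in milliseconds; no
  collision-cross-section calibration is modeled.

Every simulator is a pure function of (spec, seed); identical inputs
give byte-identical serialized output.

**What passing tests do not show:** the generator has centroided
stick spectra, no chromatographic peak shapes, no ion suppression, no
adducts, no correlated biological background (e.g. species-level
metabolome structure), and its drift/abundance scales are modeled, not
measured. Recovery rates on this generator demonstrate the logic of
the pipeline, not its performance on instrument data.

## Screening

EICs of the two diagnostics (98.0970 THP, 106.0657 Pyr) are extracted
from function 2 at 10 ppm (the tolerance within which all reference
deviations fall); peaks are local maxima with prominence >= 0.25 x
apex and bounds at the nearest minima. Each peak's bounds window is
searched in function 1 against the library (default 10 ppm); the
claimed charge is verified from the 1.003355/z isotope spacing with
the first-isotope ratio required inside (0.1, 0.9) — wide enough for
C29–C54 species (expected ratios 0.31–0.58) while rejecting the k=2
isotopologue masquerading as a z=1 spacing (ratio ~0.05). Fragments
are confirmed in function 2 within the same window. The default
acceptance rule (precursor AND >= 1 diagnostic AND >= 1 F fragment,
each configurable) mirrors the diagnostic-gated screening workflow.
The score, `w_ppm (1-|ppm|/tol) + w_diag #diag + w_frag frac_F +
w_iso iso`, is a ranking convenience, not a probability. When two
library entries match one peak both annotations are kept, ranked by
score then |ppm| — identifications at this stage are tentative by
construction.

## TAP / pseudo-MS3

A driftogram at the target m/z (+-0.05 Da) is peak-picked with a
minimum separation of 0.5 ms (closer maxima are suppressed, keeping
the higher apex). Secondary spectra whose drift bins fall inside a
peak's bounds are merged at 0.01 Da to form its pseudo-MS3 spectrum.
Classification: `ring-opened` if the spectrum contains
2*mz + m(H) - m(C2H6N) within 0.05 Da; `compact/onium` if it contains
both onium fragments of the best library match at the precursor m/z;
otherwise `unclassified`. A signature peak must reach 5% of the
spectrum base peak — drift populations overlap at their tails, and
without a relative floor the cross-talk from a neighboring
population's signature would misclassify peaks.

## Prioritization

Normalization follows the standard metabolomics recipe: sample sum
normalization, zero replacement by half the smallest positive
normalized value, log10 (base and zero rule are this package's
choices; the upstream tools leave them unstated), then per-feature
unit-variance scaling (zero-variance features dropped with a logged
warning). PCA is computed by SVD of the centered matrix, explained
fractions from squared singular values, with the sign convention that
each loading vector's largest-magnitude entry is positive.

Candidate selection runs k-means (k=2, 20 restarts, seeded) on the
first two score dimensions. The smaller cluster becomes the candidate
set only if (a) its cytotoxic fraction strictly exceeds the other
cluster's and (b) it is uniformly cytotoxic (`min_active_fraction`,
default 1.0). Gate (b) is deliberate: with ~8 actives scattered over
28 samples, a random split's smaller cluster is active-enriched about
half the time, so gate (a) alone would routinely promote noise
clusters; requiring uniform activity keeps the false-positive rate of
the prioritization near the few-percent level while leaving a genuine
chemically driven cluster (which is uniformly active) untouched.
Separating components are those with between-cluster variance share
above 0.5. Driver features are ranked by |loading| on the separating
components and matched against the library at 10 ppm. The abundance
heat-map matrix records the strongest precursor-hit intensity per
(compound, sample), optionally z-scored per compound.

Activity calls use strict `viability < 50%`. The reference viability
table contains one extract at 51% listed among the cytotoxic ones;
the package preserves that value as data and calls it inactive under
the strict rule — the threshold is a parameter for users who want the
inclusive reading.

## Problem sizes and determinism

Default test and acceptance runs use the full 28-sample cohort with
2100 background features; recovery statistics are computed over 10
seeds for both the screening (13/13 compounds, 0 background
annotations) and the prioritization (exact recovery of the 3 injected
carriers) checks. All randomness flows from user-supplied integer
seeds through `numpy` `SeedSequence` streams.

## Known limitations

- The element table covers C/H/N/O only (sufficient for this alkaloid
  class); extendable via the shipped JSON table.
- The first doubly charged viscosaline species reported in the
  reference data is not derivable from the stated formulas; it is
  carried as a printed-only value and never matched by default.
- Monomeric 3-APAs and the halitoxin/manzamine/sarain classes are out
  of scope, as are adduct networks, negative mode, and retention-time
  prediction.
- PCA explained-variance figures from real cohorts are properties of
  real data; the synthetic cohort makes no attempt to reproduce them.
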