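# Methods

## The comparison being modelled

Two cell states (proliferative, PRO; quiescent, QUI) are profiled on two
platforms. A two-channel spotted microarray hybridizes both samples to the
same slide with different dyes (Cy3/Cy5), yielding paired intensities per
~70-mer probe; RNA-seq yields per-transcript read counts. Because the
platforms quantify different probe universes, the analysis proceeds in
four steps: normalize each platform, map array probes onto transcript-level
feature probes, correlate and intersect the per-probe QUI/PRO fold changes,
and arbitrate disagreements with qRT-PCR on a gene panel.

## Microarray model and processing

Simulated channel intensity for a probe sourced from transcript *t* is

```
I_channel = scale · a_state(t) · g_channel · exp(ε),   ε ~ N(0, σ_array²)
```

with state-to-channel assignment set by the dye orientation, multiplicative
channel gains `g` (dye bias), and log-normal proportional noise. Decoy
probes (no target in the genome) read a constant background level instead.
Crosstalk then mixes the clean channels symmetrically,
`obs_A = clean_A + α·clean_B`.

Processing inverts this model: the crosstalk unmixing is the exact algebraic
inverse `clean_A = (obs_A − α·obs_B)/(1−α²)` (α ≥ 0.5 is rejected as a
matter of policy — the unmixing becomes ill-conditioned approaching the
singular point; values driven negative by noise are floored at 1e-6 and
flagged). Dye bias is removed by LOWESS on the MA representation
(M = log2 cy5/cy3, A = ½ log2 cy5·cy3): the fitted curve M̂(A) — tricube
weights, span 0.3, 3 robustifying iterations, via statsmodels — is
subtracted from M and the channels are reconstructed preserving A exactly.
A single coefficient α with symmetric mixing is the simplest invertible
crosstalk model; nothing in the processing depends on the simulator's noise
being log-normal.

LOWESS note: normalization is exactly idempotent once the fitted trend
captures the data (e.g. a constant M offset); on noisy data a second pass
moves the fit by the smoother's noise response (order σ/√window), so
idempotence is asserted only in the converged regime.

Dye swaps are represented as orientation metadata (`qui-cy5`/`qui-cy3`),
never by relabelling intensity columns; swapping is therefore an involution
and turns per-probe cy5/cy3 ratios into reciprocals while the
orientation-aware QUI/PRO fold change of a correctly labelled scan is
unchanged. Replicate arrays are combined by the geometric mean of fold
changes (arithmetic mean in log2), which commutes with reciprocals.

## RNA-seq model and processing

Expected counts are proportional to abundance × transcript length, scaled
so each replicate's expected total equals its library size; counts are
negative binomial via a gamma–Poisson mixture (variance μ + d·μ²; d = 0
gives Poisson). Feature probes span each annotated transcript's full extent
(1-based inclusive coordinates, forward-strand reference sequence). RPKM is
`1e9·count/(length·total reads)` with the total taken over probes in the
sample. Replicates are pooled by summing raw reads and renormalizing —
read-level pooling, not an average of per-replicate RPKMs. Fold changes add
a 0.05 pseudocount to both numerator and denominator RPKM, preventing
division by zero at silent probes (both silent ⇒ FC = 1).

### Conservation of total output

RPKM divides by the per-sample total, so the fold change of every probe is
multiplied by the compositional factor Σ(a·L)_PRO / Σ(a·L)_QUI. If the two
states differed in total (length-weighted) transcript output, even
noise-free RPKM fold changes would be offset from the per-gene truth by a
shared constant. The generator therefore conserves total transcriptional
output between states — quiescence redistributes rather than rescales the
transcriptome: change assignments (gene set, signs, magnitudes) are
rejection-sampled until the weighted totals agree within 0.005 log2 units
(weights default to 1; the pipeline passes transcript lengths). This is a
modelling choice, not a theorem about real cells: absolute RNA content does
change with proliferative state in reality, and composition-normalized
quantities are silently blind to that.

## Probe mapping

For array probe *M* with sequence *s* and design chromosome *c*:

1. **Sequence method** — candidates are the feature probes on chromosome
   *c* whose spanned sequence contains *s* or its reverse complement as a
   contiguous substring. Matching is exact (a 70-mer hybridization probe is
   treated as a verbatim subsequence; no mismatches or gaps). Reverse
   complement matching is on by default (probes may be spotted antisense to
   the reference) and can be disabled.
2. **Resolution** — a unique candidate is taken; among several (typically
   splice variants) a candidate sharing one of the probe's transcript IDs
   wins, otherwise the lexicographically smallest feature-probe ID is taken
   and flagged ambiguous. The tie-break replaces an arbitrary choice with a
   deterministic one so mappings are reproducible and order-invariant.
3. **ID fallback** — with no sequence candidate, the probe's transcript IDs
   are scanned in sorted order and the first one carried by a feature probe
   wins; probes with no IDs (and no sequence match) stay unmapped.

Summary percentages follow the reporting convention of the emulated design:
mapped share of array probes to the nearest integer, unique matched share of
feature probes to one decimal.

## Concordance statistics

* **Correlation suite** — Pearson on raw values, Pearson on log2 values,
  Spearman (average ranks on ties); inputs must be strictly positive so the
  log is defined, and the log transform leaves Spearman untouched since it
  preserves rank order.
* **Fisher z** — two independent correlations are compared with
  z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), two-sided normal
  p-value. The independent-samples form is used even where both
  correlations share one vector (e.g. both platforms against qPCR), which
  is anti-conservative in principle; flagged here rather than corrected.
* **Top-k overlap** — probes are ranked by fold change (ties broken by
  ascending probe ID), and the intersection size n of the two platforms'
  top-k lists is referred to an empirical null: each of 10,000 trials draws
  two independent uniform k-subsets of the common probe universe S and
  records their overlap; p = share of trials with overlap ≥ n (the raw
  trial count is reported alongside). Conditioning on one subset, the null
  overlap is exactly Hypergeom(|S|, k, k), which provides the closed-form
  oracle used in testing; the Monte-Carlo path is retained as the
  pipeline's primary statistic. The universe defaults to the unique mapped
  feature probes (configurable to the mapped-array-probe count).
* **Threshold concordance** — among common probes with FC above a cutoff
  (default 5) on one platform, the share also above it on the other,
  reported to one decimal (undefined → NaN when nothing passes the cutoff).
* No multiple-testing correction is applied anywhere in the pipeline, and
  no differential-expression testing is performed.

## qRT-PCR arbitration

CT values follow `CT = intercept + slope·log2(abundance) + N(0, σ_CT²)`
with the default slope of −1 cycle per doubling (100 % amplification
efficiency; efficiency correction is out of scope). Replicate reactions are
averaged at the CT stage, per gene and state, before any fold-change
arithmetic. For each target/normalizer pair,
ΔΔCT = (CT_t,QUI − CT_n,QUI) − (CT_t,PRO − CT_n,PRO) and FC = 2^−ΔΔCT; the
per-gene FC is the arithmetic mean over the four normalizers (a geometric
mean is available behind a flag — log-scale averaging is the statistically
tidier convention, the arithmetic mean is the classical one; the choice is
recorded in the report). Gene-level array fold changes use the geometric
mean over that gene's probes. Adjudication compares |log2 FC_platform −
log2 FC_qPCR| per gene; differences below 1e-12 are ties. An optional
filter restricts to strongly changed genes (qPCR FC > t or < 1/t).

## Generator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| transcripts / chromosomes | 500 / 3 | desk-scale stand-in for a 149k-probe annotation |
| array probes | 600 (70-mers) | several probes per expressed gene, as on spotted arrays |
| decoy fraction | 0.10 | exercises unmapped-probe handling |
| ID-fallback fraction | 0.05 | probes whose sequence no longer matches the reference but whose annotation survives |
| changed genes | 50 at \|log2 FC\| ≥ log2 5 | the fivefold-change regime the design targets; magnitude = log2 5 + Exp(0.5) |
| baseline log2 abundance | N(6, 2²) | ~3 decades of expression |
| array noise σ (ln) | 0.3 | puts replicate FC correlations in the moderate (~0.6–0.8) regime |
| dye bias (cy3, cy5) | 1.0, 1.3 | visible MA trend for LOWESS to remove |
| crosstalk α | 0.05 | small but nonzero, so unmixing matters |
| library sizes | 2 × 1e6 per state | enough depth that Poisson error is secondary |
| NB dispersion | 0.05 | replicate count correlations high, FC correlations moderate — the regime where pooling replicates is justified |
| CT noise σ | 0.2 cycles | typical triplicate qPCR spread |

The generator emulates the statistical structure the analysis assumes —
multiplicative intensity noise, overdispersed counts, dye asymmetry,
unmappable probes — and deliberately not: image-level artefacts, spatial
print-tip effects, read alignment and its biases (counts are drawn per
feature probe directly), isoform mixtures, GC/length bias within a
transcript, or dendrimer labelling chemistry. Passing tests therefore
certify the pipeline's arithmetic and statistical calibration on data with
this structure, not the behaviour of either platform on real libraries.

## Problem sizes and numerical choices in the test suite

Tests run the generator at 60–240 probes; the noise-free end-to-end check
uses 120 transcripts and 1e6-read libraries with a per-probe error budget of
six Poisson sigmas plus 0.02 log2 (the generator's 0.005 balance tolerance
plus the pseudocount's sub-0.01 shift at that depth). The permutation-test
calibration grid covers universes {50, 100, 200} × k ∈ {5, 10, 20} at 10⁴
trials against the exact hypergeometric tail within three Monte-Carlo
standard errors. The noise sweep steps array noise σ over
{0.1, 0.5, 1.0, 2.0} with ten seeds each while holding every other noise
source at its minimum (Poisson-only counts, unit gains, α = 0), isolating
the swept factor; mean cross-platform log2-FC Pearson must exceed 0.9 at
σ = 0.1 and decrease monotonically. Determinism everywhere comes from named
substreams of a single master seed (numpy Generator seeded with
`[seed, stream, ...]`); full-run manifests carry SHA-256 checksums and
reruns reproduce identical bytes.

## Known limitations

* The compositional balance assumption above; real two-state designs can
  differ in total RNA output, which RPKM fold changes absorb as a global
  offset.
* Exact substring mapping cannot tolerate even one mismatch; probes
  designed against a different genome build than the annotation will fall
  through to the ID fallback or drop out.
* The Fisher-z comparison ignores the dependence between correlations
  sharing a vector.
* The permutation and hypergeometric nulls treat probes as exchangeable;
  correlated probes (overlapping transcripts) make the test anti-
  conservative for strongly nested universes.
* qPCR modelling assumes perfect efficiency and stable normalizers by
  construction.
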