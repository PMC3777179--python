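# Methods

## Bisulfite conversion model

Conversion is modeled on the top strand only: every CG dinucleotide becomes
YG and every other C becomes T; A, G, T are untouched, so length and the
positions of non-C bases are preserved. A terminal C converts to T (it cannot
open a CpG). Reverse PCR primers are matched by reverse-complementing the
*converted* forward strand — bottom-strand conversion chemistry is not
modeled, because the assays quantify the forward strand. Input outside
A/C/G/T (lowercase, IUPAC ambiguity codes) is rejected rather than guessed
at; references should be cleaned upstream.

## Assay geometry

Coordinates are 1-based and inclusive at both ends. Reverse primers keep
their printed 5′→3′ annotation (5′ coordinate first, possibly descending) and
are normalized internally. The amplicon runs from the leftmost to the
rightmost coordinate touched by either PCR primer, inclusive. Primers must be
CpG-free (standard bisulfite design practice; a Y in a primer is an error)
and at least 10 nt.

GC% is reported to one decimal, rounding half away from zero (matching
design-report conventions). Melting temperatures use the Breslauer
nearest-neighbor parameter set at 100 mM monovalent salt and 200 nM primer
(`assay.TM_CONDITIONS`). Published design reports compute Tm under
unstated, software-specific settings — the same primer sequence can appear
with two different printed Tm values depending on whether it is scored as a
PCR or a sequencing primer — so Tm here is advisory: under the chosen
conditions the four PCR primers of the packaged assays agree with their
design-report values to within about 1 °C, sequencing primers (scored by the
design software under laxer conditions) differ by several °C, and no
quantification result depends on Tm.

## Dispensation orders and the signal model

A dispensation order is a base string with optional per-position control
marks. Generated orders walk the template 5′→3′: one dispensation serves a
whole homopolymer run (peak height scales with run length — linear,
unsaturated luminescence; the saturation seen in very long runs is out of
scope since these templates' longest run is 3), and at each Y a C then a T
dispensation resolve both branches before the walk advances. C before T is a
convention chosen to match the quantification reading (C peak =
methylated); one consistent choice is required. When controls are requested
the order is prefixed by a blank dispensation — a base that cannot be
incorporated at the template start, preferring one absent from the first ten
read-out positions — and a conversion-control C, placed where no legitimate
C incorporation can occur. Templates starting with C or Y get no conversion
control (a warning is raised): a leading C dispensation would carry real
signal there.

The expected-signal engine tracks the molecule mixture as weight per state,
where a state is the template position plus, when the position is a CpG
whose branch an earlier dispensation has already revealed (molecules that
sat at a Y through a C or T dispensation without incorporating are known to
carry the other base), that revealed base. States are merged, so the live
set stays small, yet the result is exactly the weighted sum over all 2^k
explicit branch classes — the brute-force enumeration is kept as the test
oracle and as the engine of order validation, which reports per-class
template consumption, completeness, and identifiability.

Note a subtlety of real mixtures: a T dispensation serving a run that ends
just before a CpG also carries the site's unmethylated molecules through the
Y (e.g. the kit template's leading TT peak has height 2 + (1 − m₁)). The
generated order's dedicated T dispensation for such a site is then silent,
but the signal remains linear in m and the site identifiable; the "TT peak
is exactly double the single T" picture holds exactly on a fully methylated
template.

Identifiability is defined as full column rank of the matrix
[h(0) | h(e₁)−h(0) | … | h(e_k)−h(0)] (intercept plus per-site columns),
with singular values below 1e-9 of the largest treated as zero. For
in-phase (generated) orders the expected signal is exactly linear in m, so
this matrix is the exact model; for out-of-phase orders it is the
linearization at m = 0.

Vendor-printed orders are honored verbatim and only validated, never
regenerated — the commercial kit interleaves controls in an unpublished
pattern. For the packaged kit pair, validation shows every branch class
stops after 14 of the 17 read-out bases (the trailing TTT is never read);
the order is nevertheless fully identifiable.

## Quantification

Peak heights are arbitrary units, so the model is h ≈ s·f(m) with a free
scale s. Writing the linear design in the variables (s, s·m₁ … s·m_k) makes
the fit a single linear least-squares solve; estimates are m̂ᵢ = clip(uᵢ/s,
0, 1), reported in percent. Rank-deficient designs raise an error naming the
unresolvable sites. For out-of-phase orders the exact mixture signal is
multilinear rather than linear in m, so the linear solution seeds a bounded
nonlinear least-squares refinement (trust-region reflective, m ∈ [0,1]ᵏ,
s > 0) on the exact forward model; for in-phase orders the linear solve is
already exact and refinement is skipped. Where a site's C and T peaks are
isolated the fit reduces, for model-consistent data, to the classic ratio
m% = 100·h_C/(h_C + h_T).

Quality colors threshold the site's relative misfit — Σ|observed − fitted|
over the dispensations carrying the site's signal, divided by the fitted
signal there: ≤ 5% blue (good), ≤ 15% yellow (pass), else red (bad). The
conversion check passes when the control peak is at most 5% of the mean
reference peak (dispensations whose expected incorporation is exactly one
base regardless of methylation). The instrument's own quality and calling
algorithms are proprietary; these thresholds are this package's documented,
configurable choices, stated as pass/fail semantics only in the assay's
source material.

## Noise model and synthetic scenarios

Observed height = noiseless × (1 + N(0, cv)), truncated at zero. The source
measurements report no noise model; multiplicative Gaussian noise is the
simplest model consistent with peak-proportional error, and cv defaults to
0.05. Structurally empty dispensations stay exactly zero under this model —
additive background (camera noise, reagent glow) is not modeled, so
conversion-control pass rates in simulation are optimistic relative to real
instruments.

A scenario is a condition with per-site true means (percent), a
between-replicate sd (default 3 points, truncated-Gaussian draws in [0,1]),
a replicate count, and the pyrogram noise cv. Built-in scenarios carry the
study conditions: positive control 86/71/77 and negative control 2/2/2;
cell lines NHDF/HEK293/CKA-CA/HACAT with totals 56/53/51/49 at n = 5/3/3/5
(known only as totals, applied uniformly across the kit's three sites);
HACAT control 53/59/63 vs 5-aza + trichostatin A treatment 36/40/42 at
n = 6; and glioma parental vs temozolomide-resistant lines at 60 vs 45,
n = 4 — configurable placeholders encoding the reported direction
(resistant lines hypomethylated), since no numeric means were published.
Scenarios default to a generated in-phase order for the kit template, so
noiseless calls are exact and all dispersion comes from the declared sd and
cv. What passing scenario tests shows is therefore calibration and power of
the *pipeline* under its own noise model — not instrument-specific artifacts
(background signal, apyrase kinetics, PCR bias), which are out of scope.

## Statistics

Total methylation of a call is the arithmetic mean over its CpG sites.
Condition comparisons use the two-sided two-sample Student's (pooled
variance) t-test, on totals or independently per site; Welch's test is an
option. When both groups are degenerate (zero variance) with equal means, p
is reported as 1. No multiple-testing correction is applied by default
(matching the source analysis); Bonferroni across sites is available. The
null rejection rate of the full pipeline (two independent draws of the same
scenario) is verified at 5% ± 2% over 1000 trials.

## Problem sizes and numerics

Property tests run random templates up to length 40 with ≤ 4 CpG sites,
where 2^k enumeration is cheap; the exact-recovery grid uses steps of 0.05
over all three kit sites (9261 vectors) at a 1e-9 tolerance. Monte-Carlo
checks use 200 replicates for recovery, 100 seeds for QC rates, and 1000
trials for null calibration. All random draws flow through
`numpy.random.default_rng` seeds recorded in outputs; least squares uses
`numpy.linalg.lstsq` and `scipy.optimize.least_squares`.

## Known limitations

- Forward strand only; no bottom-strand or non-CpG (CHG/CHH) methylation.
- No additive background noise, homopolymer saturation, PCR amplification
  bias, or incomplete-conversion simulation (conversion failure can be
  expressed only through the control peak, not through template C
  contamination).
- Tm values are advisory estimates under one documented parameterization.
- Indels, sequence variants, and raw instrument files are out of scope.
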