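# Methods

## Model and assumptions

The test treats a candidate trial's baseline summary as one study in a
fixed-effect inverse-variance meta-analysis of mean differences, alongside
two simulated comparator trials (SCTs) that embody the null hypothesis of
ideal randomization. For arms with means x̄₁, x̄₂, SDs s₁, s₂ and sizes
n₁, n₂:

    MD      = x̄₁ − x̄₂
    Var(MD) = s₁²/n₁ + s₂²/n₂
    wᵢ      = 1 / Var(MDᵢ)
    MD̂      = Σ wᵢ MDᵢ / Σ wᵢ,   SE(MD̂) = (Σ wᵢ)^(−1/2)
    Q       = Σ wᵢ (MDᵢ − MD̂)²,  df = k − 1
    I²      = max(0, 100 · (Q − df) / Q)   (0 when Q = 0)

Assumptions inherited from this construction:

- the baseline variable's between-arm contrast is adequately summarized by
  a mean difference with normal-theory variance (large-sample form; no
  small-sample Hedges-type correction);
- a uniform integer distribution over the reported range is an acceptable
  stand-in for the trial population's baseline distribution when building
  the comparators — the test never compares *means* across real and
  simulated studies directly, only the heterogeneity of arm *differences*,
  which is what makes this tolerable;
- one consistent direction convention (test/A arm minus control/B arm) for
  every study in the pool; flipping one study's sign changes Q, so the
  convention is fixed package-wide.

The classification is deliberately binary on the I² point estimate: 0 →
negative, > 0 → positive. No confidence interval for I² is computed; the
method uses the point estimate only.

## SCT generation

An SCT of size N_T over the inclusive integer range [low, high] consists of
patient IDs 1..N_T, a block-randomized A/B allocation, and N_T uniform
integer values drawn with replacement and sorted ascending, paired with the
allocation column by row position. Per-arm summaries use the sample SD
(n − 1 denominator), the convention of trial baseline tables.

Block randomization fills complete blocks of size 4 (configurable, even)
with a uniformly permuted half-A/half-B pattern; when N_T is not a multiple
of the block size, the tail takes the first r elements of one further
permuted block, bounding the group-size imbalance by block_size/2. This
truncated-block rule reproduces the group splits observed in the bundled
reference dataset (14/12 at N_T = 26, 341/342 at N_T = 683).

A single seeded `numpy.random.Generator` drives each SCT, allocation drawn
before values, making every SCT a pure function of (N_T, range, block size,
seed).

## The null pair

Even under ideal randomization, a two-study Q exceeds its single degree of
freedom with non-trivial probability (Q is approximately χ²₁, so the
rounded pair I² is positive in roughly a third of draws). The generator
therefore regenerates SCT pairs with successive derived seeds until the
pair's rounded I² is 0, records the number of attempts for audit, and
fails loudly (reporting every attempted I² value) if a cap —
`max_null_attempts`, default 100 — is exhausted. The cap corresponds to a
failure probability of roughly 0.32¹⁰⁰ per test; in practice one to three
attempts suffice.

A degenerate range with low = high produces constant value columns: both
SCT mean differences are exactly 0 and the pair is accepted immediately,
bypassing pooling (zero-variance effects cannot be inverse-variance
weighted, but zero heterogeneity holds trivially).

## Rounding and classification basis

I² is computed at full precision throughout and rounded (nearest integer,
ties away from zero) only for display and, by default, for classification.
Classifying on the rounded value matches how standard meta-analysis
software displays I² and avoids flagging microscopic heterogeneity
(I² < 0.5%) that any practitioner would read as zero; `classification_basis
= "raw"` is available for the stricter reading. The bundled replay of the
16 reference studies reproduces every published integer I² with this
full-precision-then-round policy, so no intermediate rounding is
implemented.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `block_size` | 4 | allocation block; bounds arm-size imbalance by block_size/2 |
| `max_null_attempts` | 100 | budget for the zero-I² pair confirmation |
| `classification_basis` | `"rounded"` | integer-percent vs raw I² for the 0/1 call |
| `seed` | 0 | master seed; all SCT seeds derive from it (kept < 2³¹) |
| range [low, high] | per trial | inclusive integer span of the baseline variable |

Unit handling: means and SDs are carried in whatever unit the trial reports
(years or months for age); the method is unit-invariant because I² is
scale-free, so no conversion is attempted.

## Converters for practical use

When a report prints a median and range instead of mean/SD, the Hozo
approximation is provided: mean = (low + 2·median + high)/4 for all n, and
SD = √(((low − 2·median + high)²/4 + (high − low)²)/12) for n ≤ 15,
(high − low)/4 for 15 < n ≤ 70, (high − low)/6 for n > 70 (branch
boundaries closed on the left, following the approximation's published
form). A standard error converts to SD as sd = se·√n.

## Accuracy simulation

The simulation study estimates the test's operating characteristics under a
controllable selection-bias mechanism. What it emulates: two-arm trials
whose baseline values are uniform integers on a realistic range and whose
allocation starts block-randomized; bias is injected as **directional
misallocation** — a fraction `bias_fraction` of patients is chosen
uniformly, discordant (A, B) pairs among the chosen are formed in random
order, and each pair is swapped if needed so its older member sits in the
test arm. Swaps preserve both group sizes exactly, so only the value
balance is distorted — the signature of selection bias at baseline — and
`bias_fraction = 0` reduces to ideal randomization.

What it does **not** emulate about real trials: non-uniform and continuous
age distributions, unequal planned allocation ratios, baseline variables
other than one integer-valued measurement, and subtler bias mechanisms
(e.g. unblinding near block boundaries). Passing simulations therefore show
that the test detects value-linked misallocation of a given strength under
idealized marginals, not that it detects every real-world bias.

Sensitivity = positives among truly biased replicates, specificity =
negatives among truly unbiased ones; 95% intervals use the Wilson score
method (stable near proportions of 0 and 1, where this test operates).
Per-replicate seeds are drawn from a scenario-level stream, so extending
`n_replicates` preserves the existing replicates as a prefix.

Default simulation conditions (CLI): N_T = 100, range 18–80 (the modal
range of the reference dataset), bias fractions {0, 0.25, 0.5, 1.0}, 200
replicates per cell. The test suite uses 30–50 replicates per cell and
10⁴-replicate vectorized draws for the χ² calibration of Q; these sizes
give coarse Monte-Carlo tolerances (Kolmogorov–Smirnov statistic < 0.025,
3-standard-error bands on means) that the properties under test clear with
a wide margin.

## Numerical and degenerate-input choices

- Zero-variance studies (both arms SD = 0) are rejected with a dedicated
  error rather than given infinite weight.
- A group of fewer than two patients has no sample SD and is rejected.
- `ValueRange` permits low = high for programmatic degenerate cases; the
  CSV reader requires low < high for real trial records.
- Pooling requires at least two studies; I² requires df ≥ 1 and truncates
  to 0 at Q ≤ df.
- Replay mode recomputes (rather than forces) the supplied pair's I² and
  warns, without aborting, if its rounded value is positive.

## Known limitations

- The test is one-variable-at-a-time; testing several baseline variables
  and combining flags is left to the caller.
- A cohort study balanced on the tested variable (e.g. age-matched groups)
  will test negative despite non-random allocation — the bundled reference
  dataset contains two such studies.
- The binary I² > 0 rule has no explicit false-positive control; its
  observed false-positive rate under ideal randomization is estimated by
  the simulation module rather than set by design.
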