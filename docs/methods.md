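# Methods

## The design problem

An auditory statistical-learning experiment manipulates the *uncertainty*
of a tone stream while holding everything else fixed. The stream is a
first-order Markov chain over five pure tones: from every tone, exactly two
successor tones are possible, one taken with probability `p_high` and the
other with `1 − p_high`. The residual uncertainty of such a chain is the
conditional entropy of the next tone given the current one,

    H(X_{t+1} | X_t) = −(p log2 p + (1 − p) log2(1 − p)),   p = p_high,

which for the three target ratios 90:10, 80:20 and 2:1 gives 0.47, 0.72 and
0.92 bits. The 2:1 ratio is displayed as "67:33" (rounded percentages) but
stored as the exact fraction: only at exactly 2/3 does the entropy print as
0.92 bits and do 300 per-state transitions split integrally (200:100).

### Chain topology

Both successor maps (high and low) are self-loop-free bijections on the
state set that disagree at every state. Bijectivity is the load-bearing
choice: it makes the transition matrix doubly stochastic (uniform
stationary distribution, so the theoretical conditional entropy is the
same binary entropy at every state and every model order) and gives every
node of the transition multigraph equal in- and out-degree, which is what
guarantees an Eulerian circuit and hence exact-count generation for every
ratio. The concrete maps are seed-controlled random derangement pairs,
redrawn until the union graph is strongly connected; distinct seeds give
the counterbalanced chain variants.

## Exact-count sequence generation

A 1500-tone stream has 1499 transitions, which cannot split five states ×
300 transitions exactly. The generator therefore builds the closed
1500-edge multigraph (each state: `300 · p_high` high-edge copies, the rest
low), draws a seeded uniformly-random Eulerian circuit (independent shuffle
of each node's edge stack + Hierholzer's algorithm, random start node), and
emits the first 1500 node visits. Exactly one edge — the one closing the
circuit — goes unused, so every per-state empirical transition probability
deviates from its target by at most 1/300 and the empirical first-order
conditional entropy matches theory to within 0.005 bits. Each tone appears
exactly 300 times.

Phases are equal thirds (500 tones). Silent probe periods (0.6 s) are
drawn one per non-overlapping 50-tone block, uniformly within the block;
by default the tone stream is treated as statistically continuous across
silences (they are attention probes, not structural boundaries), with an
option to drop n-gram windows that span one.

## n-gram re-analysis

The same stream can be read through a predictive model of any order n:
slide a window of n context tones plus one outcome, count occurrences,
and summarise with the plug-in conditional entropy
`H = Σ_c P̂(c) Σ_o −P̂(o|c) log2 P̂(o|c)`. For a genuinely first-order
source this estimate is non-increasing in n (conditioning on more context
never increases a plug-in entropy on the same sample) and orders 1 and 2
agree closely at these sample sizes. No smoothing or bias correction is
applied — the plug-in estimator is the quantity of interest here, not a
population estimate.

### Condition labels

* **Order 1.** Every transition is "high" or "low" according to the branch
  of the *generating* chain (model TPs, not empirical counts); surprisal is
  the model value −log2 p of the branch taken.
* **Order n ≥ 2 (comparison pairs).** Two order-n contexts that differ only
  in their first (oldest) tone and lead to the same outcome form a pair;
  the member with the larger occurrence count is the "high" side. Because
  the pair shares its entire last n−1 context tones and the outcome, every
  statistic of order < n is identical across the two sides — the contrast
  isolates genuinely order-n pattern knowledge. Pair selection requires a
  configurable minimum count per side (default 5; sparse patterns at order
  4 in short phases are otherwise unstable), takes the top two qualifying
  contexts per (tail, outcome) group, and drops exact ties by default.
  The per-event surprisal at order n is the within-pair empirical value
  −log2(count_side / pair_total); for these chains it estimates the
  first-order branch probability of the *oldest* transition in the window,
  which is precisely the quantity the pair design isolates.

## Synthetic evoked responses

The forward model emulates two hemispheres' auditory source strength
(nAm) per tone: a Gaussian bump (σ = 20 ms) at ~100 ms whose amplitude is

    A = base_amp · hemi_gain · habituation(phase) · (1 + beta_amp · s) · (1 + jitter)

with `s` the event's surprisal at the simulated listener's true model
order, latency `100 + gamma_lat · s` ms, white noise everywhere (baseline
included), per-trial amplitude jitter, and a per-subject Gaussian random
effect on `base_amp`. Epochs span −100…+500 ms at 600 samples/s (360
samples). Events excluded at the true order are simulated at `s = 0`; they
never enter a selective average at that order and are distributed equally
over both classes at any other order, so they bias no contrast.

Defaults (chosen once, from a signal-to-noise budget, before any recovery
run): `base_amp` 20 nAm (a typical auditory N1m source strength),
`beta_amp` 0.10 per bit, `gamma_lat` 5 ms/bit, habituation multipliers
(1.0, 0.85, 0.75) over the three phases, hemisphere gains (1.0, 1.3)
(right larger), `noise_sd` 5 nAm, trial jitter 5%, subject sd 3 nAm. At
the 90:10 ratio these give a low-minus-high difference of ≈ 6 nAm against
a selective-average noise floor well below 1 nAm — effects point in the
directions such experiments report (habituation across phases, right >
left, low-TP > high-TP) with comfortable but not degenerate headroom.
Budget sketch: the rare class keeps ≥ 100 epochs per average, so the
averaged-peak noise is ≲ 5/√100 = 0.5 nAm per side.

What the generator does *not* emulate: 1/f or sensor-space noise,
multi-component waveforms (P1/N1m/P2), latency jitter of the component
itself, inter-subject latency differences, or any hemisphere × probability
crossover. Passing tests therefore demonstrate correctness of the
measurement pipeline and identifiability of the model order under the
stated forward model — not waveform realism.

Artifact epochs for rejection testing are injected as single-sample spikes
of ±500 nAm at a configurable rate.

## Measurement pipeline

Fixed order: rejection (absolute threshold, either hemisphere, any
sample; default 5 × the 99.9th percentile of the data, far above clean
signal and far below injected spikes) → zero-phase 4th-order Butterworth
2–40 Hz band-pass → baseline correction (−100…0 ms mean) → selective
averaging per hemisphere × phase × class → peak = maximum |source
strength| in 60–180 ms (earliest sample on ties) → difference amplitude =
low-class minus high-class peak.

A numerical caveat verified during development: the 2–40 Hz band-pass
itself attenuates the 20 ms Gaussian template by roughly 20%, because the
bump has substantial spectral mass below 2 Hz, and the zero-phase filter
spreads response energy backwards into the baseline window. This is a
physical property of high-pass filtering evoked responses, not a pipeline
defect; absolute pipeline outputs are validated against the
band-pass-filtered analytic template (2% agreement), while
condition-amplitude *ratios* are immune to the common attenuation. The
60–180 ms search window brackets the simulated latency shifts
(100 + 5·3.32 ≈ 117 ms at the rarest branch).

## Statistics

`rm_anova` is the classical fully-within-subject repeated-measures ANOVA:
cell means per subject, every main effect and interaction up to full
order, each tested against its own effect-by-subject interaction. Sums of
squares come from inclusion–exclusion over marginal means; the partition
identity (Σ effect SS + Σ error SS + subject SS = total SS) is asserted on
every call at 1e−8 relative tolerance. Degenerate inputs are flagged
rather than hidden: all-constant data reports NaN F ("no-variance"), zero
error variance with a non-zero effect reports infinite F
("zero-error-variance"), incomplete designs raise with instructions.
Uncorrected F values are the primary report; Greenhouse–Geisser epsilons
and corrected p-values are computed
alongside from the contrast-score covariance (epsilon is 1 for single-df
effects and unavailable when subjects ≤ effect df). Bonferroni post-hoc
tests are paired t-tests on subject-level cell means with p multiplied by
the number of comparisons, capped at 1; identical conditions report p = 1.

### Order recovery

`recover_order` estimates the simulated listener's model order as the
argmax over analysis orders of the cohort-mean difference amplitude (ties
resolve to the lower order). The identifiability argument: at analysis
order m the comparison pairs share all statistics of order < m, so a
listener of true order n < m produces a null contrast (the driving lag-n
branch is part of the shared tail of every order-m pair). Conversely, for
n > m the lag-n branch indicator is independent of the lag-m classification
in a first-order chain, so the contrast is null there too. Only at m = n
does the contrast capture the full surprisal difference, so the difference
amplitude peaks at the true order and recovery reduces to an argmax.

The recovery harness simulates 20 cohorts per true order (6 subjects ×
3 sequences each, full pipeline per subject) — sizes chosen to keep a
complete three-order experiment to a few minutes on one core while leaving
the per-cohort estimate comfortably above its noise floor. The type-I
calibration suite runs 300 null simulations of a 2×3 within design with 12
subjects.

## Known limitations

* The plug-in entropy at orders 3–4 on 500-tone phases is biased low
  (sparse contexts); reported values are the plug-in statistic, by design.
* Comparison pairs are restricted to the top two contexts per (tail,
  outcome) group, so a state with three or more qualifying predecessors
  contributes one pair only.
* The forward model's effect sizes are order-of-magnitude choices, not
  fits to any recording; no claim about real effect magnitudes follows
  from the simulations.
* Sensor-space processing (gradiometer artifacts in pT/cm, signal-space
  separation, dipole fitting) is out of scope; the pipeline operates on
  source-strength waveforms directly.
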