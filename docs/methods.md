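# Methods

## Trafficking model

Each cell is an independent continuous-time Markov chain over three
compartments: **blood** (one global pool), **perivascular** and
**tissue-localized** (both belonging to a named tissue). Four per-hour
rates govern exchange:

| rate | transition | meaning |
| --- | --- | --- |
| `exit_rate_blood` | blood → tissue-localized | egress into the tissue parenchyma |
| `return_rate_tissue` | tissue-localized → blood | egress back to circulation |
| `peri_entry_rate` | blood → perivascular | entry into the perivascular niche |
| `peri_exit_rate` | perivascular → blood | return from the niche |

All waiting times are exactly exponential (event-driven simulation, no
time discretization), so there is no discretization bias when comparing to
closed forms. Transitions form a star around blood: there is no direct
perivascular ↔ tissue-localized exchange. Three compartments were chosen
because sinusoidal organs (spleen, liver, lung) contain an
antibody-exposed perivascular pool that is distinct from both flowing
blood and the deep tissue pool; in a non-sinusoidal tissue such as lymph
node the perivascular rates are simply left at zero.

Time is measured in non-negative **hours before harvest**; harvest is 0
and the 5-minute IVas infusion is 0.0833 h. Trajectories start at the
earliest pulse time plus an optional burn-in margin and are initialized at
the **analytic stationary distribution** of the chain
(π_B : π_P : π_T = 1 : peri_entry/peri_exit : exit/return for the
irreducible case), which is exact and removes any need for a simulated
warm-up; `burn_in_hours` therefore defaults to 0. For reducible chains
(some compartment absorbing) the limiting occupancy from the initial
compartment is used and flagged as degenerate.

A **retention marker** (CD69 analog) is acquired at a memoryless rate
while tissue-localized (default 1.0/h), lost at a memoryless rate in blood
(default 0.5/h), and frozen in the perivascular compartment. These
defaults make marker positivity accumulate over hours of tissue residence,
reproducing the qualitative association between the marker and tissue
localization that the analysis is meant to detect. An optional
`marker_initial_prob` starts cells marker-positive independently of
history; with acquisition and loss set to zero this yields a
history-independent marker, the null condition for stratified analyses.

## Labeling model

Each infusion is a **zero-duration pulse**: the infused antibody's in-vivo
half-life (minutes) is two orders of magnitude below the smallest
inter-pulse gap (2 h), so a cell is labeled iff its compartment at the
pulse instant is exposed. The default exposure policy is blood only; for
sinusoidal tissues the perivascular compartment is added, since infused
antibody reaches the perivascular space there. Labels are permanent —
no downstream operation may clear a call. Dose is metadata only; labeling
efficiency per pulse is assumed 1.0 and exposed as a config knob, since no
per-pulse efficiency estimate is available to calibrate against.

Fluorescence is a per-channel mixture of lognormal populations
(background: median 100, log-sd 0.6; labeled: median 5000, log-sd 0.5 —
roughly a 1.7-decade separation, comfortable for one-dimensional gating).
Gates are drawn at the 0.999 empirical quantile of a pre-infusion negative
control (inclusive linear-interpolation quantile, bit-stable), calling
positive strictly above threshold. The 0.999 default trades a 0.1%
false-positive floor against robustness to rare control outliers; under
the default populations total misclassification is ~0.05–0.1%.

## Positional-history classification

For tissue-harvested cells with a readable IVas pulse: **IVas+** if
positive at the final (≤ 0.25 h) pulse; otherwise **recent immigrant** if
positive at ≥ 1 interpretable earlier pulse; otherwise **tissue
localized**. The three classes partition the classifiable cells exactly.
When the IVas pulse is masked, or an IVas− cell has no interpretable
earlier pulse (including single-pulse schedules), the cell is
**indeterminate** — tissue localization is never assumed by default.

The **continuously circulating** fraction of blood-harvested cells counts
cells positive at every interpretable pulse within the lookback window
(window boundary inclusive). Masked pulses trigger complete-case handling:
a cell with any masked pulse inside a window is excluded from numerator
and denominator of that window's summary, mirroring how an extravasated
infusion is handled in practice; no imputation is defensible from pulse
data. CC is defined only for blood draws and IVas/RI/TL only for tissue
harvests, enforced by the pipeline's grouping on harvest site.

Transition flows are 2×2 call contingencies between consecutive
interpretable pulses; a pulse masked for every cell is bridged so its
neighbours become consecutive. The Sankey export is a nodes/links
structure (node = pulse × state; link = count and exact count-ratio
fraction) consumable by standard renderers; no plotting is done here.

## Estimators

**Entry rate** = 100 × (IVas− cells positive at the window pulse / IVas−
cells) / window hours, window defaulting to 6 h and requiring a pulse at
exactly the window boundary (positions are pulse samples; nothing is
interpolated). The denominator is IVas− cells, not all tissue cells, so
the rate is per extravascular cell; it is never converted to absolute
flux, since absolute tissue cellularity is unknown. A cell positive both
at −6 h and earlier still counts in the numerator — the definition is
literal and this caveat is intentional: such cells entered within the
window regardless of older labels. At stationarity the hourly influx into
the tissue pool, as a fraction of the pool, equals `return_rate_tissue`
(flux balance π_B·exit = π_T·return), which is what the recovery analysis
checks the estimator against.

**Blood residence** inverts a CC fraction under memoryless exit:
rate = −ln(CC)/lookback, mean residence = 1/rate (infinite at CC = 1,
flagged). Because being labeled at every pulse only requires presence in
blood *at the pulse instants*, CC ≥ exp(−true rate × lookback) and the
estimate is a **lower bound on the exit rate** / upper bound on residence;
the tests verify this inequality across exit rates 0.02–0.5/h. The
single-window inversion is the default because the scientific conclusions
it supports are threshold-shaped ("residence greater than the window");
`fit_exit_rate_multiwindow` provides a log-linear fit over several
lookbacks for simulator validation.

**Marker-stratified TL** applies the classifier separately within marker+
and marker− cells; an empty stratum is reported as undefined, never zero.

## Statistics

`wilcoxon_exact` computes the two-sided rank-sum p-value with midranks for
ties. When both groups have ≤ 8 observations the null distribution of the
rank sum is enumerated exactly via a subset-sum dynamic program over
doubled midranks (doubling makes every sum an integer, so tail comparisons
are exact); this is equivalent to enumerating all C(n+m, n) assignments,
and an independent brute-force enumeration oracle checks it in the tests.
Two-sidedness follows the tail-doubling convention,
p = min(1, 2·min(P(W ≤ w), P(W ≥ w))), chosen to match common
implementations; the alternative sum-of-both-extremes convention can
differ for asymmetric tied distributions. Larger groups use the
tie-corrected normal approximation with continuity correction. Pairwise
subset p-values are reported unadjusted by default (three pairs), with a
Holm step-down adjustment behind a flag. Technical replicates are averaged
per animal before testing; with a single replicate the SEM is reported as
missing, not zero. Whether such cross-subset comparisons should be paired
within animals is ambiguous in practice; the unpaired test is implemented.

## Randomness and performance

Cohorts of 10^5–10^6 cells must simulate in seconds on one CPU, so the
cohort engine advances all cells of a block **in parallel**: each loop
iteration draws one exponential waiting time per still-active cell,
retires cells whose next event would pass harvest, and records events in
flat arrays from which per-pulse states are recovered by vectorized
counting. The marker process is layered on the resulting segments, one
round per segment index (at most one marker flip is possible per segment).
Randomness comes from one PCG64 generator per (animal, subset, tissue)
block, spawned deterministically from the cohort seed; identical seeds
give byte-identical cohorts. A consequence of drawing event-synchronous
batches is that changing a block's cell count reshuffles that block's
stream; the per-cell reference implementation `simulate_trajectory` (plain
Gillespie) is kept alongside and the two engines are cross-checked
statistically in the tests. Pipeline stages (labeling, intensities,
control draws) use fixed, separate substreams of the study seed.

Problem sizes used by the validation suite and `scripts/acceptance.py`:
50,000 cells per schedule × rate configuration for the oracle comparison
(27 configurations), 10,000 cells per subset per replicate for exit-rate
recovery (20 replicates), 20,000 cells for entry-rate recovery, 6,000 per
replicate for marker stratification, 2,200 datasets for the exact-test
checks. These sizes put Monte-Carlo standard errors well below the effect
sizes being verified while keeping the full validation run around a
minute.

## What the generator does and does not emulate

It emulates: memoryless exchange between blood, perivascular and tissue
pools with subset-specific rates; instantaneous vascular pulse labeling
with permanent retention; lognormal negative/positive fluorescence with
negative-control gating; a tissue-acquired retention marker; per-animal
uninterpretable infusions. It does **not** emulate: proliferation or
depletion pharmacokinetics, subset interconversion or differentiation,
within-tissue spatial structure (distance to vessels), non-exponential
residence times, between-animal rate heterogeneity (animals are i.i.d.
replicates of the same kinetics), antibody saturation or dose effects, or
spectral spillover between channels. Passing tests therefore demonstrate
correctness of the analysis pipeline and estimator behavior under the
stated model — not that real cells obey memoryless kinetics; in real data
residence times may be heavy-tailed, making the residence bound even more
conservative.

## Numerical choices and degenerate inputs

Stationary occupancies use the closed form for irreducible chains and an
explicit reachability/absorption analysis otherwise (degenerate flag set).
Pulse-time comparisons use a 1e-9 h tolerance; window boundaries are
inclusive. Zero-variance intensity populations degenerate to point masses
at the median. `cc = 1` maps to zero exit rate and infinite residence;
`cc ≤ 0` is rejected. Empty eligible sets (all cells masked, no IVas−
cells, empty marker stratum) raise or report undefined rather than
returning zero. Quantile gating uses numpy's inclusive linear
interpolation so thresholds are reproducible bit-for-bit.

## Known limitations

- Lymph-node IVas+ cells are treated per the label policy only; whether
  they represent blood contamination or a cortical perivascular pool is a
  biological question the simulator deliberately does not decide (the
  per-tissue sinusoidal flag chooses the exposure model).
- The entry-rate denominator (IVas− cells) differs subtly from "% of all
  tissue cells per hour"; with small IVas+ fractions the two are close,
  but the literal per-IVas− definition is what is implemented.
- All animals in one cohort must share pulse times and channels; studies
  with structurally different schedules are run as separate cohorts.
- The exact Wilcoxon branch is limited to group sizes ≤ 8; beyond that the
  tie-corrected normal approximation is used.
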