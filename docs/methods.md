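# Methods

This note documents the models and algorithms implemented in `spikeseq`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not demonstrate.

## Edit similarity between binned windows

A recording is segmented into windows of length `T_w` seconds, each split
into `L` bins of width `b` (`L = T_w / b`; window starts advance by a
stride, by default `T_w`, i.e. non-overlapping; bins are half-open
`[start, end)`).  A window is the `N × L` matrix of per-neuron spike counts;
column `r_i` is the population pattern of bin `i`.

Two windows are aligned by dynamic programming over an `(L+1) × (L+1)`
table with zero borders.  At cell `(i, j)` the score is

```
ε[i,j] = max( 0,
              ε[i-1, j-1] + r_i · r_j',
              ε[i-u, j] − exp(α·u),
              ε[i, j-r] − exp(α·r) )
```

where `u` and `r` are the lengths of the vertical/horizontal gap runs ending
at the cell.  The runs are tracked greedily: before the score cell is
evaluated, the tracker compares starting a fresh single gap from the
adjacent cell against extending the previous run by one, both costed at the
current cell, and keeps the better; the kept run then provably dominates all
abandoned runs at every later cell (the exponential cost gap between two
runs only widens), so the greedy candidate equals the maximum over all run
lengths.  Counters reset when the zero floor is taken: a restart begins a
fresh local alignment.  Tie-breaking prefers diagonal over vertical over
horizontal moves, giving a deterministic traceback.

**Readout.**  The similarity is the maximum cell of the table — the score
of the best local chain of bin matches, with leading and trailing offsets
free.  This readout is what makes the two stated invariants hold:
`E(W, W) = Σ‖r_i‖²` and invariance under a pure temporal shift of the
pattern inside the window.  (Reading the top-right cell instead penalises
trailing offsets whenever the two windows' active parts end at different
bins.)

**Equivalence with exhaustive search.**  For small problems the DP equals a
brute-force maximum over all monotone partial alignments charging
`exp(α·g)` per maximal run of `g` skipped bins (`tests/oracles.py`).  The
equivalence requires that a single run is never more expensive than any
split of it, which holds whenever `exp(α(g1+g2)) ≤ exp(αg1) + exp(αg2)`
over the reachable run lengths — true throughout the α ≤ 0.25, L ≤ 6 domain
the property tests use.  For large `α·g` the recursion can beat single-run
charging by splitting a long gap across intermediate cells; the recursion,
not the single-run accounting, is the method.

**Choosing α.**  α is the timing-lag tolerance: a lag of `g` bins between
consecutive matches costs `exp(α·g)`, so α ≈ 0.1 with 10-ms bins tolerates
lags of tens of milliseconds (hippocampal jitter), α ≈ 1 demands near-exact
alignment (used for the synchronous-assembly benchmarks), α → ∞ recovers
contiguous matching.

## MinHash candidate pruning

Scoring all `M(M−1)/2` window pairs is infeasible for long recordings, and
pairs sharing few active neurons cannot score highly.  Each window is
reduced to its Boolean activity mask (neuron fired at least once); mask
overlap is Jaccard similarity; and a banded MinHash signature — `n = b·l`
seeded hash functions, minimum hash over active neurons per function —
retains a pair iff the two signature columns agree on all `l` rows of at
least one of `b` bands, which occurs with probability
`p(s) = 1 − (1 − s^l)^b`.  The hash family is a keyed bijective 64-bit
mixing function (splitmix64 finalizer), so distinct neurons never collide
within a hash function, and band slices are grouped by their exact value
tuple (no second-level hash collisions).

The band geometry is fitted to the data assuming independent Poisson
neurons at the observed mean rates: with `p_i = 1 − (1 − (#_i/T)·b)^L` the
per-window activation probability, `N1 = Σ p_i`, `N2 = Σ p_i²`, the
expected mask Jaccard of unrelated windows is `J1 = N2/(2N1 − N2)`, and of
windows sharing `N3` extra coincident neurons
`J2 = (N2 + N3)/(2N1 − N2 − N3)`.  A brute-force search over
`b, l ∈ [1, 50]` returns the cheapest `(b, l)` with `p(J1) ≤ 0.1` and
`p(J2) ≥ 0.8` (fewest hash functions, then fewer rows).  `N3` should be of
the order of the assembly size, discounted by the members' chance
activation (e.g. 20-member assemblies at ~33% chance activation → N3 ≈ 10).
When no geometry separates `J1` from `J2` — dense background activity, long
windows — the pipeline falls back to scoring all pairs and says so.

## Two-stage clustering

Distances `D(k,k') = max(E) − E(k,k')` (maximum over computed pairs;
uncomputed pairs at maximal distance) feed OPTICS
(scikit-learn, precomputed metric, ξ-extraction with ξ = 0.05, `MinPts`
exposed).  OPTICS is used as a noise filter: windows in no dense group are
discarded.  Two guard rails around the ξ-extraction: a "cluster" spanning
more than 90% of the sample with reachability spread below ξ·median is the
root interval of a flat profile and is discarded; and because the
extraction can truncate genuinely dense groups at particular `MinPts`
values, benchmark protocols search `MinPts` (and `v`) over a grid and keep
the best score, as in the published protocol.

The survivors form a weighted graph — by default an edge per computed pair
with positive similarity, since the MinHash stage has already sparsified to
plausible pairs; threshold and mutual top-K rules are available — on which
COPRA assigns overlapping communities: each node holds up to `v`
(label, coefficient) pairs, one asynchronous sweep updates nodes in seeded
shuffled order by averaging neighbour labels with edge weights, labels
below `1/v` are pruned (seeded-random argmax kept if all fall below), and
iteration stops when the per-label node-count histogram repeats.
Communities below two members are dropped; windows may carry several
labels, and windows in none are noise.

## Profiles

Member windows are z-scored per neuron — `(c − mean)/variance` with moments
over every bin of the recording — damping high-rate neurons.  (Dividing by
the variance rather than the standard deviation follows the method's
definition; it rescales neurons monotonically and leaves peak orders
unchanged.)  The profile of a cluster is built by simplified
Barton–Sternberg iteration: initialise from two seed-chosen members'
alignment; per update, align one more member (seeded random cycles by
default; the classic pick-the-most-similar strategy is available as
`original_order=True`) to the current tentative profile via the
edit-similarity traceback, fold its aligned bins into a running average
(unaligned profile bins decay toward zero at the same `1/t` rate), and view
the average through a Gaussian filter whose width shrinks geometrically
from `L` bins to one bin over the update budget (10× the member count by
default; the similarity between successive profiles is recorded as the
convergence trace and iteration stops early when its relative change falls
below 10⁻³ after every member has been visited once).  The filter is
applied to the running average, not cumulatively to the already-filtered
profile — cumulative filtering diffuses without bound; with the running
average a cluster of identical windows returns exactly that window under a
one-bin filter, independent of the seed.

## Synthetic benchmarks

The generator superimposes assemblies on independent homogeneous Poisson
background trains (assembly members keep their background spikes).  A
synchronous occurrence places one spike per member at the occurrence time;
a sequential one spaces members evenly across `span/time_scale` seconds in
order (or reverse); every spike gets uniform jitter on ±jitter.  Occurrence
starts are uniform subject to not crossing window boundaries (window index
drawn without replacement per assembly).  Ground truth records every
occurrence; a window's true label is the assembly of the earliest
occurrence overlapping it, windows overlapping none form the noise class.

Named regimes (population, rate, duration, assembly layout) reproduce the
published benchmark configurations; the values not stated anywhere —
the planted-sequence validation regime's population (60 neurons, 60 s) and
the embedded-sequence benchmark's window lengths (200 ms for 100-ms
sequences, 500 ms for 500-ms ones), jitter (none) and α (1.0) — are this
package's choices, fixed once.  Detection quality is scored by purity /
inverse purity / their harmonic mean, with unassigned windows forming one
detected noise cluster so both partitions cover all windows; benchmark
protocols report the best score over a clustering-parameter grid
(`MinPts, v ∈ {2, 3, 5, 8, 12, 16, 20}`, a subgrid of the published 2–20
range) per dataset, and the acceptance script averages 8–10 datasets per
regime.

What passing these benchmarks shows: the pipeline separates planted
synchronous and sequential assemblies from stationary Poisson background at
realistic rates and jitters, at the published performance level.  What it
does not show: robustness to non-stationary rates, theta/ripple-locked
firing, bursting, overlapping assemblies sharing members, or spike-sorting
artefacts — none of which the generator emulates.

## Significance model

The Poisson shuffle redraws each neuron's spike times i.i.d. uniformly,
preserving per-neuron counts exactly.  Mean profile-match scores per
position bin `x` for raw (`R_x`) and shuffled (`S_x`) data are modelled as

```
R_x ~ Normal(μ_x, σ_raw)         S_x ~ Normal(μ_x + δ_x, σ_sge)
μ_x ~ Normal(2μ_{x−1} − μ_{x−2}, σ_μ)      δ_x ~ Cauchy(δ_{x−1}, σ_δ)
```

— a locally-linear smooth baseline with heavy-tailed jumps in the
raw-vs-surrogate offset.  The Cauchy is parameterised by location and scale
(it has no mean or variance); the four scales get uniform priors on
(0, 10× the data scale); empty position bins are treated as unobserved.
The reported effect is `−δ_x` (positive = raw exceeds surrogate), flagged
significant when its 95% credible interval is entirely positive.  The
posterior is sampled with the emcee ensemble sampler (default stretch move;
2·ndim+2 walkers, 2500 steps, first 1000 discarded, thinned by 4).
Differential-evolution moves were evaluated and rejected: on this target
they underdisperse badly.  Validation is by parameter recovery on data
drawn from the model itself: a single injected jump is flagged and its CI
covers the truth in ≥90% of repetitions, with ~2% false flags under the
null.

## Degenerate inputs and numerical conventions

Zero-variance neurons are excluded from z-scoring (zeroed, with a warning);
windows with empty activity masks receive a sentinel signature and never
pair; two all-zero masks have Jaccard similarity 0 by convention; supervised
scores with zero denominators are 0 with a warning; an empty similarity
store, an empty retained set, and fewer windows than `MinPts` raise or warn
explicitly.  A single master seed fans out to per-stage seeds through
`numpy.random.SeedSequence`; identical inputs and seeds reproduce every
stage bit-for-bit.

## Known limitations

The greedy gap tracker implements the method's stated recursion; it equals
exhaustive search in the regimes quantified above but is not a general
affine-gap aligner.  OPTICS ξ-extraction is the least stable stage
(see guard rails above).  The MinHash stage assumes sparse activity masks;
at high rates or long windows it degrades to all-pairs scoring.  Window
length must be chosen near the sequence time-scale; sequences longer than
the window are only partially matched.  The CLI's position-significance
subcommand assigns windows to position bins by nearest sample of the
position series, which assumes the series samples the whole recording.
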