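# Methods

## Data model

A *recording* is one epoch (default 900 s) of per-electrode spike
timestamps on a known layout, tagged with day in vitro (DIV), condition
and culture id. The default layout is the standard commercial 60-electrode
geometry: an 8×8 grid with the four corners absent, 200 µm pitch, 30 µm
electrodes. The layout is fully configurable because vendors and labs
differ in which grid positions record (and whether one is a reference
electrode). Times are seconds from epoch start, stored and serialized at
1 µs resolution; intervals are half-open `[t0, t1)`.

Raw-trace spike detection uses a fixed negative threshold (default
−20 µV, ≈ 6–8 SD of baseline noise at typical recording quality) with
1 ms pre / 2 ms post cutouts at 25 kHz. The spike time is the
threshold-crossing sample. A dead time equal to the post window (the
acquisition convention is not standardized; this choice guarantees
non-overlapping cutouts) suppresses re-triggering, and crossings too close
to a trace boundary for a full cutout are discarded.

## Burst detection

The max-interval family, three phases applied in this order:

1. **Scan.** Walking the train in time order, a candidate opens at spike
   *i* when ISI(i, i+1) ≤ `max_isi_start` and extends while each next ISI
   ≤ `max_isi_end`, closing at the first larger gap.
2. **Merge.** Consecutive candidates with onset-minus-previous-offset
   < `min_ibi_merge` are fused. Merging precedes filtering so two small
   candidates can fuse into a valid burst.
3. **Filter.** Candidates with duration < `min_burst_duration` or fewer
   than `min_spikes_in_burst` spikes are dropped.

Defaults 0.17 / 0.30 / 0.20 s / 0.01 s / 3 spikes are the conventional
max-interval settings of commercial spike-train packages; all are mandatory
config fields recorded in output provenance. The implementation reduces
phase 1 to maximal runs of ISIs ≤ `max_isi_end` (each run holds at most
one candidate, opening at its first start-qualifying ISI), which is
vectorizable; the test suite verifies it spike-for-spike against a literal
per-spike state machine on thousands of random trains.

The inter-burst interval (IBI) is onset-to-onset by default (an
offset-to-next-onset mode is available). Note that on tonic Poisson firing
above roughly 1 Hz, chance spike clumping alone produces a nontrivial
max-interval burst rate (~1/min at 0.75 Hz with the defaults); this is a
property of the method, not a bug, and it shapes sensible simulator
settings (below).

## Network parameters

Per recording: total spikes; % spikes in bursts; burst rate and burst
duration averaged over electrodes bursting **more than** 1/min; network
size counting electrodes bursting **at least** 1/min (the threshold
asymmetry is deliberate and preserved); burst pattern = CV across
electrodes of the per-electrode mean IBI (sample SD, ddof = 1; an
alternative within-electrode-CV mode exists because the definition admits
both readings); correlation index.

The correlation index of two event trains is
`CI = N_ab · T / (N_a · N_b · 2Δt)` with `N_ab` the count of cross pairs
within ±Δt (default 0.1 ms), i.e. the coincidence rate normalized by the
chance rate of independent stationary trains, so independent Poisson
trains give ≈ 1. The network value is the mean over unordered electrode
pairs where both have events. Events default to *all spikes*: at a 0.1 ms
window, burst onsets are too sparse for statistical power, but both
burst-spike and burst-onset event sources are selectable. Undefined
parameters (e.g. burst rate in a culture with no qualifying electrode)
are reported as missing, never zero.

## Simulator

Per electrode: homogeneous Poisson tonic firing; network burst events
drawn as a Poisson process (rate `net_burst_rate`/min) shared by the
whole culture; an electrode is a network *member* with probability
`member_prob` (drawn once per recording), and members join each event
with probability `participation_prob`, shifting onset by Gaussian jitter
(`onset_jitter_sd`) and emitting max(3, Poisson(`spikes_per_burst_mean`))
spikes with exponential ISIs (`intra_burst_isi_mean`); electrode-autonomous
bursts likewise at `indep_burst_rate`/min. A per-electrode gamma gain
(mean 1, CV `rate_heterogeneity_cv`) scales the tonic and autonomous burst
rates, producing electrode-to-electrode spread in firing and burst
schedules. Spikes are restricted to [0, T], merged, sorted, de-duplicated
at 1 µs. All randomness flows from one integer seed; experiment-level
sub-seeds are spawned deterministically per (condition, culture, DIV).

The membership layer exists because the measured *network size* must be
able to grow with maturation and to arrest under a phenotype: raising the
event rate alone saturates network size at the full grid.

**Maturation trajectory** (linear between DIV 5 and DIV 12 endpoints):
tonic 0.2 → 0.6 Hz, network events 0.5 → 3.0/min, participation
0.6 → 0.9, membership 0.35 → 0.95, jitter 50 → 20 ms, spikes/burst
6 → 12, intra-burst ISI 30 → 20 ms, autonomous bursts 0.3 → 0.5/min,
heterogeneity CV 0.3. These reproduce the qualitative maturation
signature — total spikes and network size climbing steeply over the week —
with DIV-12 electrode burst rates around 3/min. The DIV-12 tonic rate is
deliberately kept at 0.6 Hz: much higher out-of-burst rates make chance
clumping dominate the burst statistics (see above), which contradicts the
ordering the knockdown phenotypes must exhibit against controls.

**Presets.** Control and NTC are identical (transfection itself has no
modeled effect). `dctn5_kd` (onset DIV 7): network event rate overridden
to 5.8/min with full member participation, autonomous bursts off, and
membership frozen at its DIV-6 value (network-growth arrest). `dlg2_kd`
(DIV 6–11, recovered at 12): event rates ×1.9, intra-burst ISI ×1.5.
`tnik_kd` (from DIV 8): intra-burst ISI ×0.4, tonic ×0.35, jitter ×0.3,
heterogeneity ×0.5, participation → 1 (shorter, tighter, more synchronous
bursts; larger in-burst spike fraction). `disc1_kd` (DIV 12 only):
intra-burst ISI ×1.5. Only the Dctn5 5.8/min figure is quantitatively
anchored; the remaining effect sizes are fixture constants chosen to be
comfortably detectable at n = 8 cultures, and the presets are qualitative
by design.

**What the simulator does not emulate:** electrode noise and spike-sorting
artifacts, spatial structure on the grid (all electrodes are
exchangeable), non-stationarity within an epoch, culture-level random
effects beyond sampling noise, and day-to-day correlation of the same
culture (days are drawn independently, matching per-day cross-sectional
testing). Passing tests therefore demonstrate correctness of the
analysis pipeline and internal consistency of the generative model — not
biological validity on real recordings.

## Statistics

One-way fixed-effects ANOVA per (parameter, DIV) cell via the classical
sum-of-squares decomposition (exposing MSE and df); Fisher's LSD pairwise
tests `t = (m_i − m_j)/√(MSE(1/n_i + 1/n_j))` on the within-group df,
two-sided. The *protected* variant (default) interprets pairwise calls
only when the omnibus ANOVA rejects at α; an unprotected override exists
because the gating convention varies between labs. α = 0.05, no
multiple-testing correction across barcode cells (each cell is reported
per-cell, as is conventional for this assay). The experimental unit is
the culture; missing culture values are dropped with a logged count, and
cells with zero within-group variance (F undefined) are reported as
no-test. The barcode rule and its consequences: because an *increase*
call also requires the two controls NOT to differ, the null
false-positive rate per cell is well below α (≈ 1% empirically), and the
maximum attainable power is ≈ 95% (the controls falsely differ in ≈ 5% of
experiments).

## Problem sizes and numerical choices

Validation runs use: the full 60-electrode grid at T = 900 s for
parameter-recovery checks (burst rate/duration averaged over 12 replicate
recordings, since a single epoch holds only ~45 network events and has
~15% Poisson spread in its realized event count); 12-electrode (4×4 minus
corners), T = 300 s cross-sections for the 200-run size and 20-run power
experiments, where the tested properties are scale-free. The measured
Dctn5 burst rate is taken at DIV 7, the preset's onset day, where control
tonic rates are low enough that chance-clumping bursts stay below the
1/min qualifying threshold; burst merging makes the pipeline recover
~5.5–5.9/min from the generating 5.8/min. Ties and degenerate inputs:
empty trains yield no bursts; identical timestamps are impossible after
1 µs de-duplication; CI pairs with an empty side are excluded from the
network mean; sample SD uses ddof = 1 throughout.
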