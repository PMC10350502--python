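# Methods

## The laser neuron

`microspike` simulates a semiconductor micropillar laser with an
integrated saturable absorber, a well-studied photonic analogue of a
spiking neuron.  The dynamics are the three-variable Yamada-type rate
equations for the intracavity intensity *I*, the gain *G* and the
saturable absorption *Q*:

    dI/dt = I (G − Q − 1) + β (G + η)²
    dG/dt = γ_G (μ₁(t) − G (1 + I))
    dQ/dt = γ_Q (μ₂ − Q (1 + s I))

Time is dimensionless, in units of the cavity photon lifetime
(physically ~1–2 ps; the conversion is documented but never used in
computation).  The defaults — `gamma_G = gamma_Q = 0.005`, `mu2 = 2`,
`s = 10`, `beta = 1e-4`, `eta = 1.4` — are typical semiconductor
values and form the named preset `"paper2023"`.  The carrier rates
γ ≪ 1 make the system slow–fast: carriers recover on a timescale of
~200 time units while intensity pulses develop in a few units.

Below the laser threshold `mu1_th = 1 + mu2` the device has a quiet
equilibrium and is *excitable*: a pump perturbation that drives the net
gain `R = G − Q − 1` above zero triggers one calibrated intensity pulse
(a spike), followed by an absolute and a relative refractory period
while the gain recovers.  Above a lower pump value (≈ 2.68 at the
defaults, located by bisection) the quiet state destabilises and the
laser self-pulses periodically with no input.

The spontaneous-emission source is implemented exactly as the squared
form β(G+η)²; some Yamada variants use the linear form β(G+η), which is
selectable through `LaserParams(emission_exponent=1)`.  The choice
shifts the quiet-state intensity and hence all excitability boundaries
by several percent (see *Calibration* below).

## Numerics

The pump μ₁(t) is piecewise constant (boxcar pulses), so the adaptive
RK45 integrator (`scipy.integrate.solve_ivp`, rtol 1e-8, atol 1e-12) is
restarted at every pump discontinuity and the solution is sampled on a
0.5-unit grid — dense enough that no pulse (width of tens of units) can
be missed.  A deliberately independent fixed-step classical RK4
integrator (dt = 0.01, also segment-restarted) serves as a
cross-validation oracle in the tests; the two agree to better than
1e-5 relative at spike peaks.

Spikes are local maxima of *I* above an intensity threshold of 1
(dimensionless): the quiet intensity is O(β) ≈ 1e-4–1e-2 while pulses
reach O(10–100), so the threshold is uncritical over orders of
magnitude.  Peaks closer than 50 units to the previous accepted peak
are discarded (earlier peak kept); peak times are refined by parabolic
interpolation, giving timing resolution well below the sample step.
Latency is measured from the onset of the first input bit (time origin
of the pump program); "no spike" is declared only after 3000 units of
post-stimulus padding, comfortably beyond the largest latencies of
interest.  Quiet steady states are found by one-dimensional bracketed
root-finding in *I* after substituting the *G* and *Q* nullclines.

Every distinct stimulus (bit pattern + tuning) is integrated once per
process and memoised; all sweeps, codebooks and subset searches reuse
the cached spike trains.  Because the system is autonomous and starts
from its steady state, an onset-delayed program spikes exactly the
delay later than the undelayed one; rank-order delay searches therefore
reuse the same cached solutions.

## Input coding and receptive fields

A bit sequence p₀p₁… drives the pump as
μ₁(t) = μ₀ + Σᵢ c·pᵢ·Π_{τp}(t − i·τb − τd), with boxcar pulses of
duration τp ≤ τb on half-open intervals (so abutting pulses
concatenate).  Throughout the digit task τb = 50 and τp = 30: the bit
time is slightly shorter than the relative refractory period, so
consecutive pulses *summate* and the neuron can be tuned to fire only
after a sufficiently long run of "1"s.  In the short-pulse limit only
the pulse energy τp·c matters.

Images are 5×5 binary grids read as ten receptive fields: rows H1–H5
left→right and columns V1–V5 top→bottom.  The scan direction matters
because the asymmetric marker patterns "10111" and "11101" are
mirror-related; a config switch (`column_direction="up"`) flips the
column read-out and with it the roles of digits 2 and 5.

## Calibration of the detector operating points

The excitability landscape of the implementation was measured directly
(firing thresholds in c at μ₀ = 1.25, τb = 50, τp = 30):
c\*(111) = 5.39, c\*(1111) = 4.45, c\*(10111) = 4.63, c\*(11101) = 5.13.
The asymmetry detector works because a leading lone pulse pre-charges
the gain before the following triple arrives, whereas a trailing lone
pulse arrives after the triple has already failed: between c = 4.63 and
5.13 the pattern "10111" fires while its mirror "11101" does not.

Detector units are therefore tuned as follows:

| unit intent | fields | μ₀ | c | rationale |
|---|---|---|---|---|
| "111" | H1 H3 H5 V2 V4 | 1.25 | 6.0 | min-run = 3, robust to ±5 % in both parameters |
| "1111" | V2 V3 V4 | 1.25 | 5.0 | inside the min-run-4 band (4.45, 5.39) |
| "10111" | V2 V4 | 1.25 | 5.0 | inside the discrimination band (4.63, 5.13) |

Every unit's tuning is checked at build time against its intent
(`DetectorSpec.validate`); a bank whose tunings do not realise their
intents refuses to build.  This validation-driven calibration is the
package's procedure for fixing operating points: thresholds in this
system are sharp, so a few-percent shift in the model (e.g. the
spontaneous-emission variant) moves band edges by a few percent, and
the bands — not individual printed numbers — are the portable
description.

The spike-time read-out uses μ₀ = 2.65, c = 0.36: just above the 3-run
firing threshold (c\*₃(2.65) = 0.345), where the 3-run/4-run latency
gap is δτ = 184 ≫ τb = 50, satisfying the design criterion that
distinct run features land in distinct τb-wide stamp windows.  The gap
grows without bound as c approaches the threshold from above and
collapses to a few units once c exceeds it by more than ~30 %.
The rank-order read-out uses μ₀ = 2.6, c = 0.7 with per-field onset
delays (24, 47, 20, 60, 91, 9, 67) for (V2, V3, V4, H1, H3, H4, H5):
here every ≥3-pulse feature fires with a strongly pattern-dependent
latency, and the delays break the remaining arrival degeneracies.

## Output coding schemes

*Event coding* — 10 detector units; the fire/no-fire vector is looked
up in a codebook built on the reference font.  The mirror digits 2 and
5 produce codes that differ exactly in the asymmetry-sensitive (c = 5.0,
V2/V4) units.  An all-zero code is a legal codebook entry by default
(`allow_empty_code`); with the strict flag a silent bank decodes to
"unknown".

*Spike-time coding* — one neuron per field over
{V2, V3, V4, H1, H3, H4, H5}; each field contributes a stamp
k = ⌊(t_spike − t_min)/τb⌋ + 1 clipped to 1..5 (0 = silent), where
t_min is the earliest spike observed over the font at the fixed tuning
and is stored in the codebook.  Seven neurons replace the ten event
units because the stamp carries pattern *and* position information.

*Rank-order coding* — the same seven fields with their fixed delays;
only the identity order of the first ≤ 3 spikes is kept.  Arrivals
closer than 0.5 units are ties, broken by field declaration order with
a warning; with the default delays no ties occur on the packaged font
(latency coincidences between fields are separated by the pairwise
delay differences, all ≥ 4).

`min_field_subset` performs the exhaustive size-ordered subset scan
(≤ 2¹⁰ cheap tuple comparisons over cached codes) and finds that seven
fields are also the *minimum* for unique stamp codes on the packaged
font; `search_delays` Monte-Carlo-samples integer delay vectors from
[1, 100] with a seeded generator and returns those with unique,
tie-free rank codebooks.

## The digit font

The packaged font (`data/digits5x5.txt`) is a synthetic reconstruction:
ten 5×5 digits designed, starting from a classic pixel font, so that
the structural constraints of the classifiers hold simultaneously —
every digit has a ≥3 run in some field; 2 and 5 are exact mirror twins
carrying "10111"/"11101" markers; the event, spike-time and rank
codebooks are all unique; the minimal spike-time field subset has size
exactly 7; and every stamp sits ≥ 2 time units away from a bin
boundary.  The design search (simulated annealing over pixel flips,
capped at 5 changed pixels per digit, followed by greedy reversion
toward the seed) used the simulator's own frozen pattern-response
tables, so the font is calibrated to the implemented dynamics.  The
font is versioned data: the validator (`validate_font`) and the
classification tests are its acceptance gate.  One consequence of the
design: digit 0 activates no detector at all and is encoded by the
empty event/rank code (the same role the all-silent digit plays in the
empty-code discussion for spike counting).

## What the synthetic task does and does not show

The study is fully numerical and noiseless: pump waveforms are exact
boxcars, parameters are identical across neurons, and spike times are
deterministic.  Real micropillars add spontaneous-emission noise
(latency jitter, which grows exactly where the latency itself grows),
device-to-device parameter spread (addressed qualitatively by the ±5 %
robustness box), and finite modulation bandwidth.  Passing tests show
that the coding schemes are internally consistent and robust at the
stated operating points of the model — not that a physical array would
reach the same classification margins.

## Known limitations

* Coherent (optical-field) injection into *I* is out of scope; inputs
  act incoherently on the pump only.
* No stochastic simulation; noise is discussed only qualitatively.
* The excitability boundaries quoted above are specific to the squared
  spontaneous-emission term and the printed parameter set; the linear
  variant shifts them upward by ~5 % (e.g. c\*(111) = 5.67, self-pulsing
  onset 2.83 instead of 2.68).
* Images larger than 5×5 are not supported (the field extraction is
  hard-wired to the digit task's geometry).
* Self-pulsing onset is defined operationally (first spike within a
  5000-unit horizon from the reference initial state); near the onset
  the first inter-spike interval diverges, so much longer horizons can
  shift the estimate slightly downward.
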