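# Methods

## The cross-bridge cycle

A myosin Ic head is modelled as a continuous-time Markov chain over five
states: detached (1), weakly bound with ADP·Pi (2), and the strongly
bound ADP (3), nucleotide-free (4) and ATP (5) states.  The chain is a
single loop — 1↔2↔3↔4↔5↔1 — so exactly one ATP is hydrolysed per
forward cycle and the chemistry is tightly coupled to the mechanics (no
futile cycles, no mechanical-loss parameter).

Force enters in three places.  The two power strokes (Δx₁ = 5.8 nm on
Pi release, Δx₂ = 2 nm on ADP release) split the stroke work F·Δx
between forward and reverse rates through force-distribution factors
δ₁, δ₂ ∈ [0, 1]: ω23 = ω23⁰e^(−δ₁FΔx₁/kBT), ω32 = ω̂32⁰[Pi]·
e^((1−δ₁)FΔx₁/kBT), and analogously for ω34/ω43.  The exits from the
ATP state (5→1 detachment and 5→4 ATP release) share the sigmoidal
factor g(F) = 2(1−ω_off)/(1+e^(ξF/kBT)) + ω_off — the catch bond: g(0)=1,
g→ω_off under resisting load, g→2−ω_off under assisting load (evaluated
unclipped for negative F).  Nucleotide- and actin-binding rates are
first order in the respective concentrations.

Thermodynamic consistency requires the product of forward over reverse
rates around the loop to equal e^((Δμ−(Δx₁+Δx₂)F)/kBT), with
Δμ = kBT·ln([ATP]K_eq/([ADP][Pi])) and K_eq = 4.9·10⁵ M.  This fixes the
force-free ATP-release constant,

    ω54⁰ = (ω̂12/ω̂15)·ω23⁰·ω34⁰·ω̂45⁰·ω51⁰ / (ω21·ω̂32⁰·ω̂43⁰·K_eq),

and forces ω54 to carry the same g(F) as ω51 (the factors cancel in the
loop ratio).  The packaged parameter set recomputes ω54⁰ at load time
(3.08 s⁻¹ with the packaged actin-binding constants; 3.04 s⁻¹ with the
binding-branch ratio π₂/(1−π₂) = 499 — the two differ only through
rounding of the printed constants, within 2%).  A user can override
ω54⁰, at the cost of the `balanced` flag.

Immediate consequences used throughout: the stall force
F_s = Δμ/(Δx₁+Δx₂) (≈12.6 pN at physiological concentrations), the
effective velocity v = Δx₁ΔJ₂₃ + Δx₂ΔJ₃₄ = (Δx₁+Δx₂)·J with J the
common loop flux, and detailed balance (all edge fluxes zero) exactly at
Δμ = 0, F = 0.

## Parameters

| quantity | symbol | default | unit |
|---|---|---|---|
| power strokes | Δx₁, Δx₂ | 5.8, 2.0 | nm |
| force-distribution factors | δ₁, δ₂ | 0.12, 0 | — |
| catch-bond length / offset | ξ, ω_off | 13.45 nm, 0.001 | |
| Pi release / binding | ω23⁰, ω̂32⁰ | 1.5 s⁻¹, 4.5·10⁻¹⁰ s⁻¹μM⁻¹ | |
| ADP release / binding | ω34⁰, ω̂43⁰ | 3.9 s⁻¹, 2.17 s⁻¹μM⁻¹ | |
| ATP binding / release | ω̂45⁰, ω54⁰ | 0.26 s⁻¹μM⁻¹, balanced | |
| detachment (weak / ATP state) | ω21, ω51⁰ | 164, 314 | s⁻¹ |
| actin binding (state 2 / 5) | ω̂12, ω̂15 | 0.76, 0.0015 | s⁻¹μM⁻¹ |
| thermal energy | kBT | 4 | pN·nm |
| head stiffness | κ | 0.5 | pN/nm |

Internal units are pN, nm, s and μM; K_eq is stored in molar and
converted where it meets μM ratios.  The packaged ω̂12 (0.76) and the
branch probability π₂ = ω̂12/(ω̂12+ω̂15) = 0.998 are redundantly
determined; 0.76 is kept as the packaged default although the chain
ω̂12 = π₂ω̂15/(1−π₂) gives 0.7485 — a rounding discrepancy of ~1.5%
whose source (the rounding of π₂) the calibration literature does not
resolve.

## Attachment statistics (first passage)

The measured quantity in an isometric clamp is the lifetime of the
strongly bound episode, t_sb.  Its inverse is computed by Hill's
closed-diagram construction: states 1 and 2 are made absorbing and the
absorbed probability current is redirected to the entry states — state 3
with weight π₃ (the relative stationary current ω23P2 versus ω15P1) and
state 5 with weight 1−π₃ — self-loops being dropped since they cancel in
a master equation.  The stationary current of this closed 3-state
diagram, ω32p3 + ω51p5, equals 1/t_sb; equivalently, t_sb is the mean
absorption time of the 3-state transient chain started from the
π₃-weighted entry distribution (the fundamental-matrix construction is
kept as the independent oracle in the tests, along with the expanded
rational closed form).  The filament detachment rate k_off uses the same
construction with only state 1 absorbing and entry weights (π₂, 1−π₂).
Both rates depend on the actin-binding constants only through their
ratio, hence are invariant to the actin concentration — this is what
licenses the two-stage fit below.  The weak/detached time follows from
the steady state as t_wb = t_sb(1/P_sb − 1), so t_sb/(t_sb+t_wb) = P_sb
identically.

Degenerate inputs (no exit route from the transient set) return zero
rate rather than a singular solve.

## Ensemble of heads

A cluster of N identical heads, each a linear spring of stiffness κ in
parallel, is described by a birth–death chain over the bound count n,
with attachment rate (N−n)k_on, k_on = (ω̂12+ω̂15)[actin], and
detachment rate n·k_off(f) at per-head force f.  Load sharing:
cooperative (f = F/n — detachment of one head loads the rest, which the
catch bond converts into mutual stabilisation), fixed (f = F/N), or
self-consistent (f = F/⟨ñ⟩, solved by damped fixed-point iteration with
a bisection fallback).  The stationary distribution is the standard
product form, accumulated in log space so N of a few hundred is safe;
k_off is never evaluated at n = 0, per-head forces are clamped at f ≥ 0
(the ensemble treats resisting loads), and a vanishing k_off flags
absorption at n = N.  Extension is x = F/(⟨n⟩κ); the Ca²⁺ release is
Δx = F(1/(κ_Ca⟨n⟩_Ca) − 1/(κ⟨n⟩)) with ⟨n⟩_Ca computed at k_on/β and
stiffness κ_Ca (β scales both actin-binding constants equally — the
modulation is specified only as a reduction of the binding probability).

**Conditions for the ensemble-level figures.**  The headline ensemble
numbers (extension < 5 nm up to 20 pN; ≈20–30 nm release for N = 10
after a 100-fold binding reduction; ≈40 nm nearly force-independent
release for N = 50 with tenfold softening) are evaluated at
physiological nucleotides and **1 mM actin**, the concentration at which
the cycle's actin dependence saturates.  This is a deliberate design
choice: the cooperative-ensemble description is the high-actin limit
(where it also agrees best with the coupled simulation), and the release
magnitude is extremely sensitive to actin availability — at 100 μM the
post-Ca²⁺ attachment rate k_on/β ≈ 0.76 s⁻¹ cannot balance
k_off ≈ 30–80 s⁻¹, the ensemble collapses to ⟨n⟩ ≈ 0.1, and the nominal
release exceeds 400 nm; at 10 mM the ensemble barely releases (≈2 nm).
Users studying other regimes should treat the actin concentration as a
first-class parameter (`Conditions.actin`).

## Coupled-head simulation

The Monte Carlo model couples each head by its own spring to a rigid
common backbone.  Mechanics are quasi-static: after every chemical event
the backbone position solves Σ_bound κ(a_i − X) = F, each bound head
feels the signed force f_i = κ(a_i − X) (assisting values enter the same
rate laws, g(f) > 1 allowed), and all force-dependent rates are
refreshed.  A head binds tension-free (a_i = X at binding; no rebinding
memory), the 2→3 stroke advances its anchor by Δx₁ and 3→4 by Δx₂, and
reverse strokes move the anchor back symmetrically — chosen so that a
strained head satisfies the same loop thermodynamics as the analytic
cycle.  The algorithm is an exact Gillespie simulation driven by a
single-integer-seeded PCG64 generator; trajectories are bit-reproducible
for a fixed seed.  A single head under force clamp is a
time-homogeneous chain (its spring force equals the clamp force while
bound), so that case runs through an exact scalar fast path.  Full
detachment under load is logged (and the backbone holds position until a
tension-free rebinding) unless the run is configured to terminate.
Rate-law exponents are capped at ±500 with a warning — only reachable
under extreme artificial strain.

In motility mode (zero load, free backbone) the velocity is the
least-squares slope of X(t) after burn-in, with a standard error from
slopes of ten contiguous segments; runs with more than 10% fully
detached time are flagged unreliable.  Two hundred coupled heads at
saturating ATP (1 mM, trace ADP/Pi, 100 μM actin, κ = 0.5 pN/nm — the
coupling stiffness and chemistry of that scenario are assumptions, as no
measured values exist for the membrane-coupled assay) glide at ≈22–25
nm/s.

## Calibration

`derived_parameters` encodes the identity chain that fixes most
constants from literature values: t_wb = t_sb(1−r)/r = 1.72 s from the
duty ratio r = 0.11 and t_sb = 0.213 s; ω̂43 = ω34⁰/K_ADP = 2.17
s⁻¹μM⁻¹; ω̂32 = (ω23⁰/[Pi])e^(ΔG₂₃/kBT) ≈ 4.5·10⁻¹⁰ s⁻¹μM⁻¹ with
ΔG₂₃ = −15 kBT at the source's assumed 1 mM Pi; ω̂12 = π₂ω̂15/(1−π₂);
and ω54⁰ from the balance condition.

`bin_events` bins attachment events in 1-pN force bins (edges at integer
multiples; events beyond 6 pN excluded, as power strokes are only
characterised below that load) and estimates each bin's unbinding rate
as the inverse mean duration with exponential-lifetime confidence
bounds rate·χ²_{α/2,2n}/(2n) and rate·χ²_{1−α/2,2n}/(2n), α = 0.05.

`joint_fit` minimises Σ((model − estimate)/w)² over all bins of both
nucleotide conditions simultaneously, w being half the CI width
(asymmetric weights are available but off by default).  Because the bin
estimate converges to the *harmonic* average of the rate over the bin's
force span, the model side is the harmonic bin average on a 9-point
sub-grid, not the bin-centre value — at bin centres the fit acquires a
visible bias wherever the curve is steep on the 1-pN scale.  Free
parameters {ω21, ω51⁰, δ₁, δ₂, ξ, ω_off} are optimised with rates and ξ
in log space under bounds δ ∈ [0,1], ω_off ∈ (0,1], from 20 seeded
random starts (trust-region reflective least squares), keeping the best
objective; ω54⁰ is re-balanced at every evaluation so the fit never
leaves the thermodynamically consistent manifold.  During this fit ω15
is pinned at 1 s⁻¹ (only the ratio ω12/ω15 = π₂/(1−π₂) enters 1/t_sb).
`fit_binding_rate` then recovers ω̂15 by a bracketed root solve of
t_wb(ω15) = target at 100 μM actin.

**Identifiability.**  The unbinding curve is well determined by a
two-condition, 500-events-per-condition dataset, but the individual
parameters are not: the Fisher information at the generating values
gives Cramér–Rao relative standard deviations of roughly 1.4 (ω21), 2.1
(ω51⁰), 0.25 (δ₁) and 0.26 (ξ) — the model is sloppy, with strong
ω21/ω51⁰/ω_off trade-offs.  Noise-free curves are recovered to machine
precision; noisy fits recover the curve (within the data noise) rather
than the parameter vector.  Point estimates of ω21 and ω51⁰ from a
single dataset of this size should therefore be read with factor-of-two
error bars; tightening them requires more events or external
constraints.

## Synthetic data

The generator emulates the isometric-clamp measurement: per event a
clamp force is drawn (uniform on 0–6 pN by default, or a clustered
mixture mimicking trap-style force clustering), and the attachment
duration is exponential with rate 1/t_sb(F) — matching the analysis
assumption that recorded lifetimes are strongly-bound episodes.  The
default conditions are the two experimental nucleotide sets (5 mM ATP,
and 1 mM ATP with 50 μM ADP, both with 0.1 μM contamination of the
unreported species — the contamination levels are assumptions).  A
`full_cycle` mode instead harvests strongly-bound sojourns from
single-head Gillespie runs, cross-checking the exponential shortcut.
An optional dead time (default 0, typically 5 ms) censors short events
to emulate finite temporal resolution.  Not emulated: trap compliance,
bead diffusion, detection noise, force drift within an event — so
passing round-trip tests demonstrates correctness of the analysis
pipeline under its own assumptions, not robustness to instrument
effects.

## Numerical choices

* Steady state: closed-form spanning-tree numerators are primary; a
  rank-revealing SVD null-space solve is the cross-check (agreement
  ≤10⁻⁹ enforced in tests).  An actin-free (reducible) chain returns all
  mass on state 1 with a degeneracy flag.
* Root finding (occupancy crossings): grid scan on [0, 6] pN (241
  points) with bisection refinement to 10⁻³ pN; all sign changes are
  reported, the lowest is the crossover.
* Ensemble products in log space, renormalised after exponentiation.
* Exponent caps at ±500 in all rate laws.
* Problem sizes in the shipped tests and examples — ~10⁴ simulated
  strong-binding events for dwell statistics, 20-second 30-head runs for
  the ensemble comparison, a 6-second 200-head run for motility, 500
  events per condition for the calibration round trip — were chosen as
  the smallest sizes at which the statistical assertions (3-SE and 10%
  agreement) are meaningful.

## Known limitations

* The force laws are calibrated below 6 pN; above ~10 pN per head the
  reverse-stroke rate ω32 grows like e^(0.88FΔx₁/kBT) and dominates
  detachment.  Ensemble scenarios that push single heads far beyond 6 pN
  (small clusters under 20 pN loads after Ca²⁺) extrapolate the rate
  laws outside their calibrated range.
* k_off counts brief weak-state touches; with ω21 ≈ 164 s⁻¹ most
  attachment events are milliseconds long.  Observables that depend on
  k_off (ensemble occupancy, release) are therefore sensitive to the
  weak-binding branch, which optical-trap lifetime data constrain only
  indirectly.
* The ensemble model ignores head geometry and the ~37-nm actin binding
  repeat; N is an effective number of engageable heads.
* Parameter point estimates from single datasets are sloppy (see
  Calibration); the package deliberately reports fit spread via
  multi-start objectives rather than asymptotic standard errors.
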