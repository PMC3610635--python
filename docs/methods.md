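# Methods

## Model

A single receptor chain carries up to four ITAMs, each with two
phosphorylatable tyrosines.  Sites are indexed in phosphorylation order,
membrane-distal ITAM first.  Three cytosolic partners act on the chain in
one well-mixed compartment (concentrations in µM, time in s; no membrane
geometry is represented):

* **kinase** (Lck-like): binds an eligible unphosphorylated site and, in a
  single catalytic step, phosphorylates it and dissociates
  (`E + S ⇌ ES → E + P`; no separate product complex);
* **phosphatase** (CD45-like): the mirror image, removing a phosphate per
  catalytic cycle;
* **ZAP-70**: binds any *doubly* phosphorylated ITAM that is neither
  ZAP-occupied nor engaged by the phosphatase, one molecule per ITAM,
  independently of events elsewhere on the chain; while bound it protects
  the ITAM from dephosphorylation.

Constraints: at most one enzyme molecule (kinase or phosphatase) per chain
at a time; ZAP occupancy up to one per fully phosphorylated ITAM; a bound
kinase never blocks ZAP binding.

Two phosphorylation schemes are supported.  Under **sequential** order the
kinase only binds the frontier site (the lowest-index unphosphorylated
site) and the phosphatase only the frontier phosphate — dephosphorylation
is last-on-first-off, the unique reverse-order reading consistent with the
enumerated network sizes below.  Under **random** order every
unphosphorylated (phosphorylated) site is independently eligible for the
kinase (phosphatase), other rules unchanged.  A mixed scheme (sequential
phosphorylation, random dephosphorylation) is deliberately not
implemented: it is ill-posed without extra assumptions about how the
sequential frontier recovers from out-of-order vacancies.

Sites within an ITAM are distinguishable species-wise; this is required
for sequential bookkeeping and harmless under the random scheme.

## Network generation

Species and reactions are produced by breadth-first closure from the
all-unphosphorylated, unbound state: every rule application on a reached
species contributes one irreversible mass-action reaction (bind, unbind or
catalysis; molecularity ≤ 2) and possibly new species.  The three free
molecules are always included.  For the wild-type three-ITAM sequential
chain with ZAP-70 this yields exactly 53 species and 168 reactions; one
ITAM gives 11/14, two ITAMs 25/56, and the random three-ITAM chain
728 species / 2430 reactions.  The test suite checks the small networks
species-for-species and reaction-for-reaction against an independent
nested-loop enumerator.  Exporters write a re-importable tab-separated
netlist and a minimal SBML Level 3 document (species, mass-action kinetic
laws as MathML, local rate parameters) produced by the package's own
small XML writer.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| enzyme kon | 0.1 | µM⁻¹s⁻¹ | sub-diffusion-limited association; with koff + kcat below, Km = 20 µM ≫ substrate, so neither enzyme is saturated (the observed ultrasensitivity is *not* zero-order) |
| enzyme koff | 1 | s⁻¹ | order-unity turnover |
| enzyme kcat | 1 | s⁻¹ | order-unity turnover; kinase and phosphatase kinetically identical by default |
| ZAP-70 kon | 100 | µM⁻¹s⁻¹ | diffusion-limited association; with the koff anchor this puts the middle ITAM's Kd at 10 nM, in the reported range for tandem-SH2 binding to doubly phosphorylated ITAMs, and makes ZAP loading near-saturating when the kinase dominates |
| ZAP-70 koff | 10 / 1 / 0.1 | s⁻¹ | distal→proximal ladder: 10-fold affinity steps in the phosphorylation direction, anchored at 1 s⁻¹ for the middle ITAM; only the anchor and the ratios are constrained, the ladder is the wild-type's defining feature |
| chain total | 0.5 | µM | receptor-scale substrate |
| kinase total E | 1 | µM | fixed during sweeps |
| phosphatase total F | E/10ˣ | µM | the swept dose variable |
| ZAP-70 total | 6 | µM | abundant cytosolic pool, 4× the 3-per-chain binding capacity — the excess the loading stoichiometry and S_max comparisons assume |

FcεRI γ- and β-chain ITAMs are modelled purely as ZAP-70 off-rates 10×
and 100× the high-affinity zeta-1 value; the differential-enzyme variants
give the kinase a 10-fold per-ITAM affinity ladder rising distal→proximal
and the phosphatase the reverse, with shared kon and kcat.

All defaults are config-overridable.  A documented condition, not a free
dial: ZAP-70 must exceed the chain's binding capacity for the headline
behaviour — cutting ZAP-70 to 0.6 µM (capacity 1.5 µM), or raising the
chain 10-fold past the ZAP pool, demonstrably degrades the Hill number
below 3.  The robustness suite therefore perturbs the ten *reaction
rates* (enzyme kon/koff/kcat ×2, ZAP kon, three ZAP koffs) 10-fold in
each direction, and separately asserts the ZAP-excess degradation as a
mechanism prediction.

## Steady states

The stoichiometry matrix, mass-action fluxes and analytic Jacobian are
assembled from the network; the four conserved moieties (total chain,
kinase, phosphatase, ZAP-70) are read off species compositions and
verified to annihilate the stoichiometry matrix exactly.  Steady states
are found by stiff integration (LSODA, analytic Jacobian, expanding time
windows up to t_max = 10⁶ s) from the resting state, followed by a damped
Newton polish on the square system in which four rate rows are replaced
by the conservation constraints (MINPACK hybr as fallback).
Integration-then-polish guarantees the physically reachable branch;
path-independence from a fully loaded start is tested (no hysteresis —
the switch is monostable).  Acceptance contract per solve: max |dc/dt| ≤
10⁻⁸ × the largest total, conserved totals matched to 10⁻⁶ relative,
concentrations ≥ −10⁻¹² µM (clipped to 0 for reporting).  Non-convergence
raises, carrying the last residual; failed sweep points are reported,
never interpolated.

Dose-response sweeps warm-start each point's Newton polish from the
neighbouring solution (falling back to the full from-rest solve whenever
the polish misses its contract); warm and cold starts are checked to
agree.  Default grid: 61 points, x ∈ [−2, 2], auto-extended by one decade
per side (up to three times) when a plateau is unreached.  The comparison
experiments and the test suite use a 41-point grid over the same range —
fine enough that fitted Hill numbers are stable to well under the
tolerances asserted.

## Curve analysis

Hill fits use lmfit least squares on
`S(x) = S_min + (S_max − S_min)/(1 + 10^{n(x50−x)})` with
data-derived initial guesses (tail plateaus, half-max crossing, n = 1)
and seeded multi-start jitter (5 starts, seed 0 by default) to avoid
local minima; `S_max ≥ S_min` is enforced by parameterizing the span.
Fits are performed in absolute units — `n` and `x50` are invariant to
normalization under this form — and normalized curves are also emitted.
A curve must approach both plateaus (outer 3-point windows flat to 5% of
the range, median-based so point noise does not trip it) or the fit
refuses and advises grid extension; non-monotone curves are fit with a
warning flag.  EC10/EC90 are located on the *computed* curve (monotone
envelope, plateau-median normalization, PCHIP inverse interpolation) —
deliberately fit-independent — and `log10(EC90/EC10)` serves as the
second steepness metric; on exact Hill curves it reproduces
`log10(81)/n` to 10⁻⁴.

The ratio-invariance check compares sweeping F at fixed E against
sweeping E at fixed F on the same x grid.  At the defaults the curves
agree to ~1.6% (relative to the maximum); the discrepancy shrinks an
order of magnitude when enzyme association is slowed (kon/10), i.e. deep
in the first-order regime where enzyme–substrate complexes are
negligible.  Raising enzyme totals does *not* shrink it — that pushes
association toward the off-rate and out of the first-order regime — so
near-invariance at the defaults is an empirical observation, not an
exact symmetry.

## Limitations

* Steady-state only: no time courses, no stochastic (particle) simulation.
* One receptor chain species per model; no CD3 γε/δε ITAMs or full
  10-ITAM receptor, and no downstream signaling beyond ZAP-70 docking.
* No receptor triggering, kinase regulation or bistability mechanisms.
* The random-scheme reaction count depends on rule conventions (per-site
  enzyme engagement, one enzyme per chain); the species count robustly
  exceeds 500, and exact counts are reported by `network_summary` for
  inspection.
* Figure-level comparisons are ordering/property claims (which
  architecture is steeper, more potent, larger) rather than absolute
  curve positions, which depend on the absolute affinity anchors.
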