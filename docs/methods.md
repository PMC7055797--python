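# Methods

## The four-strain duplication model

The simulator follows a bacterial population through repeated batch-growth
cycles with serial dilution. Four strain classes are tracked: wild type
(`Wt`), carriers of a tandem duplication spanning at least two essential
genes (`Dup`), carriers with one essential gene inactivated in one copy
(`Δ1`), and carriers with a different essential gene inactivated in each
copy (`Δ2`). Five transitions connect them —

```
Wt → Dup     duplication formation          μ = 1e-4 /generation
Dup → Wt     segregation to single copy     μ = 1e-2
Dup → Δ1     first gene inactivation        μ = 1e-5
Δ1 → Wt      segregation (intact copy only) μ = 5e-3
Δ1 → Δ2      second gene inactivation       μ = 1e-5
```

— and `Δ2` is absorbing: once each copy has lost a different essential
gene, segregation of either copy is lethal and the duplication (hence the
rearranged gene order) is fixed in that lineage. Duplication formation
and segregation defaults sit mid-range in the experimentally observed
spontaneous window (10⁻⁵–10⁻²), inactivation at the canonical ~10⁻⁵ per
gene per generation; every arrow is independently configurable. The `Δ1`
segregation rate is half the `Dup` rate because only the recombinant that
retains the intact essential-gene copy survives.

## Growth cycles

Within a cycle, strain i grows at the Monod rate ψᵢ(R) = Vᵢ·R/(R+k) on a
shared resource R, with dR/dt = −e·Σnᵢψᵢ(R). Parameters (plain numbers,
no unit system): r₀ = 100, k = 1, e = 1e-8, giving a batch carrying
capacity r₀/e = 10¹⁰ cells. The conversion efficiency is a deliberate
calibration: it pins the end-of-cycle population at the 10¹⁰ cells the
serial-passage protocol is defined around, and remains user-configurable.
Counts are absolute cells (the protocol's population sizes — 10⁶ founder,
10¹⁰ capacity, 10⁸ bottleneck — are absolute, and no culture volume is
defined anywhere).

The coupled system is integrated with LSODA (rtol 1e-8, atol 1e-3 cells;
counts span 1 to 10¹⁰). A cycle ends when R drops below 1e-6·r₀ — the
Monod rate never reaches zero in finite time, so exact exhaustion is
replaced by this threshold; failing to exhaust the resource before
`max_time` is an explicit error, never a silent truncation. Strains at
count zero stay exactly zero (no spontaneous generation inside the ODE).
Two structural facts are used as test oracles: conservation
(Σn(t) − Σn(0) = (r₀ − R(t))/e at every step) and the exact reduction
nᵢ(τ) = nᵢ(0)·exp(Vᵢτ) in transformed time τ = ∫R/(R+k)dt, which turns
the end state into a solver-independent scalar root-find.

## Serial passaging and mutant seeding

Each passage: grow to exhaustion → seed mutants → record the end-of-cycle
census → dilute 100-fold into fresh medium. Cumulative generations are
counted on the total population (log₂ of the per-cycle fold expansion,
≈ 6.66 per passage), and a run stops at 1000 generations (~151 passages).

Mutant appearance is built on the per-cell probability
p = min(1, gᵢ·μᵢ→ⱼ), where gᵢ is the parent strain's log₂ fold-expansion
over the cycle just completed (capping at 1 because p is a probability).
Three seeding modes exist:

* **scaled** (default): the number of converted cells per arrow is
  Poisson(nᵢ·p), applied to end-of-cycle counts before dilution. This is
  the population-level reading of the per-cell probability, and the one
  the package treats as the model proper: mutant supply scales with the
  parent population, duplications arise within a few passages of a 10¹⁰
  cell culture, and the neutral Wt⇄Dup subsystem settles at the classical
  mutation–segregation balance μ_f/(μ_f+μ_b) ≈ 0.0099 — the behavior an
  independent per-generation two-state Markov chain predicts.
* **single**: one uniform draw per arrow per passage; x < p seeds exactly
  one cell, joining the culture after the bottleneck so a single-cell
  lineage grows a full cycle before first facing dilution. This literal
  single-cell Monte Carlo is retained for sensitivity analysis. It is not
  the default because its mutant supply is independent of population
  size: with μ = 1e-4 and g ≈ 6.6 the expected wait for the *first*
  duplication (~1500 passages) exceeds the entire 1000-generation
  protocol, so almost no run would ever leave the wild-type state.
* **poisson**: as *single* but with a Poisson-distributed event count.

In every mode conversion moves cells (the parent is decremented by the
seeded number, capped at its count): segregation converts a `Dup` cell
back to `Wt` rather than spawning an extra cell, which is what gives the
neutral system a balance point at all.

Bottlenecks are continuous by default (every count divided by the
dilution factor; fractional cells permitted, matching a deterministic ODE
treatment); binomial thinning per strain is available as `stochastic`.
With default population sizes the scaled-mode Poisson means are large, so
replicate-to-replicate variation is modest; stochasticity matters most at
small capacities or with the single-cell modes.

Outcome labels: `fixed_d2` when the Δ2 fraction first reaches the
fixation threshold (0.99 of the total, configurable; the generation of
first crossing is reported), `segregated` when duplication-bearing
classes were present but are gone at the end, `steady_state` when every
strain fraction changes by < 1e-3 over the last 10% of passages (a pure
wild-type run therefore classifies as steady state), else `incomplete`.
Replicate r of a scenario runs with seed `scenario.seed + r` on an
independent stream; identical scenario and seed give bit-identical
trajectories.

Fitness presets A–F cover the standard selection scenarios: no
duplication advantage (A), 5%/25% advantage (B/C), and C plus a further
2%/5%/10% advantage for `Δ2` (D/E/F), composed multiplicatively
(v_Δ2 = 1.25·1.02 … 1.25·1.10). `Δ1` is assigned the duplication fitness;
its own fitness is not separately constrained by anything, and this
assumption is the natural neutral choice. When comparing fixation times
across presets, runs that have not fixed by the 1000-generation horizon
enter as right-censored at the horizon.

## Coverage scanner

Inputs are a per-base depth track (bedGraph or position/depth TSV) and
optionally a long-form pileup table (contig, pos, ref, allele, count),
GFF3 CDS annotation and a reference FASTA. All internal coordinates are
0-based half-open; GFF3 is converted at ingestion.

Pipeline and defaults: sliding window 1 kb, step 100 bp (min/mean/max per
window); window means normalized by the genome-wide median window mean — a
robust baseline provided duplicated blocks cover under half the windows;
duplication calls are maximal runs of windows at ratio ≥ 1.5, merged
across gaps ≤ 2 kb, discarded under 5 kb. Call boundaries are placed half
a step outside the outermost qualifying window center: a 1 kb window first
crosses the 1.5 threshold when it half-overlaps a 2× block, so the
crossing lies between the outermost qualifying window and its neighbor
and the midpoint is the unbiased boundary estimate (observed accuracy:
within one 100 bp step of truth). Divergent sites are reported inside
calls at depth ≥ 30 when the strongest non-reference allele (ties broken
lexicographically) has fraction within 0.3–0.7 — wide enough for binomial
scatter around 0.5 at ~150× depth, while excluding fixed differences and
rare noise. The detection thresholds formalize what was originally a
visual assessment of coverage tracks; all are exposed as configuration.

Effect classification is minimal by design: indels in a CDS are
`frameshift` or `inframe_indel` by length mod 3; substitutions are
translated in frame (strand- and phase-aware, spliced intervals
supported) into `synonymous` / `missense:R276C`-style /
`nonsense:...` labels; sites outside every CDS are `intergenic`. A CDS
whose spliced length is not a multiple of 3 raises an explicit
annotation error.

## Synthetic data

The generator emulates the scanner's target signal: depth at each base is
negative-binomial with mean = mean_depth × copy number (default mean 150,
dispersion 0.05 so var = m + 0.05 m²; dispersion 0 degenerates to
Poisson), duplications are embedded as copy-number blocks, and divergent
sites draw their alternate count binomially at the specified true
fraction, with site depth taken from the generated track for
consistency. Truth BED/TSV files accompany every dataset.

The bundled worked fixture uses a 120 kb contig, one 21 kb duplication at
copy 2, background depth 77.5 (so the duplicated site sits at ~155×), and
a single `+T` insertion at true fraction 0.49 inside an embedded
401-codon gene — the geometry of the one fully characterized diverging
duplication the scanner is calibrated against.

What passing tests on this generator do **not** show about real data: no
read-length autocorrelation (window-mean variance is understated), no
mapping bias, GC bias or repeat-driven coverage artifacts, no sequencing
error in allele counts, and no mobile-element copy-number signal (which a
practitioner must distinguish from segmental duplication). The scanner's
recovery statistics on synthetic tracks are therefore an upper bound on
real-data performance.

## Numerical and design notes

* Batch end states are solver-accurate to ~1e-8 relative except for
  strains founded by ~1 cell, where the absolute tolerance (1e-3 cells)
  dominates early and accuracy is ~1e-5 relative.
* Probabilities capped at 1; rates validated into [0, 1]; arrows out of
  `Δ2` rejected at validation.
* The end-to-end checks run the simulator at full scale
  (capacity 10¹⁰, 100 neutral-scenario seeds, 50 seeds per selection
  panel) and the scanner benchmark at 50 seeds × two duplications per
  200 kb contig; the whole suite completes in a few minutes on one CPU.
  Unit tests use a miniature protocol (capacity 10⁶) with identical
  structure.
* Known limitations: two-copy duplications only (no higher
  amplification), at most one concurrent duplication lineage per strain
  class, no death/maintenance terms or chemostat mode, no split-read or
  breakpoint-level refinement in the scanner, and mutator phenotypes only
  via scaling the rate constants.
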