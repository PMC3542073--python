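# Methods

## Scope

`glycosim` models N-glycan processing in the Golgi as string rewriting plus
reactor kinetics, and closes the loop against MALDI-TOF glycan profiling:

1. **Network generation** — enzyme specificities are substring-rewrite
   rules on a condensed linear code for glycan trees; iterating them from
   the ER-exit structures (Man9 and a small inert mono-glucosylated Man9)
   yields the reaction network.
2. **Kinetics** — a cascade of four well-mixed Golgi compartments at
   steady state, with competitive Michaelis–Menten kinetics coupling every
   substrate of an enzyme through a shared denominator.
3. **Spectrum synthesis** — predicted glycan abundances become a
   permethylated, sodiated MALDI stick spectrum with full isotope
   envelopes.
4. **Fitting** — enzyme activity levels are adjusted by
   Levenberg–Marquardt until the synthetic spectrum matches a processed
   experimental (or emulated) spectrum, optionally with between-condition
   activity ratios pinned to transcript-expression ratios.

## Glycan linear code and rules

Residues are written `<symbol><anomeric><locant>` (e.g. `GNb2`), children
before parents, the lowest-locant branch inline and higher-locant branches
parenthesized in ascending order; the reducing-end residue carries no
linkage suffix. Canonicalization is re-serialization under that ordering;
two branches at one locant are rejected. The rule pattern language has
five metacharacters: `…` (any balanced substring), `_` (any substring
whose every `(` is closed, surplus `)` allowed), `|` (empty or one
parenthesized group), `*` (the reaction site — the first position at
which the substrate and product patterns differ), and the `Gnbis`
abbreviation for the bisecting-GlcNAc motif. Formulas are wrapped in
parentheses before matching so a leading `(` anchors a non-reducing
terminus. Constraints combine subpatterns with not/and/or; `*`-anchored
subpatterns are evaluated with `*` pinned to the reaction site.
Parameter-adjustment conditions are evaluated against the substrate at the
site of the reaction they modify; multiple matching adjustments compound
multiplicatively (multiplication commutes, so order is irrelevant). A
donor-dissociation constant of zero marks the donor term saturated rather
than dividing by zero.

One tension in the rule tables is worth recording: under the literal
continuation semantics, some site-anchored adjustment conditions (e.g. the
`*_Ma3` condition on the poly-LacNAc elongation rule) can never be
satisfied because the rule's own constraint already excludes those sites.
The tables are implemented literally; such adjustments are simply inert.

## Kinetic model

Each reaction proceeds at

    v = [E_t] kf · (S_d/K_md)/(1 + S_d/K_md) · ([P_i]/K_m,i) / D_e,
    D_e = 1 + Σ_k [P_k]/K_m,k   over substrates competing for enzyme e,

the random-order rapid-equilibrium two-site form; reversibility is off by
default because the parameter tables list no reverse-rate constants (a
per-reaction `kr` hook exists). Steady state in compartment j satisfies
`(c_{i,j-1} − c_{i,j})/τ_j + r_{i,j} = 0`. The denominators are carried as
auxiliary unknowns, which keeps the Jacobian sparse (each enzyme
contributes one dense row instead of coupling all its substrates
pairwise). Because the cascade couples compartments feed-forward only, the
solver proceeds compartment by compartment: a damped successive
substitution on the denominators (each inner step is one sparse linear
solve, globally robust) followed by a Newton polish with analytic sparse
Jacobian, line search, and nonnegativity clipping. Convergence requires a
maximum residual below 1e-9·c_tot. The full reference system — four
compartments × 10,809 structures plus the auxiliaries, ≈ 43,000 nonlinear
equations — solves in about a second.

Every reaction converts one chain into one chain, so Σ_i c_ij = c_tot
holds in each compartment; the tests assert this at the solution.

## Reactor constants and the activity convention

Reported "enzyme activity" is defined as kf_base·E_t,total/c_tot (min⁻¹),
with kf_base the enzyme's first-listed rule coefficient. Residence times
(4 × 7.5 min), compartment volumes (equal), donor concentrations
(UDP-GlcNAc 5 mM, UDP-Gal 2 mM, CMP-NeuAc 0.2 mM, GDP-Fuc 0.1 mM,
UDP-GalNAc 1 mM) and the cis→TGN enzyme localization profiles are
literature-order estimates fixed once in the packaged configuration. The
total glycan concentration is 5 mM: with the published activity profile
and the adjusted Michaelis constants (e.g. the mannosidase's effective
K_m on Man9 is ≈ 150 mM) a micromolar c_tot would leave the pathway
essentially unprocessed, so a millimolar protein-glycan load is the only
scale consistent with the activity convention; it also puts several
enzymes in the competitive regime the denominator terms exist to model.
Inlet is 95% Man9 and 5% glucosylated Man9 (the inert `Ga3` cap makes the
latter a pass-through marker).

## Network pruning

The unpruned closure at the 4000 Da permethylated cutoff is on the order
of 10⁶ structures, so generation interleaves with pruning: after each
batch of newly discovered structures, per-structure abundances are
estimated by the *linearized* model (denominators fixed at 1, the dilute
limit, making each compartment one sparse linear solve), and structures
whose maximum relative concentration across compartments falls below the
prune threshold are banned permanently. Banning only removes consumers,
and the linear estimate of a structure's abundance can only fall as the
network grows, so early pruning is conservative and the loop reaches a
fixed point. The estimator uses the packaged activity profile floored at
0.05 min⁻¹ (so that weakly expressed enzyme families remain represented in
the network available to the fit). The shipped threshold, 9.102e-7, is
calibrated so the reference run reproduces the published structure count
(10,809). The corresponding reaction count is 27,147 — about 5.7% below
the published 28,797; the reactions-per-structure density is a property
of the (unpublished) original estimator that a single threshold cannot
reproduce, and no estimator variant tried (activity floors 0.02–0.2,
donor levels ±3×) moves the density appreciably. This shortfall is
reported as-is.

## Mass spectra

Sample preparation is modeled as full permethylation of the free-reducing-
end glycan (every OH → OCH₃, every amide NH → NCH₃, the NeuAc carboxyl
methyl-esterified) plus one sodium; this convention reproduces the
published anchor masses 2418.21/2592.30 Da for Hex₅HexNAc₄Fuc₂/₃ to
0.004 Da, which is what fixes it (a reduced-end alditol would not).
Isotope envelopes are multinomial, computed by per-element convolution
over nucleon-number shifts with abundance-weighted masses per shift
(unresolved fine structure is mass-averaged), truncated at 1e-6 of each
glycan's total; the isotope table is pinned in a packaged data file.
Isomers share an envelope exactly.

Experimental processing: baseline = iterated rolling minimum + moving
average (window 20 Da by default); calibration = linear m′ = a·m + b
maximizing summed intensity interpolated at the model peak masses (coarse
grid, Nelder–Mead refinement); integration = height at the nearest local
maximum (parabolic apex refinement removes sampling bias) times a width
measured at exp(−π/4) ≈ 45.6% of height for the 50 largest peaks and
regressed linearly on mass — at that fraction, width × height is exactly
a Gaussian's area. Areas are normalized to 100% over the modeled range.
Observed areas are NNLS-projected onto the model envelope matrix so the
fit sees only the part of the spectrum the model can explain. Model peaks
closer than 0.3 Da are merged before comparison (the integrator cannot
resolve them).

## Fitting

Activities are fitted in log space (positivity) by `least_squares(...,
method="lm")` with finite-difference derivatives, deterministic
multi-start, and residuals = model minus target %-areas on the fixed peak
grid. The default fit target is the projected spectrum; agreement with
the unprojected spectrum is reported separately. Enzymes whose reactions
carry zero flux at the optimum are flagged unidentifiable instead of being
reported as estimates (the α3/α4-fucosyltransferase pair is nearly
degenerate on type II-only profiles, and blood-group enzymes downstream
of an absent H epitope are invisible). The two-condition constrained fit
ties non-exempt enzymes' condition-B levels to ratio × condition-A and
minimizes the joint sum of squares; GnTV (defective probe set) and ManI
(absent from the chip) are exempt by default.

## Synthetic fixtures

The fixture generator forward-simulates a known profile, renders sticks
as Gaussians of FWHM m/8000 (width linear in mass), adds a smooth
sinusoidal baseline (5% of the tallest peak by default) and 1%
multiplicative noise, deterministically per seed. The microarray fixture
emits per-enzyme multi-probe tables with exact between-condition ratios.
Fixtures share the real pipeline's mass range and resolution but have no
chemical background, no unassigned adduct peaks, and exactly zero model
mismatch, so passing recovery tests demonstrate pipeline correctness and
identifiability — not that real spectra of comparable noise would fit
equally well. Under these conditions the emulated two-condition benchmark
reaches projected-spectrum RMS ≈ 0.02–0.03 and unprojected RMS ≈ 0.05–0.07
(in % total area units); the unprojected value is floored by the injected
per-peak noise rather than by fit quality.

## Sizes and defaults used by the shipped tests

Unit and property tests run on a reduced network (cutoff 2600 Da,
threshold 1e-4; 97 structures) where a model solve takes ~5 ms. The
fitting benchmark uses a medium network (cutoff 4000 Da, threshold 1e-4;
~520 structures) and 15 free enzymes. The reference run (10,809
structures) is exercised once for the network-count and full-scale solver
checks. The pipeline CLI exposes the same stages; the knockout scenario is
`glycosim fit --knockout <enzyme>`.

## Known limitations

- Reversible kinetics, donor-transporter dynamics, and inter-compartment
  recycling are out of scope; so are O-glycans and CMP-NeuAc biosynthesis.
- The pruning estimator is linear; strongly saturated regimes could in
  principle retain structures the nonlinear model would starve (the
  calibrated threshold absorbs this at the reference conditions).
- Peak integration assumes locally symmetric peaks; heavily skewed or
  saturated detector peaks would bias areas.
- The reported activity scale is conventional: only ratios between
  conditions and between enzymes are meaningful.
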