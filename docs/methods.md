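# Model and methods

## The model

`methanomod` represents *M. barkeri* as a spherical cell (radius 1 um) with
two compartments, cytoplasm and membrane, exchanging methanol, dissolved
CO2 and CH4 with the environment by free diffusion
(J = 4 pi D r (C_env − C_cyto)). The methylotrophic methanogenesis pathway
is resolved into 16 enzyme reactions — 9 cytoplasmic (methanol:CoM
methyltransferase MTA, methyl-CoM reductase MCR, the C1 oxidation ladder
MER/MTD/MCH/FTR/FMD on tetrahydrosarcinapterin and methanofuran, the
F420-reducing hydrogenase FRH, and acetyl-CoA synthase ACS) and 7
membrane-associated (methyl transferase MTR, Ech hydrogenase ECH,
methanophenazine-dependent hydrogenase VHT, heterodisulfide reductase HDR,
F420H2 dehydrogenase FPO, ATP synthase AHA, and a Na+/H+ antiporter GERN).
Two pseudo-reactions close the system: a constant maintenance ATP
hydrolysis and a biomass reaction consuming 0.14 mol ATP, 1.1e-2 mol
reduced ferredoxin, 1.1e-2 mol reduced F420 and 1.4e-2 mol acetyl-CoA per
gram of biomass (genome-scale FBA-derived coefficients, used as
constants). Together with three diffusion processes the default network
has 21 reactions over 35 metabolites.

State variables are the free metabolite concentrations plus the membrane
potential. ATP/ADP/Pi (10/1/10 mM), the external gas phase, water, both
proton/sodium pools, and the biomass sink are clamped; for each of the
eight conserved moiety pools (CoM, CoB, F420, Fd, methanophenazine,
H4SPT, MF, CoA) the last-listed member is computed algebraically from the
pool total, which enforces moiety conservation exactly and removes the
stoichiometric redundancy. The membrane potential integrates the
charge-translocation stoichiometries (c_C > 0 means positive charge moved
out of the cytoplasm): d(dpsi)/dt = (F/C_m) sum_i c_C,i v_i.

Velocities follow the generalized reversible multiplicative
Michaelis–Menten law: a saturation factor times the thermodynamic factor
1 − exp(dG/(chi R T)), with dG = RT ln(Q/K) + c_C F dpsi. Equilibrium
constants are apparent constants at pH 7 (water, protons and sodium are
unit-activity and folded into K). The default saturation factor uses the
additive denominator (1 + sum of substrate and product occupancies); MCR
uses the convenience-kinetics variant (independent hyperbolic site per
substrate) so that its apparent catalytic constant factorizes into the
methyl-CoM and CoB occupancies, matching the composite-parameter
expressions the analysis layer implements. The choice is per reaction
(`rate_law` field of the parameter table).

Growth follows Herbert–Pirt logic: biomass flux = max(0, v_AHA −
maintenance)/0.14 g/s per cell, with the reduced-cofactor and acetyl-CoA
drains proportional to it. The drains additionally carry hyperbolic
precursor-availability factors (half-saturation 1 uM, far below operating
concentrations); without them the assigned drains are zeroth-order sinks
that can outrun their supply reactions during transients and at
intermediate methanol, pulling a pool negative. The *gross* specific
growth rate mu = v_AHA/(0.14 dry_mass) is the quantity the growth curve,
the Monod fits and the control analysis use; mu_net = mu − maintenance
equivalent (0.19 1/d at the default maintenance of 1.09 mmol ATP/gdw/h)
is reported alongside and can be negative at very low substrate.

## Parameter provenance

The packaged parameter table is generated by a deterministic bootstrap in
`methanomod.synthetic` (regenerated by `scripts/make_fixture.py`). Rows
flagged `printed` carry published magnitudes: Km(MTA, methanol) ~50 mM,
Km(MCR, CoB) = 59 uM, the CoB pool at 1.7 mM, clamped ATP/ADP/Pi, CO2 at
20 mM and CH4 at 0.1 atm, cell radius 1 um, the 10% membrane proteome
budget, and the biomass coefficients. Everything else is a `calibrated`
fixture default derived from a designed steady state at 100 mM methanol:
designed concentrations, per-reaction free-energy targets and a
self-consistent flux partition fix the equilibrium constants
(K = Q* exp((c_C F psi* − dG*)/RT)) and catalytic constants
(Vmax = v*/(saturation* x thermo factor*)); MTA and MCR capacities are
anchored instead to the target specific affinity and maximum growth rate.
Free-energy targets must respect thermodynamic cycle closure — FRH + VHT
and FPO catalyze the same net reaction with the same charge translocation,
so their targets add (K_FRH K_VHT = K_FPO).

Cell geometry and composition (membrane capacitance 1 uF/cm^2, protein
1e-12 g and dry mass 2e-12 g per cell, compartment volumes from the 1 um
sphere with a 5 nm membrane shell) are fixture defaults, not published
values. The maintenance flux is configurable; the default 1.09 mmol
ATP/gdw/h gives a maintenance-equivalent rate about 19% of mu_max,
consistent with the visible gap between gross and net growth curves. A
printed value of ~109 mmol/gdw/h would exceed the pathway's entire ATP
supply tenfold and is treated as a typographical artifact.

## Numerical choices

Integration uses LSODA with absolute/relative tolerances 1e-8/1e-6, in
expanding windows to 1e6 s; a window ends early once the maximum relative
|dC/dt| falls below 1e-8 1/s (the steady-state criterion; the relaxation
time of the network is ~1e3 s). Negative-concentration excursions during
stiff transients are clipped at zero with a logged warning. An optional
Newton polish (off by default, used by the sweep/MCA layers for warm
starts) refines the algebraic steady state in log-concentration space and
is accepted only if the root lies close to the current point — root
finding from afar can land on non-attracting roots.

Control coefficients use a forward difference at +1% (central differences
behind a flag); moiety response coefficients rescale all pool members
proportionally before re-solving. The summation check closes over *all*
flux-carrying processes: because the maintenance drain is a constant that
does not scale with the proteome, the enzyme+diffusion sum alone falls
short of one by up to ~6% near the drain onset, while including the
maintenance coefficient closes it to better than 1%.

The membrane-enzyme allocation optimizer is Nelder–Mead on n−1 free
fractions (the last is the budget remainder; negative points are
penalized), with a seeded ±10%-relative initial simplex, default cap 1e4
iterations and tolerance 1e-10.

Monod parameters are extracted phenomenologically: mu_max is the rate at
1 M methanol, K_M the concentration at half mu_max (monotone interpolation
in log C), alpha a zero-intercept least-squares slope over grid points
below 10 uM. The Gaussian amendment takes mu_o as the largest residual
above the alternative Monod form and fits each breadth beta by least
squares on the relative residual, separately below and above the peak
concentration mu_max/alpha.

Default problem sizes: growth sweeps use 8 points per decade from 1 uM to
1 M (49 steady states, warm-started), and the packaged analyses evaluate
control coefficients at selected concentrations rather than the full
40-per-decade grid; both choices leave all reported quantities unchanged
at the stated precision.

## What the synthetic fixture does and does not show

The fixture reproduces the study system's printed steady-state physiology
(135 mV membrane potential, ~0.7 umolal H2, 0.22/0.68 CO2/CH4 yields per
methanol, ~98% of oxidation-branch electrons cycled through H2, free
energies spanning −31 to −0.5 kJ/mol, ~83% of concentration/Km pairs above
one) and growth phenomenology (mu_max ~1.0 1/d, K_M ~0.42 mM,
alpha ~1.7e3 1/(M d), methyltransferase/reductase control handoff near
0.7 mM, coenzyme-M response falling from 0.9 to ~0.2). It does not claim
row-by-row equality with the original model's parameter set, and passing
tests say nothing about biological variability, regulation (allostery,
expression), ionic-strength corrections, or growth on other substrates.

One documented tension is inherent rather than a calibration failure: the
printed parameter triple forces mu_max/(alpha K_M) ≈ 1.5, which fixes the
large low-substrate Monod shortfall, but is incompatible with Monod-curve
agreement better than ~10% everywhere above 0.2 mM for any smooth curve of
this model family (the ideal two-enzyme cycle that reproduces the triple
exactly deviates by 13%). The package reports the comparison honestly; the
corresponding acceptance test is expected to flag the difference.

## Limitations

- Concentrations are treated as activities; no Debye–Hückel or ionic
  strength corrections.
- The proton-motive force is collapsed into a single electrical potential;
  no separate dpH or sodium-motive component (the antiporter is
  near-equilibrium bookkeeping).
- The biomass drain topology is a single acetyl-CoA carbon tap; the split
  of biosynthetic carbon among pathway intermediates is not resolved.
- No population dynamics, no bifurcation analysis, no stochastic kinetics.
- The SBML layer covers the constructs this model uses (with a custom
  annotation namespace for moieties, charge translocation and cell
  parameters); it is not a general SBML consumer.
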