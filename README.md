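# methanomod

A kinetic/stoichiometric model of *Methanosarcina barkeri* growing on
methanol, built to ask what the Monod equation does — and does not —
capture about a real metabolic network.

The package simulates the methylotrophic methanogenesis pathway (16
enzymes in two compartments, 35 metabolites, 8 conserved cofactor moiety
pools, free diffusion of methanol/CO2/CH4, and an explicitly tracked
membrane potential) with thermodynamically constrained reversible
Michaelis–Menten kinetics,

    v_i = W_prot k_i phi_i * saturation(C; K_m) * [1 - exp(dG_i/(chi_i R T))]
    dG_i = RT ln(Q_i / K_i) + c_C,i F dpsi,

couples the pathway to growth through a Herbert–Pirt split of the ATP
synthase flux (maintenance first, the surplus into a pseudo-biomass
reaction with genome-scale-derived stoichiometry), and analyses the result
with metabolic control analysis (scaled coefficients
eps_i = (phi_i/mu) dmu/dphi_i) and Monod-equation parameter extraction:

    mu = mu_max C / (C + K_M)            (Monod)
    mu = mu_max alpha C / (mu_max + alpha C)   (alternative form)
    mu = alt. form + mu_o exp[-pi (ln(mu_max/(alpha C))/beta)^2]  (amended)

It is aimed at microbial physiologists and systems-biology modelers who
want a working, tested example of growth kinetics emerging from enzyme
kinetics, membrane energetics and moiety conservation — and of how the
phenomenological parameters mu_max, K_M and alpha map onto the
rate-determining enzymes (methyl-CoM reductase at high methanol,
methanol:CoM methyltransferase at low methanol) and the coenzyme M pool.

## Worked example

```python
from methanomod import default_model, solve_steady_state
from methanomod.growth import yield_report
from methanomod.diagnostics import electron_flux_partition

model = default_model()            # packaged parameterization, 100 mM methanol
ss = solve_steady_state(model, polish=True)
print(f"psi  = {ss.state.psi*1e3:.1f} mV")
print(f"mu   = {ss.mu*86400:.3f} 1/d (net {ss.mu_net*86400:.3f} 1/d)")
print(f"H2   = {ss.state.conc['h2']*1e6:.2f} umol/L")
y = yield_report(ss)
print(f"CO2, CH4 per methanol = {y['co2_per_methanol']:.3f}, "
      f"{y['ch4_per_methanol']:.3f}")
print(f"H2-cycling share = "
      f"{electron_flux_partition(ss, model)['h2_cycling']:.3f}")
```

prints

```
psi  = 135.1 mV
mu   = 1.002 1/d (net 0.815 1/d)
H2   = 0.71 umol/L
CO2, CH4 per methanol = 0.220, 0.681
H2-cycling share = 0.978
```

i.e. at laboratory methanol the cell holds a 135 mV membrane potential,
grows at about one doubling per day, keeps dissolved H2 below a micromolar
while cycling ~98% of the oxidation-branch electrons through it, and emits
fewer CO2 and CH4 per methanol than the catabolic stoichiometry (1/4 and
3/4) because biosynthesis drains carbon and reducing power.

The same model drives a command-line pipeline:

```
methanomod simulate --methanol 100
methanomod sweep --min 0.001 --max 1000 --per-decade 8 --out curve.tsv
methanomod monod-fit curve.tsv --out fit.json
methanomod mca --min 0.01 --max 100 --out profile.tsv
methanomod diagnostics --methanol 100 --out-dir reports/
```

`monod-fit` on the packaged model's sweep yields mu_max ≈ 1.0 1/d,
K_M ≈ 0.42 mM and alpha ≈ 1.7e3 1/(M d); the control-coefficient profile
shows the methyltransferase dominating growth control below ~0.2 mM, the
reductase above ~15 mM, and the coenzyme M pool's response coefficient
falling from ~0.9 to ~0.2–0.3 across that range.

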