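# ecathsim

A reaction–diffusion simulator for **electrochemical catheters**: central
venous catheters that generate the biocide hypochlorous acid (HOCl) in
situ by electrolysis of the 0.9% NaCl saline they are filled with, to
prevent catheter-associated bloodstream infections. The package is aimed
at device designers and modelers who need to know how much HOCl a given
electrode layout and operating potential delivers to each part of the
lumen — hub, Luer connectors, and tube — and on what time scale.

## Model

A working electrode (WE, anode) held at potential φ_we oxidizes chloride,

    Cl⁻ + H₂O ⇌ HOCl + H⁺ + 2e⁻     (i_we)
    2H⁺ + 2e⁻ ⇌ H₂                   (i_ce, counter electrode)

with Butler–Volmer current densities

    i = i₀ [ e^{(1−α)Fη/RT} − e^{−αFη/RT} ],   η = φ_applied − E,

where E is the local Nernst potential computed from standard potentials
(V vs Ag/AgCl) and local concentrations; Faraday's law r_e = −i/2F
converts current into species surface fluxes. In solution, HOCl
dissociation and water autoionization are treated kinetically with large
reversible rates, and four irreversible reactions degrade HOCl to Cl⁻,
ClO₂⁻ and ClO₃⁻ with Arrhenius temperature dependence. Each species obeys

    ∂c_i/∂t = D_i ∇²c_i + R_i,     D_i = D_{i,298K} (T/298K)^{3/2},

solved by an implicit (BDF) method of lines on a 1D finite-volume grid
with variable fluid cross-section along the hub → Luer → tube stack
(25 °C in the hub and connectors, 37 °C in the implanted tube), no-flux
ends, and electrode wires coupled through their lateral surface area.
See `docs/methods.md` for the full parameter set and numerical choices.

## Worked example

Run the baseline design — WE and CE in the hub only, 48 h at
1.5 V vs Ag/AgCl — and read off the dosimetry:

```python
from ecathsim import run_config, scenario_config

result = run_config(scenario_config("scenario1"), "out/s1")
print(result.extremum("HOCl", 48 * 3600))            # domain max, mM
print(result.volume_average("tube", "HOCl", 48 * 3600))
```

This prints `0.8199309784352355` and `0.0029305295220677257`: after 48 h
the model holds ≈0.82 mM HOCl at the top of the hub — within the
0.5–2 mM range reported to inhibit common catheter colonizers — while
the tube average stays near zero (≈0.003 mM), because diffusion over the
0.3 m tube is far slower than the 48 h polarization. The run directory
contains `summary.json` (extrema, per-compartment averages and pH, charge
passed, conservation audit), tidy `volume_averages.csv`, and per-snapshot
`profiles.csv`. The summary for this run reports, e.g.,

```json
"compartment_final_HOCl_mM": {"hub": 0.7829, "luer_top": 0.5476,
                              "luer_bottom": 0.2779, "tube": 0.0029},
"min_pH": 2.616,
"net_charge_passed_C": 0.2851,
"audit": {"chlorine_drift": 8.5e-16, "flagged": false}
```

i.e. the hub acidifies to pH ≈ 2.6 (unbuffered saline; H⁺ is produced by
both chloride oxidation and HOCl degradation) and total chlorine is
conserved to machine precision.

The same is available from the shell:

```sh
ecathsim run --scenario scenario3 --out out/s3
ecathsim sweep --scenario scenario1 --out out/sweep \
    --parameter we_potential --values 1.5,1.7,1.9
ecathsim audit out/s3
```

Presets cover the four design studies: hub-only electrodes
(`scenario1`, plus `scenario1_relax` with 120 h open-circuit
relaxation), raised WE potential (`scenario2_1.7V`, `scenario2_1.9V`),
a WE extended through the whole tube (`scenario3`), and the extended WE
with per-compartment diameters chosen to equalize wire-area per fluid
volume (`scenario4`). Custom YAML configurations (any preset as a base,
any parameter overridden) are accepted via `--config`.

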