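# Model and methods

`ecathsim` simulates in-situ hypochlorous acid (HOCl) generation inside a
saline-filled intravascular catheter fitted with electrodes ("e-catheter").
A working electrode (WE) held at a fixed anodic potential oxidizes chloride,

    Cl⁻ + H₂O ⇌ HOCl + H⁺ + 2e⁻            (working electrode, anode)
    2H⁺ + 2e⁻ ⇌ H₂                          (counter electrode, cathode)

and the generated biocide speciates, degrades and diffuses along the lumen.
This note records the governing model, the numerical choices, and the
places where the design was genuinely open.

## Species and homogeneous chemistry

Ten species are tracked: HOCl, ClO⁻, ClO₂⁻, ClO₃⁻, O₂, H⁺, H₂, OH⁻, Cl⁻,
Na⁺. Two acid–base equilibria are treated *kinetically* with large but
finite reversible rates, so that equilibrium is a fast fixed point of the
ODE system rather than an algebraic constraint:

    r_a,HOCl = k_a (c_HOCl − c_ClO⁻ c_H⁺ / K_a,HOCl),     k_a = 1000 s⁻¹
    r_a,H₂O  = k_a* (1 − c_OH⁻ c_H⁺ / K_a,H₂O),           k_a* = 1000 mol m⁻³ s⁻¹

with K_a,HOCl = 3.16×10⁻⁵ mol m⁻³ and K_a,H₂O = 10⁻⁸ mol² m⁻⁶. Four
irreversible reactions degrade HOCl (rate laws in mol m⁻³ s⁻¹ after SI
conversion; constants at their literature reference temperatures):

| reaction | rate law | k(T_ref) | T_ref | E_a (kcal/mol) |
|---|---|---|---|---|
| HOCl → H⁺ + Cl⁻ + ½O₂ | K₀ c_HOCl | 4.65×10⁻⁴ min⁻¹ | 30 °C | 19 |
| 2HOCl → 2H⁺ + Cl⁻ + ClO₂⁻ | K₁ c²_HOCl | 0.45 L mol⁻¹ min⁻¹ | 30 °C | 15 |
| HOCl + ClO₂⁻ → H⁺ + Cl⁻ + ClO₃⁻ | K₂ c_HOCl c_ClO₂⁻ | 3×10⁻³ L mol⁻¹ min⁻¹ | 30 °C | 15 |
| HOCl + ClO⁻ → H⁺ + Cl⁻ + ClO₂⁻ | K₃ c_HOCl c_ClO⁻ | 7.5×10⁻⁶ L mol⁻¹ min⁻¹ | 60 °C | 15 |

Species rates are ν·r with the signed stoichiometric coefficients of the
balanced equations (so the second-order reaction consumes two HOCl per
rate unit). Chlorine atoms balance identically in every reaction; this is
asserted exactly in the tests. Rate constants are moved from their
reference temperature to the local cell temperature with the Arrhenius
correction k(T) = k_ref exp(−(E_a/R)(1/T − 1/T_ref)), R = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹; activation energies are read as kcal/mol, the only
dimensionally consistent reading of the tabulated "kcal" entries. HCl,
HClO₂ and HClO₃ are treated as fully dissociated strong acids, so the
degradation network is written directly in ionic form. Chlorate carries
charge −1. Two tabulated rate constants (k_HOCl = 3.4, k_ClO = 4.4×10⁴
m³ mol⁻¹ s⁻¹, with activation energies 7.7 and 11.6 kcal/mol) are not
attached to any reaction in the documented network; they are parsed and
stored but inert by default.

The initial electrolyte is unbuffered saline: c_H⁺ = 1000·10^(−pH₀),
c_OH⁻ = K_a,H₂O/c_H⁺, c_Na⁺ = C_NaCl, and c_Cl⁻ from electroneutrality
(acidity supplied as dissociated HCl); defaults pH₀ = 5.5, C_NaCl =
154.04 mol m⁻³ (0.9% NaCl). All other species start at zero.

## Electrode kinetics

Electrode potentials are fixed (highly conductive wires) and the solution
potential is zero (highly conductive saline), so the overpotential is
η = φ_applied − E with E the local Nernst potential:

    E_we = E⁰_we − (RT/2F) ln[(c_H⁺/c_ref)⁻¹ (c_HOCl/c_ref)⁻¹ (c_Cl⁻/c_ref)]
    E_ce = E⁰_ce − (RT/2F) ln[(c_H⁺/c_ref)⁻² (c_H₂/c_ref)]

with E⁰_we = 1.297 V and E⁰_ce = −0.197 V vs Ag/AgCl. The reference
concentration c_ref is not tabulated with the other parameters; the 1 M
standard state (1000 mol m⁻³) is used, consistent with standard-state
redox potentials. Current densities follow the Butler–Volmer law as
documented for this system,

    i = i₀ [exp((1−α)Fη/RT) − exp(−αFη/RT)],

anodic positive, with i₀ = 0.032 / 0.003 A m⁻² and α = 0.95 / 0.05 for
WE / CE. Exponent arguments are capped at ±50; the cap never binds at
operating potentials (|η| ≲ 1 V). Faraday's law converts current density
to the reduction-direction area rate r_e = −i/(2F), and species surface
fluxes are the reduction stoichiometry times r_e: positive anodic current
at the WE therefore produces HOCl and H⁺ and consumes Cl⁻.

At t = 0 the Nernst logarithms of the product species (HOCl, H₂) are
singular; concentrations are floored at ε = 10⁻¹² mol m⁻³ *inside
logarithms and rate laws only* (the state itself is never clamped). The
floor sets the (large but finite) initial driving force. Sensitivity of
48 h results to ε is negligible because the anodic exponent is shallow
((1−α)F/RT ≈ 1.95 V⁻¹): moving ε by three decades changes the initial
current by ~20% and the 48 h HOCl maximum by < 0.1%, since the system is
kinetically, not thermodynamically, limited after the first minutes.

## Geometry and transport

The catheter is a stack of four cylindrical segments — hub (32.6 mm ×
5.4 mm ⌀), Luer-lock top (6.4 mm × 4.0 mm), Luer-lock bottom (12.2 mm ×
1.6 mm) and tube (300 mm × 1.6 mm) — 351.2 mm in total. The hub and
connectors sit at 25 °C, the implanted tube at 37 °C; diffusivities scale
as D = D₂₉₈ (T/298 K)^{3/2}. O₂ is tracked as a degradation product but
has no tabulated diffusivity; the textbook 2.0×10⁻⁹ m² s⁻¹ for O₂ in
water at 25 °C is used.

Because the dominant gradient is axial (radial diffusion across the hub
equilibrates in ~2 h versus 48 h runs), the lumen is reduced to a 1D
finite-volume chain with variable fluid cross-section (lumen minus wire
area). Electrode wires couple to the balance through their lateral area
per cell, a_k = π d_wire Δx, converting surface fluxes to volumetric
sources a_k/V_k × flux; Nernst/Butler–Volmer concentrations are the local
cell values. Consequences of the reduction: "maximum near the WE surface"
becomes the axial maximum over wire-bearing cells, and radial
boundary-layer enhancement (estimated ≲ 0.1 mM for these currents) is not
resolved. The CE shares the hub's axial extent with the WE; its 1.47 mm
radial offset has no 1D meaning and is dropped. Temperatures are
segment-wise constant with a jump at the connector/tube junction; no heat
equation is solved.

Interior faces use a two-point flux in which each half-cell contributes
its own diffusive resistance (Δx/2)/(A D). This is exact for
piecewise-linear steady profiles across segment junctions, where the
cross-section jumps (the junction aperture is the smaller of the two
adjoining sections, taken as a zero-thickness constriction); within a
uniform segment it reduces to the standard A·D·∇c face flux. Both domain
ends are no-flux. An earlier variant that divided the minimum face area
by the center-to-center distance converged only at first order across
junctions and could not meet the 1% grid-convergence requirement;
the resistance form does.

## Time integration

The kinetic equilibria make the system stiff (Jacobian scales of
k_a c_H⁺/K_a ~ 10⁵ s⁻¹ against 10⁵–10⁶ s horizons), so the method of
lines uses SciPy's variable-order BDF with a supplied Jacobian sparsity
pattern: a dense 10×10 species block per cell plus same-species coupling
to neighbor cells. Tolerances default to rtol 10⁻⁶, atol 10⁻⁹ mol m⁻³
(overridable). Polarization phase boundaries are hard integrator
restarts; switching polarization off removes the electrode sources (open
circuit), with no potential ramp. The solver may produce transient
negative concentrations of order atol; rate laws see max(c, 0) and
logarithms max(c, ε), and any persistent negative beyond −10·atol aborts
the run. Default resolution is 30/5/10/200 cells for
hub/Luer-top/Luer-bottom/tube (245 cells, 2450 unknowns); a 48 h scenario
integrates in a few seconds on one CPU, and halving Δx changes 48 h
compartment-average HOCl by < 1%.

## Scenario presets

All presets polarize at WE 1.5 V / CE −0.6 V vs Ag/AgCl for 48 h with
0.245 mm wires unless stated: **scenario1** hub-only WE and CE;
**scenario1_relax** adds 120 h open circuit; **scenario2_1.7V/1.9V**
raise the WE potential; **scenario3** extends the WE through the
connectors and tube; **scenario4** uses a 0.615 mm WE in the hub and a
0.054 mm WE below it, equalizing wire-area/fluid-volume between hub and
tube to within 2%. Default snapshots are the 8 h reporting grid (hourly
for scenarios 3–4, whose tube transients peak between snapshots; 24 h
steps during relaxation).

## Verification

Independent oracles (no code shared with the solver): the erfc closed
form for reaction-free step diffusion (agreement ≤ 1% before the walls
are felt); a deliberately naive fixed-step RK4 batch integrator with step
doubling to 10⁻⁸ self-consistency for the 0D chemistry (agreement ≤ 0.1%;
run at reduced equilibrium rate constants where explicit stability
demands it, and on the degradation-only network at physical constants).
Exact audits: chlorine-atom and sodium totals (drift ≤ 10⁻⁴ over full
scenario runs; observed ~10⁻¹⁴), and the charge ledger d/dt ΣzᵢcᵢV =
(I_we + I_ce)/F, verified instantaneously from the assembled right-hand
side at every snapshot rather than by quadrature between snapshots, which
would add O(10%) error from the fast initial current decay. Monotonicity
properties (Butler–Volmer in η, Arrhenius in T, WE current decay under
constant potential via Nernst product feedback, potential ordering of
48 h maxima) are asserted on the actual scenario runs.

## Known limitations

* The reduced-dimension model cannot resolve radial boundary layers at
  the wire surface or around the radially offset CE.
* Ionic migration and convection are excluded by construction (zero
  solution potential, stagnant fluid), as is Cl₂ gas chemistry (generated
  HOCl stays below Cl₂ solubility) and any interaction with biological or
  pharmaceutical material in the lumen.
* Dissolved O₂ and H₂ accumulate without outgassing.
* The published reference values for these scenarios come from a 3D
  finite-element solution whose reported concentrations imply a
  substantially larger Faradaic charge yield than the documented
  electrode equations produce; see the quantitative-reproduction tests,
  which compare this model's outputs to those values at a ±20% band and
  record where the documented physics lands below them. The
  hard property suite, not the reproduction band, is the correctness
  contract of this package.
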