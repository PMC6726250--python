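# Methods

## Model structure

The simulator integrates an eleven-variable open-cell model of hepatocyte
Ca²⁺ dynamics.  Four Ca²⁺ pools are represented: the bulk cytosol, the
mitochondria-associated ER membrane microdomain (MAM), the mitochondrial
matrix, and the ER lumen.  The ER concentration is not a state variable:
total intracellular Ca²⁺ `C_t` is tracked explicitly (driven only by
plasma-membrane entry and PMCA efflux), and `C_ER` is recovered
algebraically from `C_t` and the other pools through the volume ratios
(`R_V1` cytosol:MAM = 2000, `R_V2` cytosol:ER = 10, `R_V3`
cytosol:mitochondria = 15) and free-Ca²⁺ fractions (`f_c` = 0.01 for
cytosol/MAM/ER, `f_m` = 3·10⁻⁴ for mitochondria).  Keeping `C_t` as the
integrated quantity makes total-Ca²⁺ bookkeeping exact: with the
plasma-membrane fluxes removed the model is closed and `C_t` is constant
to solver tolerance (this is a test).

IP₃ receptor gating uses the two-mode park/drive scheme.  Of the six
gating variables, four (m₂₄, h₂₄, m₄₂, m_n42) relax much faster than the
rest and are evaluated at their quasi-equilibria inside the right-hand
side; only the slow inactivation gates h₄₂ (bulk receptors) and h_n42
(MAM receptors) are integrated.  Their relaxation rates interpolate
between the park-mode recovery rate `L_IPR` = 0.02 s⁻¹ and the drive-mode
inhibition rate `H_IPR` = 0.1 s⁻¹ according to the drive-mode fraction.
The Ca²⁺ concentration sensed at the receptor pore is
`C_p = C_p0 · C_ER / 680`, with 680 µM treated as a fixed reference ER
concentration (a constant of the gating fit, not a tunable parameter).
The fifteen-variable model without the quasi-steady-state reduction is not
implemented.

Mitochondrial metabolism follows the standard lumped description: ATP
hydrolysis (including the SERCA ATP cost, one ATP per two Ca²⁺ pumped),
the adenine nucleotide translocator, the F₁F_O-ATPase, pyruvate
dehydrogenase, NADH oxidation by the electron transport chain, the
Ca²⁺-stimulated aspartate–glutamate carrier, and an ohmic proton leak.
ATP_c, ATP_m and NAD⁺ are never integrated; they are recovered from the
conserved totals (`A_tot_cyt` = 2500 µM, `A_tot_mito` = 15000 µM,
`N_tot_mito` = 250 µM), so the conservation laws hold identically.

### Ambiguous algebraic forms

Two rate laws are typeset ambiguously in the published description and
were resolved against the cited source models (Magnus–Keizer via the
Wacquier formulation):

* **MCU**: the allosteric term is `L_MCU / (1 + C/K₂)^2.8` (divided, not
  multiplied) — `K₂` is the *activation* constant, so the term must shrink
  as Ca²⁺ rises.
* **ANT**: the thermodynamic factors are `exp(−F·V_m/(R·T))` in the
  numerator and `exp(−0.5·F·V_m/(R·T))` in the denominator.  The
  positive-exponent reading would drive the translocator backwards
  (cytosolic ATP imported into the matrix) at physiological V_m ≈ 150 mV.
* **NCX**: `V_NCX · (C_mito/C_source) · exp(p₂·V_m)`, the source-side
  concentration read as a ratio (thermodynamic driving-force form); the
  source concentration is floored at 10⁻¹² µM.
* **h₂₄ quasi-equilibrium**: implemented with squared exponents,
  `k₋₂₄² / (C_p² + k₋₂₄²)`, as printed.

## Stimulation

IP₃ relaxes to a piecewise-constant target `P_s(t)` at rate
`τ_p` = 0.1 s⁻¹; square pulses add a constant production rate M (µM/s) on
the open interval (t₀, t₀+Δ), so a pulse with M = 10, Δ = 0.2 delivers
≈ 2 µM of IP₃.  Every protocol breakpoint (segment edge, pulse edge) is a
hard integrator restart, and within each piece the stimulus is a true
constant, so square pulses are represented exactly rather than smoothed.
The target is right-continuous at steps; the pulse is zero at both edges
(Heaviside convention H(0) = 0) — a measure-zero choice fixed for
determinism.

## Numerics

* **Integrator**: LSODA (Adams/BDF switching; the system is stiff, with
  effective rates from ω_c = 10⁻³ s⁻¹ up to the metabolic and gating
  scales), rtol 10⁻⁸, per-variable atol (10⁻¹⁰ µM for concentrations,
  10⁻⁸ for gates, 10⁻⁶ mV for V_m).  Halving the tolerances moves spike
  times by < 0.1 s and peaks by < 0.1% (tested).
* **Rest state**: every protocol simulation starts from the `P_s` = 0
  steady state of its parameter set, obtained by 5000 s of relaxation
  followed by Newton polishing; convergence means a state-scaled residual
  sup-norm below 10⁻⁹.  At this state the net SERCA flux vanishes, which
  pins `C_cyt/C_ER = √k̄` (10⁻⁴ for control; verified to 10⁻⁶ relative in
  tests), and the MAM inactivation gate sits at h_n42 ≈ 0.998.  Rest
  states are cached per parameter set.
* **Output grid**: uniform, default 0.1 s; 0.01 s for pulse transients
  where peak heights feed finite differences.  Transient peaks are refined
  by quadratic interpolation through the three samples around the grid
  argmax.

## Analysis conventions

* **Spike detection**: prominence-based local maxima (scipy
  `find_peaks`), prominence ≥ 0.2 × the window's dynamic range, minimum
  separation 2 s (MAM spikes are narrow).  Checked against a brute-force
  O(n²) local-extremum oracle on synthetic spike trains.
* **Frequency**: (spike count − 1)/(last − first spike time); zero with a
  flag when fewer than two spikes.
* **Condition comparisons** (frequency, mitochondrial level) use the full
  two-hour window from stimulation onset.  For per-window oscillation
  metrics elsewhere, the first 300 s after a step are discarded (the MAM's
  large stimulation-onset spike would otherwise dominate the prominence
  scale).  "Average mitochondrial level" is reported as the time average;
  the average of inter-spike baselines is computed alongside, since either
  reading is defensible.
* **Sensitivities**: one-sided forward differences at +0.1%, exactly as
  the published table describes (no central differences).  Each perturbed
  parameter set is re-equilibrated to its own rest state before the pulse
  — this convention reproduces the published k̄ row almost exactly,
  whereas sharing the baseline initial state flips its sign, so
  re-equilibration is clearly the right reading.  The baseline run is
  shared across parameters.
* **Oscillation cessation**: a staircase segment counts as oscillating if,
  after a 100 s post-step margin, at least 3 cytosolic spikes are detected
  *and* spiking persists to the segment end (last spike within 2 median
  interspike intervals of the end).  The persistence clause distinguishes a
  sustained limit cycle from the damped 2–3-spike burst that follows a
  step into the saturated high-IP₃ regime; without it the obesity model's
  dying burst at P_s = 0.9 µM would be misread as oscillation.

## Validation status and known discrepancies

The implementation reproduces, from the printed equations alone: the
drive-mode open probability (0.724), sustained oscillations at
P_s = 0.3 µM with exactly four MAM spikes per cytosolic spike, the
MAM/cytosol/ER concentration hierarchy, the obesity-vs-control frequency
increase (+19.2%, published ≈ +19%), the qualitative metabolic phenomenology
(V_m, NADH and ATP rising at spike onset with slow relaxation), the
V_nSERCA, H_IPR and h_n42(0) orderings, the staircase result (obesity
ceases oscillating at P_s = 0.9 µM vs 1.2 µM for control), and 21 of 24
sensitivity signs with close magnitudes (k_IPR → C_cyt peak 2.13 vs 2.11;
V_MCU → C_mito peak 0.795 vs 0.785; k̄ rows within a few percent).

Two mitochondrial-amplitude quantities deviate from the published values:
the obesity model's average mitochondrial Ca²⁺ level comes out +49%
(time average; +63% for the baseline definition) against a published
≈ +86%, and the synthetic-linker normalized transient peak comes out 1.43
against a published ≈ 1.2 (the linker surface ratio was tuned by the
original authors to hit 1.2 in their implementation).  Both quantities
scale with the MCU flux, which multiplies `exp(p₁·V_m)` with
p₁ = 0.1 mV⁻¹ — a few-mV difference in the membrane-potential trajectory
changes mitochondrial amplitudes substantially while leaving cytosolic
observables nearly untouched.  Since the metabolic rate laws are exactly
the part of the printed model where typesetting lost information (the ANT
exponents above), we regard these two gaps as inherited from the printed
source rather than resolvable here; the corresponding tests are left
failing rather than loosened.  Three sensitivity signs (k_nIPR → C_cyt in
both conditions, R_S2 → C_cyt under obesity, the latter two with published
magnitudes ≤ 0.032) also disagree.

## Limitations

The model is deterministic and spatially homogeneous per compartment —
stochastic receptor gating, Ca²⁺ microgradients and ER–plasma-membrane
junctions are out of scope.  Glycolysis is a single constant, so the model
is not suitable for studying obesity effects *on metabolism* (as opposed
to Ca²⁺ handling).  Parameter conditions are qualitative representations
of expression-level changes, not fitted protein quantifications.
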