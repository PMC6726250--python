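# mamcal

Deterministic ODE modelling of intracellular Ca²⁺ dynamics in mouse
hepatocytes, with an **explicit mitochondria-associated ER membrane (MAM)
compartment** coupled to a lumped model of mitochondrial metabolism.  The
package is aimed at computational cell biologists studying ER–mitochondria
Ca²⁺ crosstalk and how obesity-linked changes in channel expression and MAM
formation reshape Ca²⁺ signals.

## The model

The cell is divided into four well-mixed Ca²⁺ pools — bulk cytosol
(C_cyt), MAM microdomain (C_MAM), mitochondrial matrix (C_mito) and ER
lumen (C_ER) — plus the total intracellular Ca²⁺ C_t, which is governed
only by plasma-membrane fluxes.  C_ER is recovered algebraically from the
total:

    C_ER = R_V2 f_c ( C_t − C_MAM/(R_V1 f_c) − C_cyt/f_c − C_mito/(R_V3 f_m) )

where the R_V are cytosol:compartment volume ratios (the MAM is 1/2000 of
the cytosolic volume, which is why small fluxes produce tens-of-µM MAM
spikes) and f_c, f_m are free-Ca²⁺ fractions.

ER Ca²⁺ release goes through IP₃ receptors with two-mode **park/drive
gating**: the receptor population switches between a mostly-closed park
mode and a drive mode with open probability q₂₆/(q₂₆+q₆₂) ≈ 0.72.  Fast
gates are held at quasi-equilibrium, so only the two slow inactivation
gates (h₄₂, h_n42) are integrated and the state space is 11-dimensional:

    C_cyt, C_MAM, C_mito, C_t, P (IP₃), h42, hn42, ADP_c, ADP_m, N (NADH), V_m

Fluxes: IPR release into cytosol and MAM, SERCA reuptake from both (with
reverse term k̄·C_ER², so at rest C_cyt/C_ER = √k̄), Magnus–Keizer MCU
uptake and NCX extrusion on both mitochondrial membrane sectors (weighted
by the MAM surface ratios R_S1, R_S2), MAM↔cytosol diffusion, and
plasma-membrane entry (leak + SOCC + ROCC) and PMCA efflux.  Mitochondrial
metabolism (ATP hydrolysis, ANT, F₁F_O-ATPase, pyruvate dehydrogenase,
NADH oxidation, aspartate–glutamate carrier, proton leak) drives the
inner-membrane potential V_m, which feeds back on MCU/NCX exponentially.

Three named conditions ship with the package:

* `control` — lean wild-type hepatocyte (the default constant table);
* `obesity` — ob/ob overrides: R_S1 = R_S2 = 0.3, k_IPR = 0.35 s⁻¹,
  k_nIPR = 0.3 s⁻¹, V_MCU = 1.3·10⁻⁵ µM s⁻¹, k̄ = 1.25·10⁻⁸;
* `linker` — synthetic ER–mitochondria linkers: R_S1 = R_S2 = 0.48.

## Worked example

```python
from mamcal import StimulusProtocol, integrate, oscillation_summary
from mamcal.analysis import mam_spikes_per_cytosolic_spike
from mamcal.scenarios import build_parameters

params = build_parameters("control")
protocol = StimulusProtocol.constant(0.3, t_end=900.0)   # P_s = 0.3 µM
traj = integrate(params, protocol, output_dt=0.05)        # starts from rest

cyt = oscillation_summary(traj, "C_cyt", window=(300, 900))
mam = oscillation_summary(traj, "C_MAM", window=(300, 900))
print(f"cytosolic spikes: {cyt.n_spikes}, frequency {cyt.mean_frequency:.4f} Hz")
print(f"MAM spikes: {mam.n_spikes}, mean peak {mam.spike_peaks.mean():.1f} uM")
print(f"MAM spikes per cytosolic spike: "
      f"{mam_spikes_per_cytosolic_spike(traj, (300, 900)):.0f}")
```

prints

```
cytosolic spikes: 4, frequency 0.0072 Hz
MAM spikes: 18, mean peak 16.3 uM
MAM spikes per cytosolic spike: 4
```

i.e. sustained cytosolic oscillations with a ~140 s period, MAM Ca²⁺
spikes an order of magnitude higher than the ~2.6 µM cytosolic peaks (and
well below the ~500 µM ER level), and four MAM spikes per cytosolic spike
— the MAM fires faster because its post-spike Ca²⁺ floor stays elevated,
re-priming Ca²⁺-induced Ca²⁺ release sooner.

The same machinery is scriptable from the shell:

```sh
mamcal rest --condition control          # 11-variable steady state
mamcal compare --a control --b obesity   # % frequency / mito-level deltas
mamcal sensitivity --condition control   # 0.1% peak-sensitivity table
mamcal scan --condition obesity          # staircase cessation scan
mamcal figure fig4 --out-dir out/        # re-run one figure panel set
mamcal simulate examples/pulse_transient.yaml
```

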