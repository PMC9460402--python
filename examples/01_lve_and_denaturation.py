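"""Quality control of a gel before any molecular-weight analysis.

An amplitude sweep locates the linear viscoelastic (LVE) window — the
amplitudes at which the moduli do not depend on the applied strain — and a
temperature sweep locates the denaturation temperature Td, above which the
triple helix unfolds and the measurement destroys the sample.
"""

import rheomwd as rm

scenario = rm.SyntheticScenario(noise_sigma=0.02, seed=0)

amp_sweep, amp_truth = rm.generate_amplitude_sweep(scenario)
region = rm.detect_lve_region(amp_sweep, rel_tol=0.05)
print(f"LVE region: strain {region.amplitude_lower:.3g} .. "
      f"{region.amplitude_upper:.3g} ({region.n_points_in_region} points), "
      f"plateau G' = {region.plateau_g_prime:.0f} Pa")
print(f"  (generator placed the boundary at {amp_truth['lve_upper_true']})")

t_sweep, t_truth = rm.generate_temperature_sweep(scenario)
res = rm.denaturation_summary(t_sweep)
print(f"Td from 50% viscosity drop: {res.td_viscosity.value:.2f} degC")
print(f"Td from tan-delta maximum:  {res.td_tandelta.value:.2f} degC")
print(f"  methods agree within {res.method_agreement:.2f} degC "
      f"(truth {t_truth['td_true']} degC)")
print("Frequency sweeps must stay inside the LVE window and below Td.")
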