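"""Sensing a decaying thermal gradient through fluctuations.

A line of fixed kernel sensors (TRP-channel-like proteins, reading the local
membrane temperature through a Gaussian kernel of width 0.1) filters its
input through a first-order activation/deactivation response (rate 1e4,
gain 1/3).  The membrane starts with a sinusoidal temperature profile of
relative amplitude a0 on top of the baseline 3.0 and relaxes while
fluctuating.

Prints, per amplitude, the spatial modulation recovered from the filtered
indicator against the replicate-to-replicate noise level: the gradient is
resolvable when the modulation clearly exceeds the noise.
"""

from memselm.scenarios import SensingConfig, modulation_amplitude, run_thermal_sensing

cfg = SensingConfig(a0_values=(1.0, 0.1, 0.01), replicates=8, seed=7)
summary, xs = run_thermal_sensing(cfg)

print(f"{'a0':>6} {'modulation':>12} {'noise level':>12} {'resolved?':>10}")
for a0 in cfg.a0_values:
    amp, noise = modulation_amplitude(summary, a0)
    print(f"{a0:>6} {amp:>12.5f} {noise:>12.5f} {'yes' if amp > 3 * noise else 'no':>10}")
print()
print("Large profile amplitudes survive the thermal noise after filtering;")
print("sub-percent amplitudes are obscured by the spontaneous fluctuations.")
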