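"""Hot Brownian escape from a membrane energy well.

A particle sits in a Gaussian energy well (depth 1.5e-4, five times the
baseline thermal energy) on a staggered lattice.  A sustained laser-like
heating spot of relative amplitude c3 is centered on the well; as the
particle heats up through the interfacial region its diffusion grows and the
barrier becomes easy to cross.

Prints the mean first-passage time to radius 0.4 from the well center per
heating amplitude (replicates censored at T_max count at T_max).
"""

from memselm.scenarios import EscapeConfig, escape_summary, run_hot_escape

cfg = EscapeConfig(c3_values=(0.0, 10.0), replicates=10, T_max=30.0, seed=7)
df = run_hot_escape(cfg)
print(escape_summary(df).to_string(index=False))
print()
print("At c3 = 0 the particle stays trapped for the whole horizon (censored);")
print("at c3 = 10 it heats up and escapes in a small fraction of that time.")
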