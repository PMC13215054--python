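"""Action-potential accounting and the energetic cost of firing.

Spike trains follow the duty-cycle convention: within each full cycle a
train fires at the given rate for the duty window, with spikes at both
window edges when they land on the grid.  The total ATP cost of a train
combines the constant non-signalling base rate with the per-AP budgets
of the five signalling components.
"""

import phosphagen as pg

protocols = {
    "worked example (10 Hz, 0.6 s duty, 1 cycle)": pg.FiringProtocol(10, 0.6, 1.0, 1),
    "locomotion (42 Hz, 0.8/1 s, 240 cycles)": pg.protocol_preset("locomotion"),
    "Ca2+ pumping (50 Hz, 2/4 s, 60 cycles)": pg.protocol_preset("ca_pumping"),
    "single 60 Hz train of 30 APs": pg.protocol_preset("train_60hz"),
}
for name, p in protocols.items():
    print(f"{name}: {pg.count_action_potentials(p)} APs")

# cost of the worked example on a synthetic terminal
term = pg.gen_terminal_params(pg.GeneratorSpec(seed=1))
train = pg.spike_times(pg.FiringProtocol(10, 0.6, 1.0, 1))
t_end = float(train.times[-1]) + 10 * max(term.tau.values())
total = pg.integrated_cost(train, term, t_end)
base = term.base_rate * t_end
print()
print(f"synthetic terminal '{term.name}': per-AP cost "
      f"{term.per_ap_cost_mm() * 1e3:.3f} uM")
print(f"7-AP train, integrated to t = {t_end:.0f} s: {total:.3f} mM consumed")
print(f"  of which base (housekeeping) = {base:.3f} mM and "
      f"signalling = {total - base:.4f} mM (= 7 x per-AP budget)")
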