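"""What the phosphagen system does to ATP dynamics under load.

The same synthetic terminal is driven through six locomotion-style
firing cycles with the arginine-kinase equilibrium enforced (phosphagen
present) and with it disabled (knock-down).  Average ATP is barely
affected, but the within-cycle excursions — the volatility — and the
depth of the ATP/ADP drawdown change several-fold.
"""

import numpy as np

import phosphagen as pg

term = pg.gen_terminal_params(pg.GeneratorSpec(seed=1))
cfg = pg.SimulationConfig(
    terminal=term,
    protocol=pg.FiringProtocol(rate=42, duty=0.8, full_cycle=1.0, n_cycles=6),
)
with_ph, without_ph = pg.compare_phosphagen(cfg)

for label, res in [("with phosphagen", with_ph), ("without phosphagen", without_ph)]:
    v = res.volatility(res.atp)
    print(f"{label}:")
    print(f"  mean [ATP]                 = {res.atp.mean():.4f} mM")
    print(f"  per-cycle [ATP] excursion  = {v.mean_ptp * 1e3:.3f} uM")
    print(f"  detrended [ATP] SD         = {v.detrended_std * 1e3:.3f} uM")
    print(f"  minimum ATP/ADP            = {res.atp_adp_ratio.min():.1f}")
    print(f"  minimum |dG| available     = {np.abs(res.free_energy).min():.2f} kJ/mol")

ratio = (without_ph.volatility(without_ph.atp).mean_ptp
         / with_ph.volatility(with_ph.atp).mean_ptp)
print()
print(f"Removing the phosphagen multiplies per-cycle ATP volatility ~{ratio:.0f}x")
print("while leaving the time-averaged level essentially unchanged: the")
print("phosphagen is a temporal buffer, not an extra energy source.")
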