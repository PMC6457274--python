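"""Partition a simulated cycle into pull/push zones and report muscle work.

Zones 1-4 are crank-angle quadrants; zones 1 and 4 form the pull phase,
2 and 3 the push phase.  Net musculotendon work per muscle and zone shows
which muscle groups drive which part of the cycle.
"""

import numpy as np

from handleprop import (
    ArmConfig,
    CrankLengthProfile,
    MechanismConfig,
    MuscleRoster,
    muscle_work,
    peak_forces,
    rom_summary,
    simulate_cycles,
)
from handleprop.analysis import ZonePartition
from handleprop.optimize import ExcitationSplines

roster = MuscleRoster.default()
arm, mech = ArmConfig(), MechanismConfig()
rng = np.random.default_rng(7)
nodes = 0.05 + 0.45 * rng.random((len(roster), 6))
trace = simulate_cycles(
    CrankLengthProfile.from_radius(0.12),
    ExcitationSplines(nodes, cycle=mech.period),
    roster, arm, mech,
).evaluation_cycle()

zones = ZonePartition()
work = muscle_work(trace, zones)
print(work.to_dataframe().round(3))
print()
rom = rom_summary(trace)
print(rom[["min_deg", "max_deg", "rom_deg", "outside_ergonomic"]].round(1))
print()
peaks = peak_forces(trace)
top = sorted(peaks, key=peaks.get, reverse=True)[:3]
print("strongest peak forces:", {m: round(peaks[m], 1) for m in top}, "N")
# Positive zone work marks concentric (shortening) muscle action in that
# quarter of the cycle; the four zone columns sum to the per-muscle total.
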