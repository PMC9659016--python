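"""Drying-process metrics from raw measurements.

Builds a small logged drying run and computes the four endpoint metrics:
dry-basis moisture content, drying time under the controller's stopping
rule, specific energy consumption and rehydration capacity.
"""

import numpy as np

from berryopt import (
    EnergyRecord,
    MoistureSeries,
    RehydrationRecord,
    drying_time,
    moisture_content,
    rehydration_capacity,
    specific_energy,
)

# a 1 kg batch at 80% initial moisture (wet basis), logged every 10 min;
# masses decay exponentially toward the dry-solids mass of 0.2 kg
times = np.arange(0, 600, 10.0)
masses = 0.2 + 0.8 * np.exp(-times / 110.0)
series = MoistureSeries(times=times, masses=masses, M0=1.0, MC0=0.8)

print(f"initial moisture content: {moisture_content(masses[0], 1.0, 0.8):.2f} kg/kg d.b.")
t_dry = drying_time(series, threshold=0.05)
print(f"drying time (first log point with MC < 0.05): {t_dry:.0f} min")

water_removed = masses[0] - masses[-1]
sec = specific_energy(EnergyRecord(E=4.0, m_water=water_removed))
print(f"specific energy consumption: {sec:.2f} MJ per kg of water removed")

rc = rehydration_capacity(RehydrationRecord(W0=0.050, Wt=0.1675))
print(f"rehydration capacity: {rc:.2f} (soaked mass / dried mass)")

# The drying time is where the controller would stop the dryer; SEC and RC
# are the efficiency and quality endpoints used throughout the optimization.
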