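"""Shared study scenario for the numbered analysis drivers.

One simulated 1,200-dive deployment (200 dives of each of the six types)
over the canyon-edge bathymetry; every driver regenerates it from the same
seed, so the scripts can run independently and in any order.
"""

import divetype as dt

SEED = 42
SCENARIO = dt.ScenarioConfig(n_dives_per_type=200, seed=SEED)


def deployment():
    return dt.generate_deployment(SCENARIO)
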