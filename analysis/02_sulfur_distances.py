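#!/usr/bin/env python
"""S-gamma separations and disulfide reformability across conditions.

For every disulfide-reduction code at both pHs, generates three synthetic
replicates, pools both monomers (n = 6), and reports the mean separation
and the fraction of samples under the 0.4 nm reformability cutoff for each
native pair, plus the non-native interchange pairs.  Writes
results/sulfur_reformability.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from psitraj.core import CONDITION_CODES, resolve_condition
from psitraj.sulfur import interchange_pairs, reformability, sg_distances
from psitraj.synthetic import make_trajectory, spec_for_condition
from psitraj.traj_io import select_window

N_FRAMES = 201
SEED = 2021

rows = []
for ph in (3.0, 7.4):
    for code in CONDITION_CODES:
        native, nonnative = [], []
        for rep in range(3):
            spec = spec_for_condition(ph, code, seed=SEED + rep, n_frames=N_FRAMES)
            traj = select_window(make_trajectory(spec), 0.10)
            native.extend(sg_distances(traj, replicate=rep))
            nonnative.extend(interchange_pairs(traj, replicate=rep))
        _, reduced = resolve_condition(code)
        for pool, native_flag in ((native, True), (nonnative, False)):
            for pair in sorted({s.pair for s in pool}):
                subset = [s for s in pool if s.pair == pair]
                d = np.concatenate([s.distances for s in subset])
                v = reformability(subset, cutoff=0.4)
                rows.append(
                    {
                        "ph": ph, "code": code,
                        "pair": f"{pair[0]}-{pair[1]}",
                        "native": native_flag,
                        "state": "reduced" if pair in reduced else
                                 ("intact" if native_flag else "non-native"),
                        "mean_nm": round(float(d.mean()), 4),
                        "sd_nm": round(float(d.std()), 4),
                        "fraction_below_0.4nm": round(v.fraction_below, 3),
                        "likely_reform": v.likely_reform,
                    }
                )

Path("results").mkdir(exist_ok=True)
df = pd.DataFrame(rows)
df.to_csv("results/sulfur_reformability.csv", index=False)

native_df = df[df["native"]]
print(native_df[native_df["ph"] == 3.0].to_string(index=False))
reduced = native_df[native_df["state"] == "reduced"]
print(
    f"\nReduced pairs held near their planted separations: 31-71 stays under "
    f"the 0.4 nm cutoff (reform fraction "
    f"{reduced[reduced['pair'] == '31-71']['fraction_below_0.4nm'].mean():.2f} on average), "
    f"while 6-99 sits near 0.5 nm and rarely reads as reformable."
)
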