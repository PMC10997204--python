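"""Project size-fraction EFs onto the three log-normal source modes.

Reads results/ef_records.csv, computes each mode's mass share per
impactor fraction and the mass-weighted mode EFs for the mean/low/high
scenarios; writes results/mode_weights.csv and results/mode_efs.csv.
"""

from pathlib import Path

import pandas as pd

import pfaa_ssa as P
from pfaa_ssa.chamber import records_from_frame
from pfaa_ssa.source_function import (
    default_modes,
    mode_ef_table,
    mode_mass_fractions,
    submicron_mass_share,
)

base = Path(__file__).resolve().parent.parent / "results"
scheme = P.SizeFractionScheme()
modes = default_modes()
records = records_from_frame(pd.read_csv(base / "ef_records.csv"))

rows = []
for k, m in enumerate(modes):
    w = mode_mass_fractions(m, scheme)
    for f in scheme.fractions:
        rows.append((k, m.median_um, f, scheme.d_p(f), w[f - 1]))
weights = pd.DataFrame(rows, columns=["mode", "median_um", "fraction", "d_p_um", "weight"])
weights.to_csv(base / "mode_weights.csv", index=False)

table = mode_ef_table(records, modes, scheme)
efs = pd.DataFrame(
    [(h, m, sc, v) for (h, m, sc), v in sorted(table.items())],
    columns=["homolog", "mode", "scenario", "ef"],
)
efs.to_csv(base / "mode_efs.csv", index=False)

print(f"salt mass below 1 um: {100 * submicron_mass_share(modes):.1f}%")
for h in sorted(efs["homolog"].unique()):
    sub = efs[(efs["homolog"] == h) & (efs["scenario"] == "mean")]
    vals = ", ".join(f"mode {int(r.mode)} ({modes[int(r.mode)].median_um} um): "
                     f"{r.ef:.3g}" for r in sub.itertuples())
    print(f"{h} mean-scenario mode EFs: {vals}")
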