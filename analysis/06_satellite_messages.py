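"""Classify satellite-summarized dives by IQR windows and validate them.

Transmitted Behavior Messages carry only max depth, duration, shape, and
post-dive interval for four consecutive Qualifying Dives.  Each summarized
dive is assigned the dive type whose archived (Q1, Q3) windows contain both
values, and the assignment is validated against the archived cluster label
of the same dive.  Writes the classified messages and the per-type
agreement table under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import divetype as dt
from divetype.synthetic import simulate_behavior_messages
from scenario import deployment

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    dep = deployment()
    res = dt.run_pipeline(dep.series, dep.fixes, dep.grid)

    msgs = simulate_behavior_messages(dep.truth)
    print(f"{len(msgs)} qualifying dives summarized in "
          f"{msgs['message_id'].nunique()} messages of 4")

    classified = dt.classify_summary_dives(msgs, res.model.type_quantiles)
    archived = res.labeled.set_index("start_time")["type_name"]
    matched = []
    for t in classified["start_time"]:
        diffs = (archived.index - t).total_seconds()
        i = int(np.argmin(np.abs(diffs)))
        matched.append(archived.iloc[i] if abs(diffs[i]) < 120 else None)
    classified["archived_type"] = matched

    known = classified[(classified["assigned_type"] != "Unknown")
                       & classified["archived_type"].notna()]
    print(f"classifiable (non-Unknown): {len(known)} of {len(classified)} "
          f"({100 * len(known) / len(classified):.1f}%)")

    rows = []
    for name in sorted(known["archived_type"].unique()):
        sub = known[known["archived_type"] == name]
        rows.append({"type_name": name, "n": len(sub),
                     "agreement_pct": 100.0 * (sub["assigned_type"] == name).mean()})
    agreement = pd.DataFrame(rows)
    print("agreement with archived classification:")
    print(agreement.round(1).to_string(index=False))

    classified.to_csv(OUT / "classified_messages.csv", index=False)
    agreement.to_csv(OUT / "summary_agreement.csv", index=False)
    print(f"wrote classified messages and agreement table to {OUT}")


if __name__ == "__main__":
    main()
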