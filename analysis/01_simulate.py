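"""Simulate the study deployment and summarize what the tag would record.

Writes the ground-truth dive table and the GPS fix table under results/.
"""

from pathlib import Path

from scenario import SCENARIO, deployment

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    dep = deployment()
    truth, fixes = dep.truth, dep.fixes

    days = len(dep.series) / 86400.0
    print(f"deployment: {len(truth)} dives over {days:.1f} days "
          f"({len(dep.series):,} 1-Hz samples)")
    print(f"fix attempts succeeded: {len(fixes)} "
          f"(success prob {SCENARIO.fix_success_prob})")
    q = truth.groupby("type_name")["qualifying"].mean().round(2)
    print("qualifying-dive fraction by type:")
    print(q.to_string())
    print(f"qualifying dives/day: {truth['qualifying'].sum() / days:.1f}")

    truth.to_csv(OUT / "truth.csv", index=False)
    fixes.to_csv(OUT / "fixes.csv", index=False)
    print(f"wrote {OUT / 'truth.csv'} and {OUT / 'fixes.csv'}")


if __name__ == "__main__":
    main()
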