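"""Score P50 sensory gating (S2/S1 ratio) for every subject.

Each paired-click session is epoched, 10-50 Hz filtered, +/-100 uV
rejected and averaged; S1 is the most prominent positive peak 40-80 ms
post-click and S2 the positive peak within 15 ms of the S1 latency. A
higher S2/S1 ratio means weaker gating. Subjects without a scoreable S1
are logged and excluded, as in clinical practice.

Usage: python analysis/03_p50_gating.py [--seed 0] [--scale desk|study]
"""

import argparse
from pathlib import Path

import pandas as pd

from eegmark.pipeline import PipelineConfig, compute_gating_measures
from eegmark.synthetic import desk_cohort_spec, make_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--scale", default="desk", choices=["desk", "study"])
    args = ap.parse_args()

    cohort = make_cohort(desk_cohort_spec(args.seed, args.scale))
    cfg = PipelineConfig(seed=args.seed)
    rows = [compute_gating_measures(s, cfg) for s in cohort.iter_subjects()]
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "gating_measures.csv", index=False)

    meta = cohort.manifest.set_index("subject_id")
    ok = table[table.status != "s1_not_detected"].join(meta["group"], on="subject_id")
    print(f"wrote {len(table)} rows -> {RESULTS / 'gating_measures.csv'}")
    print(f"excluded (no S1): {(table.status == 's1_not_detected').sum()}")
    print("S2/S1 ratio by group (higher = worse gating):")
    print(ok.groupby("group")["ratio"].agg(["mean", "std"]).round(3))


if __name__ == "__main__":
    main()
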