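"""Rank the 20 candidate parameters by NCA, filter by t-test, keep top 10.

Runs the selection on the synthetic feature table produced by
02_extract_features.py (regenerating it if absent) and, separately,
replays the selection policy on the packaged published ranking/p-value
table to confirm it reproduces the published choice of 10 parameters.
Writes results/selection_report.csv and results/selection_published.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from eegcbf import io as eio
from eegcbf.features import FEATURE_NAMES
from eegcbf.pipeline import build_feature_table
from eegcbf.selection import (
    load_published_selection_table,
    run_selection,
    select_features,
)
from eegcbf.synth import GeneratorConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    table_path = ROOT / "results" / "feature_table.csv"
    if table_path.exists():
        table = eio.read_feature_table(table_path)
    else:
        table = build_feature_table(simulate_cohort(GeneratorConfig(seed=args.seed)))

    result = run_selection(table, FEATURE_NAMES)
    report = result.report()
    out = ROOT / "results" / "selection_report.csv"
    out.parent.mkdir(exist_ok=True)
    report.to_csv(out, index=False, float_format="%.6g")
    print("selection on the synthetic cohort (NCA rank, then p < 0.05 filter):")
    print(report.to_string(index=False))
    print(f"\nselected ({len(result.selected)}): {', '.join(result.selected)}")

    ref = load_published_selection_table()
    replayed = select_features(
        ref["feature"].tolist(), ref["nca_rank"].to_numpy(), ref["p_value"].to_numpy()
    )
    ref_out = ref.assign(replayed_selected=ref["feature"].isin(replayed))
    ref_out.to_csv(ROOT / "results" / "selection_published.csv", index=False)
    agree = (ref_out["replayed_selected"] == (ref_out["published_decision"] == "selected")).sum()
    print(
        f"\nreplaying the policy on the published ranking table reproduces "
        f"{agree}/20 published decisions"
    )


if __name__ == "__main__":
    main()
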