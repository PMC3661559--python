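#!/usr/bin/env python
"""Mature-miRNA composition statistics.

Summarizes length classes and 5' initial base preferences both for the
packaged reference set of 40 published novel rice intronic matures and for
the matures called from the synthetic study, writing both summaries as
JSON.  The reference set shows the canonical split: 20-22-nt species
favoring a 5' U (AGO1 loading) and a large 24-nt class favoring 5' A
(DNA-methylation-guiding species).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from intromir.classify_profile import composition_summary, load_reference_matures


def describe(summary, label):
    print(f"\n{label}: {summary.total} matures")
    for cls in sorted(summary.class_counts):
        n = summary.class_counts[cls]
        bases = ", ".join(
            f"{b}:{summary.first_base_percent(cls, b)}%" for b in "UAGC"
        )
        print(f"  {cls:>6} nt  n={n:<3} ({summary.class_percent(cls)}%)  5' {bases}")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--calls", type=Path, default=Path("results/discovery/calls.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/composition.json"))
    args = ap.parse_args()

    reference = composition_summary(list(load_reference_matures()["sequence"]))
    describe(reference, "published reference matures")

    payload = {"reference": reference.as_dict()}
    if args.calls.exists():
        calls = pd.read_csv(args.calls, sep="\t")
        synthetic = composition_summary(list(calls["mature_sequence"]))
        describe(synthetic, "synthetic-study calls")
        payload["synthetic_calls"] = synthetic.as_dict()

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(payload, fh, indent=1)
    print(f"\nwrote {args.out}")


if __name__ == "__main__":
    main()
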