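#!/usr/bin/env python
"""Reduce each trial to its pre-decision sensorimotor predictors.

Computes the decision lick time (first lick of the answer period, session
median for no-lick trials), restricts every touch-conditioned quantity to
pre-decision touches, and writes the per-trial feature table. Reports how
many trials feed the Hilbert decoders after excluding trials with
exclusively retraction touches.
"""

import argparse
import json
from pathlib import Path

from whiskloc.features import apply_retraction_exclusion, build_feature_table
from whiskloc.session import read_session


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    session = read_session(args.results / "session.h5")
    table = build_feature_table(session)
    table.to_csv(args.results / "features.csv", index=False)

    hil, excluded = apply_retraction_exclusion(table)
    n_touch = int((table["touch_count"] > 0).sum())
    with open(args.results / "exclusions.json", "w") as fh:
        json.dump({"retraction_only_trials":
                   [int(i) for i in excluded["trial_id"]]}, fh, indent=1)
    print(f"feature rows: {len(table)} "
          f"({n_touch} touch trials, {len(table) - n_touch} no-touch)")
    print(f"Hilbert-eligible trials (protraction touches): {len(hil)} "
          f"({100 * len(hil) / max(n_touch, 1):.1f}% of touch trials); "
          f"retraction-only excluded: {len(excluded)}")
    print(f"wrote {args.results/'features.csv'}")


if __name__ == "__main__":
    main()
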