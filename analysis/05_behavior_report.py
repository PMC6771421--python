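#!/usr/bin/env python
"""Session-level behavioral statistics report.

Writes the psychometric curve, boundary-discrimination table, touch-count-
conditioned lick probabilities, and the pre/post-touch whisk-count KL
divergences. The signatures to look for: a near-step psychometric curve,
lick-probability differences that grow with distance from the boundary,
go > no-go lick probability at matched touch counts (touch count alone does
not explain choice), and a much larger whisk-count divergence after the
first touch than before it (touch-adaptive exploration).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from whiskloc.behavior import (boundary_discrimination,
                               lick_probability_by_touch_count,
                               protraction_targeting, session_psychometric,
                               whisk_count_distributions)
from whiskloc.session import read_session


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--plot", action="store_true",
                    help="also write psychometric.png (requires matplotlib)")
    args = ap.parse_args()
    session = read_session(args.results / "session.h5")

    curve = session_psychometric(session)
    pd.DataFrame({"bin_left": curve.bin_edges[:-1],
                  "bin_right": curve.bin_edges[1:],
                  "lick_probability": curve.lick_probability,
                  "n_trials": curve.trial_counts,
                  "ci_low": curve.ci_low, "ci_high": curve.ci_high}) \
        .to_csv(args.results / "psychometric.csv", index=False)
    print("psychometric curve (posterior -> anterior):",
          np.round(curve.lick_probability, 2))

    bd = boundary_discrimination(session)
    bd.to_csv(args.results / "boundary_discrimination.csv", index=False)
    print("lick-probability difference at <=0.5 / <=5 mm from boundary: "
          f"{bd['lick_diff'].iloc[0]:.2f} / {bd['lick_diff'].iloc[-1]:.2f}")

    lp = lick_probability_by_touch_count(session)
    lp.to_csv(args.results / "lick_by_touch_count.csv", index=False)

    wc = whisk_count_distributions(session)
    with open(args.results / "whisk_kl.json", "w") as fh:
        json.dump({"kl_pre": wc.kl_pre, "kl_post": wc.kl_post,
                   "whisks_pre_touch_mean": float(wc.pre_counts_touch.mean()),
                   "whisks_post_touch_mean": float(wc.post_counts_touch.mean())},
                  fh, indent=1, sort_keys=True)
    print(f"whisks before/after first touch: {wc.pre_counts_touch.mean():.1f} / "
          f"{wc.post_counts_touch.mean():.1f}; "
          f"KL(touch || no-touch): pre {wc.kl_pre:.3f}, post {wc.kl_post:.3f}")

    protraction_targeting(session).to_csv(
        args.results / "protraction_targeting.csv", index=False)

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.errorbar(curve.bin_centers, curve.lick_probability,
                    yerr=[curve.lick_probability - curve.ci_low,
                          curve.ci_high - curve.lick_probability],
                    fmt="o-", color="k")
        ax.axvline(session.config.boundary_position, ls="--", c="gray")
        ax.set_xlabel("pole position (mm, posterior to anterior)")
        ax.set_ylabel("lick probability")
        fig.tight_layout()
        fig.savefig(args.results / "psychometric.png", dpi=150)
        print(f"wrote {args.results/'psychometric.png'}")


if __name__ == "__main__":
    main()
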