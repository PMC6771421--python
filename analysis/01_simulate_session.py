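#!/usr/bin/env python
"""Simulate one expert go/no-go localization session and summarize it.

Generates a 200-trial session with the default motor and task statistics
(cue-triggered whisking, boundary-targeted noisy protraction, touch-adaptive
bout extension, choices from the midpoint + touch-count rule), writes it to
results/session.h5 with a trials.csv sidecar, and prints the behavioral
summary a session should reproduce: higher touch probability on go than
no-go trials, a posterior-to-anterior touch-count gradient, and ~80%
discrimination accuracy.
"""

import argparse
from pathlib import Path

import numpy as np

from whiskloc.config import SessionConfig
from whiskloc.session import GO, LICK, NOGO, write_session
from whiskloc.synth import generate_session


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-trials", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SessionConfig(n_trials=args.n_trials, rng_seed=args.seed)
    session = generate_session(cfg)
    write_session(session, args.out / "session.h5",
                  trials_csv=args.out / "trials.csv")

    go = [t for t in session.trials if t.trial_type == GO]
    nogo = [t for t in session.trials if t.trial_type == NOGO]
    pos = np.array([t.pole_position for t in session.trials])
    cnt = np.array([t.n_touches for t in session.trials])
    acc = np.mean([t.outcome in ("hit", "correct_rejection")
                   for t in session.trials])
    print(f"session: {len(session)} trials (seed {args.seed})")
    print(f"touch probability: go {np.mean([t.n_touches > 0 for t in go]):.3f}, "
          f"no-go {np.mean([t.n_touches > 0 for t in nogo]):.3f}")
    print(f"touch count: most posterior bin {cnt[pos < 1].mean():.1f}, "
          f"most anterior bin {cnt[pos > 9].mean():.1f}")
    print(f"lick rate: go {np.mean([t.choice == LICK for t in go]):.3f}, "
          f"no-go {np.mean([t.choice == LICK for t in nogo]):.3f}")
    print(f"discrimination accuracy: {acc:.3f}")
    print(f"wrote {args.out/'session.h5'} and {args.out/'trials.csv'}")


if __name__ == "__main__":
    main()
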