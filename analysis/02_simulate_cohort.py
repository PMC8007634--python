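"""Simulate the synthetic observer cohort's 2AFC trial logs.

Fifteen observers, each with subject-level psychometric parameters drawn
around the per-law cohort means, complete the full 405-trial design (3 laws x
9 conditions x 15 replications, pseudo-random order).  A small fraction of
response times falls outside the allowed window to exercise the exclusion
rules.  One CSV log per subject is written under results/experiment/trials.
"""

import argparse
from pathlib import Path

from paradur.config import RunConfig, Seeds
from paradur.pipeline import run_experiment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/experiment"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = RunConfig(
        seeds=Seeds(
            schedule=args.seed, cohort=args.seed + 1, responses=args.seed + 2,
            bootstrap=args.seed + 3,
        )
    )
    trials = run_experiment(cfg, args.out)
    n_subj = trials["subject_id"].nunique()
    print(f"Simulated {n_subj} subjects x {len(trials) // n_subj} trials.")
    print(f"Trial logs written under {args.out}/trials")


if __name__ == "__main__":
    main()
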