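#!/usr/bin/env python
"""Forward-simulate a pupillometry cohort.

Each simulated participant gets their own ground-truth pupil response
function (Gamma kernel, parameters jittered inside the fitting bounds) and
condition gains on the sustained response ordered by perceived numerosity
(24-isolated > 18-isolated ~ 24-connected > 18-connected).  Sessions are
500 Hz traces with AR(1) noise and Poisson blinks, one numerosity x
polarity per session with connectedness intermixed, written in the same
delimited formats the preprocessing stage consumes.

Raw traces land in scratch/run/raw (large); the ground-truth table is
copied to results/run/.
"""

import shutil
from pathlib import Path

import numpy as np

from pupilnum import io as pio
from pupilnum.pipeline import RunConfig, stage_simulate

RUN = Path("scratch/run")
RESULTS = Path("results/run")

CONFIG = RunConfig(
    experiment=1,
    n_participants=8,          # cohort scaled for a desk run
    trials_per_session=20,     # per (numerosity, polarity) session
    psych_sessions=3,
    psych_trials_per_session=40,
    seed=2021,
    out_dir=str(RUN),
)


def main():
    RUN.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    pio.dump_config_file(CONFIG.to_dict(), RUN / "config.yaml")
    master = np.random.SeedSequence(CONFIG.seed)
    _, sim_seed, _ = master.spawn(3)
    stage_simulate(CONFIG, RUN, np.random.default_rng(sim_seed))
    shutil.copy(RUN / "raw" / "ground_truth_prf.csv", RESULTS / "ground_truth_prf.csv")
    n_files = len(list((RUN / "raw").glob("*_trace.csv")))
    print(f"simulated {CONFIG.n_participants} participants, {n_files} sessions "
          f"({CONFIG.trials_per_session} trials each) under {RUN}/raw")


if __name__ == "__main__":
    main()
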