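#!/usr/bin/env python
"""Measure the connectedness illusion psychophysically.

Each simulated participant judges which of two arrays is more numerous
(2AFC, probe grid 8-24 dots, 3 sessions x 40 trials) against the 18-dot
reference, once with connected probes (observer PSE at 70% of the
reference: the illusion) and once with isolated probes (no bias).
Cumulative-Gaussian fits give the PSE; the bias index expresses the PSE
shift in percent.
"""

import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from pupilnum import io as pio
from pupilnum.pipeline import RunConfig, stage_psychophysics
from pupilnum.psychometrics import predicted_perceived_numerosity

RUN = Path("scratch/run")
RESULTS = Path("results/run")


def main():
    cfg = RunConfig.from_dict(pio.load_config_file(RUN / "config.yaml"))
    master = np.random.SeedSequence(cfg.seed)
    _, _, psych_seed = master.spawn(3)
    stage_psychophysics(cfg, RUN, np.random.default_rng(psych_seed))
    shutil.copy(RUN / "psych" / "psychometric_fits.csv", RESULTS / "psychometric_fits.csv")

    fits = pd.read_csv(RESULTS / "psychometric_fits.csv")
    summary = fits.groupby("connectedness")["bias_percent"].agg(["mean", "sem"]).round(2)
    print("bias index (% PSE shift from the 18-dot reference):")
    print(summary.to_string())
    mean_bias = fits.query("connectedness == 'connected'")["bias_percent"].mean()
    pred = predicted_perceived_numerosity(24, mean_bias)
    print(f"\nunder the recovered connected-condition bias ({mean_bias:+.1f}%), a "
          f"24-dot connected array should appear ~{pred:.1f} dots — close to an "
          "isolated 18-dot array, which is why those two cells evoke similar "
          "pupil responses.")


if __name__ == "__main__":
    main()
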