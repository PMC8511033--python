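#!/usr/bin/env python
"""Condition-level statistics and the final report.

Runs the 2x2 repeated-measures ANOVA (numerosity x connectedness) on the
1-6 s window means and on the sustained betas, the paired t-test of the
extreme cells (24 isolated vs 18 connected) with Cohen's d, and the BCEA
fixation-stability control, then writes the combined Markdown report.
"""

import shutil
from pathlib import Path

from pupilnum import io as pio
from pupilnum.pipeline import RunConfig, stage_report

RUN = Path("scratch/run")
RESULTS = Path("results/run")


def main():
    cfg = RunConfig.from_dict(pio.load_config_file(RUN / "config.yaml"))
    stage_report(cfg, RUN)
    for f in (RUN / "report").iterdir():
        shutil.copy(f, RESULTS / f.name)
    print((RESULTS / "report.md").read_text())


if __name__ == "__main__":
    main()
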