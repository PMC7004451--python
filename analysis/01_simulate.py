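#!/usr/bin/env python
"""Stage 1: generate a synthetic study world with a known interaction.

Writes daily weather-station series, daily PM2.5 monitor series and a sampled
case-control subject table under results/pipeline/, together with a manifest
of the generative truth (true stratum odds ratios and RERI) that stage 3 can
be checked against.
"""

from analysis_config import CONFIG
from heatpm.pipeline import cmd_simulate

if __name__ == "__main__":
    paths = cmd_simulate(CONFIG)
    for name, path in paths.items():
        print(f"{name}: {path}")
    print("Truth: OR(PM|no EHE)=1.0, OR(PM|EHE)=1.6 -- see true_params.yaml")
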