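#!/usr/bin/env python
"""Stage 2: derive per-subject exposures from the simulated world.

For every pregnancy: the weeks-3--8 critical window, the nearest PM2.5
monitor within 50 km and its 42-day window mean (dichotomized at the control
80th percentile), the nearest weather station's window-mean dew point, and
heat-event flags under both duration rules.  Subjects with no monitor within
50 km stay in the table with an exclusion reason, mirroring the inclusion
rule of monitor-based exposure assessment.
"""

import pandas as pd

from analysis_config import CONFIG
from heatpm.pipeline import cmd_expose

if __name__ == "__main__":
    path = cmd_expose(CONFIG)
    expo = pd.read_csv(path, comment="#")
    print(f"exposure table: {path} ({len(expo)} subjects)")
    print(f"  excluded (no monitor within 50 km): "
          f"{(expo['exclusion_reason'] == 'no_monitor_within_50km').sum()}")
    print(f"  high PM2.5: {expo['pm_high'].mean():.1%}  "
          f"EHE95 exposed: {expo['ehe95_exposed'].mean():.1%}  "
          f"EHE90 exposed: {expo['ehe90_exposed'].mean():.1%}")
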