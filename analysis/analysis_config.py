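"""Shared configuration for the numbered analysis stages.

One compact synthetic study: a 3-degree-square study area with a dense
monitor network (so most residences fall within 50 km of a monitor), five
years of daily weather, and a case-control sample drawn from a cohort whose
truth has no PM2.5 effect without a heat event (OR 1.0) and a PM2.5 odds
ratio of 1.6 when a heat event overlaps the critical window.
"""

from heatpm.pipeline import PipelineConfig

CONFIG = PipelineConfig(
    out_dir="results/pipeline",
    seed=2021,
    n_subjects=8000,
    n_cases=2000,
    n_controls=3000,
    residence_box=(31.5, 33.0, -97.5, -96.0),
    n_monitors=8,
    true_intercept=-1.2,
    true_or_pm=1.0,
    true_or_ehe=1.3,
    true_or_pm_given_ehe=1.6,
)
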