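"""The Ca2+ current-release cooperativity experiment, scaled for a desk run.

Drives a small active zone with nine APs of graded width, collects total
Ca2+ influx (Q_Ca) and mean vesicular release probability per width, and
fits the slope in double-logarithmic coordinates.  Channels placed under the
30 nm exclusion rule give a high slope (~2.5-3: many channels control each
vesicle); purely random channels give a shallow slope (~1.3: the nearest
channel dominates).
"""

import numpy as np

from calyxsim import SimConfig, generate_active_zone, place_channels_exclusion_zone
from calyxsim.experiments import (
    cooperativity_experiment,
    default_width_scales,
    graded_trial_schedule,
)

az = generate_active_zone(0.05, 6, seed=42)
cfg = SimConfig()
scales = default_width_scales()
schedule = graded_trial_schedule(scales, 150)  # desk-scale trial counts

res = cooperativity_experiment(
    az, cfg,
    lambda s: place_channels_exclusion_zone(az, 14, 30.0, seed=s),
    n_trials=schedule, n_spatial_seeds=1, width_scales=scales, seed=5,
)
print("width scale | Q_Ca (fC) | mean p_ves | in fit")
for w, q, p, inc in zip(res.width_scales, res.q_ca_fC[0], res.mean_p_ves[0],
                        res.fits[0].included):
    print(f"   {w:5.2f}    |  {q:6.2f}   |  {p:7.4f}  | {'yes' if inc else 'no'}")
print(f"\nfitted log-log slope: {res.slope_mean:.2f}")
print("A slope near 3 approaches the five-site sensor's intrinsic ceiling "
      "(~3.5):\nrelease at every vesicle is shaped by many overlapping "
      "channel domains.")
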