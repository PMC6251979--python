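"""Build a default day-long trial schedule and inspect its timing.

The session embeds 40 six-second trials into ~8 hours of everyday phone
use: intertrial intervals follow the Fleshler–Hoffman progression (mean
exactly 12 minutes, irregular order) and a control-judgment probe follows
every 8th trial.
"""

import numpy as np

from contingencylab import ExperimentConfig, generate_schedule, scheduled_session_duration

config = ExperimentConfig()  # canonical low-density arm
schedule = generate_schedule(config, seed=1)

print(f"trials:            {schedule.n_trials}")
print(f"judgment probes:   {len(schedule.judgment_times_s)}")
print(f"mean ITI:          {schedule.iti_s.mean() / 60:.2f} min")
print(f"shortest/longest:  {schedule.iti_s.min() / 60:.2f} / "
      f"{schedule.iti_s.max() / 60:.2f} min")
print(f"session length:    {scheduled_session_duration(schedule) / 3600:.2f} h")
print(f"first probe at:    {schedule.judgment_times_s[0] / 3600:.2f} h")

# The mean ITI is exactly 12 minutes by construction; the spread around it
# (here roughly 0.5 to 50 minutes) is what makes trial timing feel random
# while the session still fits the planned ~8-hour day.
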