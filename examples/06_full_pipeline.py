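"""Run the whole pipeline from one config and inspect the run report.

Stages: ingest/generate -> mapping -> per-sponsor collaboration network ->
trim (95% industry / 90% non-industry) -> fixed-margin null model -> map
equation clustering.  The report records counts at every stage plus seeds.
"""

import json

from trialscape import default_config
from trialscape.workflow import RunConfig, run_pipeline

config = RunConfig(
    synthetic=default_config(rate_scale=0.03, seed=8),
    n_reps=5_000,  # 90,000 in a full analysis
    seed=9,
    n_restarts=4,
)
result = run_pipeline(config)
print(json.dumps(result.report.as_dict(), indent=2, default=str))
# "sponsors" shows, per sponsor type, how many international trials entered
# the incidence matrix, countries kept after trimming, pairs tested, pairs
# flagged and clusters found; reruns with identical config reproduce the
# report exactly.
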