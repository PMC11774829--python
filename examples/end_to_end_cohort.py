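"""Simulate a small synthetic adenoma cohort and run the full pipeline.

Nine base-excision-repair-deficient (MUTYH-like) adenomas against 27
control adenomas: paired caller VCFs are generated against a synthetic
reference, then intersected, filtered (depth >= 50, VAF >= 10 %),
catalogued into 96 channels, refit into signature exposures, and compared
between groups.
"""

import tempfile
from pathlib import Path

from adenosig import RunConfig, run_analyze, run_report, run_simulate
from adenosig.simulate import default_profiles

config = RunConfig(seed=1)
profiles = [p for p in default_profiles()
            if p.label in ("MUTYH_adenoma", "control_adenoma")]

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    run_simulate(config, tmp / "cohort", profiles=profiles)
    run_analyze(config, tmp / "cohort", tmp / "analysis")
    print(run_report(tmp / "analysis"))

print("The SBS18+SBS36 row is the diagnostic readout: the simulated")
print("MUTYH-like group was planted at ~66 % marker exposure vs ~8 % in")
print("controls, and the pipeline recovers that separation (Cohen's d > 2).")
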