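"""Shared configuration for the demo analysis runs."""

from pathlib import Path

from phenoweek import CohortConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

#: 20-participant, 12-week synthetic study, default 80:20 split,
#: default missingness and effect sizes.
DEMO = CohortConfig(n_participants=20, n_weeks=12, seed=7)
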