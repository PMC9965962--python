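"""Shared configuration for the numbered analysis scripts.

One seed governs the whole replication; every script reads and writes
under ``results/replication`` (small text tables) while bulky epoch
files go to ``scratch/``.
"""

from pathlib import Path

from paee.synthetic import enrolled_study_config

STUDY_SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "replication"
SCRATCH = ROOT / "scratch" / "replication"

CONFIG = enrolled_study_config(seed=STUDY_SEED)
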