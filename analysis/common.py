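"""Shared locations and settings for the numbered analysis scripts.

The scripts replay the full study design on synthetic data (no raw
sequencing data is publicly available for the original experiment): 3
knockdown/scrambled pairs and 3 m6A-IP/IgG pairs, 50,000 reads each, with a
quarter of the 300 references methylated and 60% of those carrying a planted
GGACU (RRACH) site.  Run them in order from the repository root:

    python analysis/01_simulate.py
    python analysis/02_trim.py
    ...

Heavy intermediates (FASTQs) stage under scratch/analysis/; each script
publishes its small result tables to results/analysis/.
"""

import logging
import shutil
from pathlib import Path

from mirmeth.synthetic import SimulationConfig

WORK = Path("scratch/analysis")  # staging area, FASTQ-heavy
SIM = WORK / "sim"
BASE = WORK
RESULTS = Path("results/analysis")
SEED = 7

CONFIG = SimulationConfig(seed=SEED)


def setup_logging() -> None:
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(levelname)s %(message)s")


def publish(*names: str) -> None:
    """Copy small artifacts from the staging area into results/analysis."""
    RESULTS.mkdir(parents=True, exist_ok=True)
    for name in names:
        shutil.copy(WORK / name, RESULTS / Path(name).name)
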