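"""Generate the synthetic experiment: catalog, ground truth, 12 FASTQs.

Finding to expect: 300 references (19-27 nt), 75 methylated, 45 of those
carrying the planted GGACU site; 50,000 reads per sample in each of
scr_1..3, kd_1..3, m6A_1..3, IgG_1..3.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import CONFIG, SIM, publish, setup_logging

import pandas as pd

from mirmeth.pipeline import run_simulate


def main() -> None:
    setup_logging()
    run_simulate(CONFIG, SIM)
    publish("sim/truth.tsv", "sim/samplesheet.tsv")
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t", index_col="name")
    n_meth = int(truth["methylated"].sum())
    n_plant = int((truth["motif_pos"] >= 0).sum())
    print(f"simulated {len(truth)} references -> {SIM}")
    print(f"  methylated: {n_meth}; with planted {CONFIG.planted_motif}: "
          f"{n_plant}")
    print(f"  reads: {CONFIG.reads_per_sample} per sample x "
          f"{4 * CONFIG.n_replicates} samples")


if __name__ == "__main__":
    main()
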