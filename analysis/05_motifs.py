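"""Scan IUPAC motif spaces discriminating called-methylated references from
the rest.

Finding to expect: the top 3-mer matches the planted GGACU site (GAC or a
degenerate generalization such as RAC/GSA), Bonferroni-significant; the
4-mer space takes longer (37,248 motifs) and points at the same site.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import BASE, CONFIG, publish, setup_logging

from mirmeth.motifdisc import motif_matches_sequence
from mirmeth.pipeline import motif_input_sets, run_motifs


def main() -> None:
    setup_logging()
    ip, bg = motif_input_sets(BASE, BASE)
    print(f"IP set: {len(ip)} sequences; background: {len(bg)}")
    results = run_motifs(ip, bg, ["3-2-2-0", "4-2-2-1"], BASE)
    publish("motifs_3-2-2-0_top50.tsv", "motifs_4-2-2-1_top50.tsv")
    for form, df in results.items():
        top = df.iloc[0]
        hit = motif_matches_sequence(top["motif"], CONFIG.planted_motif)
        print(f"form {form}: top motif {top['motif']} "
              f"(a={top['a']}/{top['a'] + top['b']}, "
              f"fisher_p={top['fisher_p']:.3g}, "
              f"bonferroni_p={top['bonferroni_p']:.3g}) "
              f"{'matches' if hit else 'does NOT match'} the planted site")


if __name__ == "__main__":
    main()
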