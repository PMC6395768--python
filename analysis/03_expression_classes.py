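#!/usr/bin/env python
"""Build the HEG/LEG gene sets from protein-per-transcript.

Joins the protein ppm table with mRNA tpm, ranks genes by ppm/tpm,
takes the top and bottom 30%, and reports how strongly the resulting
sets enrich for the genes simulated under translational selection.
"""

from pathlib import Path

import pandas as pd

from trnacodon.expression import protein_per_transcript, select_heg_leg
from trnacodon.io_formats import read_abundance_table, read_protein_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    protein = read_protein_table(ROOT / "sim" / "protein.tsv")
    mrna = read_abundance_table(ROOT / "sim" / "mrna_abundance.tsv")
    records = protein_per_transcript(protein, mrna)
    sets = select_heg_leg([records])
    print(f"{len(records)} genes with positive ppm and tpm; "
          f"|HEG| = {len(sets.heg)}, |LEG| = {len(sets.leg)}")

    truth = pd.read_csv(ROOT / "sim" / "gene_truth.tsv", sep="\t")
    planted = set(truth.loc[truth.is_heg, "gene_id"])
    frac_heg = len(sets.heg & planted) / len(sets.heg)
    frac_leg = len(sets.leg & planted) / len(sets.leg)
    print(f"planted selected genes: {frac_heg:.1%} of HEG, {frac_leg:.1%} of LEG "
          f"(baseline {len(planted) / len(truth):.1%})")

    for name, ids in (("heg", sets.heg), ("leg", sets.leg)):
        path = ROOT / f"{name}_genes.txt"
        path.write_text("\n".join(sorted(ids)) + "\n")
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
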