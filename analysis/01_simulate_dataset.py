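#!/usr/bin/env python
"""Generate the synthetic study dataset.

Writes the paper-like fixture (48 taxa, 200 single-copy ortholog
alignments with heterogeneous missingness, a 10-state lifestyle trait on
the true tree) to scratch/dataset/ and prints an inventory.
"""

from pathlib import Path

import phylosample as ps

OUT = Path("scratch/dataset")
SEED = 1


def main() -> None:
    fixture = ps.generate_fixture_study("paper-like", seed=SEED, out_dir=OUT)
    m = fixture.manifest
    print(f"simulated {m['n_taxa']} taxa, {m['n_genes']} genes, "
          f"{m['total_length']:,} bp total")
    print(f"poorly assembled taxa (90% gene missingness): {', '.join(m['poor_taxa'])}")
    print(f"true root lifestyle state: {m['true_root_state']}")
    print(f"wrote {OUT}/genes/*.fasta, true_tree.nwk, traits.tsv, manifest.json")


if __name__ == "__main__":
    main()
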