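#!/usr/bin/env python
"""Generate the synthetic four-genome study and write the sequence bundle.

The ancestor plastome (23 kb, quadripartite, 14 genes) and three diverged
genomes are built deterministically from the study seed. GenBank and aligned
FASTA go to scratch/ (they are regenerable); the planted ground truth — the
partition coordinates and per-gene omega — goes to results/ as JSON.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, STUDY_SEED

from plastocub.io import write_fasta, write_genbank
from plastocub.study import POSITIVE_GENES, build_study, study_divergence_spec


def main() -> None:
    genomes, truth = build_study(STUDY_SEED)
    out = SCRATCH / "study"
    out.mkdir(parents=True, exist_ok=True)
    write_genbank(genomes, out / "study_genomes.gb")
    # substitution-only divergence: the genomes are already column-aligned
    write_fasta([(g.identifier, g.sequence) for g in genomes], out / "study_alignment.fasta")

    RESULTS.mkdir(exist_ok=True)
    dspec = study_divergence_spec(0)
    truth_doc = {
        "seed": STUDY_SEED,
        "genomes": [g.identifier for g in genomes],
        "partition": {
            "LSC": truth.lsc, "IRb": truth.irb, "SSC": truth.ssc, "IRa": truth.ira,
            "ir_length": truth.ir_length,
        },
        "junctions": truth.junctions,
        "positive_genes": POSITIVE_GENES,
        "default_omega": dspec.default_omega,
        "coding_rate": dspec.coding_rate,
        "noncoding_rate": dspec.noncoding_rate,
        "gc_bias_beta": dspec.beta,
    }
    (RESULTS / "study_ground_truth.json").write_text(
        json.dumps(truth_doc, indent=2) + "\n"
    )
    print(f"wrote {len(genomes)} genomes ({len(genomes[0])} bp each) to {out}")
    print(f"planted IR length {truth.ir_length} bp; junctions {truth.junctions}")
    print(f"positive-selection genes: {sorted(POSITIVE_GENES)}")


if __name__ == "__main__":
    main()
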