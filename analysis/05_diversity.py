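#!/usr/bin/env python
"""Sliding-window nucleotide diversity across the four study genomes.

Windows of 600 bp at 200 bp steps over the whole-genome alignment; windows
are labelled by the ancestor's annotation (gene, or flanking-gene pair for
intergenic midpoints). Writes the window table and prints the hypervariable
regions and the coding/noncoding contrast.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, STUDY_SEED

from plastocub.diversity import (
    AlignmentMatrix,
    column_to_position_map,
    diversity_summary,
    label_windows,
    sliding_windows,
)
from plastocub.study import build_study


def main() -> None:
    genomes, truth = build_study(STUDY_SEED)
    aln = AlignmentMatrix([g.identifier for g in genomes], [g.sequence for g in genomes])
    windows = sliding_windows(aln, window=600, step=200)
    ancestor = genomes[0]
    windows = label_windows(
        windows, ancestor, column_to_position_map(aln, ancestor.identifier)
    )
    summary = diversity_summary(windows)

    frame = pd.DataFrame(
        [
            {
                "start": w.start, "end": w.end, "midpoint": w.midpoint,
                "usable_sites": w.usable_sites, "pi": round(w.pi, 4),
                "label": w.label,
            }
            for w in windows
        ]
    )
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "pi_windows.tsv", sep="\t", index=False)

    print(
        f"{len(windows)} windows; genome-wide mean pi {summary['mean_pi']:.4f};"
        f" max {summary['max_pi']:.4f} at"
        f" {int(summary['max_window_start'])}-{int(summary['max_window_end'])}"
    )
    top = frame.nlargest(5, "pi")
    print("most variable windows:")
    for _, row in top.iterrows():
        print(f"  {row['start']:>6}-{row['end']:<6} pi={row['pi']:.4f}  {row['label']}")

    genic = frame[frame["label"].str.contains("~") == False]  # noqa: E712
    intergenic = frame[frame["label"].str.contains("~")]
    ir_mask = (frame["midpoint"] >= truth.irb[0]) & (frame["midpoint"] <= truth.irb[1])
    print(
        f"mean pi: genic windows {genic['pi'].mean():.4f},"
        f" intergenic windows {intergenic['pi'].mean():.4f},"
        f" IRb windows {frame[ir_mask]['pi'].mean():.4f}"
        " (purifying selection keeps coding windows below noncoding ones;"
        " the simulated IR is mostly intergenic, so unlike an rRNA-rich real"
        " IR it diverges at the noncoding rate)"
    )


if __name__ == "__main__":
    main()
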