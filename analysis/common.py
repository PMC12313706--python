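"""Shared configuration for the analysis scripts.

One fixed seed defines the synthetic study; every script regenerates the
genomes deterministically from it (generation takes well under a second), so
no intermediate data files need to be exchanged between scripts. Tables land
in results/, bulky sequence files in scratch/.
"""

from pathlib import Path

STUDY_SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
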