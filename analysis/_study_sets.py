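"""Shared definition of the synthetic nine-set study used by the drivers.

Nine CDS sets shaped like small AT-rich plastome gene complements (44-52
genes each, third-position GC around 26-29%) with per-set codon-preference
sharpness varied so the bias diagnostics have signal to find. Used by every
numbered analysis script; real genomes can be substituted by pointing the
scripts at data/genomes/ once scripts/reproduce_study.py --fetch has run.
"""

from pathlib import Path

from codonbias.simulate import SynthesisParams

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
# regenerable multi-FASTA inputs are bulky; keep them out of the results tree
FASTA_DIR = ROOT / "scratch" / "synthetic_genomes"

#: set name -> generator parameters (one synthetic "species" each)
STUDY_SETS: dict[str, SynthesisParams] = {
    f"set{i+1:02d}": SynthesisParams(
        n_genes=n, concentration=conc, gc3=gc3, seed=1000 + i
    )
    for i, (n, conc, gc3) in enumerate(
        [
            (50, 0.8, 0.28),
            (44, 1.0, 0.27),
            (47, 0.6, 0.265),
            (50, 1.2, 0.26),
            (48, 0.9, 0.265),
            (48, 0.7, 0.272),
            (52, 1.1, 0.28),
            (52, 0.8, 0.292),
            (51, 1.0, 0.269),
        ]
    )
}
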