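#!/usr/bin/env python
"""Codon-frequency comparison of each synthetic set against model tables.

Model-organism codon usage is consumed as Kazusa-format text files from
data/model_tables/ when present (e.g. hand-downloaded snapshots); otherwise
two synthetic stand-in tables (one similar in bias to the study sets, one
strongly diverged) are generated so the band arithmetic has something to
bite on. Prints the divergent / similar codon counts per (set, model) pair.
"""

import pandas as pd
from _study_sets import FASTA_DIR, RESULTS, ROOT, STUDY_SETS

from codonbias.comparison import (
    per_thousand_frequencies,
    read_kazusa_file,
)
from codonbias.io import filter_cds, parse_fasta_cds
from codonbias.metrics import count_codons
from codonbias.pipeline import run_cross_species, run_species
from codonbias.simulate import SynthesisParams, generate_cds_set

MODEL_DIR = ROOT / "data" / "model_tables"


def synthetic_model_tables():
    """Two synthetic stand-ins for model-organism usage tables.

    Not real organisms: one mirrors the study sets' AT-rich bias, the other
    is GC-shifted and sharply biased, so comparisons span both bands.
    """
    similar = generate_cds_set(
        SynthesisParams(n_genes=40, concentration=1.0, gc3=0.28, seed=777)
    )
    diverged = generate_cds_set(
        SynthesisParams(n_genes=40, concentration=0.15, gc3=0.62, seed=778)
    )
    return [
        per_thousand_frequencies(count_codons(similar), "synthetic_similar"),
        per_thousand_frequencies(count_codons(diverged), "synthetic_diverged"),
    ]


def main() -> None:
    if MODEL_DIR.is_dir() and any(MODEL_DIR.glob("*.txt")):
        models = [read_kazusa_file(p) for p in sorted(MODEL_DIR.glob("*.txt"))]
        print(f"model tables from {MODEL_DIR}: "
              f"{', '.join(m.organism for m in models)}")
    else:
        models = synthetic_model_tables()
        print("no local model tables found; using synthetic stand-ins")

    bundles, counts = [], {}
    for name in STUDY_SETS:
        records = parse_fasta_cds(FASTA_DIR / f"{name}.fasta", species=name)
        kept, _ = filter_cds(records)
        counts[name] = count_codons(kept)
        bundles.append(run_species(records, name))

    cross = run_cross_species(bundles, model_tables=models,
                              per_species_counts=counts)
    table = cross["model_comparison"]
    print("\nratio bands (divergent: ratio >= 2 or <= 0.5):")
    print(table.to_string(index=False))
    out = RESULTS / "model_comparison.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, sep="\t", index=False)
    print(f"\nwritten to {out}")


if __name__ == "__main__":
    main()
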