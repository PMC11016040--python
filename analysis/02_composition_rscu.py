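#!/usr/bin/env python
"""Composition and RSCU analysis of the nine synthetic sets.

Runs the per-species pipeline on each FASTA written by 01_simulate.py and
prints the composition summary (GC by codon position, L_aa) plus each set's
high-frequency codons; the full report bundles land under results/study/.
"""

import pandas as pd
from _study_sets import FASTA_DIR, RESULTS, STUDY_SETS

from codonbias.io import parse_fasta_cds
from codonbias.pipeline import RunConfig, run_species


def main() -> None:
    config = RunConfig(out_dir=RESULTS / "study")
    rows, hf_sets = [], {}
    for name in STUDY_SETS:
        records = parse_fasta_cds(FASTA_DIR / f"{name}.fasta", species=name)
        bundle = run_species(records, name, config)
        if "error" in bundle:
            raise SystemExit(f"{name}: {bundle['error']}")
        rows.append(bundle["composition"].iloc[0])
        hf_sets[name] = bundle["hf_codons"]
    table = pd.DataFrame(rows)
    print("Composition (percent GC by codon position):")
    print(table.to_string(index=False))
    print("\nHF codons per set:")
    for name, hf in hf_sets.items():
        print(f"  {name}: {len(hf)} HF codons")
    common = set.intersection(*(set(v) for v in hf_sets.values()))
    print(f"\ncommon HF codons across the nine sets ({len(common)}): "
          f"{', '.join(sorted(common))}")
    print(f"\nreport bundles written under {RESULTS / 'study'}")


if __name__ == "__main__":
    main()
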