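#!/usr/bin/env python
"""Fetch the nine forage-legume chloroplast genomes and rerun the analysis.

Downloads each RefSeq flat file into data/genomes/ (only with --fetch; the
library itself never touches the network), then runs the full per-species
pipeline and prints the headline quantities: per-species composition and
kept-CDS counts, RSCU extremes, shared high-frequency codons, preferred-codon
A/T share, neutrality slopes, CA axis-1 inertia, and the optimal-codon total.

    python scripts/reproduce_study.py --fetch
    python scripts/reproduce_study.py --out-dir results/study
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.request
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "data" / "genomes"

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=gbwithparts&retmode=text&id={accession}"
)


def fetch_genomes() -> None:
    from codonbias.study import STUDY_ACCESSIONS

    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for species, accession in STUDY_ACCESSIONS.items():
        dest = DATA_DIR / f"{accession}.gb"
        if dest.exists():
            print(f"{accession} ({species}): already present")
            continue
        print(f"{accession} ({species}): fetching ...")
        with urllib.request.urlopen(EFETCH.format(accession=accession)) as fh:
            dest.write_bytes(fh.read())
        time.sleep(0.4)  # NCBI rate courtesy


def run_study(out_dir: Path | None) -> int:
    import pandas as pd

    from codonbias.io import extract_cds_from_genbank, filter_cds
    from codonbias.metrics import count_codons
    from codonbias.pipeline import RunConfig, run_cross_species, run_species
    from codonbias.study import STUDY_ACCESSIONS

    missing = [
        acc for acc in STUDY_ACCESSIONS.values()
        if not (DATA_DIR / f"{acc}.gb").exists()
    ]
    if missing:
        print(f"missing genome files for {missing}; run with --fetch first",
              file=sys.stderr)
        return 2

    config = RunConfig(out_dir=out_dir)
    bundles = []
    comp_rows = []
    for species, accession in STUDY_ACCESSIONS.items():
        records = extract_cds_from_genbank(
            DATA_DIR / f"{accession}.gb", species=species
        )
        bundle = run_species(records, species, config)
        if "error" in bundle:
            print(f"{species}: {bundle['error']}", file=sys.stderr)
            return 3
        bundles.append(bundle)
        row = bundle["composition"].iloc[0].to_dict()
        row.update(
            accession=accession,
            n_before=bundle["n_input"],
            n_after=bundle["n_kept"],
            slope=bundle["neutrality"].slope[0],
            r=bundle["neutrality"].r[0],
            axis1_pct=bundle["coa_inertia"].inertia_pct[0],
            axis1_4_pct=bundle["coa_inertia"].inertia_pct[:4].sum(),
            n_optimal=len(bundle["optimal_codons"].optimal),
        )
        comp_rows.append(row)

    table = pd.DataFrame(comp_rows)
    cols = ["species", "accession", "n_before", "n_after", "l_aa",
            "gc1", "gc2", "gc3", "gc_mean", "slope", "r",
            "axis1_pct", "axis1_4_pct", "n_optimal"]
    print("\nPer-species summary:")
    print(table[cols].to_string(index=False))

    rscu_by_species = {
        b["species"]: {r.codon: r.rscu for r in b["rscu"].itertuples()}
        for b in bundles
    }
    flat = [(v, c, sp) for sp, d in rscu_by_species.items()
            for c, v in d.items() if v > 0]
    print(f"\nmax RSCU: {max(flat)[0]:.2f} at {max(flat)[1]} ({max(flat)[2]})")
    print(f"min RSCU: {min(flat)[0]:.2f} at {min(flat)[1]} ({min(flat)[2]})")

    cross = run_cross_species(bundles)
    print(f"\ncommon HF codons ({len(cross['common_hf_codons'])}): "
          f"{', '.join(cross['common_hf_codons'])}")
    over = None
    for d in rscu_by_species.values():
        s = {c for c, v in d.items() if v > 1.6}
        over = s if over is None else over & s
    print(f"overrepresented (RSCU > 1.6) in all nine ({len(over)}): "
          f"{', '.join(sorted(over))}")
    print(f"preferred-codon A/T share: {cross['preferred_codon_at_pct']:.2f}%")
    print(f"optimal codons total: {cross['n_optimal_total']}")
    print(f"common optimal codons: {', '.join(cross['common_optimal_codons'])}")

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table[cols].to_csv(out_dir / "study_summary.tsv", sep="\t", index=False)
    return 0


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fetch", action="store_true",
                        help="download the genome flat files from NCBI")
    parser.add_argument("--out-dir", type=Path, default=None)
    args = parser.parse_args()
    if args.fetch:
        fetch_genomes()
    return run_study(args.out_dir)


if __name__ == "__main__":
    sys.exit(main())
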