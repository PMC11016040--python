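"""Study inputs: the nine forage-legume chloroplast genome accessions.

The comparative analysis this package was built around runs on the NCBI
RefSeq plastomes below. The library never downloads them itself (see
scripts/reproduce_study.py for a fetch-and-run driver); the mapping lives
here so every driver and test names the inputs consistently.
"""

#: species -> RefSeq accession of its chloroplast genome
STUDY_ACCESSIONS: dict[str, str] = {
    "Trifolium repens": "NC_024036.1",
    "Melilotus officinalis": "NC_070051.1",
    "Galega orientalis": "NC_069214.1",
    "Clitoria ternatea": "NC_047365.1",
    "Astragalus laxmannii": "NC_052923.1",
    "Galega officinalis": "NC_051885.1",
    "Pisum sativum": "NC_014057.1",
    "Stylosanthes guianensis": "NC_058691.1",
    "Medicago sativa": "NC_042841.1",
}
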