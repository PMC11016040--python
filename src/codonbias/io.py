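"""Reading CDS sets from FASTA or GenBank and applying the five CDS filters.

A coding sequence enters the downstream statistics only if it

1. has a length that is an integer multiple of 3 (``frame``),
2. is at least 300 nt long (``min_length``),
3. contains only the unambiguous bases A, C, G, T (``alphabet``),
4. starts with ATG (``start_codon``) and ends with TAA/TAG/TGA (``stop_codon``),
5. carries no in-frame stop codon before the final one (``internal_stop``).

Rejected records are reported with the first rule they fail, in that fixed
order, so filter reports are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetics import STOP_CODONS, START_CODON

MIN_LENGTH_NT = 300

#: Rule identifiers in evaluation (and reporting) order.
FILTER_RULES = (
    "frame",
    "min_length",
    "alphabet",
    "start_codon",
    "stop_codon",
    "internal_stop",
)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence, 5'->3' in coding orientation."""

    id: str
    sequence: str
    species: str = ""
    source: str = "fasta"

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    """Outcome of filter_cds: kept count plus per-record first failure."""

    n_input: int
    n_kept: int
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def to_rows(self, kept_ids: Sequence[str]) -> list[dict]:
        rows = [{"id": i, "status": "kept", "failed_rule": ""} for i in kept_ids]
        rows += [
            {"id": i, "status": "rejected", "failed_rule": r}
            for i, r in self.rejections
        ]
        return rows


def parse_fasta_cds(path: str | Path, species: str = "") -> list[CdsRecord]:
    """Read a multi-FASTA of nucleotide CDS; sequences are uppercased.

    Raises ValueError when the file has sequence data before any header.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError(
                f"{path}: line {lineno} precedes any FASTA header"
            )
        break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            CdsRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                species=species,
                source="fasta",
            )
        )
    return records


def extract_cds_from_genbank(path: str | Path, species: str = "") -> list[CdsRecord]:
    """Extract every CDS feature of a GenBank flat file as a CdsRecord.

    Joined (multi-interval) locations are concatenated in feature order and
    minus-strand features reverse-complemented, so each record reads 5'->3'
    in coding orientation. Features with coordinates outside the parent
    sequence raise a ValueError naming the feature.
    """
    path = Path(path)
    records: list[CdsRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        genome_len = len(rec.seq)
        sp = species or rec.annotations.get("organism", rec.id)
        counter: dict[str, int] = {}
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            name = _feature_name(feat, counter)
            for part in feat.location.parts:
                if int(part.start) < 0 or int(part.end) > genome_len:
                    raise ValueError(
                        f"{path}: CDS {name} coordinates {part} outside "
                        f"sequence of length {genome_len}"
                    )
            seq = str(feat.extract(rec.seq)).upper()
            records.append(
                CdsRecord(id=name, sequence=seq, species=sp, source="genbank")
            )
    return records


def _feature_name(feat, counter: dict[str, int]) -> str:
    q = feat.qualifiers
    base = (q.get("gene") or q.get("locus_tag") or q.get("protein_id") or ["cds"])[0]
    counter[base] = counter.get(base, 0) + 1
    # multi-copy genes (e.g. inverted-repeat duplicates) stay distinct records
    return base if counter[base] == 1 else f"{base}.{counter[base]}"


def first_failed_rule(seq: str) -> str | None:
    """Return the identifier of the first filter rule violated, or None."""
    if len(seq) % 3:
        return "frame"
    if len(seq) < MIN_LENGTH_NT:
        return "min_length"
    if not _VALID_BASES.issuperset(seq):
        return "alphabet"
    if not seq.startswith(START_CODON):
        return "start_codon"
    if seq[-3:] not in STOP_CODONS:
        return "stop_codon"
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return "internal_stop"
    return None


def filter_cds(
    records: Iterable[CdsRecord],
) -> tuple[list[CdsRecord], FilterReport]:
    """Apply the five CDS quality rules; rejections are reported, not raised."""
    records = list(records)
    kept: list[CdsRecord] = []
    rejections: list[tuple[str, str]] = []
    for rec in records:
        rule = first_failed_rule(rec.sequence)
        if rule is None:
            kept.append(rec)
        else:
            rejections.append((rec.id, rule))
    report = FilterReport(
        n_input=len(records), n_kept=len(kept), rejections=rejections
    )
    return kept, report


def write_filter_report(
    report: FilterReport, kept: Sequence[CdsRecord], path: str | Path
) -> None:
    """Write the filter outcome as TSV with columns id, status, failed_rule."""
    import pandas as pd

    rows = report.to_rows([r.id for r in kept])
    pd.DataFrame(rows, columns=["id", "status", "failed_rule"]).to_csv(
        path, sep="\t", index=False
    )


def write_fasta(records: Sequence[CdsRecord], path: str | Path) -> None:
    """Write CDS records as multi-FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
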