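"""Codon usage frequency comparison against model-organism tables.

Frequencies are per-thousand codons, the convention of the Kazusa codon
usage database text format ("CODON freq (count)" entries in four-column
blocks, RNA or DNA alphabet). The host/model frequency ratio is banded:
a ratio >= 2 or <= 0.5 marks a codon as divergent between the two organisms
(a poor heterologous-expression pairing), while the open interval (0.5, 2)
marks it similar. Codons with zero model frequency have an undefined ratio
and are reported separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .genetics import CODONS
from .metrics import CodonCountTable

_ENTRY = re.compile(r"([ACGTUacgtu]{3})\s+(\d+(?:\.\d+)?)\s*(?:\(\s*(\d+)\s*\))?")


@dataclass
class FrequencyTable:
    """Per-thousand codon usage frequencies for one organism."""

    organism: str
    freq: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.freq)
        if missing:
            raise ValueError(f"missing codons: {sorted(missing)[:4]} ...")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("negative frequency")


def parse_kazusa_table(text: str, organism: str = "") -> FrequencyTable:
    """Parse Kazusa-style codon usage text; U is mapped to T.

    Raises ValueError for duplicate or missing codons.
    """
    freq: dict[str, float] = {}
    for m in _ENTRY.finditer(text):
        codon = m.group(1).upper().replace("U", "T")
        if codon in freq:
            raise ValueError(f"duplicate codon {codon}")
        freq[codon] = float(m.group(2))
    missing = set(CODONS) - set(freq)
    if missing:
        raise ValueError(f"table lacks codons: {sorted(missing)}")
    return FrequencyTable(organism=organism, freq=freq)


def read_kazusa_file(path: str | Path, organism: str = "") -> FrequencyTable:
    path = Path(path)
    return parse_kazusa_table(path.read_text(), organism or path.stem)


def write_kazusa_table(table: FrequencyTable, path: str | Path) -> None:
    """Write a frequency table in the four-column Kazusa text layout."""
    lines = []
    for i in range(0, 64, 4):
        chunk = [
            f"{c} {table.freq[c]:.1f}(     0)" for c in CODONS[i : i + 4]
        ]
        lines.append("  ".join(chunk))
    Path(path).write_text("\n".join(lines) + "\n")


def per_thousand_frequencies(
    table: CodonCountTable, organism: str = ""
) -> FrequencyTable:
    """Convert codon counts to per-thousand frequencies (sums to 1000)."""
    n = table.n_codons
    if n == 0:
        raise ValueError("empty codon count table")
    return FrequencyTable(
        organism=organism,
        freq={c: 1000.0 * table.counts[c] / n for c in CODONS},
    )


@dataclass
class ComparisonResult:
    host: str
    model: str
    n_divergent: int
    n_similar: int
    divergent: list[str] = field(default_factory=list)
    undefined: list[str] = field(default_factory=list)
    ratios: dict[str, float] = field(default_factory=dict)


def compare_frequencies(
    host: FrequencyTable, model: FrequencyTable
) -> ComparisonResult:
    """Band the host/model frequency ratio for all 64 codons.

    Ratios are taken on the per-thousand frequencies exactly as given (both
    tables are expected on the same per-thousand scale); boundary ratios of
    exactly 2 or 0.5 fall in the divergent band.
    """
    divergent, undefined = [], []
    ratios: dict[str, float] = {}
    for c in CODONS:
        if model.freq[c] == 0:
            undefined.append(c)
            continue
        ratio = host.freq[c] / model.freq[c]
        ratios[c] = ratio
        if ratio >= 2.0 or ratio <= 0.5:
            divergent.append(c)
    n_sim = 64 - len(divergent) - len(undefined)
    return ComparisonResult(
        host=host.organism,
        model=model.organism,
        n_divergent=len(divergent),
        n_similar=n_sim,
        divergent=divergent,
        undefined=undefined,
        ratios=ratios,
    )
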