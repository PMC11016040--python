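"""Synthetic CDS generators with controlled codon-usage structure.

Every pipeline stage is testable without downloads: the generators emit
gene sets shaped like a chloroplast CDS complement (by default ~48 genes per
set, lengths >= 300 nt and multiples of 3, AT-rich third positions around
GC3 = 27.5%) with three independently tunable knobs:

* a per-family Dirichlet concentration controlling selection-like codon
  preference sharpness (low = sharp bias, high/None = uniform, i.e. a
  mutation-only gene);
* a third-position GC target emulating compositional (mutation) pressure;
* a planted linear GC12-GC3 relationship with Gaussian noise for
  neutrality-plot parameter recovery.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import FAMILIES, FAMILY_SIZE, SENSE_CODONS, STOP_CODONS
from .io import CdsRecord

_GC = frozenset("GC")

_AMINO_ACIDS = tuple(aa for aa in FAMILIES if aa != "*")


@dataclass(frozen=True)
class SynthesisParams:
    """Controls for generate_cds_set.

    concentration is the symmetric Dirichlet parameter for within-family
    codon preferences; None means exactly uniform preferences (the
    mutation-only limit). gc3 is the target third-position G+C fraction of
    degenerate families. Defaults mirror a small AT-rich plastid gene set.
    """

    n_genes: int = 48
    min_length_nt: int = 300
    max_length_nt: int = 2400
    concentration: float | None = 1.0
    gc3: float = 0.275
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length_nt < 300 or self.min_length_nt % 3:
            raise ValueError("min length must be >= 300 and a multiple of 3")
        if self.max_length_nt < self.min_length_nt:
            raise ValueError("max length below min length")
        if not 0.0 <= self.gc3 <= 1.0:
            raise ValueError("gc3 target must lie in [0, 1]")


def _tilted_family_probs(
    pref: np.ndarray, codons: tuple[str, ...], theta: float
) -> np.ndarray:
    """Tilt within-family preferences by the third-position GC weight theta."""
    tilt = np.array([theta if c[2] in _GC else 1.0 - theta for c in codons])
    w = pref * tilt
    total = w.sum()
    if total <= 0:
        raise ValueError(
            f"third-position tilt {theta} infeasible for family {codons}: "
            "no codon with positive weight"
        )
    return w / total


def _calibrate_tilt(
    prefs: dict[str, np.ndarray], gc3: float
) -> dict[str, np.ndarray]:
    """Choose the tilt so the gene's expected GC3 equals the target.

    With amino acids drawn uniformly, the expected third-position GC is the
    mean over families of the tilted within-family GC-ending probability —
    a monotone function of the tilt weight, solved by bisection. The
    non-degenerate Met (ATG) and Trp (TGG) floor expected GC3 at 0.10.
    """
    from scipy.optimize import brentq

    def expected_gc3(theta: float) -> float:
        tot = 0.0
        for aa in _AMINO_ACIDS:
            codons = FAMILIES[aa]
            if len(codons) == 1:
                tot += 1.0 if codons[0][2] in _GC else 0.0
                continue
            p = _tilted_family_probs(prefs[aa], codons, theta)
            tot += sum(pi for pi, c in zip(p, codons) if c[2] in _GC)
        return tot / len(_AMINO_ACIDS)

    lo, hi = expected_gc3(0.0), expected_gc3(1.0)
    if not lo <= gc3 <= hi:
        raise ValueError(
            f"gc3 target {gc3} outside the feasible range [{lo:.3f}, {hi:.3f}] "
            "for these family preferences"
        )
    if gc3 == lo:
        theta = 0.0
    elif gc3 == hi:
        theta = 1.0
    else:
        theta = brentq(lambda t: expected_gc3(t) - gc3, 0.0, 1.0, xtol=1e-10)
    out = {}
    for aa in _AMINO_ACIDS:
        codons = FAMILIES[aa]
        if len(codons) == 1:
            out[aa] = np.ones(1)
        else:
            out[aa] = _tilted_family_probs(prefs[aa], codons, theta)
    return out


def generate_cds_set(params: SynthesisParams) -> list[CdsRecord]:
    """Sample a reproducible CDS set passing all five quality filters.

    Each gene draws its own within-family preference vectors (Dirichlet),
    tilts them toward the third-position GC target, samples amino acids
    uniformly for the interior, and wraps the codons in ATG ... stop.
    """
    rng = np.random.default_rng(params.seed)
    records = []
    n_cod_min = params.min_length_nt // 3
    n_cod_max = params.max_length_nt // 3
    for g in range(params.n_genes):
        n_codons = int(rng.integers(n_cod_min, n_cod_max + 1))
        prefs: dict[str, np.ndarray] = {}
        for aa in _AMINO_ACIDS:
            k = FAMILY_SIZE[aa]
            if params.concentration is None:
                prefs[aa] = np.full(k, 1.0 / k)
            else:
                # floor keeps every codon reachable (sharp draws can hit 0.0)
                pref = rng.dirichlet(np.full(k, params.concentration))
                pref = np.clip(pref, 1e-9, None)
                prefs[aa] = pref / pref.sum()
        fam_probs = _calibrate_tilt(prefs, params.gc3)
        aas = rng.choice(len(_AMINO_ACIDS), size=n_codons - 2)
        body = []
        for ai in aas:
            aa = _AMINO_ACIDS[ai]
            codons = FAMILIES[aa]
            body.append(codons[rng.choice(len(codons), p=fam_probs[aa])])
        stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
        seq = "ATG" + "".join(body) + stop
        records.append(
            CdsRecord(id=f"synth_{g:03d}", sequence=seq, species="synthetic",
                      source="fasta")
        )
    return records


def generate_neutrality_set(
    b: float,
    noise_sd: float,
    n: int,
    seed: int,
    intercept: float = 0.2,
    n_codons: int = 600,
    gc3_range: tuple[float, float] = (0.10, 0.70),
) -> list[CdsRecord]:
    """Genes whose (GC3, GC12) pairs follow GC12 = a + b*GC3 + eps.

    Per gene, a GC3 target is drawn uniformly on ``gc3_range`` and a GC12
    target from the planted line plus Gaussian noise; codons are then sampled
    i.i.d. from the product of position-specific base distributions
    (restricted to sense codons), so the realized compositions scatter around
    the targets by multinomial noise only. The fairly long default gene
    length and wide GC3 spread keep that errors-in-variables attenuation of
    the regression slope well below its standard error at n = 200.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError("slope b must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sense = np.array(SENSE_CODONS)
    records = []
    for g in range(n):
        gc3_t = rng.uniform(*gc3_range)
        gc12_t = intercept + b * gc3_t + rng.normal(0.0, noise_sd)
        gc12_t = min(max(gc12_t, 0.02), 0.98)
        probs = _positional_codon_probs(gc12_t, gc3_t)
        body = rng.choice(sense, size=n_codons - 2, p=probs)
        seq = "ATG" + "".join(body) + "TAA"
        records.append(
            CdsRecord(id=f"neut_{g:03d}", sequence=seq, species="synthetic",
                      source="fasta")
        )
    return records


def _positional_codon_probs(gc12: float, gc3: float) -> np.ndarray:
    """Position-specific base model over sense codons.

    The first two positions follow the GC12 target exactly; the third
    position follows the GC3 target renormalized over the bases that do not
    complete a stop codon given the first two (so excluding stops does not
    distort the GC12 marginal).
    """
    def base_p(gc: float) -> dict[str, float]:
        return {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}

    p12 = base_p(gc12)
    p3 = base_p(gc3)
    z = {}  # prefix -> normalizer over allowed third bases
    for c in SENSE_CODONS:
        z[c[:2]] = z.get(c[:2], 0.0) + p3[c[2]]
    w = np.array(
        [p12[c[0]] * p12[c[1]] * p3[c[2]] / z[c[:2]] for c in SENSE_CODONS],
        dtype=float,
    )
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate base composition")
    return w / total


def uniform_usage_gene(n_per_codon: int, seed: int = 0) -> CdsRecord:
    """A gene using every sense codon exactly n_per_codon times.

    Codon order is shuffled by seed; an ATG start and a TAA stop wrap the
    body. Within every family usage is exactly uniform, so Wright's ENC
    attains the uniform-usage limit of 61 (the raw estimator overshoots and
    is capped).
    """
    if n_per_codon < 1:
        raise ValueError("n_per_codon must be >= 1")
    rng = np.random.default_rng(seed)
    body = [c for c in SENSE_CODONS for _ in range(n_per_codon)]
    rng.shuffle(body)
    seq = "ATG" + "".join(body) + "TAA"
    return CdsRecord(id="uniform", sequence=seq, species="synthetic",
                     source="fasta")


def realized_gc_fractions(record: CdsRecord) -> tuple[float, float]:
    """(gc12, gc3) fractions of one CDS — convenience for generator tests."""
    seq = record.sequence
    n = len(seq) // 3
    gc12 = sum(seq[i] in _GC for i in range(len(seq)) if i % 3 != 2)
    gc3 = sum(seq[i] in _GC for i in range(2, len(seq), 3))
    return gc12 / (2 * n), gc3 / n

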