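"""Per-species and cross-species orchestration of the full analysis.

run_species turns one filtered CDS set into the machine-readable reports
behind every table and figure substrate of the study design: filter report,
composition row, RSCU/RFSC/HF long table, per-gene index table, ENC-plot /
PR2 / neutrality tables, optimal-codon list, and CA coordinates with
axis-index correlations. run_cross_species aggregates species bundles into
the shared-HF set, optimal-codon totals, preferred-codon A/T share, and
model-organism frequency comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import coa as coa_mod
from .comparison import (
    FrequencyTable,
    compare_frequencies,
    per_thousand_frequencies,
)
from .indices import GeneIndexRecord, cai, cai_weights, enc, enc_expected
from .io import CdsRecord, filter_cds
from .metrics import (
    CodonCountTable,
    amino_acid_count,
    classify_hf_codons,
    composition_row,
    count_codons,
    gc_by_position,
    rscu_long_table,
    rscu_rfsc,
)
from .sources import (
    neutrality_fit,
    optimal_codons,
    pr2_point,
    select_expression_datasets,
)


@dataclass
class RunConfig:
    """Knobs shared by every stage; defaults follow the study conventions."""

    extreme_fraction: float = 0.1
    delta_rscu_threshold: float = 0.08
    hf_rfsc_cutoff: float = 0.6
    hf_excess: float = 0.5
    n_axes: int = 4
    out_dir: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.extreme_fraction <= 0.5:
            raise ValueError("extreme_fraction must lie in (0, 0.5]")
        if self.delta_rscu_threshold <= 0:
            raise ValueError("delta_rscu_threshold must be positive")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def gene_index_records(
    per_gene: list[tuple[str, CodonCountTable]], config: RunConfig | None = None
) -> list[GeneIndexRecord]:
    """Per-gene index table: GC composition, ENC, CAI, L_aa, PR2 coordinates.

    The CAI reference is the pooled count table of the ENC-defined
    high-expression set (lowest-ENC extreme fraction).
    """
    config = config or RunConfig()
    partial = []
    for gid, table in per_gene:
        gc = gc_by_position(table)
        p = pr2_point(table, gid)
        partial.append(
            GeneIndexRecord(
                gene_id=gid, gc=gc, enc=enc(table), cai=math.nan,
                l_aa=amino_acid_count(table), pr2_x=p.x, pr2_y=p.y,
            )
        )
    high_ids, _ = select_expression_datasets(partial, config.extreme_fraction)
    reference = _pool(t for gid, t in per_gene if gid in high_ids)
    weights = cai_weights(reference)
    by_id = dict(per_gene)
    return [
        GeneIndexRecord(
            gene_id=g.gene_id, gc=g.gc, enc=g.enc,
            cai=cai(by_id[g.gene_id], weights),
            l_aa=g.l_aa, pr2_x=g.pr2_x, pr2_y=g.pr2_y,
        )
        for g in partial
    ]


def _pool(tables) -> CodonCountTable:
    pooled = CodonCountTable({}, scope="species")
    for t in tables:
        pooled = pooled + t
    return pooled


def run_species(
    records: list[CdsRecord],
    species: str,
    config: RunConfig | None = None,
) -> dict:
    """Run every analysis stage for one species; returns the report bundle.

    When config.out_dir is set the bundle is also written as TSV files under
    out_dir/<species>/. A stage failure is recorded under 'error' with the
    stage name and later stages are skipped.
    """
    config = config or RunConfig()
    bundle: dict = {"species": species}
    stage = "filter"
    try:
        kept, report = filter_cds(records)
        bundle["filter_report"] = pd.DataFrame(
            report.to_rows([r.id for r in kept]),
            columns=["id", "status", "failed_rule"],
        )
        bundle["n_input"], bundle["n_kept"] = report.n_input, report.n_kept
        if not kept:
            raise ValueError("no CDS passed the filters")

        stage = "composition"
        per_gene = [(r.id, count_codons(r)) for r in kept]
        pooled = _pool(t for _, t in per_gene)
        bundle["composition"] = pd.DataFrame([composition_row(species, pooled)])

        stage = "rscu"
        pooled_rscu = rscu_rfsc(pooled)
        hf = classify_hf_codons(
            pooled_rscu, config.hf_rfsc_cutoff, config.hf_excess
        )
        bundle["rscu"] = rscu_long_table(species, pooled_rscu, hf)
        bundle["hf_codons"] = sorted(hf)

        stage = "gene_indices"
        genes = gene_index_records(per_gene, config)
        bundle["gene_indices"] = pd.DataFrame(
            {
                "gene": g.gene_id,
                "gc3s": round(g.gc.gc3s, 2),
                "gc12": round(g.gc.gc12, 2),
                "gc3": round(g.gc.gc3, 2),
                "gc_mean": round(g.gc.gc_mean, 2),
                "enc": round(g.enc, 2),
                "cai": round(g.cai, 4),
                "l_aa": g.l_aa,
                "pr2_x": round(g.pr2_x, 4),
                "pr2_y": round(g.pr2_y, 4),
            }
            for g in genes
        )

        stage = "enc_plot"
        bundle["enc_plot"] = pd.DataFrame(
            {
                "gene": g.gene_id,
                "gc3s": round(g.gc.gc3s, 2),
                "enc": round(g.enc, 2),
                "expected_enc": round(enc_expected(g.gc.gc3s / 100.0), 2),
            }
            for g in genes
            if not math.isnan(g.gc.gc3s)
        )

        stage = "neutrality"
        fit = neutrality_fit(genes)
        bundle["neutrality"] = pd.DataFrame(
            [
                {
                    "species": species,
                    "slope": round(fit.slope, 4),
                    "intercept": round(fit.intercept, 4),
                    "r": round(fit.r, 4),
                    "p": fit.p_value,
                    "n_genes": fit.n_genes,
                    "mutation_pct": round(fit.mutation_pct, 2),
                    "selection_pct": round(fit.selection_pct, 2),
                }
            ]
        )

        stage = "optimal_codons"
        high_ids, low_ids = select_expression_datasets(
            genes, config.extreme_fraction
        )
        by_id = dict(per_gene)
        result = optimal_codons(
            _pool(by_id[g] for g in high_ids),
            _pool(by_id[g] for g in low_ids),
            config.delta_rscu_threshold,
            high_ids=sorted(high_ids),
            low_ids=sorted(low_ids),
        )
        bundle["optimal_codons"] = result

        stage = "coa"
        matrix = coa_mod.build_rscu_matrix(per_gene)
        ca = coa_mod.correspondence_analysis(matrix, config.n_axes)
        coords = pd.DataFrame(
            ca.row_coords, columns=[f"axis{k+1}" for k in range(ca.n_axes)]
        )
        coords.insert(0, "gene", ca.genes)
        bundle["coa_coords"] = coords
        bundle["coa_inertia"] = pd.DataFrame(
            {
                "axis": range(1, len(ca.inertia_fraction) + 1),
                "inertia_pct": [round(100 * f, 2) for f in ca.inertia_fraction],
            }
        )
        gene_set = set(ca.genes)
        bundle["coa_correlations"] = coa_mod.axis_index_correlations(
            ca, [g for g in genes if g.gene_id in gene_set]
        )
        bundle["coa"] = ca
        bundle["gene_index_records"] = genes
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        bundle["error"] = StageError(stage, exc)
        return bundle

    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir) / species)
    return bundle


def run_cross_species(
    bundles: list[dict],
    model_tables: list[FrequencyTable] | None = None,
    per_species_counts: dict[str, CodonCountTable] | None = None,
) -> dict:
    """Aggregate per-species bundles into the cross-species report.

    Returns the common HF codon set, per-species and total optimal-codon
    counts, the A/T share of preferred (RSCU > 1) codons, and — when model
    tables and pooled species counts are given — the frequency-ratio band
    counts against each model organism.
    """
    ok = [b for b in bundles if "error" not in b]
    if len(ok) < 2:
        raise ValueError("need at least 2 successfully processed species")

    common_hf = set(ok[0]["hf_codons"])
    for b in ok[1:]:
        common_hf &= set(b["hf_codons"])

    opt_rows = []
    common_optimal: set[str] | None = None
    for b in ok:
        res = b["optimal_codons"]
        opt_rows.append(
            {
                "species": b["species"],
                "n_optimal": len(res.optimal),
                "codons": ",".join(res.optimal),
            }
        )
        common_optimal = (
            set(res.optimal)
            if common_optimal is None
            else common_optimal & set(res.optimal)
        )

    n_pref = n_pref_at = 0
    for b in ok:
        pref = [
            row.codon
            for row in b["rscu"].itertuples()
            if row.rscu > 1.0
        ]
        n_pref += len(pref)
        n_pref_at += sum(1 for c in pref if c[2] in "AT")

    report: dict = {
        "common_hf_codons": sorted(common_hf),
        "optimal_by_species": pd.DataFrame(opt_rows),
        "n_optimal_total": int(sum(r["n_optimal"] for r in opt_rows)),
        "common_optimal_codons": sorted(common_optimal or set()),
        "preferred_codon_at_pct": (
            100.0 * n_pref_at / n_pref if n_pref else math.nan
        ),
    }

    if model_tables and per_species_counts:
        rows = []
        for species, counts in per_species_counts.items():
            host = per_thousand_frequencies(counts, species)
            for model in model_tables:
                cmp_res = compare_frequencies(host, model)
                rows.append(
                    {
                        "host": species,
                        "model": model.organism,
                        "divergent": cmp_res.n_divergent,
                        "similar": cmp_res.n_similar,
                        "undefined": len(cmp_res.undefined),
                    }
                )
        report["model_comparison"] = pd.DataFrame(rows)
    return report


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, value in bundle.items():
        if isinstance(value, pd.DataFrame):
            value.to_csv(out_dir / f"{key}.tsv", sep="\t", index=False)
    res = bundle.get("optimal_codons")
    if res is not None:
        pd.DataFrame(
            {
                "codon": list(res.delta_rscu),
                "rscu_high": [res.rscu_high[c] for c in res.delta_rscu],
                "rscu_low": [res.rscu_low[c] for c in res.delta_rscu],
                "delta_rscu": [res.delta_rscu[c] for c in res.delta_rscu],
                "optimal": [c in res.optimal for c in res.delta_rscu],
            }
        ).to_csv(out_dir / "optimal_codons.tsv", sep="\t", index=False)
    sidecar = {
        "species": bundle.get("species"),
        "n_input": bundle.get("n_input"),
        "n_kept": bundle.get("n_kept"),
        "hf_codons": bundle.get("hf_codons"),
        "optimal": list(res.optimal) if res is not None else None,
    }
    (out_dir / "summary.json").write_text(json.dumps(sidecar, indent=1))
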