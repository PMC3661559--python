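"""End-to-end discovery pipeline: introns -> inverted repeats -> expression
gate -> hairpin fold -> siRNA exclusion -> duplex calling -> classification.

All numeric thresholds live in :class:`PipelineConfig`, whose defaults are
the study conditions: 100-read expression gate summed across libraries,
>20-read mature/star support, 40% duplex read ratio, <=4 duplex mismatches,
<3000-nt cluster gap, 2.5 target-score cutoff, k=10 / 50-iteration k-means.
Each stage logs its survivor count so a run can be audited as a funnel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import classify_profile, ir_finder, mirna_caller, srna_mapping
from .genome_io import GeneModel, Intron, SmallRnaLibrary, extract_introns, merge_libraries
from .hairpin_fold import FoldEngine, assess_hairpin, fold
from .mirna_caller import PrecursorCall

logger = logging.getLogger("intromir")


@dataclass
class PipelineConfig:
    """All module thresholds, one flat symbol table."""

    # ir.*
    ir_seed_len: int = 11
    ir_min_identity: float = 0.8
    ir_join_gap: int = 15
    ir_min_len: int = 50
    ir_min_cov: float = 0.30
    # expression gate
    min_total_reads: int = 100
    # fold.*
    fold_min_loop: int = 3
    fold_min_paired_fraction: float = 0.5
    fold_max_stems: int = 1
    # sirna.*
    sirna_window: int = 30
    sirna_min_starts: int = 10
    sirna_max_antisense_fraction: float = 0.10
    # caller.*
    caller_min_reads: int = 20
    caller_max_mismatches: int = 4
    caller_max_bulge_size: int = 2
    caller_max_bulges: int = 1
    caller_star_jitter: int = 0
    caller_allow_star_deficient: bool = True
    caller_min_ratio: float = 0.40
    mirna_like_min_len: int = 1000
    mirna_like_min_products: int = 8
    # cluster
    cluster_max_gap: int = 3000
    # expr.*
    expr_rpm_factor: float = 2.0
    expr_pseudocount: float = 1.0
    expr_kmeans_k: int = 10
    expr_kmeans_max_iter: int = 50
    expr_max_zero_samples: int = 3
    # target.*
    target_max_score: float = 2.5
    target_cleavage_mode: str = "or"
    seed: int = 0


@dataclass
class DiscoveredPrecursor:
    """A called precursor with its genomic context."""

    call: PrecursorCall
    intron: Intron
    ir: ir_finder.InvertedRepeat

    @property
    def genomic_interval(self) -> tuple[int, int]:
        return self.ir.genomic_start, self.ir.genomic_end

    def locus(self) -> classify_profile.PrecursorLocus:
        return classify_profile.PrecursorLocus(
            self.call.precursor_id,
            self.intron.gene_id,
            self.intron.chrom,
            self.ir.genomic_start,
            self.ir.genomic_end,
            self.intron.ordinal,
            self.call.n_products,
        )


@dataclass
class DiscoveryResults:
    stage_counts: dict[str, int] = field(default_factory=dict)
    precursors: list[DiscoveredPrecursor] = field(default_factory=list)
    classes: list[classify_profile.PrecursorClass] = field(default_factory=list)
    clusters: dict[str, str] = field(default_factory=dict)
    composition: classify_profile.CompositionSummary | None = None

    @property
    def mature_sequences(self) -> list[str]:
        return [
            s for p in self.precursors for s in p.call.mature_sequences
        ]

    def calls_table(self) -> pd.DataFrame:
        rows = []
        for p in self.precursors:
            cls = next(
                (c for c in self.classes if c.precursor_id == p.call.precursor_id), None
            )
            for d in p.call.duplexes:
                rows.append(
                    {
                        "precursor_id": p.call.precursor_id,
                        "precursor_length": len(p.call.hairpin),
                        "product": f".{d.rank}",
                        "mature_sequence": d.mature_sequence,
                        "mature_reads": d.mature_count,
                        "star_reads": d.star_count,
                        "star_deficient": d.star_deficient,
                        "host_gene": p.intron.gene_id,
                        "intron": p.intron.ordinal,
                        "category": cls.category if cls else "",
                        "cluster": (cls.cluster_id or "") if cls else "",
                        "duplex_read_ratio": round(p.call.duplex_read_ratio, 4),
                        "mirna_like": p.call.mirna_like,
                    }
                )
        return pd.DataFrame(rows)


def run_discovery(
    genome,
    models: list[GeneModel],
    libraries: list[SmallRnaLibrary],
    config: PipelineConfig | None = None,
    fold_engine: FoldEngine | None = None,
) -> DiscoveryResults:
    """Execute the discovery funnel and return calls plus stage counts."""
    cfg = config or PipelineConfig()
    results = DiscoveryResults()

    introns = extract_introns(models, genome)
    _log_stage(results, "introns", len(introns))

    irs: list[ir_finder.InvertedRepeat] = []
    for intron in introns:
        if len(intron.sequence) < 2 * cfg.ir_seed_len:
            continue
        hits = ir_finder.self_align_revcomp(
            intron.sequence, cfg.ir_seed_len, cfg.ir_min_identity
        )
        for ir in ir_finder.cluster_hits_to_irs(
            hits,
            intron.intron_id,
            intron.sequence,
            cfg.ir_min_len,
            cfg.ir_min_cov,
            cfg.ir_join_gap,
        ):
            irs.append(ir_finder.with_genomic_coords(ir, intron))
    irs = ir_finder.dedupe_irs(irs) if irs else []
    _log_stage(results, "inverted_repeats", len(irs))

    intron_by_id = {i.intron_id: i for i in introns}
    pooled = merge_libraries(libraries)

    expressed: list[tuple[ir_finder.InvertedRepeat, srna_mapping.ReadStack]] = []
    for ir in irs:
        stack = srna_mapping.map_reads(pooled, ir.sequence, ir.intron_id)
        if srna_mapping.expression_gate(stack, cfg.min_total_reads):
            expressed.append((ir, stack))
    _log_stage(results, "expressed_irs", len(expressed))

    folder = fold_engine or (lambda seq: fold(seq, cfg.fold_min_loop))
    folded = []
    for ir, stack in expressed:
        hairpin = folder(ir.sequence)
        verdict = assess_hairpin(
            hairpin, cfg.fold_min_paired_fraction, cfg.fold_max_stems
        )
        if verdict.accepted:
            folded.append((ir, stack, hairpin))
    _log_stage(results, "good_hairpins", len(folded))

    surviving = []
    for ir, stack, hairpin in folded:
        if srna_mapping.is_continuous_coverage(
            stack, cfg.sirna_window, cfg.sirna_min_starts
        ):
            continue
        if (
            srna_mapping.antisense_unique_fraction(stack)
            > cfg.sirna_max_antisense_fraction
        ):
            continue
        surviving.append((ir, stack, hairpin))
    _log_stage(results, "after_sirna_exclusion", len(surviving))

    counter = 0
    for ir, stack, hairpin in surviving:
        counter += 1
        call = mirna_caller.call_precursor(
            stack,
            hairpin,
            precursor_id=f"{ir.intron_id}.pre{counter}",
            min_reads=cfg.caller_min_reads,
            min_ratio=cfg.caller_min_ratio,
            mirna_like_min_len=cfg.mirna_like_min_len,
            mirna_like_min_products=cfg.mirna_like_min_products,
            max_mismatches=cfg.caller_max_mismatches,
            max_bulge_size=cfg.caller_max_bulge_size,
            max_bulges=cfg.caller_max_bulges,
            star_jitter=cfg.caller_star_jitter,
            allow_star_deficient=cfg.caller_allow_star_deficient,
        )
        if call is not None:
            results.precursors.append(
                DiscoveredPrecursor(call, intron_by_id[ir.intron_id], ir)
            )
    _log_stage(results, "called_precursors", len(results.precursors))
    _log_stage(
        results,
        "mature_mirnas",
        sum(p.call.n_products for p in results.precursors),
    )

    loci = [p.locus() for p in results.precursors]
    results.clusters = classify_profile.assign_clusters(loci, cfg.cluster_max_gap)
    results.classes = classify_profile.categorize(loci, results.clusters)
    results.composition = classify_profile.composition_summary(
        [s.replace("T", "U") for s in results.mature_sequences]
    )
    return results


def _log_stage(results: DiscoveryResults, name: str, count: int) -> None:
    results.stage_counts[name] = count
    logger.info("stage %-22s %6d survivors", name, count)


def run_report(results: DiscoveryResults) -> dict:
    """Machine-readable summary of a discovery run."""
    by_cat = {"UMP": 0, "MMP": 0, "CP": 0}
    for c in results.classes:
        by_cat[c.category] = by_cat.get(c.category, 0) + 1
    return {
        "stage_counts": dict(results.stage_counts),
        "n_precursors": len(results.precursors),
        "n_matures": sum(p.call.n_products for p in results.precursors),
        "n_mirna_like": sum(1 for p in results.precursors if p.call.mirna_like),
        "categories": by_cat,
        "n_clusters": len(set(results.clusters.values())),
        "composition": (
            results.composition.as_dict() if results.composition else {}
        ),
    }
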