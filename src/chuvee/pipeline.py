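"""End-to-end screening pipeline.

Stages: hit-table EVE calling with the voting rule; assembly-quality
filters plus flank-extended redundancy clustering; per-locus architecture
annotation and classification; homolog expansion from complete elements;
solo-LTR detection from the LTRs of complete elements; summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .architecture import (Category, ClassifiedLocus, classify_window,
                           detect_solo_ltrs, expand_homologs)
from .filters import FilterReport, filter_and_deduplicate
from .report import SummaryTable, summarize
from .screen import EveCall, HomologyHit, Strategy, SubjectRecord, call_eves
from .seqio import Contig, find_orfs


@dataclass
class PipelineConfig:
    flank_bp: int = 10_000          # mode II / architecture window size
    min_flank: int = 4_000
    min_orf_aa: int = 100
    cluster_identity: float = 0.90
    evalue_max: float = 1e-4
    domain_min_score: int = 60
    ltr_params: dict = field(default_factory=dict)
    expansion_min_identity: float = 75.0
    expansion_min_hit_len: int = 150
    solo_ltr_tolerance: int = 200
    solo_ltr_min_identity: float = 75.0


@dataclass
class PipelineResult:
    eve_calls: list[EveCall]
    filter_reports: list[FilterReport]
    loci: list[ClassifiedLocus]
    summary: SummaryTable


def _gly_peptide(contig: Contig, eve: EveCall, min_aa: int) -> str:
    """Longest ORF peptide overlapping the EVE locus (its coding region)."""
    locus = eve.locus
    a = max(0, locus.start - 2_000)
    b = min(len(contig.seq), locus.end + 2_000)
    sub = Contig("_g", contig.seq[a:b])
    best = ""
    for orf in find_orfs(sub, min_aa):
        g_start, g_end = a + orf.interval.start, a + orf.interval.end
        if g_start < locus.end and g_end > locus.start and len(orf.peptide) > len(best):
            best = orf.peptide
    return best


def run_pipeline(contigs: list[Contig],
                 hit_tables: dict[Strategy, list[HomologyHit]],
                 taxonomy: dict[str, SubjectRecord],
                 domain_refs: dict[str, str],
                 config: PipelineConfig | None = None,
                 assembly_id: str = "assembly") -> PipelineResult:
    config = config or PipelineConfig()
    by_id = {c.id: c for c in contigs}

    # 1. homology screen: loci + voting + extraction modes
    eves = call_eves(hit_tables, taxonomy, by_id,
                     flank_bp=config.flank_bp, evalue_max=config.evalue_max)

    # 2. assembly-quality filters and redundancy clustering
    survivors, reports = filter_and_deduplicate(
        eves, by_id, min_flank=config.min_flank,
        min_orf_aa=config.min_orf_aa,
        cluster_identity=config.cluster_identity)

    # 3. architecture annotation of each EVE locus
    loci: list[ClassifiedLocus] = []
    for eve in survivors:
        contig = by_id[eve.locus.contig_id]
        locus = classify_window(contig, eve.locus, domain_refs, eve=eve,
                                window_bp=config.flank_bp,
                                min_score=config.domain_min_score,
                                ltr_params=config.ltr_params)
        if locus.category in (Category.ANAKIN_COMPLETE,
                              Category.ANAKIN_DEFECTIVE_2LTR,
                              Category.ANAKIN_DEFECTIVE, Category.SOLO_GLY):
            locus.gly_peptide = _gly_peptide(contig, eve, config.min_orf_aa)
        loci.append(locus)

    # 4. homolog expansion from complete elements (element span = LTR to LTR)
    complete: dict[str, str] = {}
    ltr_library: dict[str, str] = {}
    for locus in loci:
        if locus.category in (Category.ANAKIN_COMPLETE, Category.PAO_COMPLETE) \
                and locus.ltr_pair is not None:
            contig = by_id[locus.locus.contig_id]
            pair = locus.ltr_pair
            key = f"{locus.locus.contig_id}:{pair.left.start}-{pair.right.end}"
            complete[key] = contig.seq[pair.left.start:pair.right.end]
            ltr_library[key + "_L"] = contig.seq[pair.left.start:pair.left.end]
            ltr_library[key + "_R"] = contig.seq[pair.right.start:pair.right.end]

    expanded = expand_homologs(
        complete, contigs, domain_refs, eve_calls=survivors,
        min_identity=config.expansion_min_identity,
        min_hit_len=config.expansion_min_hit_len,
        window_bp=config.flank_bp, min_score=config.domain_min_score,
        existing=loci, ltr_params=config.ltr_params)
    loci.extend(expanded)

    # 5. solo LTRs from the library of complete-element LTRs
    solo = detect_solo_ltrs(
        contigs, ltr_library, domain_refs,
        tolerance=config.solo_ltr_tolerance,
        window_bp=config.flank_bp,
        min_identity=config.solo_ltr_min_identity,
        min_score=config.domain_min_score)
    taken = [l.locus for l in loci]
    for s in solo:
        if any(s.locus.overlap(iv) >= 0.5 * min(len(s.locus), len(iv))
               for iv in taken):
            continue
        loci.append(s)

    loci.sort(key=lambda l: (l.locus.contig_id, l.locus.start))
    return PipelineResult(eve_calls=eves, filter_reports=reports, loci=loci,
                          summary=summarize(loci, assembly_id))
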