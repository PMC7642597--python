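"""Per-assembly summary tables, track/marker exports, truth evaluation.

The summary mirrors the per-genome table layout of the screen: chuvirus
endogenized regions (nucleoprotein, solo glycoprotein, Anakin, RdRp), the
Anakin breakdown (complete / defective with both LTRs / defective), the
same breakdown for Pao elements without glycoprotein, and solo LTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .architecture import Category, ClassifiedLocus
from .seqio import Interval
from .simulate import PlantedTruth

SUMMARY_COLUMNS = [
    "assembly", "nucleoprotein", "solo_glyco", "anakin", "rdrp",
    "anakin_complete", "anakin_defective_2ltr", "anakin_defective",
    "anakin_total", "pao_complete", "pao_defective_2ltr", "pao_defective",
    "pao_total", "solo_ltr",
]


@dataclass
class SummaryTable:
    assembly_id: str
    counts: dict = field(default_factory=dict)  # Category -> int

    def n(self, category: Category) -> int:
        return self.counts.get(category, 0)

    @property
    def anakin_total(self) -> int:
        return (self.n(Category.ANAKIN_COMPLETE)
                + self.n(Category.ANAKIN_DEFECTIVE_2LTR)
                + self.n(Category.ANAKIN_DEFECTIVE))

    @property
    def pao_total(self) -> int:
        return (self.n(Category.PAO_COMPLETE)
                + self.n(Category.PAO_DEFECTIVE_2LTR)
                + self.n(Category.PAO_DEFECTIVE))

    def row(self) -> list:
        return [
            self.assembly_id, self.n(Category.NP_EVE),
            self.n(Category.SOLO_GLY), self.anakin_total,
            self.n(Category.RDRP_EVE), self.n(Category.ANAKIN_COMPLETE),
            self.n(Category.ANAKIN_DEFECTIVE_2LTR),
            self.n(Category.ANAKIN_DEFECTIVE), self.anakin_total,
            self.n(Category.PAO_COMPLETE),
            self.n(Category.PAO_DEFECTIVE_2LTR),
            self.n(Category.PAO_DEFECTIVE), self.pao_total,
            self.n(Category.SOLO_LTR),
        ]


@dataclass
class CategoryEval:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


@dataclass
class EvalReport:
    per_category: dict = field(default_factory=dict)  # Category -> CategoryEval

    @property
    def total(self) -> CategoryEval:
        agg = CategoryEval()
        for ev in self.per_category.values():
            agg.tp += ev.tp
            agg.fp += ev.fp
            agg.fn += ev.fn
        return agg


def summarize(loci: list[ClassifiedLocus], assembly_id: str) -> SummaryTable:
    counts: dict[Category, int] = {}
    for locus in loci:
        if locus.category is Category.NONE:
            continue
        counts[locus.category] = counts.get(locus.category, 0) + 1
    return SummaryTable(assembly_id, counts)


def write_summary_tsv(tables: list[SummaryTable], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for t in tables:
            fh.write("\t".join(str(x) for x in t.row()) + "\n")


def evaluate_against_truth(loci: list[ClassifiedLocus],
                           truth: list[PlantedTruth],
                           min_overlap: float = 0.5,
                           clean_only: bool = True) -> EvalReport:
    """Greedy one-to-one matching of predictions to the planted ledger.

    A prediction matches a planted element when their intervals overlap by
    at least ``min_overlap`` of the shorter one and the categories agree.
    """
    truth = [t for t in truth if t.clean or not clean_only]
    report = EvalReport()
    categories = {t.category for t in truth} | \
        {l.category for l in loci if l.category is not Category.NONE}
    for category in categories:
        ev = CategoryEval()
        preds = [l for l in loci if l.category is category]
        trues = [t for t in truth if t.category is category]
        pairs = []
        for i, p in enumerate(preds):
            for j, t in enumerate(trues):
                ov = p.locus.overlap(t.interval)
                if ov >= min_overlap * min(len(p.locus), len(t.interval)):
                    pairs.append((ov, i, j))
        pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_p: set[int] = set()
        used_t: set[int] = set()
        for ov, i, j in pairs:
            if i in used_p or j in used_t:
                continue
            used_p.add(i)
            used_t.add(j)
            ev.tp += 1
        ev.fp = len(preds) - len(used_p)
        ev.fn = len(trues) - len(used_t)
        report.per_category[category] = ev
    return report


def export_markers(loci: list[ClassifiedLocus],
                   min_gly_aa: int = 100) -> tuple[list, list]:
    """Phylogenetic marker export.

    Set 1: glycoprotein peptides strictly longer than ``min_gly_aa``.
    Set 2: concatenated RT+RH peptides per element (RT first); elements with
    neither RT nor RH are excluded.
    Headers encode assembly locus and category.
    """
    gly_set: list[tuple[str, str]] = []
    rtrh_set: list[tuple[str, str]] = []
    for locus in loci:
        name = (f"{locus.locus.contig_id}_{locus.locus.start}_{locus.locus.end}"
                f"_{locus.category.value}")
        if locus.gly_peptide and len(locus.gly_peptide) > min_gly_aa:
            gly_set.append((f"GLY_{name}", locus.gly_peptide))
        rt = next((d.peptide for d in locus.domains if d.domain.value == "RT"), "")
        rh = next((d.peptide for d in locus.domains if d.domain.value == "RH"), "")
        if rt or rh:
            rtrh_set.append((f"RTRH_{name}", rt + rh))
    return gly_set, rtrh_set


def write_bed6(loci: list[ClassifiedLocus], path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.locus
            fh.write("\t".join((iv.contig_id, str(iv.start), str(iv.end),
                                locus.category.value, "0", iv.strand)) + "\n")


def write_gff3(loci: list[ClassifiedLocus], path) -> None:
    """One parent feature per element, child features per LTR/domain/GLY."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, locus in enumerate(loci, 1):
            iv = locus.locus
            pid = f"locus{i:04d}"
            fh.write("\t".join((
                iv.contig_id, "chuvee", "mobile_genetic_element",
                str(iv.start + 1), str(iv.end), ".", iv.strand, ".",
                f"ID={pid};category={locus.category.value}")) + "\n")
            children = []
            if locus.ltr_pair is not None:
                children += [("long_terminal_repeat", locus.ltr_pair.left),
                             ("long_terminal_repeat", locus.ltr_pair.right)]
            children += [(f"polypeptide_domain", d.interval) for d in locus.domains]
            if locus.eve is not None:
                children.append(("viral_sequence", locus.eve.locus))
            for kind, civ in children:
                fh.write("\t".join((
                    civ.contig_id, "chuvee", kind, str(civ.start + 1),
                    str(civ.end), ".", civ.strand, ".",
                    f"Parent={pid}")) + "\n")


def write_marker_fasta(records: list[tuple[str, str]], path) -> None:
    from .seqio import write_fasta
    write_fasta(records, path)
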