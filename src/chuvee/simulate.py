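"""Synthetic mosquito-like assemblies with planted elements and truth ledger.

The generator plants copies of one (or more) BEL-Pao element "family" into
random background contigs.  A family consists of one LTR sequence (length
drawn from a truncated normal, mean 670 sd 120, clipped to 100-900 bp), five
domain coding blocks (GAG 900, PR 300, RT 700, RH 450, INT 850 nt — typical
Pao proportions), family-shared spacers, and one chuvirus-derived
glycoprotein lineage whose amino-acid identity to the exogenous viral
reference is drawn from the empirically observed 29-56% band.  All copies
of a category are deletion derivatives of the family element, which mirrors
replication by retrotransposition followed by decay and is what makes
homolog expansion from a single complete copy recover the whole set.

Glycoprotein copy lengths follow a log-normal with median 880 nt clipped to
117-1977 nt; copies planted as "clean" (intended to pass the assembly
filters) are conditioned on the pass-capable part of that band (>= 330 nt,
so the encoded ORF clears the 100-aa cutoff); the filter-stress options
plant the failing cases deliberately (short contigs, N runs, sub-100-aa
ORFs).

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .architecture import Category
from .screen import (HomologyHit, ProductClass, Strategy, SubjectRecord)
from .seqio import Contig, Interval, revcomp, translate

BASES = np.array(list("ACGT"))

DOMAIN_NT_LEN = {"GAG": 900, "PR": 300, "RT": 700, "RH": 450, "INT": 850}

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# sense codons per amino acid (standard table), used for back-translation
_CODONS_BY_AA: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _aa = translate(_codon)
            if _aa != "*":
                _CODONS_BY_AA.setdefault(_aa, []).append(_codon)

VIRAL_REFS = {"chuv_gly_ref": ProductClass.GLY,
              "chuv_rdrp_ref": ProductClass.RDRP,
              "chuv_np_ref": ProductClass.NP}
KNOWN_EVE_REFS = {"known_eve_gly": ProductClass.GLY,
                  "known_eve_rdrp": ProductClass.RDRP,
                  "known_eve_np": ProductClass.NP}


@dataclass
class SimConfig:
    """Study conditions for one synthetic run."""

    seed: int = 0
    counts: dict = field(default_factory=dict)  # Category name -> copies
    n_contigs: int = 4
    contig_length: int = 200_000
    gc: float = 0.45
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    ltr_divergence: float = 0.0
    identity_band: tuple[float, float] = (0.2903, 0.5641)
    gly_len_range: tuple[int, int] = (117, 1977)
    gly_len_median: float = 880.0
    ltr_len_range: tuple[int, int] = (100, 900)
    ltr_len_mean: float = 670.0
    ltr_len_sd: float = 120.0
    min_gap: int = 22_000          # keeps +/-10 kb windows single-element
    margin: int = 11_000           # clearance from contig ends for clean copies
    min_clean_gly_nt: int = 330    # ORF-filter pass-capable glycoprotein length
    decoy_subjects: int = 0        # non-viral references injected per EVE locus
    decoys_outrank_viral: bool = False
    n_fail_flank: int = 0          # stress: EVEs on short contigs
    n_fail_n: int = 0              # stress: EVEs with an N run inside the locus
    n_fail_orf: int = 0            # stress: short-ORF EVEs (rejection-sampled context)

    def __post_init__(self):
        for rate in (self.sub_rate, self.indel_rate, self.ltr_divergence):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        for v in self.counts.values():
            if v < 0:
                raise ValueError("counts must be >= 0")


@dataclass
class PlantedTruth:
    """Ledger entry for one planted element copy."""

    element_id: str
    category: Category
    interval: Interval
    strand: str
    components: dict  # name -> (genomic start, end); names: LTR_L, LTR_R, domains, GLY...
    sub_rate: float = 0.0
    ltr_divergence: float = 0.0
    clean: bool = True


@dataclass
class Family:
    """Shared sequence material for one element lineage."""

    ltr: str
    domains_nt: dict
    domain_peptides: dict
    gly_nt: str
    gly_peptide: str
    gly_identity: float
    rdrp_eve_nt: str
    rdrp_identity: float
    np_eve_nt: str
    np_identity: float
    viral_peptides: dict
    spacer: str
    pad: str


@dataclass
class SimResult:
    contigs: list[Contig]
    truth: list[PlantedTruth]
    family: Family
    config: SimConfig
    hit_tables: dict = field(default_factory=dict)
    taxonomy: dict = field(default_factory=dict)


def sample_background(length: int, gc: float, seed: int) -> str:
    """I.i.d. background DNA at the stated GC fraction; deterministic."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return _random_dna(rng, length, gc)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def _mutate_peptide(rng: np.random.Generator, pep: str, identity: float) -> str:
    n_mut = round((1 - identity) * len(pep))
    pos = rng.choice(len(pep), size=n_mut, replace=False)
    out = list(pep)
    for i in pos:
        choices = [a for a in AA20 if a != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _backtranslate(rng: np.random.Generator, pep: str) -> str:
    return "".join(_CODONS_BY_AA[a][rng.integers(0, len(_CODONS_BY_AA[a]))]
                   for a in pep)


def _substitute(rng: np.random.Generator, seq: str, rate: float,
                lo: int = 0, hi: int | None = None) -> str:
    """Random substitutions at the given per-site rate on seq[lo:hi]."""
    if rate <= 0:
        return seq
    hi = len(seq) if hi is None else hi
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    span = hi - lo
    n = rng.binomial(span, rate)
    if n == 0:
        return seq
    pos = lo + rng.choice(span, size=n, replace=False)
    lut = {ord(b): [ord(c) for c in "ACGT" if c != b] for b in "ACGT"}
    for i in pos:
        alts = lut.get(int(arr[i]))
        if alts:
            arr[i] = alts[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def make_family(rng: np.random.Generator, config: SimConfig) -> Family:
    ltr_len = int(_truncnorm(rng, config.ltr_len_mean, config.ltr_len_sd,
                             *config.ltr_len_range))
    ltr = _random_dna(rng, ltr_len, config.gc)
    domain_peptides = {name: _random_peptide(rng, nt // 3)
                       for name, nt in DOMAIN_NT_LEN.items()}
    domains_nt = {name: _backtranslate(rng, pep)
                  for name, pep in domain_peptides.items()}
    gly_viral = _random_peptide(rng, config.gly_len_range[1] // 3)
    rdrp_viral = _random_peptide(rng, 700)
    np_viral = _random_peptide(rng, 450)
    lo, hi = config.identity_band
    gly_id = rng.uniform(lo, hi)
    rdrp_id = rng.uniform(lo, hi)
    np_id = rng.uniform(lo, hi)
    gly_pep = _mutate_peptide(rng, gly_viral, gly_id)
    rdrp_pep = _mutate_peptide(rng, rdrp_viral, rdrp_id)[:500]
    np_pep = _mutate_peptide(rng, np_viral, np_id)[:170]
    return Family(
        ltr=ltr, domains_nt=domains_nt, domain_peptides=domain_peptides,
        gly_nt=_backtranslate(rng, gly_pep), gly_peptide=gly_pep,
        gly_identity=gly_id,
        rdrp_eve_nt=_backtranslate(rng, rdrp_pep), rdrp_identity=rdrp_id,
        np_eve_nt=_backtranslate(rng, np_pep), np_identity=np_id,
        viral_peptides={"chuv_gly_ref": gly_viral, "chuv_rdrp_ref": rdrp_viral,
                        "chuv_np_ref": np_viral},
        spacer=_random_dna(rng, 30, config.gc),
        pad=_random_dna(rng, 1_300, config.gc),
    )


def _sample_gly_len(rng: np.random.Generator, config: SimConfig,
                    min_nt: int | None = None) -> int:
    lo, hi = config.gly_len_range
    lo = max(lo, min_nt or lo)
    mu = math.log(config.gly_len_median)
    for _ in range(1000):
        x = rng.lognormal(mu, 0.55)
        if lo <= x <= hi:
            return int(x) // 3 * 3
    return int(config.gly_len_median) // 3 * 3


_DEFECTIVE_DOMAIN_CHOICES = [
    ("RT", "RH"), ("GAG",), ("PR", "RT", "RH"), ("INT",), ("RT", "RH", "INT"),
    ("GAG", "PR"), ("RH",), ("GAG", "PR", "RT", "RH"),
]


def build_element(category: Category, family: Family, config: SimConfig,
                  rng: np.random.Generator,
                  gly_nt_len: int | None = None) -> tuple[str, dict]:
    """Assemble one element copy; returns (sequence, component coordinates).

    Component coordinates are relative to element start, pre-mutation
    (substitutions do not shift coordinates; indels are applied by the
    planter, which remaps them).
    """
    spacer = family.spacer
    parts: list[tuple[str, str]] = []  # (component name, seq)

    def pao_body(domains):
        body = []
        for name in ("GAG", "PR", "RT", "RH", "INT"):
            if name in domains:
                body.append((name, family.domains_nt[name]))
                body.append(("", spacer))
        return body

    def gly_part():
        n = gly_nt_len if gly_nt_len is not None else _sample_gly_len(
            rng, config, config.min_clean_gly_nt)
        n = min(n, len(family.gly_nt))
        start = int(rng.integers(0, (len(family.gly_nt) - n) // 3 + 1)) * 3
        return ("GLY", family.gly_nt[start:start + n])

    all_domains = ("GAG", "PR", "RT", "RH", "INT")
    if category is Category.ANAKIN_COMPLETE:
        parts = [("LTR_L", family.ltr), ("", spacer), *pao_body(all_domains),
                 gly_part(), ("", spacer), ("LTR_R", family.ltr)]
    elif category is Category.ANAKIN_DEFECTIVE_2LTR:
        doms = _DEFECTIVE_DOMAIN_CHOICES[rng.integers(0, len(_DEFECTIVE_DOMAIN_CHOICES))]
        doms = doms[:4] or ("RT",)
        parts = [("LTR_L", family.ltr), ("", spacer), *pao_body(doms),
                 gly_part(), ("", family.pad), ("LTR_R", family.ltr)]
    elif category is Category.ANAKIN_DEFECTIVE:
        doms = _DEFECTIVE_DOMAIN_CHOICES[rng.integers(0, len(_DEFECTIVE_DOMAIN_CHOICES))]
        parts = [*pao_body(doms), gly_part()]
        if rng.random() < 0.5:
            parts = [("LTR_L", family.ltr), ("", spacer)] + parts
    elif category is Category.PAO_COMPLETE:
        parts = [("LTR_L", family.ltr), ("", spacer), *pao_body(all_domains),
                 ("", spacer), ("LTR_R", family.ltr)]
    elif category is Category.PAO_DEFECTIVE_2LTR:
        doms = _DEFECTIVE_DOMAIN_CHOICES[rng.integers(0, len(_DEFECTIVE_DOMAIN_CHOICES))]
        doms = doms[:4] or ("RT",)
        parts = [("LTR_L", family.ltr), ("", spacer), *pao_body(doms),
                 ("", family.pad), ("LTR_R", family.ltr)]
    elif category is Category.PAO_DEFECTIVE:
        doms = _DEFECTIVE_DOMAIN_CHOICES[rng.integers(0, len(_DEFECTIVE_DOMAIN_CHOICES))]
        parts = [*pao_body(doms)]
        if rng.random() < 0.5:
            parts = [("LTR_L", family.ltr), ("", spacer)] + parts
    elif category is Category.SOLO_LTR:
        parts = [("LTR_L", family.ltr)]
    elif category is Category.SOLO_GLY:
        parts = [gly_part()]
    elif category is Category.RDRP_EVE:
        parts = [("RDRP_EVE", family.rdrp_eve_nt)]
    elif category is Category.NP_EVE:
        parts = [("NP_EVE", family.np_eve_nt)]
    else:
        raise ValueError(f"no template for category {category}")

    seq_parts = []
    components: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, s in parts:
        if name:
            components[name] = (pos, pos + len(s))
        seq_parts.append(s)
        pos += len(s)
    seq = "".join(seq_parts)

    # per-copy mutations: substitutions on the element body; the LTRs (kept
    # identical by concerted evolution until excision) instead diverge from
    # each other at the configured per-LTR rate
    ltr_spans = [components[n] for n in ("LTR_L", "LTR_R") if n in components]
    original_ltrs = [seq[a:b] for a, b in ltr_spans]
    seq = _substitute(rng, seq, config.sub_rate)
    if ltr_spans:
        chars = list(seq)
        for (a, b), orig in zip(ltr_spans, original_ltrs):
            chars[a:b] = _substitute(rng, orig, config.ltr_divergence)
        seq = "".join(chars)
    if config.indel_rate > 0:
        seq, components = _apply_indels(rng, seq, components, config.indel_rate)
    return seq, components


def _apply_indels(rng, seq, components, rate):
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq, components
    positions = np.sort(rng.choice(len(seq), size=n, replace=False))[::-1]
    seq_list = list(seq)
    events = []  # (pos, shift)
    for p in positions:
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5:  # deletion
            del seq_list[p:p + length]
            events.append((int(p), -min(length, len(seq) - p)))
        else:
            ins = _random_dna(rng, length, 0.5)
            seq_list[p:p] = list(ins)
            events.append((int(p), length))
    new_components = {}
    for name, (a, b) in components.items():
        na, nb = a, b
        for p, shift in events:
            if p < a:
                na += shift
                nb += shift
            elif p < b:
                nb = max(na + 1, nb + shift)
        new_components[name] = (max(0, na), nb)
    return "".join(seq_list), new_components


def plant_elements(config: SimConfig) -> SimResult:
    """Build contigs, plant every configured element copy, return the ledger.

    Clean copies are placed with >= ``margin`` clearance from contig ends and
    >= ``min_gap`` between copies so classification windows never mix two
    elements.  Stress copies (short flanks, N runs, short ORFs) are planted
    on dedicated extra contigs.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    family = make_family(rng, config)

    copies: list[tuple[Category, str, dict, bool]] = []
    for cat_name, count in sorted(config.counts.items()):
        category = Category(cat_name)
        for i in range(count):
            seq, comps = build_element(category, family, config, rng)
            copies.append((category, seq, comps, True))
    order = rng.permutation(len(copies))
    copies = [copies[i] for i in order]

    backgrounds = [_random_dna(rng, config.contig_length, config.gc)
                   for _ in range(config.n_contigs)]
    contig_ids = [f"contig_{i+1}" for i in range(config.n_contigs)]

    truth: list[PlantedTruth] = []
    pieces: dict[str, list[str]] = {cid: [] for cid in contig_ids}
    cursors = {cid: 0 for cid in contig_ids}
    consumed = {cid: 0 for cid in contig_ids}

    def place(cid, seq_bg, element_seq, comps, category, clean, eid, strand):
        """Append background up to a start position, then the element."""
        start = cursors[cid]
        pieces[cid].append(element_seq)
        if strand == "-":
            element_final = revcomp(element_seq)
            pieces[cid][-1] = element_final
            L = len(element_seq)
            comps = {name: (L - b, L - a) for name, (a, b) in comps.items()}
        iv = Interval(cid, start, start + len(element_seq))
        truth.append(PlantedTruth(
            element_id=eid, category=category, interval=iv, strand=strand,
            components={n: (start + a, start + b) for n, (a, b) in comps.items()},
            sub_rate=config.sub_rate, ltr_divergence=config.ltr_divergence,
            clean=clean))
        cursors[cid] += len(element_seq)

    ci = 0
    for idx, (category, seq, comps, clean) in enumerate(copies):
        placed = False
        for attempt in range(config.n_contigs):
            cid = contig_ids[ci % config.n_contigs]
            ci += 1
            bg = backgrounds[contig_ids.index(cid)]
            gap = config.margin if cursors[cid] == 0 else \
                config.min_gap + int(rng.integers(0, 3_000))
            needed = gap + len(seq) + config.margin
            if consumed[cid] + needed > len(bg):
                continue
            pieces[cid].append(bg[consumed[cid]:consumed[cid] + gap])
            consumed[cid] += gap
            cursors[cid] += gap
            strand = "+" if rng.random() < 0.5 else "-"
            place(cid, bg, seq, comps, category,
                  clean, f"elem_{idx+1:03d}_{category.value}", strand)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "infeasible packing: increase contig_length or n_contigs")

    contigs: list[Contig] = []
    for cid, bg in zip(contig_ids, backgrounds):
        tail = bg[consumed[cid]:]
        seq = "".join(pieces[cid]) + tail
        contigs.append(Contig(cid, seq, assembly_id=f"sim_seed{config.seed}"))

    _plant_stress(rng, config, family, contigs, truth)
    return SimResult(contigs=contigs, truth=truth, family=family, config=config)


def _plant_stress(rng, config, family, contigs, truth):
    """Dedicated small contigs / N runs / short-ORF cases to exercise filters."""
    stress_idx = 0

    def gly_copy(min_nt, max_nt):
        n = int(rng.integers(min_nt // 3, max_nt // 3 + 1)) * 3
        start = int(rng.integers(0, (len(family.gly_nt) - n) // 3 + 1)) * 3
        return family.gly_nt[start:start + n]

    for _ in range(config.n_fail_flank):
        stress_idx += 1
        gly = gly_copy(config.min_clean_gly_nt, 900)
        left = int(rng.integers(500, 3_000))  # < 4 kb flank by construction
        right = int(rng.integers(4_500, 6_000))
        seq = _random_dna(rng, left, config.gc) + gly + _random_dna(rng, right, config.gc)
        cid = f"small_contig_{stress_idx}"
        contigs.append(Contig(cid, seq, contigs[0].assembly_id))
        truth.append(PlantedTruth(
            f"stress_flank_{stress_idx}", Category.SOLO_GLY,
            Interval(cid, left, left + len(gly)), "+",
            {"GLY": (left, left + len(gly))}, clean=False))

    for _ in range(config.n_fail_n):
        stress_idx += 1
        gly = gly_copy(config.min_clean_gly_nt, 900)
        mid = len(gly) // 2
        gly_n = gly[:mid] + "N" * 30 + gly[mid:]
        left = right = 6_000
        seq = _random_dna(rng, left, config.gc) + gly_n + _random_dna(rng, right, config.gc)
        cid = f"nrun_contig_{stress_idx}"
        contigs.append(Contig(cid, seq, contigs[0].assembly_id))
        truth.append(PlantedTruth(
            f"stress_n_{stress_idx}", Category.SOLO_GLY,
            Interval(cid, left, left + len(gly_n)), "+",
            {"GLY": (left, left + len(gly_n))}, clean=False))

    from .seqio import find_orfs  # local import avoids cycle at module load

    for _ in range(config.n_fail_orf):
        stress_idx += 1
        gly = gly_copy(120, 240)  # < 100 aa even with run-on margins
        left = right = 6_000
        cid = f"shortorf_contig_{stress_idx}"
        for _try in range(200):
            seq = _random_dna(rng, left, config.gc) + gly + \
                _random_dna(rng, right, config.gc)
            region = Contig("_r", seq)
            locus = (left, left + len(gly))
            bad = any(o.interval.start < locus[1] and o.interval.end > locus[0]
                      for o in find_orfs(region, 100))
            if not bad:
                break
        else:
            raise RuntimeError("could not build a short-ORF stress case")
        contigs.append(Contig(cid, seq, contigs[0].assembly_id))
        truth.append(PlantedTruth(
            f"stress_orf_{stress_idx}", Category.SOLO_GLY,
            Interval(cid, *locus), "+", {"GLY": locus}, clean=False))


# ---------------------------------------------------------------------------
# Mock hit / taxonomy / domain tables
# ---------------------------------------------------------------------------

_EVE_COMPONENTS = {
    "GLY": (ProductClass.GLY, "chuv_gly_ref", "known_eve_gly"),
    "RDRP_EVE": (ProductClass.RDRP, "chuv_rdrp_ref", "known_eve_rdrp"),
    "NP_EVE": (ProductClass.NP, "chuv_np_ref", "known_eve_np"),
}


def emit_mock_tables(result: SimResult) -> SimResult:
    """Produce the two-strategy hit tables and taxonomy for a planted run.

    One translated-strategy row (viral reference as query) and one
    nucleotide-strategy row (known EVE as query) per planted EVE component;
    identities of viral rows sit in the configured band.  Decoy non-viral
    rows can be injected to exercise the voting rule; with
    ``decoys_outrank_viral`` they take better e-values so the top-5 window
    holds exactly two viral references.
    """
    config = result.config
    rng = np.random.default_rng(config.seed + 1)
    fam = result.family
    identity_by_product = {
        ProductClass.GLY: fam.gly_identity,
        ProductClass.RDRP: fam.rdrp_identity,
        ProductClass.NP: fam.np_identity,
    }
    taxonomy: dict[str, SubjectRecord] = {}
    for ref, product in VIRAL_REFS.items():
        taxonomy[ref] = SubjectRecord(ref, True, product, "Chuviridae")
    for ref, product in KNOWN_EVE_REFS.items():
        taxonomy[ref] = SubjectRecord(ref, True, product, "Culicidae EVE")

    virus_rows: list[HomologyHit] = []
    eve_rows: list[HomologyHit] = []
    decoy_counter = 0
    for entry in result.truth:
        for comp_name, (product, viral_ref, known_ref) in _EVE_COMPONENTS.items():
            if comp_name not in entry.components:
                continue
            a, b = entry.components[comp_name]
            if entry.strand == "+":
                s_start, s_end = a + 1, b
            else:
                s_start, s_end = b, a + 1
            aa_len = (b - a) // 3
            identity = identity_by_product[product] * 100
            viral_evalue = 10.0 ** rng.uniform(-40, -10)
            virus_rows.append(HomologyHit(
                viral_ref, entry.interval.contig_id, round(identity, 2),
                aa_len, int(aa_len * (1 - identity / 100)), 0,
                1, aa_len, s_start, s_end, viral_evalue,
                round(aa_len * 1.9, 1), Strategy.VIRUS_GENOME_TBLASTX))
            eve_rows.append(HomologyHit(
                known_ref, entry.interval.contig_id, round(95 - 10 * rng.random(), 2),
                b - a, 0, 0, 1, b - a, s_start, s_end,
                10.0 ** rng.uniform(-60, -20), round((b - a) * 1.8, 1),
                Strategy.KNOWN_EVE_BLASTN))
            for d in range(config.decoy_subjects):
                decoy_counter += 1
                decoy_id = f"host_protein_{decoy_counter:04d}"
                taxonomy[decoy_id] = SubjectRecord(decoy_id, False,
                                                   ProductClass.OTHER, "Culicidae")
                if config.decoys_outrank_viral:
                    evalue = viral_evalue * 10.0 ** rng.uniform(-8, -2)
                else:
                    evalue = viral_evalue * 10.0 ** rng.uniform(2, 8)
                virus_rows.append(HomologyHit(
                    decoy_id, entry.interval.contig_id,
                    round(30 + 20 * rng.random(), 2),
                    aa_len, aa_len // 2, 0, 1, aa_len, s_start, s_end,
                    min(evalue, 9e-5), round(aa_len * 1.1, 1),
                    Strategy.VIRUS_GENOME_TBLASTX))
    result.hit_tables = {Strategy.VIRUS_GENOME_TBLASTX: virus_rows,
                         Strategy.KNOWN_EVE_BLASTN: eve_rows}
    result.taxonomy = taxonomy
    return result


def simulate(config: SimConfig) -> SimResult:
    """Plant elements and emit the matching mock tables in one call."""
    return emit_mock_tables(plant_elements(config))


# ---------------------------------------------------------------------------
# Ledger I/O
# ---------------------------------------------------------------------------

def write_truth_ledger(truth: list[PlantedTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tcategory\tcontig\tstart\tend\tstrand\tclean\tcomponents\n")
        for t in truth:
            fh.write("\t".join((
                t.element_id, t.category.value, t.interval.contig_id,
                str(t.interval.start), str(t.interval.end), t.strand,
                "1" if t.clean else "0",
                json.dumps(t.components, sort_keys=True))) + "\n")


def read_truth_ledger(path) -> list[PlantedTruth]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            eid, cat, contig, start, end, strand, clean, comps = \
                line.rstrip("\n").split("\t")
            out.append(PlantedTruth(
                eid, Category(cat), Interval(contig, int(start), int(end)),
                strand, {k: tuple(v) for k, v in json.loads(comps).items()},
                clean=clean == "1"))
    return out
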