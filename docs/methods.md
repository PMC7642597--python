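# Methods

This note records the models, rules and numerical choices behind the
package, what the synthetic generator does and does not emulate, and the
known limitations.

## Coordinate and sequence conventions

All coordinates are 0-based, half-open, on the forward strand of a contig;
GFF3 output converts to 1-based inclusive at the boundary. DNA is stored
upper-case over {A,C,G,T,N}; lower-case and U are normalised on input and
any other character is rejected. Hit tables use the 12-column tabular
dialect with 1-based inclusive coordinates and minus strand encoded by
descending subject coordinates.

## ORF model

ORFs are maximal stop-to-stop codon stretches in all six frames, with no
start-codon requirement (the behaviour of EMBOSS getorf's default find
mode, which the screening protocol this follows used without options).
Codons containing N translate as X and do not terminate an ORF — an EVE
locus containing N fails the assembly filter anyway, so the permissive
translation cannot rescue a bad region. Open contig ends count as ORF
boundaries, so partial ORFs at assembly edges are reported; this matters
because real EVEs sit near contig ends. Translation is Biopython's
standard table 1; the test suite checks it codon-by-codon against an
independently hand-written table and checks the six-frame scan against an
exhaustive stop-partition oracle.

## The voting rule

Candidate loci are formed by merging overlapping same-strand genomic hits,
pooled over both search strategies; opposite-strand overlaps are kept
separate (antisense integration is a distinct locus event). Hits at a
locus are ranked by ascending e-value, then descending bit score, then
lexicographic subject id — a deterministic total order, since the protocol
itself does not define tie-breaking. The window counts *distinct*
references (multiple HSPs to one subject count once):

* ≤ 4 distinct matches → EVE iff the best match is viral;
* ≥ 5 distinct matches → EVE iff ≥ 3 of the 5 best are viral.

Counting per merged locus rather than per raw query means a locus found by
both strategies is voted once, which serves the same purpose as the
post-hoc redundancy clustering of the original protocol. The default
e-value ceiling for accepting hits into the vote is 1e-4 (the observed
screen e-values run from ~9e-5 down to 0), exposed in `PipelineConfig`.

## Assembly-quality filters

Checks run in a fixed order and the first failure is terminal, so every
EVE call gets exactly one flag: flank (≥ 4 kb of contig on both sides of
the locus), undetermined bases (no N anywhere in locus ± 4 kb — the region
actually analysed downstream; whether the original protocol meant the
whole contig or the local region is ambiguous, and the local reading is
used), then ORF (some ≥ 100-aa ORF must overlap the locus; ORFs are
computed on the locus ± 4 kb slice, which bounds detectable ORFs at
~1 300 aa). Survivors are clustered CD-HIT-style on their ± 10 kb
flank-extended sequences: sort by length descending, join the first
representative at ≥ 90 % identity (identity = alignment matches / shorter
length, the CD-HIT convention), else found a cluster. Non-representative
members are flagged REDUNDANT. Retaining the flanks is what keeps
near-identical copies at *different* loci apart while collapsing the same
insertion recovered twice. Identity is computed from an edlib global
alignment restricted to the band that could still reach the threshold
(distance ≤ 2·(1−t)·shorter + length difference; beyond it the threshold
is unreachable), with a shared-16-mer prefilter in the CD-HIT style to
skip hopeless pairs without aligning.

## Direct-repeat (LTR) rule

LTR pairs are found as ungapped direct repeats. For every self-comparison
offset d in [min_len+min_sep, max_len+max_sep], the per-position match
mask (N never matches) is split into blocks at runs of more than 5
consecutive mismatches; within each block the candidate is the
maximum-scoring subsegment under match +1 / mismatch −2 (ties: smallest
end, then largest start — the streaming Kadane convention), which trims
the random overshoot that accumulates past true repeat edges. A candidate
must contain at least one run of 20 consecutive matches (the exact-k-mer
seed that also drives discovery), fall within the length band
[100, 900] bp, reach the pair-identity floor (default 80 %), and leave an
inner span (separation) of 1–15 kb. Candidates longer than the allowed
maximum are reduced to their best window of that length. Overlapping
candidates are resolved by highest identity × length, with a deterministic
leftmost tie-break. The acceptance suite checks the implementation against
an independent per-diagonal O(n²) transcription of this rule on windows
with planted repeats at 0–10 % divergence.

Defaults: seed 20 nt; mismatch-run cap 5 (a run of six mismatches is
vanishingly rare between LTRs ≤ 10 % diverged, but frequent in random
sequence, so it separates repeat from background); pair identity 80 %,
bracketing Pao biology below the ~94 % expected from two LTRs at 3 %
per-LTR divergence; separation 1–15 kb, bracketing Pao internal-region
sizes. All are config-exposed.

The same segment rule, generalised to query-vs-target offsets with a
20-mer sorted index, powers the nucleotide homolog search used by solo-LTR
detection and homolog expansion.

## Domain annotation and the translated search

Domain evidence comes from translated comparison: ORFs of the ± 10 kb
window (minimum 30 aa, so that a point-mutation stop codon fragments
rather than erases a domain) are scanned against reference peptides for
GAG, PR, RT, RH and INT with exact 4-mer seeds and ungapped BLOSUM62
X-drop extension (X = 20, ungapped Karlin–Altschul bit scores). Hits below
a raw score of 60 are dropped — random windows produce none at that floor
(checked empirically at fixed seeds), while a 30-aa fragment at ~85 %
identity scores well above it. Best non-overlapping labels are reported in
genomic coordinates. External CDD-style domain tables can be ingested
instead and feed the identical downstream decision. The same scorer
behind a desk-scale six-frame translated search (`naive_translated_search`)
emits the tabular dialect, so small screens and tests need no external
alignment binary; on exact planted peptides it attains the gap-free
Smith–Waterman optimum (checked against Biopython's aligner).

## Classification decision tree

Evidence per locus: the Pao domain subset in the window, LTR pairs,
single-LTR hits, and the EVE call (product class GLY/RDRP/NP) if any.
RdRp and NP EVEs are reported as their own categories regardless of
context, as in the summary scheme. For the rest:

| evidence | category |
|---|---|
| GLY inside a pair, all 5 domains | ANAKIN_COMPLETE |
| GLY inside a pair, 0–4 domains | ANAKIN_DEFECTIVE_2LTR |
| GLY, ≥ 1 domain, no containing pair | ANAKIN_DEFECTIVE |
| GLY, 0 domains, no containing pair | SOLO_GLY |
| no GLY, all 5 domains + pair | PAO_COMPLETE |
| no GLY, 1–4 domains + pair | PAO_DEFECTIVE_2LTR |
| no GLY, ≥ 1 domain, no pair | PAO_DEFECTIVE |
| no GLY, no domain, ≥ 1 LTR | SOLO_LTR |
| nothing | NONE (sentinel, excluded from summaries) |

Two design points where the category definitions were genuinely open:
a glycoprotein between two LTRs with *zero* detected domains is placed in
ANAKIN_DEFECTIVE_2LTR (the containment is the decisive evidence, and
totality over the evidence space requires an answer); a glycoprotein with
a nearby LTR that does not contain it and no domains is SOLO_GLY — the
stray LTR is handled separately as a solo-LTR candidate. Strict
containment inside the pair's inner span is required only for the
two-LTR ("+ LTR") categories. Domain *order* (GAG<PR<RT<RH<INT) is
recorded as evidence but not required: the categories are presence/count
based. The tree is total — exhaustive enumeration of LTR count × all 32
domain subsets × glycoprotein state yields exactly one category each.

## Solo LTRs and homolog expansion

Solo LTRs are searched with the LTRs of classified complete elements as
the library: merged nucleotide hits whose length falls within the library
mean ± 200 bp (inside [100, 900]; "around 670 bp" is not quantified
further, so the tolerance is a config knob) and whose ± 10 kb window
contains neither a Pao domain nor a second LTR hit. Homolog expansion
first collapses near-identical complete queries (greedy clustering at
0.9), searches each representative against the assembly on both strands,
merges hits within 1 kb, and re-runs the full window annotation on each
merged locus ≥ 150 bp; loci already classified are deduplicated at ≥ 50 %
overlap of the shorter interval, and loci with neither domains nor a pair
are left to the solo-LTR detector. Expansion is a fixed point: re-running
it over its own output adds nothing.

## Synthetic genomes: what they emulate

One element *family* per assembly by default: one LTR sequence (truncated
normal, mean 670 sd 120, clipped to [100, 900] bp), five domain coding
blocks (GAG 900, PR 300, RT 700, RH 450, INT 850 nt — typical Pao
proportions; only presence and order matter to the classifier, so the
exact lengths are free parameters), family spacers, and one glycoprotein
lineage derived from a synthetic viral reference at an amino-acid identity
drawn uniformly from [29.03, 56.41] % (the observed band). Planted copies
are deletion derivatives of the family element, which mirrors replication
by retrotransposition followed by decay, and is what makes expansion from
one complete copy recover the whole set — including the
Pao-without-glycoprotein copies that no EVE hit can reach. Copy
glycoprotein lengths follow a log-normal with median 880 nt clipped to
[117, 1977]; copies planted as clean are conditioned on ≥ 330 nt so their
encoded ORF clears the 100-aa filter by construction (the stress options
plant the failing cases deliberately: short contigs for the flank filter,
injected N runs, and short-ORF cases whose local background is
rejection-sampled to contain no chance ≥ 100-aa ORF — random DNA of a few
kb contains one with high probability, so rejection is required to make
the case deterministic).

Mutation model: substitutions (uniform over alternative bases) age the
element body; the two LTRs are kept identical — concerted until excision —
and instead each receives independent substitutions at the LTR-divergence
rate, so divergence 0 implies detected pair identity 100 even on aged
copies. Optional indels (geometric, mean 2) shift the ledger coordinates
accordingly. Elements are placed on random strands with ≥ 22 kb gaps and
≥ 11 kb end margins so that ± 10 kb windows never mix two elements;
background is i.i.d. at a configurable GC (default 0.45 — base composition
is a free knob, as no value is prescribed). Everything is deterministic
given the seed.

Mock hit tables emit one translated-strategy row (viral reference query)
and one nucleotide-strategy row (known-EVE query) per planted EVE
component, with identities in the configured band, plus optional non-viral
decoy rows to exercise the voting rule (with `decoys_outrank_viral`, the
top-5 window holds exactly two viral references and every locus must be
rejected).

What the generator does **not** emulate: genuine mosquito base
composition and repeat landscape (no other transposon families, no
tandem repeats, no piRNA cluster structure), nested or fragmented
insertions, target-site duplications, insertion-age structure, and
sequencing/assembly artefacts beyond N runs and short contigs. Passing
the synthetic recovery tests therefore demonstrates the correctness of
the rules and their robustness to point divergence, not performance on
real assemblies, where repeat-rich backgrounds will add ambiguity the
simulator does not create.

## Problem sizes and determinism

The shipped study design uses a six-contig, ~1.4 Mb assembly with 42
planted copies (3/5/10 Anakin complete/defective+LTR/defective, 2/6 Pao,
8 solo LTRs, 5 solo glycoproteins, 2 RdRp, 1 NP) for exact-recovery runs,
and 20 copies per category (~6 Mb) at 5 % substitutions with 3 % per-LTR
divergence for robustness runs; both finish in well under five minutes on
one CPU. Oracle-equivalence checks run at 200 random sequences (ORFs),
50 windows (LTR rule) and exhaustive enumeration (voting, classification).
All randomness flows from explicit integer seeds; pipelines contain no
randomness at all, so identical inputs give identical outputs.

## Known limitations

* The LTR finder is ungapped: an indel inside an LTR splits the repeat
  into shorter candidates, and heavily indel-mutated pairs may be missed.
* Identity for clustering derives from edit-distance alignments (unit
  costs), not affine-gap alignments; for the high thresholds used the
  difference is negligible, but reported identities are not comparable to
  affine-gap tools at low similarity.
* The translated search is ungapped and seed-limited (exact 4-mers): it is
  a screening tool calibrated for ≤ ~15 % nucleotide divergence, not a
  sensitive remote-homology method.
* Locus intervals for classified elements are evidence spans (LTR pair ∪
  domains ∪ EVE), not annotated element boundaries with target-site
  duplications; TSD/PBS/PPT detection and insertion-time dating are out of
  scope.
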