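"""The EVE annotation voting rule on ranked homology hits.

A candidate locus with four or fewer distinct database matches is annotated
as an EVE only if the best match is viral; with five or more, at least
three of the five best distinct subjects must be viral.  This guards both
against unannotated viral proteins (false negatives from trusting a single
best hit) and against misannotated database entries (false positives).
"""

from chuvee import HomologyHit, ProductClass, SubjectRecord, vote_eve


def subjects(flags):
    return {f"s{i}": SubjectRecord(
        f"s{i}", viral, ProductClass.GLY if viral else ProductClass.OTHER,
        "Chuviridae" if viral else "Culicidae")
        for i, viral in enumerate(flags)}


def hits(n):
    return [HomologyHit("locus", f"s{i}", 35.0, 100, 60, 0, 1, 100, 1, 300,
                        10.0 ** -(40 - i), 200.0 - i) for i in range(n)]


cases = [
    ("viral, viral, viral, host, host ", [True, True, True, False, False]),
    ("viral, viral, host, host, host  ", [True, True, False, False, False]),
    ("host best of three              ", [False, True, True]),
    ("single viral hit                ", [True]),
]
for label, flags in cases:
    is_eve, evidence = vote_eve(hits(len(flags)), subjects(flags))
    print(f"top hits: {label} -> {'EVE' if is_eve else 'rejected':8s} "
          f"({evidence['reason']})")
# The first case passes the 3-of-5 majority; the second fails it; the third
# fails the best-hit rule for short hit lists; the fourth passes it.
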