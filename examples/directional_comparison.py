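"""Directional matching detects failures to separate co-eluting signals.

Matching is asymmetric on purpose: one XIC in the candidate set may match
several reference XICs.  If tool A reports a concatenated bimodal signal
that tool B splits in two, then A-vs-B matches both of B's halves while
B-vs-A matches nothing over 50%, and the directional table exposes it.
"""

from xiclink.evaluate import directional_table
from xiclink.model import AnnotatedXicSet, AnnotationPoint


def xic(ids, each=10.0):
    return tuple(
        AnnotationPoint(point_id=i, mz=100.0 + i, rt=float(i), intensity=each)
        for i in ids
    )


# "merged" reports the bimodal signal as one XIC; "split" separates it
merged = AnnotatedXicSet(xics={"big": xic(range(10))}, label="merged")
split = AnnotatedXicSet(
    xics={"h1": xic(range(5)), "h2": xic(range(5, 10))}, label="split"
)

table = directional_table([merged, split])
print(table.to_string())
# Row = candidate set, column = reference set, entry = reference XICs
# matched (diagonal: set size).  merged->split is 2 (the one concatenated
# XIC covers both halves entirely); split->merged is 0 (each half covers
# exactly 50% of the merged XIC, and a match requires strictly more).
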