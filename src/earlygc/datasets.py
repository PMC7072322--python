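"""Published summary counts used as worked-example inputs.

These are cohort-level counts reported for a 49-case non-invasive
gastric-cancer study (whole-exome screening plus targeted replication) in
which LRP1 and TP53 emerged as recurrently mutated genes, and CagA (an
H. pylori effector toxin) accumulation was scored by immunofluorescence.
They are *inputs* for the contingency and frequency routines — tiny printed
tables, not sequencing data.
"""

from __future__ import annotations

from .cohort import TwoByTwo

#: CagA accumulation vs LRP1 mutation, all 49 evaluated cases:
#: 10/14 LRP1-mutant vs 8/35 LRP1-wild-type cases show CagA accumulation.
CAGA_LRP1_ALL = TwoByTwo(
    10, 4, 8, 27,
    row_labels=("LRP1 mutant", "LRP1 wild-type"),
    col_labels=("CagA accumulation", "no accumulation"),
)

#: The same contrast restricted to the 33 H. pylori-infected cases:
#: 9/9 LRP1-mutant vs 6/24 wild-type.
CAGA_LRP1_HP_INFECTED = TwoByTwo(
    9, 0, 6, 18,
    row_labels=("LRP1 mutant", "LRP1 wild-type"),
    col_labels=("CagA accumulation", "no accumulation"),
)

#: LRP1 mutated-sample counts: (mutated, cohort size) for the 49 non-invasive
#: cases and for the 58 non-invasive + advanced cases combined.
LRP1_FREQ_NONINVASIVE = (14, 49)
LRP1_FREQ_COMBINED = (18, 58)

#: TP53 vs Wnt-pathway (APC/CTNNB1) exclusivity: of 12 TP53-mutant cases,
#: 10 carried no APC/CTNNB1 mutation.
TP53_WNT_OVERLAP = (2, 12)
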