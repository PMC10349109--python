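"""In-silico consensus voting and ACMG/AMP classification.

Runs the six-predictor damage vote and the evidence-code combiner on the
worked-example variants (the published rare coding variants of the
discovery gene). Printed: votes per variant and the five-tier
classification each evidence set combines to.
"""

from myxoseek import (
    PredictorScores,
    acmg_classify,
    consensus_damaging,
    damaging_votes,
    generate_worked_example,
)

# a score vector clearing four of the six damaging thresholds
scores = PredictorScores(sift=0.02, polyphen2="D", phylop=1.5, gerp=5.2,
                         mutationtaster="N", lrt="N")
print(f"votes={damaging_votes(scores)} -> consensus damaging: "
      f"{consensus_damaging(scores)} (needs at least 4 of 6)")

print(f"\n{'variant':12s} {'evidence codes':18s} classification")
for row in generate_worked_example():
    codes = ",".join(sorted(row.evidence))
    cls = acmg_classify(row.evidence)
    print(f"{row.annotation.hgvs_c:12s} {codes:18s} {cls.value}")
# PM1+PM2 (rare, in a functional hotspot) is not enough evidence to call
# pathogenic: the combining rules leave such variants at uncertain
# significance, while PM2+BP4+BP7 and BS1+BP4 combine to likely benign.
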