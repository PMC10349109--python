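"""Expression-evidence gating and the companion quantification formulas.

Builds a two-gene expression table reproducing the study's decision
pattern — one candidate moderately expressed and decreased in tumors, one
below the credibility floor — and gates candidates on control-tissue
expression. Also evaluates the 2^-ddCt qPCR fold change and the
xenograft tumor-volume formula. Printed: RPKM, bin, percent change and
keep decision per gene, plus the two formula values.
"""

from myxoseek import (
    ExpressionRecord,
    bin_rpkm,
    ddct_relative_expression,
    expression_gate,
    tumor_volume,
)

DEPTH = 20_000_000  # mapped reads per library


def records(gene, length, control_rpkm, case_rpkm):
    def rec(sample, rpkm):
        return ExpressionRecord(gene, sample, round(rpkm * length * DEPTH / 1e9),
                                length, DEPTH)
    return [rec("N1_A", control_rpkm), rec("D1_T", case_rpkm), rec("D2_T", case_rpkm)]


table = records("KIF1C", 3200, 30.0, 10.2) + records("CYP1A2", 1650, 0.4, 0.4)

print(f"{'gene':8s} {'control':>8s} {'case':>8s} {'bin':>13s} {'change':>8s}  keep")
for res in expression_gate(
    ["KIF1C", "CYP1A2"], table,
    case_samples=["D1_T", "D2_T"], control_samples=["N1_A"],
):
    print(
        f"{res.gene:8s} {res.mean_control_rpkm:8.2f} {res.mean_case_rpkm:8.2f} "
        f"{str(res.control_bin):>13s} {res.percent_change:+7.1f}%  {res.keep}"
    )
# KIF1C: middle expression bin, ~66% decrease in tumors -> kept.
# CYP1A2: RPKM < 1 is below the credibility floor -> rejected.

fold = ddct_relative_expression(ct_target_case=24.0, ct_ref_case=18.0,
                                ct_target_control=22.5, ct_ref_control=18.0)
print(f"\nqPCR 2^-ddCt fold change (ddCt = 1.5): {fold:.3f}")
print(f"xenograft volume for 10 x 5 mm: {tumor_volume(10, 5):.0f} mm^3")
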