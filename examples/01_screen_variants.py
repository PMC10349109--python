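"""Preliminary screening of annotated variants.

Builds a handful of annotated variants spanning the filter conditions
(region, functional class, population rarity) and applies the screen.
Printed: each variant, which conditions it passes, and the surviving set.
"""

from myxoseek import (
    AnnotatedVariant,
    FuncClass,
    Region,
    ScreenConfig,
    VariantKey,
    passes_function,
    passes_maf,
    passes_region,
    preliminary_screen,
)

variants = [
    AnnotatedVariant(
        key=VariantKey.make("17", 772, "T", "G"),
        gene="KIF1C", region=Region.EXONIC, func_class=FuncClass.NONSYNONYMOUS,
        maf={"1000g2015Aug_eas": None, "esp6500siv2_all": None, "exac03": 3.4e-5},
    ),
    AnnotatedVariant(
        key=VariantKey.make("17", 3049, "G", "A"),
        gene="KIF1C", region=Region.EXONIC, func_class=FuncClass.NONSYNONYMOUS,
        maf={"exac03": 1.265e-3},  # too common: fails the < 0.001 rule
    ),
    AnnotatedVariant(
        key=VariantKey.make("17", 2895, "C", "T"),
        gene="KIF1C", region=Region.EXONIC, func_class=FuncClass.SYNONYMOUS,
        maf={},  # synonymous: wrong functional class
    ),
    AnnotatedVariant(
        key=VariantKey.make("2", 500, "A", "C"),
        gene="OTHER", region=Region.INTRONIC, func_class=FuncClass.UNKNOWN,
        maf={},  # intronic: wrong region
    ),
]

cfg = ScreenConfig()  # exon/splicing, protein-affecting, MAF < 0.001 or NA
print(f"{'variant':22s} {'region':8s} {'function':14s} {'maf':6s}")
for v in variants:
    print(
        f"{str(v.key):22s} {str(passes_region(v, cfg)):8s} "
        f"{str(passes_function(v, cfg)):14s} {passes_maf(v, cfg)}"
    )

kept = preliminary_screen(variants, cfg)
print(f"\n{len(kept)} of {len(variants)} variants survive the screen:")
for v in kept:
    print(f"  {v.key}  ({v.gene})")
# Only the rare exonic nonsynonymous variant passes all three conditions;
# a True in every column is required to survive.
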