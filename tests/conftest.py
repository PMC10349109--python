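import numpy as np
import pytest

from myxoseek import (
    AnnotatedVariant,
    Arm,
    CohortManifest,
    FuncClass,
    ManifestEntry,
    PredictorScores,
    Region,
    Tissue,
    VariantCall,
    VariantKey,
    Zygosity,
)


@pytest.fixture
def discovery_manifest() -> CohortManifest:
    """Two discovery tumors (D1, D2), one discovery blood (D2), three
    normal atria, three validation patients."""
    return CohortManifest(
        (
            ManifestEntry("D1_T", "D1", Tissue.TUMOR, Arm.DISCOVERY),
            ManifestEntry("D2_T", "D2", Tissue.TUMOR, Arm.DISCOVERY),
            ManifestEntry("D2_B", "D2", Tissue.PBMC, Arm.DISCOVERY),
            ManifestEntry("N1_A", "N1", Tissue.NORMAL_ATRIUM, Arm.NORMAL_CONTROL),
            ManifestEntry("N2_A", "N2", Tissue.NORMAL_ATRIUM, Arm.NORMAL_CONTROL),
            ManifestEntry("N3_A", "N3", Tissue.NORMAL_ATRIUM, Arm.NORMAL_CONTROL),
            ManifestEntry("V1_T", "V1", Tissue.TUMOR, Arm.VALIDATION),
            ManifestEntry("V2_T", "V2", Tissue.TUMOR, Arm.VALIDATION),
            ManifestEntry("V3_T", "V3", Tissue.TUMOR, Arm.VALIDATION),
        )
    )


def make_key(pos: int, ref: str = "A", alt: str = "G") -> VariantKey:
    return VariantKey.make("chrS", pos, ref, alt)


def make_variant(
    pos: int = 100,
    gene: str = "GENE1",
    region: Region = Region.EXONIC,
    func: FuncClass = FuncClass.NONSYNONYMOUS,
    maf: dict | None = None,
    scores: PredictorScores | None = None,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        key=make_key(pos),
        gene=gene,
        region=region,
        func_class=func,
        maf=maf or {},
        predictors=scores or PredictorScores(),
    )


def calls_for(key: VariantKey, samples, zyg: Zygosity = Zygosity.HET):
    return [VariantCall(key, s, zyg) for s in samples]
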