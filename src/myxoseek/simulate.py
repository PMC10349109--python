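"""Seed-deterministic synthetic cohort generator with planted ground truth.

The generator emulates the post-annotation data of a small tumor exome
study: a discovery arm of two patients (two tumor samples, one blood
sample), three normal-tissue controls, a validation arm of sporadic
patients, and two lab-control exomes from healthy subjects. Into a
background of screen-failing variants it plants, on a synthetic contig:

* **hereditary** candidates — in every discovery tumor and the discovery
  blood, never in normals; rare in every population database; at least
  four damaging predictor votes; their genes credibly expressed in the
  control tissue (middle bin) with a case-side decrease;
* **somatic** candidates — in the discovery tumors only;
* **systematic artifacts** — variants with the hereditary presence pattern
  that additionally recur in two or more validation patients, so the
  artifact rule removes them;
* **common variants** — population frequency at or above the rarity
  threshold in at least one database;
* **background variants** — each violates at least one screening
  condition (region, functional class, or frequency), at configured
  rates, and is scattered over random samples.

Every random draw derives from the master seed through named child
streams (variants, placement, scores, expression), so outputs are
byte-identical for a fixed config and adding a new artifact class does
not perturb the others.

The generator also emits a five-variant worked-example fixture mirroring
the published table of rare coding variants (HGVS labels, zygosity,
printed frequencies, and evidence-code sets) for regression testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .expression import ExpressionRecord, write_expression_table
from .pathogenicity import EvidenceCodeSet
from .variants import (
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
    write_manifest,
    write_variant_table,
    MAF_DATABASES,
)

__all__ = [
    "SimConfig",
    "TruthLabels",
    "SimulatedCohort",
    "generate_cohort",
    "write_cohort",
    "generate_worked_example",
    "WorkedExampleVariant",
]

_BASES = np.array(list("ACGT"))
_CONTIG = "chrS"  # synthetic contig; positions imply no real genome


@dataclass(frozen=True)
class MafSpectrum:
    """Background allele-frequency model: per-database missingness plus a
    heavy-tailed Beta frequency for present entries."""

    p_missing: float = 0.35
    beta_a: float = 0.2
    beta_b: float = 5.0


@dataclass(frozen=True)
class PredictorNoise:
    """Missingness and benign/damaging mixing of background predictor scores."""

    p_missing: float = 0.15
    p_damaging_background: float = 0.25


@dataclass(frozen=True)
class ExpressionParams:
    """Control-tissue RPKM ranges per credibility bin and the planted
    case-side fold change (0.34 = a 66% decrease)."""

    control_rpkm_middle: tuple[float, float] = (15.0, 60.0)
    control_rpkm_not_credible: tuple[float, float] = (0.05, 0.8)
    case_fold_change: float = 0.34
    gene_length_bp: tuple[int, int] = (1_000, 5_000)
    total_mapped_reads: int = 20_000_000
    n_background_genes: int = 20


@dataclass(frozen=True)
class SimConfig:
    """Study design and planting parameters of the synthetic cohort.

    The default sample design mirrors the discovery study: two discovery
    tumors (patients D1, D2), one discovery blood sample (D2), three
    normal atrial tissues, twenty-six sporadic validation patients, and
    two lab-control exomes.
    """

    seed: int = 0
    n_background_variants: int = 1_000
    n_common_variants: int = 50
    n_systematic_artifacts: int = 5
    n_planted_hereditary: int = 2
    n_planted_somatic: int = 0
    n_validation_patients: int = 26
    n_normal_atria: int = 3
    n_lab_controls: int = 2
    maf_spectrum: MafSpectrum = MafSpectrum()
    predictor_noise: PredictorNoise = PredictorNoise()
    expression_params: ExpressionParams = ExpressionParams()
    # probability each screening condition is violated by a background
    # variant (at least one violation is always enforced)
    violation_rates: tuple[float, float, float] = (0.4, 0.4, 0.5)  # region, func, maf

    def __post_init__(self) -> None:
        for name in (
            "n_background_variants",
            "n_common_variants",
            "n_systematic_artifacts",
            "n_planted_hereditary",
            "n_planted_somatic",
            "n_validation_patients",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_normal_atria < 1:
            raise ValueError("at least one normal_atrium sample is required")
        if self.n_validation_patients < 2 and self.n_systematic_artifacts > 0:
            raise ValueError(
                "systematic artifacts need >=2 validation patients to recur in"
            )


@dataclass(frozen=True)
class TruthLabels:
    """Ground-truth variant classes; pairwise disjoint by construction."""

    hereditary: frozenset[VariantKey]
    somatic: frozenset[VariantKey]
    artifacts: frozenset[VariantKey]
    common: frozenset[VariantKey]

    def __post_init__(self) -> None:
        sets = [self.hereditary, self.somatic, self.artifacts, self.common]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("truth classes must be pairwise disjoint")


@dataclass(frozen=True)
class SimulatedCohort:
    manifest: CohortManifest
    records: tuple[tuple[VariantCall, AnnotatedVariant], ...]
    control_db: frozenset[VariantKey]
    expression: tuple[ExpressionRecord, ...]
    truth: TruthLabels
    # genes of the planted hereditary variants, in planting order
    hereditary_genes: tuple[str, ...] = ()
    somatic_genes: tuple[str, ...] = ()


def _build_manifest(cfg: SimConfig) -> CohortManifest:
    entries = [
        ManifestEntry("D1_T", "D1", Tissue.TUMOR, Arm.DISCOVERY),
        ManifestEntry("D2_T", "D2", Tissue.TUMOR, Arm.DISCOVERY),
        ManifestEntry("D2_B", "D2", Tissue.PBMC, Arm.DISCOVERY),
    ]
    for i in range(1, cfg.n_normal_atria + 1):
        entries.append(
            ManifestEntry(f"N{i}_A", f"N{i}", Tissue.NORMAL_ATRIUM, Arm.NORMAL_CONTROL)
        )
    for i in range(1, cfg.n_validation_patients + 1):
        entries.append(ManifestEntry(f"V{i}_T", f"V{i}", Tissue.TUMOR, Arm.VALIDATION))
    for i in range(1, cfg.n_lab_controls + 1):
        entries.append(ManifestEntry(f"L{i}_B", f"L{i}", Tissue.PBMC, Arm.LAB_CONTROL))
    return CohortManifest(tuple(entries))


def _draw_keys(rng: np.random.Generator, n: int) -> list[VariantKey]:
    """Unique loci on the synthetic contig with distinct SNV alleles."""
    gaps = rng.integers(1, 1_000, size=n)
    positions = np.cumsum(gaps) + 1
    refs = rng.integers(0, 4, size=n)
    alt_offsets = rng.integers(1, 4, size=n)
    return [
        VariantKey(_CONTIG, int(pos), _BASES[r], _BASES[(r + off) % 4])
        for pos, r, off in zip(positions, refs, alt_offsets)
    ]


def _rare_maf(rng: np.random.Generator, spectrum: MafSpectrum) -> dict[str, Optional[float]]:
    """Frequencies that pass the rarity screen: missing or < 0.001."""
    maf: dict[str, Optional[float]] = {}
    for db in MAF_DATABASES:
        if rng.random() < 0.5:
            maf[db] = None
        else:
            maf[db] = float(rng.uniform(0.0, 0.0009))
    return maf


def _background_maf(
    rng: np.random.Generator, spectrum: MafSpectrum, force_common: bool
) -> dict[str, Optional[float]]:
    maf: dict[str, Optional[float]] = {}
    for db in MAF_DATABASES:
        if rng.random() < spectrum.p_missing:
            maf[db] = None
        else:
            maf[db] = float(np.clip(rng.beta(spectrum.beta_a, spectrum.beta_b), 0.0, 1.0))
    if force_common and not any(v is not None and v >= 0.001 for v in maf.values()):
        db = MAF_DATABASES[int(rng.integers(0, len(MAF_DATABASES)))]
        maf[db] = float(rng.uniform(0.001, 0.5))
    return maf


_DAMAGING_DRAW = {
    "sift": lambda rng: float(rng.uniform(0.0, 0.0999)),
    "polyphen2": lambda rng: str(rng.choice(["D", "P"])),
    "phylop": lambda rng: float(rng.uniform(1.0, 3.0)),
    "gerp": lambda rng: float(rng.uniform(4.1, 6.5)),
    "mutationtaster": lambda rng: str(rng.choice(["A", "D"])),
    "lrt": lambda rng: "D",
}

_BENIGN_DRAW = {
    "sift": lambda rng: float(rng.uniform(0.2, 1.0)),
    "polyphen2": lambda rng: "B",
    "phylop": lambda rng: float(rng.uniform(-2.0, 0.9)),
    "gerp": lambda rng: float(rng.uniform(-3.0, 3.9)),
    "mutationtaster": lambda rng: str(rng.choice(["N", "P"])),
    "lrt": lambda rng: str(rng.choice(["N", "U"])),
}

_PREDICTORS = list(_DAMAGING_DRAW)


def _planted_scores(rng: np.random.Generator, noise: PredictorNoise) -> PredictorScores:
    """Scores with a guaranteed consensus (>=4 damaging votes)."""
    n_damaging = int(rng.integers(4, 7))
    damaging = set(rng.choice(_PREDICTORS, size=n_damaging, replace=False))
    values = {}
    for name in _PREDICTORS:
        if name in damaging:
            values[name] = _DAMAGING_DRAW[name](rng)
        elif rng.random() < noise.p_missing:
            values[name] = None
        else:
            values[name] = _BENIGN_DRAW[name](rng)
    return PredictorScores(**values)


def _background_scores(rng: np.random.Generator, noise: PredictorNoise) -> PredictorScores:
    values = {}
    for name in _PREDICTORS:
        if rng.random() < noise.p_missing:
            values[name] = None
        elif rng.random() < noise.p_damaging_background:
            values[name] = _DAMAGING_DRAW[name](rng)
        else:
            values[name] = _BENIGN_DRAW[name](rng)
    return PredictorScores(**values)


def _passing_annotation(
    rng: np.random.Generator,
    key: VariantKey,
    gene: str,
    cfg: SimConfig,
) -> AnnotatedVariant:
    """An annotation that satisfies every preliminary screening condition."""
    return AnnotatedVariant(
        key=key,
        gene=gene,
        region=Region.EXONIC if rng.random() < 0.9 else Region.SPLICING,
        func_class=FuncClass(
            str(rng.choice(["nonsynonymous", "stopgain", "frameshift", "splicing"]))
        ),
        maf=_rare_maf(rng, cfg.maf_spectrum),
        predictors=_planted_scores(rng, cfg.predictor_noise),
    )


_FAIL_REGIONS = ["intronic", "UTR3", "UTR5", "intergenic", "other"]
_FAIL_FUNCS = ["synonymous", "other"]


def _background_annotation(
    rng: np.random.Generator, key: VariantKey, gene: str, cfg: SimConfig
) -> AnnotatedVariant:
    """An annotation violating >=1 screening condition at configured rates."""
    p_region, p_func, p_maf = cfg.violation_rates
    violate_region = rng.random() < p_region
    violate_func = rng.random() < p_func
    violate_maf = rng.random() < p_maf
    if not (violate_region or violate_func or violate_maf):
        choice = int(rng.integers(0, 3))
        violate_region, violate_func, violate_maf = (
            choice == 0,
            choice == 1,
            choice == 2,
        )
    region = (
        Region(str(rng.choice(_FAIL_REGIONS)))
        if violate_region
        else (Region.EXONIC if rng.random() < 0.9 else Region.SPLICING)
    )
    func = (
        FuncClass(str(rng.choice(_FAIL_FUNCS)))
        if violate_func
        else FuncClass(str(rng.choice(["nonsynonymous", "stopgain", "unknown"])))
    )
    maf = _background_maf(rng, cfg.maf_spectrum, force_common=violate_maf)
    if not violate_maf:
        maf = _rare_maf(rng, cfg.maf_spectrum)
    return AnnotatedVariant(
        key=key,
        gene=gene,
        region=region,
        func_class=func,
        maf=maf,
        predictors=_background_scores(rng, cfg.predictor_noise),
    )


def _expression_for_gene(
    rng: np.random.Generator,
    gene: str,
    control_rpkm: float,
    case_fold: float,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    params: ExpressionParams,
) -> list[ExpressionRecord]:
    length = int(rng.integers(params.gene_length_bp[0], params.gene_length_bp[1] + 1))
    total = params.total_mapped_reads
    records = []
    for s in control_samples:
        count = max(0, round(control_rpkm * length * total / 1e9))
        records.append(ExpressionRecord(gene, s, int(count), length, total))
    for s in case_samples:
        count = max(0, round(control_rpkm * case_fold * length * total / 1e9))
        records.append(ExpressionRecord(gene, s, int(count), length, total))
    return records


def generate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort with planted ground truth."""
    manifest = _build_manifest(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    rng_variants, rng_place, rng_scores, rng_expr = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    n_total = (
        cfg.n_planted_hereditary
        + cfg.n_planted_somatic
        + cfg.n_systematic_artifacts
        + cfg.n_common_variants
        + cfg.n_background_variants
    )
    keys = _draw_keys(rng_variants, n_total)
    it = iter(keys)
    hereditary = [next(it) for _ in range(cfg.n_planted_hereditary)]
    somatic = [next(it) for _ in range(cfg.n_planted_somatic)]
    artifacts = [next(it) for _ in range(cfg.n_systematic_artifacts)]
    common = [next(it) for _ in range(cfg.n_common_variants)]
    background = list(it)

    discovery_tumors = manifest.samples(tissue=Tissue.TUMOR, arm=Arm.DISCOVERY)
    discovery_pbmcs = manifest.samples(tissue=Tissue.PBMC, arm=Arm.DISCOVERY)
    normals = manifest.samples(tissue=Tissue.NORMAL_ATRIUM)
    validation = manifest.samples(arm=Arm.VALIDATION)
    lab = manifest.samples(arm=Arm.LAB_CONTROL)
    all_samples = manifest.sample_ids

    records: list[tuple[VariantCall, AnnotatedVariant]] = []

    def _zyg(rng: np.random.Generator) -> Zygosity:
        return Zygosity.HET if rng.random() < 0.9 else Zygosity.HOM

    def place(key, ann, samples, rng):
        zyg = _zyg(rng)  # one genotype per germline-style variant
        for s in samples:
            records.append((VariantCall(key, s, zyg), ann))

    hered_genes, som_genes = [], []
    for i, key in enumerate(hereditary, start=1):
        gene = f"GENH{i:02d}"
        hered_genes.append(gene)
        ann = _passing_annotation(rng_scores, key, gene, cfg)
        place(key, ann, discovery_tumors + discovery_pbmcs, rng_place)
    for i, key in enumerate(somatic, start=1):
        gene = f"GENS{i:02d}"
        som_genes.append(gene)
        ann = _passing_annotation(rng_scores, key, gene, cfg)
        place(key, ann, discovery_tumors, rng_place)
    for i, key in enumerate(artifacts, start=1):
        ann = _passing_annotation(rng_scores, key, f"GART{i:02d}", cfg)
        n_recur = int(rng_place.integers(2, min(6, len(validation)) + 1))
        recur = list(rng_place.choice(validation, size=n_recur, replace=False))
        place(key, ann, discovery_tumors + discovery_pbmcs + recur, rng_place)
    for i, key in enumerate(common, start=1):
        gene = f"GCOM{i:03d}"
        ann = AnnotatedVariant(
            key=key,
            gene=gene,
            region=Region.EXONIC,
            func_class=FuncClass.NONSYNONYMOUS,
            maf=_background_maf(rng_scores, cfg.maf_spectrum, force_common=True),
            predictors=_background_scores(rng_scores, cfg.predictor_noise),
        )
        # common variation is widespread: each sample carries it with p=0.5
        carriers = [s for s in all_samples if rng_place.random() < 0.5]
        if not carriers:
            carriers = [all_samples[int(rng_place.integers(0, len(all_samples)))]]
        place(key, ann, carriers, rng_place)
    for i, key in enumerate(background, start=1):
        gene = f"BG{i:04d}"
        ann = _background_annotation(rng_scores, key, gene, cfg)
        carriers = [s for s in all_samples if rng_place.random() < 0.15]
        if not carriers:
            carriers = [all_samples[int(rng_place.integers(0, len(all_samples)))]]
        place(key, ann, carriers, rng_place)

    # lab control database: everything observed in the lab-control exomes
    lab_set = set(lab)
    control_db = frozenset(
        call.key for call, _ in records if call.sample_id in lab_set
    )

    # expression: cases are the discovery tumors, control the first normal atrium
    params = cfg.expression_params
    case_samples = discovery_tumors
    control_samples = normals[:1]
    expression: list[ExpressionRecord] = []
    for gene in hered_genes + som_genes:
        control_rpkm = float(rng_expr.uniform(*params.control_rpkm_middle))
        expression.extend(
            _expression_for_gene(
                rng_expr, gene, control_rpkm, params.case_fold_change,
                case_samples, control_samples, params,
            )
        )
    for j in range(1, params.n_background_genes + 1):
        gene = f"XPR{j:03d}"
        if rng_expr.random() < 0.3:
            control_rpkm = float(rng_expr.uniform(*params.control_rpkm_not_credible))
        else:
            control_rpkm = float(rng_expr.uniform(0.05, 200.0))
        fold = float(rng_expr.uniform(0.5, 1.5))
        expression.extend(
            _expression_for_gene(
                rng_expr, gene, control_rpkm, fold, case_samples, control_samples, params
            )
        )

    truth = TruthLabels(
        hereditary=frozenset(hereditary),
        somatic=frozenset(somatic),
        artifacts=frozenset(artifacts),
        common=frozenset(common),
    )
    return SimulatedCohort(
        manifest=manifest,
        records=tuple(records),
        control_db=control_db,
        expression=tuple(expression),
        truth=truth,
        hereditary_genes=tuple(hered_genes),
        somatic_genes=tuple(som_genes),
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write manifest, variant table, control DB, expression and truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": outdir / "manifest.tsv",
        "variants": outdir / "variants.tsv",
        "control_db": outdir / "control_db.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    write_manifest(cohort.manifest, paths["manifest"])
    write_variant_table(list(cohort.records), paths["variants"], dialect="annovar_tsv")
    lines = ["chrom\tpos\tref\talt"]
    for key in sorted(cohort.control_db):
        lines.append(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}")
    paths["control_db"].write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    write_expression_table(list(cohort.expression), paths["expression"])
    truth_json = {
        cls: sorted(
            [k.chrom, k.pos, k.ref, k.alt] for k in getattr(cohort.truth, cls)
        )
        for cls in ("hereditary", "somatic", "artifacts", "common")
    }
    paths["truth"].write_text(
        json.dumps(truth_json, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths


def read_control_db(path) -> set[VariantKey]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        VariantKey.make(str(r.chrom), int(r.pos), r.ref, r.alt)
        for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Worked-example fixture (published rare-variant table)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorkedExampleVariant:
    """One row of the published rare coding-variant table."""

    call: VariantCall
    annotation: AnnotatedVariant
    evidence: EvidenceCodeSet
    expected_classification: str


def generate_worked_example() -> list[WorkedExampleVariant]:
    """The five rare coding variants of the discovery gene as a regression
    fixture: HGVS labels, zygosity, printed population frequencies and
    evidence-code sets. Genomic positions are synthetic placeholders (the
    published table identifies rows by HGVS only); frequencies are mapped
    into the screen's database keys (the ExAC value under ``exac03``).
    """
    gene = "KIF1C"

    def row(pos, ref, alt, hgvs_c, hgvs_p, zyg, func, region, exac, extra_maf, codes, expected, sample):
        maf = {"1000g2015Aug_eas": None, "esp6500siv2_all": None, "exac03": exac}
        maf.update(extra_maf)
        key = VariantKey.make("17", pos, ref, alt)
        return WorkedExampleVariant(
            call=VariantCall(key, sample, zyg),
            annotation=AnnotatedVariant(
                key=key,
                gene=gene,
                region=region,
                func_class=func,
                maf=maf,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
            ),
            evidence=EvidenceCodeSet(codes),
            expected_classification=expected,
        )

    return [
        row(
            772, "T", "G", "c.772T>G", "p.Ser258Ala", Zygosity.HET,
            FuncClass.NONSYNONYMOUS, Region.EXONIC, 3.4e-5,
            {"gnomad_exome": 3.2e-5, "korea1k": 5.0e-4, "ktopmed": 1.9e-5},
            {"PM1", "PM2"}, "uncertain_significance", "D2_T",
        ),
        row(
            899, "A", "T", "c.899A>T", "p.Tyr300Phe", Zygosity.HET,
            FuncClass.NONSYNONYMOUS, Region.EXONIC, 4.9e-5,
            {"gnomad_exome": 3.6e-5},
            {"PM1", "PM2", "PP3"}, "uncertain_significance", "D1_T",
        ),
        row(
            352, "A", "T", "c.352A>T", "p.Ile118Phe", Zygosity.HET,
            FuncClass.NONSYNONYMOUS, Region.EXONIC, None, {},
            {"PM1", "PM2", "PP3"}, "uncertain_significance", "V16_T",
        ),
        row(
            2895, "C", "T", "c.2895C>T", "p.Pro965Pro", Zygosity.HET,
            FuncClass.SYNONYMOUS, Region.EXONIC, None, {},
            {"PM2", "BP4", "BP7"}, "likely_benign", "V7_T",
        ),
        row(
            3049, "G", "A", "c.3049G>A", "p.Ala1017Thr", Zygosity.HOM,
            FuncClass.NONSYNONYMOUS, Region.EXONIC, 1.265e-3,
            {"gnomad_exome": 1.4e-3, "korea1k": 0.0131, "ktopmed": 7.37e-4},
            {"BS1", "BP4"}, "likely_benign", "V7_T",
        ),
    ]
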