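"""Domain types and file I/O for annotated variant tables and cohort manifests.

The pipeline works on post-annotation variant tables: each row is one
observation of one alternate allele in one sample, carrying the gene/region/
functional-class annotation, per-database minor allele frequencies (MAF),
and in-silico predictor scores. Two on-disk dialects are supported:

``annovar_tsv``
    A flat tab-separated table, one row per (variant, sample) observation,
    with the full annotation payload. This is the pipeline's native,
    lossless format.

``vcf_min``
    A minimal VCF 4.x file (uncompressed text) with per-sample ``GT``
    genotypes. Annotations are carried in reserved ``INFO`` keys so the
    format round-trips. Read through :mod:`pysam`.

Coordinates are 1-based VCF convention. Variant identity is the normalized
(chrom, pos, ref, alt) tuple: alleles are uppercased, the shared suffix and
then the shared prefix are trimmed (keeping at least one base of each
allele) and the position adjusted — a reference-free left normalization so
that locus equality, the basis of the recurrent-artifact rule, is
well-defined.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

__all__ = [
    "Region",
    "FuncClass",
    "Tissue",
    "Arm",
    "Zygosity",
    "VariantKey",
    "VariantCall",
    "PredictorScores",
    "AnnotatedVariant",
    "ManifestEntry",
    "CohortManifest",
    "VariantTableError",
    "ManifestError",
    "read_variant_table",
    "write_variant_table",
    "read_manifest",
    "write_manifest",
    "MAF_DATABASES",
]

#: Population frequency databases consulted by the default screen, in the
#: order the screening conditions list them.
MAF_DATABASES = ("1000g2015Aug_eas", "esp6500siv2_all", "exac03")

#: Values in MAF / predictor columns that denote a genuinely missing entry.
#: Missing is a first-class state: the frequency screen treats "absent from
#: the database" as passing, which is different from a frequency of zero.
_MISSING_TOKENS = {".", "", "NA", "nan", "NaN"}


class VariantTableError(ValueError):
    """Malformed variant table content (names file, line and column)."""


class ManifestError(ValueError):
    """Malformed cohort manifest."""


class Region(str, enum.Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    UTR3 = "UTR3"
    UTR5 = "UTR5"
    INTERGENIC = "intergenic"
    OTHER = "other"


class FuncClass(str, enum.Enum):
    NONSYNONYMOUS = "nonsynonymous"
    FRAMESHIFT = "frameshift"
    SPLICING = "splicing"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    SYNONYMOUS = "synonymous"
    UNKNOWN = "unknown"
    OTHER = "other"


class Tissue(str, enum.Enum):
    TUMOR = "tumor"
    PBMC = "pbmc"
    NORMAL_ATRIUM = "normal_atrium"


class Arm(str, enum.Enum):
    DISCOVERY = "discovery"
    VALIDATION = "validation"
    NORMAL_CONTROL = "normal_control"
    LAB_CONTROL = "lab_control"


class Zygosity(str, enum.Enum):
    HET = "Het"
    HOM = "Hom"


_ACGT = frozenset("ACGT")


def _normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix, keeping >=1 base per allele."""
    ref, alt = ref.upper(), alt.upper()
    # suffix trim
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # prefix trim (advances pos)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized identity of a single alternate allele at a locus.

    Equality and hashing use the normalized (chrom, pos, ref, alt) tuple;
    construct via :meth:`make` to apply normalization.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _ACGT:
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")

    @classmethod
    def make(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        pos, ref, alt = _normalize_alleles(int(pos), ref, alt)
        return cls(str(chrom), pos, ref, alt)

    def normalized(self) -> "VariantKey":
        return VariantKey.make(self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """One sample's observation of a variant."""

    key: VariantKey
    sample_id: str
    zygosity: Zygosity


@dataclass(frozen=True)
class PredictorScores:
    """Scores of the six in-silico pathogenicity predictors.

    Missing values are ``None``, never 0 — a predictor with no opinion must
    abstain from the damage vote rather than count as benign-with-score-0.
    """

    sift: Optional[float] = None          # [0,1]; low = damaging
    polyphen2: Optional[str] = None       # D / P / B
    phylop: Optional[float] = None        # conservation; high = damaging
    gerp: Optional[float] = None          # conservation; high = damaging
    mutationtaster: Optional[str] = None  # A / D / N / P
    lrt: Optional[str] = None             # D / N / U

    _POLYPHEN2 = frozenset("DPB")
    _MUTATIONTASTER = frozenset("ADNP")
    _LRT = frozenset("DNU")

    def __post_init__(self) -> None:
        if self.sift is not None and not 0.0 <= self.sift <= 1.0:
            raise ValueError(f"SIFT score {self.sift} outside [0,1]")
        for name, value, allowed in (
            ("polyphen2", self.polyphen2, self._POLYPHEN2),
            ("mutationtaster", self.mutationtaster, self._MUTATIONTASTER),
            ("lrt", self.lrt, self._LRT),
        ):
            if value is not None and value not in allowed:
                raise ValueError(f"{name} category {value!r} not in {sorted(allowed)}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant together with its functional annotation payload."""

    key: VariantKey
    gene: str
    region: Region
    func_class: FuncClass
    maf: Mapping[str, Optional[float]] = field(default_factory=dict)
    predictors: PredictorScores = field(default_factory=PredictorScores)
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None

    def __post_init__(self) -> None:
        for db, value in self.maf.items():
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"MAF {db}={value} outside [0,1]")
        # freeze the mapping so the dataclass stays hashable-by-identity safe
        object.__setattr__(self, "maf", dict(self.maf))

    def maf_value(self, db: str) -> Optional[float]:
        return self.maf.get(db)


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    patient_id: str
    tissue: Tissue
    arm: Arm


@dataclass(frozen=True)
class CohortManifest:
    """Sample -> (patient, tissue, cohort arm) map driving the set logic."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.sample_id in seen:
                raise ManifestError(f"duplicate sample_id {e.sample_id!r} in manifest")
            seen.add(e.sample_id)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str, str]]) -> "CohortManifest":
        entries = []
        for sample_id, patient_id, tissue, arm in rows:
            try:
                entries.append(
                    ManifestEntry(sample_id, patient_id, Tissue(tissue), Arm(arm))
                )
            except ValueError as exc:
                raise ManifestError(
                    f"sample {sample_id!r}: unknown tissue/arm value ({exc})"
                ) from exc
        return cls(tuple(entries))

    # -- convenience selectors used throughout the set logic ---------------
    def samples(self, tissue: Optional[Tissue] = None, arm: Optional[Arm] = None) -> list[str]:
        return [
            e.sample_id
            for e in self.entries
            if (tissue is None or e.tissue == tissue)
            and (arm is None or e.arm == arm)
        ]

    def patient_of(self, sample_id: str) -> str:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e.patient_id
        raise ManifestError(f"sample {sample_id!r} not in manifest")

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def discovery_patients(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.arm == Arm.DISCOVERY and e.patient_id not in seen:
                seen.append(e.patient_id)
        return seen


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_FIXED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample_id",
    "zygosity",
    "gene",
    "region",
    "func_class",
    "hgvs_c",
    "hgvs_p",
    "sift",
    "polyphen2",
    "phylop",
    "gerp",
    "mutationtaster",
    "lrt",
]


def _parse_missing_float(token: str) -> Optional[float]:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return None
    return float(token)


def _parse_missing_str(token: str) -> Optional[str]:
    token = token.strip()
    return None if token in _MISSING_TOKENS else token


def _fmt(value: object) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        if math.isnan(value):
            return "."
        return repr(value)
    return str(value)


Record = tuple[VariantCall, AnnotatedVariant]


def _maf_columns(records: Sequence[Record]) -> list[str]:
    cols = [db for db in MAF_DATABASES]
    extra = sorted(
        {db for _, ann in records for db in ann.maf} - set(cols)
    )
    return cols + extra


def _read_tsv(path: Path, column_map: Optional[Mapping[str, str]] = None) -> list[Record]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _TSV_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing required columns {missing}")
    maf_cols = [c for c in df.columns if c.startswith("maf_")]
    records: list[Record] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        row_d = dict(zip(df.columns, row))
        col = "?"
        try:
            col = "chrom/pos/ref/alt"
            key = VariantKey.make(row_d["chrom"], int(row_d["pos"]), row_d["ref"], row_d["alt"])
            col = "zygosity"
            zyg = Zygosity(row_d["zygosity"])
            col = "region"
            region = Region(row_d["region"])
            col = "func_class"
            func = FuncClass(row_d["func_class"])
            col = "predictors"
            scores = PredictorScores(
                sift=_parse_missing_float(row_d["sift"]),
                polyphen2=_parse_missing_str(row_d["polyphen2"]),
                phylop=_parse_missing_float(row_d["phylop"]),
                gerp=_parse_missing_float(row_d["gerp"]),
                mutationtaster=_parse_missing_str(row_d["mutationtaster"]),
                lrt=_parse_missing_str(row_d["lrt"]),
            )
            maf = {}
            for c in maf_cols:
                col = c
                maf[c[len("maf_"):]] = _parse_missing_float(row_d[c])
        except (ValueError, KeyError) as exc:
            raise VariantTableError(f"{path}: line {i}, column {col}: {exc}") from exc
        call = VariantCall(key, row_d["sample_id"], zyg)
        ann = AnnotatedVariant(
            key=key,
            gene=row_d["gene"],
            region=region,
            func_class=func,
            maf=maf,
            predictors=scores,
            hgvs_c=_parse_missing_str(row_d["hgvs_c"]),
            hgvs_p=_parse_missing_str(row_d["hgvs_p"]),
        )
        records.append((call, ann))
    return records


def _write_tsv(records: Sequence[Record], path: Path) -> None:
    maf_cols = _maf_columns(records)
    header = _TSV_FIXED_COLUMNS + [f"maf_{db}" for db in maf_cols]
    lines = ["\t".join(header)]
    for call, ann in records:
        p = ann.predictors
        row = [
            ann.key.chrom,
            str(ann.key.pos),
            ann.key.ref,
            ann.key.alt,
            call.sample_id,
            call.zygosity.value,
            ann.gene,
            ann.region.value,
            ann.func_class.value,
            _fmt(ann.hgvs_c),
            _fmt(ann.hgvs_p),
            _fmt(p.sift),
            _fmt(p.polyphen2),
            _fmt(p.phylop),
            _fmt(p.gerp),
            _fmt(p.mutationtaster),
            _fmt(p.lrt),
        ] + [_fmt(ann.maf.get(db)) for db in maf_cols]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# Minimal VCF dialect (via pysam)
# ---------------------------------------------------------------------------

# Numeric annotations travel as String INFO so values round-trip at full
# precision (VCF Float is single-precision in htslib).
_VCF_INFO_FIELDS = [
    ("GENE", "String", "Gene symbol"),
    ("REGION", "String", "Annotated region"),
    ("FUNC", "String", "Functional class"),
    ("HGVSC", "String", "HGVS cDNA"),
    ("HGVSP", "String", "HGVS protein"),
    ("SIFT", "String", "SIFT score"),
    ("PP2", "String", "PolyPhen-2 category"),
    ("PHYLOP", "String", "PhyloP score"),
    ("GERP", "String", "GERP++ score"),
    ("MT", "String", "MutationTaster category"),
    ("LRT", "String", "LRT category"),
]


def _zygosity_from_gt(gt: tuple, path: Path, line_hint: str) -> Optional[Zygosity]:
    alleles = tuple(a for a in gt if a is not None)
    if not alleles:
        return None
    if set(alleles) == {0}:
        return None
    if sorted(alleles) == [0, 1]:
        return Zygosity.HET
    if alleles == (1, 1):
        return Zygosity.HOM
    raise VariantTableError(
        f"{path}: record {line_hint}: unsupported genotype {gt}; only 0/0, 0/1, 1/1 "
        "(per split alternate allele) are accepted"
    )


def _read_vcf(path: Path) -> list[Record]:
    records: list[Record] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise VariantTableError(f"{path}: VCF has no sample columns (GT required)")
        for rec in vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                key = VariantKey.make(rec.chrom, rec.pos, rec.ref, alt)
                info = rec.info

                def _inf(tag: str) -> Optional[str]:
                    if tag not in info:
                        return None
                    v = info[tag]
                    if isinstance(v, tuple):
                        v = v[alt_index - 1] if len(v) >= alt_index else v[0]
                    if v is None:
                        return None
                    s = str(v)
                    return None if s in _MISSING_TOKENS else s

                def _inf_f(tag: str) -> Optional[float]:
                    s = _inf(tag)
                    return None if s is None else float(s)

                # enumerate MAF databases from the header so entries that
                # are missing in this record stay represented as missing
                maf: dict[str, Optional[float]] = {}
                for info_key in vcf.header.info.keys():
                    if info_key.startswith("MAF_"):
                        db = info_key[len("MAF_"):]
                        maf[db] = _inf_f(info_key)
                ann = AnnotatedVariant(
                    key=key,
                    gene=_inf("GENE") or "",
                    region=Region(_inf("REGION") or "other"),
                    func_class=FuncClass(_inf("FUNC") or "other"),
                    maf=maf,
                    predictors=PredictorScores(
                        sift=_inf_f("SIFT"),
                        polyphen2=_inf("PP2"),
                        phylop=_inf_f("PHYLOP"),
                        gerp=_inf_f("GERP"),
                        mutationtaster=_inf("MT"),
                        lrt=_inf("LRT"),
                    ),
                    hgvs_c=_inf("HGVSC"),
                    hgvs_p=_inf("HGVSP"),
                )
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None:
                        continue
                    # project the genotype onto this alternate allele
                    projected = tuple(
                        None if a is None else (1 if a == alt_index else 0) for a in gt
                    )
                    zyg = _zygosity_from_gt(
                        projected, path, f"{rec.chrom}:{rec.pos}"
                    )
                    if zyg is None:
                        continue
                    records.append((VariantCall(key, sample, zyg), ann))
    return records


def _write_vcf(records: Sequence[Record], path: Path) -> None:
    header = pysam.VariantHeader()
    chroms: list[str] = []
    for _, ann in records:
        if ann.key.chrom not in chroms:
            chroms.append(ann.key.chrom)
    for chrom in chroms:
        header.contigs.add(chrom)
    for tag, typ, desc in _VCF_INFO_FIELDS:
        header.info.add(tag, 1, typ, desc)
    maf_dbs = _maf_columns(records)
    for db in maf_dbs:
        header.info.add(f"MAF_{db}", 1, "String", f"MAF in {db}")
    header.formats.add("GT", 1, "String", "Genotype")
    samples: list[str] = []
    for call, _ in records:
        if call.sample_id not in samples:
            samples.append(call.sample_id)
    for s in samples:
        header.add_sample(s)

    # group per variant key, preserving first-seen order
    by_key: dict[VariantKey, tuple[AnnotatedVariant, dict[str, Zygosity]]] = {}
    for call, ann in records:
        ann0, zygs = by_key.setdefault(ann.key, (ann, {}))
        zygs[call.sample_id] = call.zygosity

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key, (ann, zygs) in by_key.items():
            rec = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            p = ann.predictors
            info_vals = {
                "GENE": ann.gene or None,
                "REGION": ann.region.value,
                "FUNC": ann.func_class.value,
                "HGVSC": ann.hgvs_c,
                "HGVSP": ann.hgvs_p,
                "SIFT": None if p.sift is None else repr(p.sift),
                "PP2": p.polyphen2,
                "PHYLOP": None if p.phylop is None else repr(p.phylop),
                "GERP": None if p.gerp is None else repr(p.gerp),
                "MT": p.mutationtaster,
                "LRT": p.lrt,
            }
            for db in maf_dbs:
                value = ann.maf.get(db)
                info_vals[f"MAF_{db}"] = None if value is None else repr(value)
            for tag, value in info_vals.items():
                if value is not None:
                    rec.info[tag] = value
            for s in samples:
                if s in zygs:
                    rec.samples[s]["GT"] = (
                        (0, 1) if zygs[s] == Zygosity.HET else (1, 1)
                    )
                else:
                    rec.samples[s]["GT"] = (0, 0)
            out.write(rec)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_variant_table(
    path: Union[str, Path],
    dialect: str = "annovar_tsv",
    column_map: Optional[Mapping[str, str]] = None,
) -> list[Record]:
    """Read a variant table; returns (call, annotation) pairs.

    ``column_map`` (annovar_tsv only) maps vendor column names onto the
    documented canonical header, e.g. ``{"Gene.refGene": "gene"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "annovar_tsv":
        return _read_tsv(path, column_map)
    if dialect == "vcf_min":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected annovar_tsv or vcf_min")


def write_variant_table(
    records: Sequence[Record], path: Union[str, Path], dialect: str = "annovar_tsv"
) -> None:
    path = Path(path)
    if dialect == "annovar_tsv":
        _write_tsv(records, path)
    elif dialect == "vcf_min":
        _write_vcf(records, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected annovar_tsv or vcf_min")


_MANIFEST_COLUMNS = ["sample_id", "patient_id", "tissue", "arm"]


def read_manifest(path: Union[str, Path]) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        raise ManifestError(f"{path}: empty manifest")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    if len(df) == 0:
        raise ManifestError(f"{path}: empty manifest")
    return CohortManifest.from_rows(
        (r.sample_id, r.patient_id, r.tissue, r.arm) for r in df.itertuples(index=False)
    )


def write_manifest(manifest: CohortManifest, path: Union[str, Path]) -> None:
    lines = ["\t".join(_MANIFEST_COLUMNS)]
    for e in manifest.entries:
        lines.append("\t".join([e.sample_id, e.patient_id, e.tissue.value, e.arm.value]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
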