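"""Preliminary per-variant screening filters.

Five conditions are applied to every annotated variant of every sample
before any cross-sample logic:

1. the variant falls in an exon or splicing region;
2. its functional class is nonsynonymous, frameshift, splicing, stopgain,
   stoploss, or unknown;
3-5. its minor allele frequency in each configured population database
   (East-Asian 1000 Genomes, ESP6500, ExAC by default) is below the rarity
   threshold (0.001) or absent from that database.

The MAF comparison is strictly less-than and every database must pass
individually. A variant absent from a database ("NA") passes that
database's condition: absence from a population catalogue is evidence of
rarity, not of frequency zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variants import AnnotatedVariant, FuncClass, Region, MAF_DATABASES

__all__ = [
    "ScreenConfig",
    "passes_region",
    "passes_function",
    "passes_maf",
    "passes_all",
    "preliminary_screen",
]

DEFAULT_REGIONS = frozenset({Region.EXONIC, Region.SPLICING})
DEFAULT_FUNC = frozenset(
    {
        FuncClass.NONSYNONYMOUS,
        FuncClass.FRAMESHIFT,
        FuncClass.SPLICING,
        FuncClass.STOPGAIN,
        FuncClass.STOPLOSS,
        FuncClass.UNKNOWN,
    }
)


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the preliminary screen.

    ``missing_passes`` controls the "or NA" clause of the frequency
    conditions; the default (True) is the published rule.
    """

    allowed_regions: frozenset[Region] = DEFAULT_REGIONS
    allowed_func: frozenset[FuncClass] = DEFAULT_FUNC
    maf_databases: tuple[str, ...] = MAF_DATABASES
    maf_threshold: float = 0.001
    missing_passes: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError(f"maf_threshold must be in (0,1), got {self.maf_threshold}")
        if not self.maf_databases:
            raise ValueError("maf_databases must be non-empty")


def passes_region(v: AnnotatedVariant, cfg: ScreenConfig = ScreenConfig()) -> bool:
    return v.region in cfg.allowed_regions


def passes_function(v: AnnotatedVariant, cfg: ScreenConfig = ScreenConfig()) -> bool:
    return v.func_class in cfg.allowed_func


def passes_maf(v: AnnotatedVariant, cfg: ScreenConfig = ScreenConfig()) -> bool:
    """True iff every configured database is below threshold or missing."""
    for db in cfg.maf_databases:
        value = v.maf_value(db)
        if value is None:
            if not cfg.missing_passes:
                return False
        elif value >= cfg.maf_threshold:  # strict "<" passes
            return False
    return True


def passes_all(v: AnnotatedVariant, cfg: ScreenConfig = ScreenConfig()) -> bool:
    return passes_region(v, cfg) and passes_function(v, cfg) and passes_maf(v, cfg)


def preliminary_screen(
    records: Sequence[AnnotatedVariant], cfg: ScreenConfig = ScreenConfig()
) -> list[AnnotatedVariant]:
    """Keep exactly the variants passing all conditions; order preserved."""
    return [v for v in records if passes_all(v, cfg)]
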