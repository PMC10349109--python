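"""Consensus in-silico damage voting and ACMG/AMP classification.

Two independent pieces of evidence machinery:

*Consensus voter.* Six predictors each cast a binary "damaging" vote —
SIFT < 0.1, PolyPhen-2 in {D, P}, PhyloP > 0.95, GERP++ > 4,
MutationTaster in {A, D}, LRT = D. A missing predictor abstains (0 votes).
A variant is called damaging by consensus when at least ``min_votes``
(default 4) predictors vote damaging.

*ACMG/AMP combiner.* Takes a set of the 28 standard evidence codes
(PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7) and applies the 2015
ACMG/AMP combining rules to produce one of the five tiers: pathogenic,
likely pathogenic, uncertain significance, likely benign, benign. The
combining rules are encoded as data (a rule list per tier) so alternative
conflict-resolution profiles can be selected:

``intervar_default``
    Mirrors the behavior of the InterVar implementation run with default
    parameters: a benign-tier call overrides a pathogenic tier that
    reached only *uncertain*, while a pathogenic tier of likely-pathogenic
    or stronger combined with any benign evidence degrades to *uncertain*.
    This profile was reverse-engineered from published classifications
    (e.g. {PM2, BP4, BP7} -> likely benign) and is the default.

``strict_acmg``
    Any co-occurrence of a fired pathogenic tier and a fired benign tier
    yields *uncertain significance*.

Evidence-code *assignment* (deciding a variant deserves PM1) is out of
scope; codes are inputs.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Collection, Iterable, Optional

from .variants import PredictorScores

__all__ = [
    "PredictorThresholds",
    "Classification",
    "ALL_EVIDENCE_CODES",
    "EvidenceCodeSet",
    "damaging_votes",
    "consensus_damaging",
    "acmg_classify",
]


class Classification(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN_SIGNIFICANCE = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


@dataclass(frozen=True)
class PredictorThresholds:
    """Damaging criteria of the six predictors plus the consensus cutoff."""

    sift_lt: float = 0.1
    polyphen2_damaging: frozenset[str] = frozenset({"D", "P"})
    phylop_gt: float = 0.95
    gerp_gt: float = 4.0
    mutationtaster_damaging: frozenset[str] = frozenset({"A", "D"})
    lrt_damaging: frozenset[str] = frozenset({"D"})
    min_votes: int = 4

    def __post_init__(self) -> None:
        if not 1 <= self.min_votes <= 6:
            raise ValueError(f"min_votes must be in 1..6, got {self.min_votes}")


def damaging_votes(
    scores: PredictorScores, th: PredictorThresholds = PredictorThresholds()
) -> int:
    """Count of predictors voting damaging (0..6); missing scores abstain.

    All numeric comparisons are strict, so boundary values (SIFT exactly
    0.1, PhyloP exactly 0.95, GERP++ exactly 4) do not vote.
    """
    votes = 0
    if scores.sift is not None and scores.sift < th.sift_lt:
        votes += 1
    if scores.polyphen2 is not None and scores.polyphen2 in th.polyphen2_damaging:
        votes += 1
    if scores.phylop is not None and scores.phylop > th.phylop_gt:
        votes += 1
    if scores.gerp is not None and scores.gerp > th.gerp_gt:
        votes += 1
    if (
        scores.mutationtaster is not None
        and scores.mutationtaster in th.mutationtaster_damaging
    ):
        votes += 1
    if scores.lrt is not None and scores.lrt in th.lrt_damaging:
        votes += 1
    return votes


def consensus_damaging(
    scores: PredictorScores, th: PredictorThresholds = PredictorThresholds()
) -> bool:
    """True when at least ``th.min_votes`` predictors vote damaging."""
    return damaging_votes(scores, th) >= th.min_votes


# ---------------------------------------------------------------------------
# ACMG/AMP evidence codes and combining rules
# ---------------------------------------------------------------------------

ALL_EVIDENCE_CODES: frozenset[str] = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)


class EvidenceCodeSet(frozenset):
    """A set of ACMG/AMP evidence codes; unknown code names are rejected."""

    def __new__(cls, codes: Iterable[str] = ()):
        codes = frozenset(str(c).strip() for c in codes)
        unknown = codes - ALL_EVIDENCE_CODES
        if unknown:
            raise ValueError(f"unknown ACMG evidence code(s): {sorted(unknown)}")
        return super().__new__(cls, codes)

    def count(self, category: str) -> int:
        """Number of codes in a strength category: PVS, PS, PM, PP, BA, BS, BP."""
        return sum(
            1 for c in self if c.startswith(category) and c[len(category):].isdigit()
        )


def _strength_counts(ev: EvidenceCodeSet) -> dict[str, int]:
    return {cat: ev.count(cat) for cat in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")}


# Each rule: (tier, predicate over the strength-count dict). Rules are the
# 2015 ACMG/AMP combining criteria, checked strongest tier first.
_PATHOGENIC_RULES = [
    lambda n: n["PVS"] >= 1
    and (n["PS"] >= 1 or n["PM"] >= 2 or (n["PM"] >= 1 and n["PP"] >= 1) or n["PP"] >= 2),
    lambda n: n["PS"] >= 2,
    lambda n: n["PS"] >= 1
    and (n["PM"] >= 3 or (n["PM"] >= 2 and n["PP"] >= 2) or (n["PM"] >= 1 and n["PP"] >= 4)),
]

_LIKELY_PATHOGENIC_RULES = [
    lambda n: n["PVS"] >= 1 and n["PM"] >= 1,
    lambda n: n["PS"] >= 1 and n["PM"] >= 1,
    lambda n: n["PS"] >= 1 and n["PP"] >= 2,
    lambda n: n["PM"] >= 3,
    lambda n: n["PM"] >= 2 and n["PP"] >= 2,
    lambda n: n["PM"] >= 1 and n["PP"] >= 4,
]

_BENIGN_RULES = [
    lambda n: n["BA"] >= 1,
    lambda n: n["BS"] >= 2,
]

_LIKELY_BENIGN_RULES = [
    lambda n: n["BS"] >= 1 and n["BP"] >= 1,
    lambda n: n["BP"] >= 2,
]


def _pathogenic_tier(n: dict[str, int]) -> Classification:
    if any(rule(n) for rule in _PATHOGENIC_RULES):
        return Classification.PATHOGENIC
    if any(rule(n) for rule in _LIKELY_PATHOGENIC_RULES):
        return Classification.LIKELY_PATHOGENIC
    return Classification.UNCERTAIN_SIGNIFICANCE


def _benign_tier(n: dict[str, int]) -> Classification:
    if any(rule(n) for rule in _BENIGN_RULES):
        return Classification.BENIGN
    if any(rule(n) for rule in _LIKELY_BENIGN_RULES):
        return Classification.LIKELY_BENIGN
    return Classification.UNCERTAIN_SIGNIFICANCE


def acmg_classify(
    ev: Collection[str], profile: str = "intervar_default"
) -> Classification:
    """Combine ACMG/AMP evidence codes into a five-tier classification."""
    ev = ev if isinstance(ev, EvidenceCodeSet) else EvidenceCodeSet(ev)
    n = _strength_counts(ev)
    path_tier = _pathogenic_tier(n)
    benign_tier = _benign_tier(n)
    path_fired = path_tier != Classification.UNCERTAIN_SIGNIFICANCE
    benign_fired = benign_tier != Classification.UNCERTAIN_SIGNIFICANCE
    has_benign_evidence = n["BA"] + n["BS"] + n["BP"] > 0

    if profile == "intervar_default":
        if path_fired and has_benign_evidence:
            return Classification.UNCERTAIN_SIGNIFICANCE
        if path_fired:
            return path_tier
        if benign_fired:
            return benign_tier
        return Classification.UNCERTAIN_SIGNIFICANCE
    if profile == "strict_acmg":
        if path_fired and benign_fired:
            return Classification.UNCERTAIN_SIGNIFICANCE
        if path_fired:
            return path_tier
        if benign_fired:
            return benign_tier
        return Classification.UNCERTAIN_SIGNIFICANCE
    raise ValueError(f"unknown profile {profile!r}")
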