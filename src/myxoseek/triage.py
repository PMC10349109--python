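"""Cross-sample candidate derivation: hereditary/somatic set logic,
recurrent-artifact elimination, and control-database subtraction.

The cohort design this logic assumes: a small discovery arm with tumor
samples from >=2 patients and at least one blood (PBMC) sample, a set of
normal-tissue controls, a validation arm of further sporadic patients, and
optionally a lab control database of variants seen in healthy in-house
exomes.

*Hereditary hypothesis* — a germline driver is present in every discovery
tumor AND in the discovery blood, and absent from every normal tissue.

*Somatic hypothesis* — a tumor-acquired driver is present in every
discovery tumor, absent from the discovery blood, and absent from every
normal tissue. The two hypotheses are mutually exclusive whenever a blood
sample exists.

*Systematic errors* — the same variant at the same locus observed in
multiple unrelated patients is treated as a platform artifact and removed
(patients, not samples: one patient's tumor + blood pair counts once).

*Control database* — variants present in the lab's healthy-control exomes
are subtracted as common local variation.

Presence/absence is genotype-blind: a heterozygous and a homozygous call
both count as "present". Zygosity is carried through to reports only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .variants import (
    AnnotatedVariant,
    Arm,
    CohortManifest,
    Tissue,
    VariantCall,
    VariantKey,
)

__all__ = [
    "CandidateSet",
    "CohortError",
    "hereditary_candidates",
    "somatic_candidates",
    "remove_systematic_errors",
    "subtract_control_db",
    "summarize",
]


class CohortError(ValueError):
    """The manifest lacks a sample role the requested set logic needs."""


@dataclass(frozen=True)
class CandidateSet:
    """Surviving candidates plus a per-stage removal ledger."""

    hypothesis: str  # "hereditary" | "somatic"
    variants: frozenset[VariantKey]
    genes: frozenset[str]
    provenance: tuple[tuple[str, int], ...]  # (stage name, variants removed)

    @property
    def n_loci(self) -> int:
        return len(self.variants)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _presence(calls: Iterable[VariantCall]) -> dict[VariantKey, set[str]]:
    """Map variant -> set of sample_ids it was observed in."""
    seen: dict[VariantKey, set[str]] = {}
    for call in calls:
        seen.setdefault(call.key, set()).add(call.sample_id)
    return seen


def _required_samples(manifest: CohortManifest, hypothesis: str) -> tuple[list[str], list[str], list[str]]:
    tumors = manifest.samples(tissue=Tissue.TUMOR, arm=Arm.DISCOVERY)
    pbmcs = manifest.samples(tissue=Tissue.PBMC, arm=Arm.DISCOVERY)
    normals = manifest.samples(tissue=Tissue.NORMAL_ATRIUM)
    if len(tumors) < 2:
        raise CohortError(
            f"{hypothesis} hypothesis requires >=2 discovery tumor samples, found {len(tumors)}"
        )
    if not pbmcs:
        raise CohortError(f"{hypothesis} hypothesis requires >=1 discovery pbmc sample")
    if not normals:
        raise CohortError(f"{hypothesis} hypothesis requires >=1 normal_atrium sample")
    return tumors, pbmcs, normals


def hereditary_candidates(
    calls: Sequence[VariantCall],
    manifest: CohortManifest,
    tumor_presence: str = "all",
) -> set[VariantKey]:
    """Variants present in the discovery tumors and blood, absent from normals.

    ``tumor_presence`` is "all" (default: present in every discovery tumor)
    or "any" (present in at least one).
    """
    tumors, pbmcs, normals = _required_samples(manifest, "hereditary")
    seen = _presence(calls)
    out = set()
    for key, samples in seen.items():
        in_tumors = (
            all(t in samples for t in tumors)
            if tumor_presence == "all"
            else any(t in samples for t in tumors)
        )
        in_pbmcs = all(p in samples for p in pbmcs)
        in_normals = any(n in samples for n in normals)
        if in_tumors and in_pbmcs and not in_normals:
            out.add(key)
    return out


def somatic_candidates(
    calls: Sequence[VariantCall],
    manifest: CohortManifest,
    tumor_presence: str = "all",
) -> set[VariantKey]:
    """Variants present in the discovery tumors, absent from blood and normals."""
    tumors, pbmcs, normals = _required_samples(manifest, "somatic")
    seen = _presence(calls)
    out = set()
    for key, samples in seen.items():
        in_tumors = (
            all(t in samples for t in tumors)
            if tumor_presence == "all"
            else any(t in samples for t in tumors)
        )
        in_pbmcs = any(p in samples for p in pbmcs)
        in_normals = any(n in samples for n in normals)
        if in_tumors and not in_pbmcs and not in_normals:
            out.add(key)
    return out


def remove_systematic_errors(
    candidates: set[VariantKey],
    calls: Sequence[VariantCall],
    manifest: CohortManifest,
    min_patients: int = 2,
    exclude_discovery: bool = True,
) -> set[VariantKey]:
    """Drop candidates recurring in >= ``min_patients`` distinct patients.

    Recurrence of the identical allele at the identical locus across
    unrelated sporadic patients is far more likely to be a platform
    artifact than independent mutation; counting is per patient (one
    patient's tumor + blood pair counts once).

    With ``exclude_discovery`` (the default) only patients outside the
    discovery arm count toward recurrence. A hereditary candidate is by
    construction carried by every discovery patient, so counting the
    discovery arm would disqualify all true candidates at the default
    threshold; the artifact signal is recurrence among the *other*,
    unrelated patients. Set ``exclude_discovery=False`` to count every
    arm's patients.
    """
    if min_patients < 2:
        raise ValueError(f"min_patients must be >= 2, got {min_patients}")
    excluded = (
        set(manifest.discovery_patients) if exclude_discovery else set()
    )
    patients_with: dict[VariantKey, set[str]] = {}
    for call in calls:
        patient = manifest.patient_of(call.sample_id)
        if patient in excluded:
            continue
        patients_with.setdefault(call.key, set()).add(patient)
    return {
        key
        for key in candidates
        if len(patients_with.get(key, set())) < min_patients
    }


def subtract_control_db(
    candidates: set[VariantKey], control_db: Iterable[VariantKey]
) -> set[VariantKey]:
    """Remove candidates present in the lab healthy-control variant database."""
    return set(candidates) - set(control_db)


def summarize(
    candidates: set[VariantKey],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    hypothesis: str = "hereditary",
    provenance: Sequence[tuple[str, int]] = (),
) -> CandidateSet:
    """Collapse surviving variants to a gene/locus summary with provenance."""
    unannotated = [k for k in candidates if k not in annotations]
    if unannotated:
        raise KeyError(
            f"{len(unannotated)} candidate(s) lack annotations, e.g. {sorted(unannotated)[0]}"
        )
    genes = frozenset(annotations[k].gene for k in candidates)
    return CandidateSet(
        hypothesis=hypothesis,
        variants=frozenset(candidates),
        genes=genes,
        provenance=tuple(provenance),
    )
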