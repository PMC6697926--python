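"""Genomic characterization of a model's probe set.

Answers "where do the purity-informative CpGs live?": fractions of probes in
CpG islands, gene bodies and promoters (TSS200 or TSS1500, the standard 450K
manifest convention) against the all-array baseline, and the overlap with a
tumor-suppressor gene list.  Categories overlap, so fractions do not sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ProbeAnnotation, ValidationError

__all__ = ["RegionProfile", "region_fractions", "tsg_overlap_fraction"]

PROMOTER_REGIONS = frozenset({"TSS200", "TSS1500"})


@dataclass(frozen=True)
class RegionProfile:
    """Island / gene-body / promoter fractions of a probe set vs the array."""

    fractions: dict  # {"Island": ..., "Body": ..., "Promoter": ...}
    baseline: dict  # same map over all annotated probes
    n_probes: int
    missing_probes: tuple = ()  # probes absent from the annotation

    def to_frame(self) -> pd.DataFrame:
        cats = sorted(self.fractions)
        return pd.DataFrame(
            {
                "category": cats,
                "fraction": [self.fractions[c] for c in cats],
                "baseline": [self.baseline[c] for c in cats],
            }
        )


def _category_fractions(table: pd.DataFrame) -> dict:
    n = len(table)
    island = sum(rel == "Island" for rel in table["island_relation"])
    body = sum("Body" in regions for regions in table["gene_region"])
    promoter = sum(bool(PROMOTER_REGIONS & regions) for regions in table["gene_region"])
    return {"Island": island / n, "Body": body / n, "Promoter": promoter / n}


def region_fractions(probes, ann: ProbeAnnotation) -> RegionProfile:
    """Fractions of a (de-duplicated) probe set per annotation category.

    Probes absent from the annotation are reported and excluded from the
    denominator; the baseline is computed over all annotated probes.
    """
    probes = list(dict.fromkeys(probes))
    if not probes:
        raise ValidationError("empty probe set")
    known = set(ann.probe_ids)
    present = [p for p in probes if p in known]
    missing = tuple(p for p in probes if p not in known)
    if not present:
        raise ValidationError("no probe of the set is covered by the annotation")
    return RegionProfile(
        fractions=_category_fractions(ann.table.loc[present]),
        baseline=_category_fractions(ann.table),
        n_probes=len(present),
        missing_probes=missing,
    )


def tsg_overlap_fraction(probes, ann: ProbeAnnotation, tsg) -> tuple:
    """Fraction of probes whose gene annotation hits a tumor-suppressor gene.

    Membership semantics: a probe mapping to several listed genes counts once
    toward the fraction but contributes every matched symbol to the returned
    list.  Matching is case-sensitive exact after whitespace trim.
    """
    tsg = {str(s).strip() for s in tsg if str(s).strip()}
    if not tsg:
        raise ValidationError("empty tumor-suppressor gene list")
    probes = list(dict.fromkeys(probes))
    if not probes:
        raise ValidationError("empty probe set")
    known = set(ann.probe_ids)
    present = [p for p in probes if p in known]
    if not present:
        raise ValidationError("no probe of the set is covered by the annotation")
    hits = 0
    matched: set = set()
    for probe in present:
        overlap = ann.table.at[probe, "gene_symbols"] & tsg
        if overlap:
            hits += 1
            matched |= overlap
    return hits / len(present), tuple(sorted(matched))
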