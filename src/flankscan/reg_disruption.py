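"""Scoring of targeting events for likely disruption of intragenic
regulatory elements, from user-supplied TFBS and ChIP-peak intervals.

A TRAP insertion is scored disruptive when it separates the promoter from
two or more high-confidence TFBS, i.e. at least two such sites lie in the
gene body 3' (transcription direction) of the insertion intron. A DEL event
is scored disruptive when at least two TFBS fall in the deleted span and at
least one ChIP peak (Pol2/CTCF/p300) corroborates regulatory activity there.
Interval comparisons use any-overlap semantics on 1-based inclusive
coordinates.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .empirical_null import chisq_homogeneity
from .models import (
    DEL,
    TRAP,
    ChiSquareResult,
    GeneModel,
    RegAnnotation,
    RegDisruptionCall,
    TargetAllele,
)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def _post_trap_region(allele: TargetAllele, model: GeneModel) -> tuple[int, int]:
    """Genomic span of the gene body 3' of the insertion intron."""
    tx = model.exons_transcription_order()
    k = allele.trap_insertion_intron
    if model.strand == "+":
        return (tx[k][0], model.end)
    return (model.start, tx[k][1])


def deleted_span(allele: TargetAllele, model: GeneModel) -> tuple[int, int]:
    """Genomic span removed by a DEL allele (deleted exons plus the introns
    between them)."""
    tx = model.exons_transcription_order()
    lo, hi = allele.deleted_exons
    coords = tx[lo - 1 : hi]
    return (min(s for s, _ in coords), max(e for _, e in coords))


def score_trap(allele: TargetAllele, model: GeneModel, ann: RegAnnotation) -> RegDisruptionCall:
    """Disrupted iff >=2 high-confidence TFBS lie 3' of the insertion intron
    within the gene body."""
    if allele.allele_class != TRAP:
        raise ValueError(f"{allele.gene_id}: score_trap requires a TRAP allele")
    allele.validate_against(model)
    lo, hi = _post_trap_region(allele, model)
    n = sum(
        1
        for t in ann.tfbs
        if t.confidence == "high"
        and t.chromosome == model.chromosome
        and _overlaps(t.start, t.end, lo, hi)
    )
    return RegDisruptionCall(
        target=model.gene_id, disrupted=n >= 2, n_tfbs_affected=n, n_chip_corroborating=0
    )


def score_del(allele: TargetAllele, model: GeneModel, ann: RegAnnotation) -> RegDisruptionCall:
    """Disrupted iff >=2 TFBS (any confidence) and >=1 corroborating ChIP
    peak fall within the deleted span."""
    if allele.allele_class != DEL:
        raise ValueError(f"{allele.gene_id}: score_del requires a DEL allele")
    allele.validate_against(model)
    lo, hi = deleted_span(allele, model)
    n_tfbs = sum(
        1
        for t in ann.tfbs
        if t.chromosome == model.chromosome and _overlaps(t.start, t.end, lo, hi)
    )
    n_chip = sum(
        1
        for p in ann.peaks
        if p.chromosome == model.chromosome and _overlaps(p.start, p.end, lo, hi)
    )
    return RegDisruptionCall(
        target=model.gene_id,
        disrupted=n_tfbs >= 2 and n_chip >= 1,
        n_tfbs_affected=n_tfbs,
        n_chip_corroborating=n_chip,
    )


def score(allele: TargetAllele, model: GeneModel, ann: RegAnnotation) -> RegDisruptionCall:
    if allele.allele_class == TRAP:
        return score_trap(allele, model, ann)
    return score_del(allele, model, ann)


def cohort_disruption_frequency(
    calls: Iterable[tuple[RegDisruptionCall, str]],
) -> dict:
    """Fraction disrupted per allele class, plus a chi-square comparison of
    DEL vs TRAP when both classes are present."""
    calls = list(calls)
    by_class: dict[str, list[RegDisruptionCall]] = {}
    for call, cls in calls:
        by_class.setdefault(cls, []).append(call)
    if not by_class:
        raise ValueError("no disruption calls")
    out: dict = {}
    for cls, cc in sorted(by_class.items()):
        out[f"pct_{cls.lower()}"] = 100.0 * sum(c.disrupted for c in cc) / len(cc)
        out[f"n_{cls.lower()}"] = len(cc)
    if DEL in by_class and TRAP in by_class:
        d = by_class[DEL]
        t = by_class[TRAP]
        table = [
            [sum(c.disrupted for c in d), sum(not c.disrupted for c in d)],
            [sum(c.disrupted for c in t), sum(not c.disrupted for c in t)],
        ]
        if all(sum(row) > 0 for row in table) and all(
            table[0][j] + table[1][j] > 0 for j in (0, 1)
        ):
            out["chisq"] = chisq_homogeneity(table)
        else:
            out["chisq"] = None
    return out
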