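"""Targeting-confirmation screen from exon-level read patterns.

Total read counts alone cannot confirm a knockout: gene-trap alleles may
splice around the cassette, deletion alleles may retain (and even up-regulate)
distal exons, and reads may map to introns. Mutants whose HOM counts are not
clearly depleted are flagged, and their per-exon HOM/WT profiles are run
through a decision cascade that distinguishes the structural patterns seen
in practice, most specific evidence first.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import DEL, TRAP, ExonProfile, GeneModel, QcClassification, TargetAllele

#: expression floor per profile (normalized reads) and presence ratio.
#: Both reuse the flag criteria: 100 reads minimum, HOM >= 20% of WT.
EXPRESSION_FLOOR = 100.0
PRESENCE_RATIO = 0.20


def flag_for_inspection(
    hom_total: float,
    wt_total: float,
    min_reads: float = EXPRESSION_FLOOR,
    ratio: float = PRESENCE_RATIO,
) -> bool:
    """True if a mutant's read totals warrant manual inspection: the gene is
    expressed (>= min_reads in either library) yet the HOM library retains at
    least ``ratio`` of the WT signal."""
    if hom_total < 0 or wt_total < 0:
        raise ValueError("read totals must be >= 0")
    return max(hom_total, wt_total) >= min_reads and hom_total >= ratio * wt_total


def classify_exon_pattern(
    hom: ExonProfile,
    wt: ExonProfile,
    allele: TargetAllele,
    model: GeneModel,
    floor: float = EXPRESSION_FLOOR,
    ratio: float = PRESENCE_RATIO,
) -> QcClassification:
    """Classify one HOM/WT exon-profile pair into a targeting verdict.

    Exon counts are ordered 5'->3' in transcription direction. The cascade:

    1. both profiles below the expression floor -> indeterminate
    2. DEL with HOM reads on the deleted exons -> failed_targeting
    3. DEL with predominantly intronic HOM reads -> intronic_only
    4. partial DEL, deleted exons silent but distal exons at/above WT
       -> distal_retention
    5. TRAP with no HOM signal past the trap intron -> trap_complete
    6. TRAP skipping exons after the trap then resuming -> splice_around
    7. all exons present at a uniformly reduced level -> uniform_hypomorph
    8. otherwise confirmed_null if HOM < ratio x WT overall, else
       failed_targeting
    """
    allele.validate_against(model)
    for prof in (hom, wt):
        if len(prof.exon_counts) != model.n_exons:
            raise ValueError(
                f"{prof.gene_id}/{prof.library_id}: {len(prof.exon_counts)} exon "
                f"counts for a {model.n_exons}-exon model"
            )
    h = np.asarray(hom.exon_counts, dtype=float)
    w = np.asarray(wt.exon_counts, dtype=float)
    th, tw = h.sum(), w.sum()
    evidence: dict = {"hom_total": float(th), "wt_total": float(tw),
                      "hom_intronic": float(hom.intronic_reads)}

    def result(verdict: str) -> QcClassification:
        return QcClassification(
            target=model.gene_id, library_id=hom.library_id,
            verdict=verdict, evidence=evidence,
        )

    # 1. expression floor
    if th + hom.intronic_reads < floor and tw + wt.intronic_reads < floor:
        return result("indeterminate")

    if allele.allele_class == DEL:
        lo, hi = allele.deleted_exons
        h_del = h[lo - 1 : hi].sum()
        w_del = w[lo - 1 : hi].sum()
        evidence["hom_deleted_exons"] = float(h_del)
        evidence["wt_deleted_exons"] = float(w_del)
        # 2. reads on exons targeted for deletion
        if h_del > 0 and h_del >= ratio * w_del:
            return result("failed_targeting")
        # 3. predominantly intronic reads
        if hom.intronic_reads > th:
            return result("intronic_only")
        # 4. partial deletion with retained distal exons at/above WT level
        if hi < model.n_exons:
            h_distal = h[hi:].sum()
            w_distal = w[hi:].sum()
            evidence["hom_distal_exons"] = float(h_distal)
            evidence["wt_distal_exons"] = float(w_distal)
            if h_del < ratio * max(w_del, 1.0) and h_distal >= max(w_distal, 1.0):
                return result("distal_retention")

    if allele.allele_class == TRAP:
        k = allele.trap_insertion_intron  # post-trap exons: ordinals k+1..n
        h_post = h[k:]
        w_post = w[k:]
        evidence["hom_post_trap"] = float(h_post.sum())
        evidence["wt_post_trap"] = float(w_post.sum())
        # per-exon presence: at least the presence ratio of WT and >= 1 read
        present = h_post >= np.maximum(1.0, ratio * w_post)
        # 5. trap complete: no post-trap exon shows HOM signal
        if not present.any():
            return result("trap_complete")
        # 6. splice-around: leading post-trap exons skipped, distal resumption
        if not present[0] and present[1:].any():
            evidence["skipped_exons"] = int(np.argmax(present))
            return result("splice_around")

    # 7. uniform hypomorph: every expressed exon reduced in step with the gene
    if tw > 0 and 0.0 < th / tw < 1.0:
        r_gene = th / tw
        expressed = w > 0
        with np.errstate(divide="ignore"):
            r_exon = np.where(expressed, h / np.where(expressed, w, 1.0), np.nan)
        rr = r_exon[expressed]
        evidence["gene_ratio"] = float(r_gene)
        if rr.size and np.all((rr >= r_gene / 2.0) & (rr <= r_gene * 2.0)):
            return result("uniform_hypomorph")

    # 8. overall depletion
    if th < ratio * tw:
        return result("confirmed_null")
    return result("failed_targeting")


#: verdicts that confirm targeting
CONFIRMED_VERDICTS = frozenset(
    {"confirmed_null", "trap_complete", "splice_around", "uniform_hypomorph",
     "distal_retention", "intronic_only"}
)


def aggregate_verdicts(verdicts: Sequence[str]) -> str:
    """Mutant-level verdict across libraries: failed targeting anywhere fails
    the mutant; otherwise the most common confirming verdict; indeterminate
    only if every library is."""
    if not verdicts:
        raise ValueError("no verdicts to aggregate")
    if "failed_targeting" in verdicts:
        return "failed_targeting"
    confirming = [v for v in verdicts if v in CONFIRMED_VERDICTS]
    if not confirming:
        return "indeterminate"
    counts = Counter(confirming)
    top = max(counts.values())
    # deterministic tie-break: first verdict (library order) at the top count
    for v in confirming:
        if counts[v] == top:
            return v


def cohort_qc(mutants: Iterable[dict]) -> pd.DataFrame:
    """Summarize flags and verdicts per allele class.

    Each mutant record: ``{"target", "allele_class", "library_flags":
    [bool, ...], "verdicts": [verdict, ...]}``. A mutant is flagged if any
    library flags it; confirmed if its aggregate verdict confirms targeting.
    """
    mutants = list(mutants)
    if not mutants:
        raise ValueError("no mutants")
    rows = []
    for cls in sorted({m["allele_class"] for m in mutants}):
        sub = [m for m in mutants if m["allele_class"] == cls]
        n = len(sub)
        flagged = sum(any(m["library_flags"]) for m in sub)
        agg = [aggregate_verdicts(m["verdicts"]) for m in sub]
        confirmed = sum(v in CONFIRMED_VERDICTS for v in agg)
        row = {
            "allele_class": cls,
            "n": n,
            "pct_flagged": 100.0 * flagged / n,
            "pct_confirmed": 100.0 * confirmed / n,
        }
        for v in sorted(set(agg)):
            row[f"pct_{v}"] = 100.0 * agg.count(v) / n
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)
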