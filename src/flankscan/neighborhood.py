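"""Strand-aware flanking-gene neighborhoods and their dysregulation summaries.

A neighbor's position is its signed centrum-to-centrum distance from the
target, with the sign flipped for minus-strand targets so that negative
always means 5' of the target's transcription direction and positive 3'.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import gene_centrum
from .models import GeneModel, NeighborGene, NeighborhoodSummary

WINDOW = 500_000  # bp, boundary-inclusive
BIN_WIDTH_KB = 50


def strand_adjusted_distance(target: GeneModel, neighbor: GeneModel) -> int:
    """Signed bp distance between centrums, negative = 5' of the target."""
    if target.chromosome != neighbor.chromosome:
        raise ValueError(
            f"{neighbor.gene_id} on {neighbor.chromosome}, target on {target.chromosome}"
        )
    d = gene_centrum(neighbor) - gene_centrum(target)
    return -d if target.strand == "-" else d


def extract_neighborhood(
    target: GeneModel, genes: Sequence[GeneModel], window: int = WINDOW
) -> list[NeighborGene]:
    """All genes (miRNAs included) within +/-window of the target's centrum,
    target itself excluded. Window boundary is inclusive."""
    if not any(g.gene_id == target.gene_id for g in genes):
        raise ValueError(f"target {target.gene_id} absent from annotation")
    out = []
    for g in genes:
        if g.gene_id == target.gene_id or g.chromosome != target.chromosome:
            continue
        d = strand_adjusted_distance(target, g)
        if abs(d) <= window:
            out.append(NeighborGene(gene_id=g.gene_id, centrum_distance=d))
    out.sort(key=lambda n: n.centrum_distance)
    return out


def summarize_target(
    target: GeneModel,
    allele_class: str,
    neighbors: Sequence[NeighborGene],
    calls: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    pair_labels: Optional[dict[str, str]] = None,
) -> NeighborhoodSummary:
    """Roll up per-library dysregulation flags for one target.

    ``calls`` is the call table from :func:`flankscan.de_test.call_differential`
    (or the S1 bypass); ``pairs`` lists the (HOM, WT) libraries belonging to
    this target's mutant line. The targeted gene itself is never counted.
    """
    if pair_labels is None:
        pair_labels = {hom: hom for hom, _ in pairs}
    dist = {n.gene_id: n.centrum_distance for n in neighbors}
    sub = calls[calls["gene_id"].isin(dist) & calls["hom_library"].isin(pair_labels)]
    by_lib = {
        (r.gene_id, r.hom_library): r.direction
        for r in sub.itertuples()
    }
    library_flags: dict[str, dict] = {}
    dysregulated: list[dict] = []
    for hom, _wt in pairs:
        label = pair_labels[hom]
        flags = {"has_up": False, "has_down": False}
        for n in neighbors:
            direction = by_lib.get((n.gene_id, hom), "ns")
            if direction == "up":
                flags["has_up"] = True
            elif direction == "down":
                flags["has_down"] = True
            if direction in ("up", "down"):
                dysregulated.append(
                    {
                        "gene_id": n.gene_id,
                        "tissue": label,
                        "direction": direction,
                        "centrum_distance": n.centrum_distance,
                    }
                )
        library_flags[label] = flags
    return NeighborhoodSummary(
        target=target.gene_id,
        allele_class=allele_class,
        n_genes_in_window=len(neighbors),
        library_flags=library_flags,
        dysregulated=dysregulated,
    )


def cohort_frequencies(
    summaries: Iterable[NeighborhoodSummary],
    by: str = "target",
    allele_class: Optional[str] = None,
) -> dict:
    """Percent of targets (or libraries) with >=1 up- / down-regulated neighbor."""
    subset = [s for s in summaries if allele_class is None or s.allele_class == allele_class]
    if not subset:
        raise ValueError(f"no summaries in class {allele_class!r}")
    if by == "target":
        n = len(subset)
        n_up = sum(s.has_up for s in subset)
        n_down = sum(s.has_down for s in subset)
    elif by == "library":
        flags = [f for s in subset for f in s.library_flags.values()]
        n = len(flags)
        n_up = sum(f["has_up"] for f in flags)
        n_down = sum(f["has_down"] for f in flags)
    else:
        raise ValueError(f"by must be 'target' or 'library', got {by!r}")
    return {"pct_up": 100.0 * n_up / n, "pct_down": 100.0 * n_down / n, "n": n}


def _dedupe_dysregulated(
    summaries: Iterable[NeighborhoodSummary], dedupe: str
) -> list[tuple[str, str, str, int]]:
    """(target, gene, direction, distance) records, unique pairs or per-library
    instances depending on ``dedupe``."""
    records = []
    for s in summaries:
        for d in s.dysregulated:
            records.append((s.target, d["gene_id"], d["direction"], d["centrum_distance"]))
    if dedupe == "instance":
        return records
    if dedupe != "pair":
        raise ValueError(f"dedupe must be 'pair' or 'instance', got {dedupe!r}")
    return sorted(set(records))


def topography(
    summaries: Iterable[NeighborhoodSummary],
    bin_width_kb: int = BIN_WIDTH_KB,
    window: int = WINDOW,
    dedupe: str = "pair",
) -> tuple[pd.DataFrame, dict]:
    """Histogram of dysregulated neighbors in signed distance bins, plus the
    median-distance summaries (|d| for down; d for 3'-up; |d| for 5'-up).

    Bins are half-open [k*w, (k+1)*w) kb tiling [-window, +window); a neighbor
    sitting exactly on the +window boundary joins the last bin.
    """
    records = _dedupe_dysregulated(summaries, dedupe)
    window_kb = window // 1000
    n_bins_side = window_kb // bin_width_kb
    lows = np.arange(-n_bins_side, n_bins_side) * bin_width_kb
    counts = {lo: {"up": 0, "down": 0} for lo in lows}
    for _t, _g, direction, d in records:
        b = math.floor(d / (bin_width_kb * 1000)) * bin_width_kb
        b = min(max(b, -window_kb), window_kb - bin_width_kb)
        counts[b][direction] += 1

    bins = pd.DataFrame(
        {
            "lo_kb": lows,
            "hi_kb": lows + bin_width_kb,
            "count_up": [counts[lo]["up"] for lo in lows],
            "count_down": [counts[lo]["down"] for lo in lows],
        }
    )

    def med(vals):
        return float(np.median(vals)) / 1000.0 if vals else None

    down_abs = [abs(d) for _t, _g, dir_, d in records if dir_ == "down"]
    up3 = [d for _t, _g, dir_, d in records if dir_ == "up" and d > 0]
    up5 = [abs(d) for _t, _g, dir_, d in records if dir_ == "up" and d < 0]
    n_up = sum(1 for r in records if r[2] == "up")
    medians = {
        "median_abs_down_kb": med(down_abs),
        "median_3p_up_kb": med(up3),
        "median_abs_5p_up_kb": med(up5),
        "n_dysregulated": len(records),
        "frac_up_3prime": len(up3) / n_up if n_up else None,
    }
    return bins, medians


def gene_density_contrast(summaries: Iterable[NeighborhoodSummary]) -> dict:
    """Mean neighbors-in-window for targets with vs without any local effect."""
    summaries = list(summaries)
    with_eff = [s.n_genes_in_window for s in summaries if s.has_up or s.has_down]
    without = [s.n_genes_in_window for s in summaries if not (s.has_up or s.has_down)]
    return {
        "mean_with_effects": float(np.mean(with_eff)) if with_eff else None,
        "mean_without_effects": float(np.mean(without)) if without else None,
        "n_with_effects": len(with_eff),
        "n_without_effects": len(without),
    }
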