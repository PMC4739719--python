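"""Genome-wide empirical null for flanking dysregulation, and the chi-square
comparisons used against it.

The null asks: across every library pair, for every gene significantly
down-regulated in the HOM library (the focal set), what fraction of genes
within +/-500 kb of the focal gene are themselves up- or down-regulated in
that same pair? This is the background rate against which the flanking
frequencies around targeted genes are compared.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import gene_centrum
from .models import ChiSquareResult, GeneModel, NullFrequency
from .neighborhood import WINDOW


def genome_wide_null(
    calls: pd.DataFrame,
    genes: Sequence[GeneModel],
    window: int = WINDOW,
    alpha: float = 0.05,
) -> NullFrequency:
    """Background frequency of dysregulated genes near down-regulated genes.

    ``calls`` must cover the full annotation for every library pair. Each
    (down-regulated gene, pair) is a focal instance; each annotated gene
    within +/-window of it (itself excluded) is one neighbor instance.
    """
    gene_ids = [g.gene_id for g in genes]
    id_index = {gid: i for i, gid in enumerate(gene_ids)}
    chrom = np.array([g.chromosome for g in genes])
    centrum = np.array([gene_centrum(g) for g in genes])

    order_by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chrom):
        on = np.where(chrom == c)[0]
        order_by_chrom[c] = on[np.argsort(centrum[on])]

    def neighbors_of(i: int) -> np.ndarray:
        on = order_by_chrom[chrom[i]]
        cen = centrum[on]
        lo = np.searchsorted(cen, centrum[i] - window, side="left")
        hi = np.searchsorted(cen, centrum[i] + window, side="right")
        sel = on[lo:hi]
        return sel[sel != i]

    n_focal = 0
    n_instances = 0
    n_up = 0
    n_down = 0
    sum_w2 = 0.0
    for hom, sub in calls.groupby("hom_library", sort=True):
        dir_arr = np.full(len(gene_ids), "ns", dtype=object)
        rows = sub[sub["gene_id"].isin(id_index)]
        dir_arr[[id_index[g] for g in rows["gene_id"]]] = rows["direction"].to_numpy()
        focal = np.where(dir_arr == "down")[0]
        n_focal += len(focal)
        weights = np.zeros(len(gene_ids))  # times each call is sampled
        for i in focal:
            nb = neighbors_of(int(i))
            n_instances += len(nb)
            weights[nb] += 1
            dirs = dir_arr[nb]
            n_up += int((dirs == "up").sum())
            n_down += int((dirs == "down").sum())
        sum_w2 += float((weights**2).sum())
    if n_focal == 0:
        raise ValueError("empty focal set: no down-regulated gene in any library")
    return NullFrequency(
        f_up=n_up / n_instances if n_instances else 0.0,
        f_down=n_down / n_instances if n_instances else 0.0,
        n_focal=n_focal,
        n_neighbor_instances=n_instances,
        n_effective=n_instances**2 / sum_w2 if sum_w2 else 0.0,
    )


def chisq_gof(observed: tuple[float, float], expected_fraction: float) -> ChiSquareResult:
    """Pearson goodness-of-fit of a 2-category count vector against an
    expected split (df=1, no continuity correction)."""
    o1, o2 = observed
    total = o1 + o2
    if total <= 0:
        raise ValueError("total observed count must be > 0")
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError("expected fraction must be in (0,1)")
    expected = (total * expected_fraction, total * (1.0 - expected_fraction))
    if min(expected) == 0:
        raise ValueError("expected cell is zero")
    statistic = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(
        statistic=float(statistic), df=1, p=p,
        observed=tuple(observed), expected=expected,
    )


def chisq_homogeneity(table) -> ChiSquareResult:
    """Pearson 2x2 test of homogeneity (df=1, no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    statistic, p, df, expected = stats.chi2_contingency(t, correction=False)
    return ChiSquareResult(
        statistic=float(statistic), df=int(df), p=float(p),
        observed=tuple(map(tuple, t)), expected=tuple(map(tuple, expected)),
    )
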