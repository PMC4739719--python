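"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design: paired HOM/WT libraries (pooled
replicates, one library per group) over several tissues for a cohort of DEL
and TRAP mutant lines; negative-binomial counts with a mean-dispersion trend;
an 8-fold knockdown of each targeted gene; and planted local dysregulation
whose up-regulated neighbors are 3'-biased (77.4% 3') and whose down-regulated
neighbors are side-symmetric, both with distance-decaying planting
probability. Exon-level profiles realize each targeting-QC verdict. Every
draw is fixed by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_io import gene_centrum, library_id
from .models import (
    DEL,
    TRAP,
    ChipPeak,
    ExonProfile,
    GeneModel,
    LibraryMeta,
    RegAnnotation,
    TargetAllele,
    TfbsSite,
)
from .neighborhood import WINDOW, strand_adjusted_distance


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Cohort shape mirrors the study (29 DEL and 15 TRAP lines, ~4 tissues
    each); planted-effect topography mirrors the reported spatial structure.
    """

    seed: int = 0
    n_chromosomes: int = 5
    chromosome_length: int = 10_000_000  # bp
    genes_per_mb: float = 20.0
    gene_length_log_mean: float = math.log(15_000.0)  # median mouse-scale gene
    gene_length_log_sd: float = 0.8
    n_targets_del: int = 29
    n_targets_trap: int = 15
    n_tissues: int = 4
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05  # Var = mu + alpha mu^2
    knockdown_factor: float = 0.125  # 8-fold knockdown of the target
    p_local_up: float = 0.20  # planting probability at distance 0
    p_local_down: float = 0.25
    bias_3prime: float = 0.774  # P(3' | planted up-regulation)
    distance_decay: float = 100_000.0  # bp scale of exp(-|d|/decay)
    effect_size_log2: float = 2.0  # planted |log2| neighbor effect
    qc_wt_total: float = 1000.0  # WT reads/gene for exon profiles
    min_neighbors: int = 5

    def __post_init__(self) -> None:
        for name in ("p_local_up", "p_local_down", "bias_3prime"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("chromosome_length", "genes_per_mb", "dispersion",
                     "distance_decay", "qc_wt_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _make_exons(rng: np.random.Generator, start: int, end: int, n_exons: int):
    """Exon structure spanning [start, end]: one exon per equal segment, the
    first anchored at the gene start and the last at the gene end."""
    length = end - start + 1
    bounds = np.linspace(0, length, n_exons + 1).astype(int)
    exons = []
    for i in range(n_exons):
        seg_lo, seg_hi = bounds[i], bounds[i + 1] - 1
        seg_len = seg_hi - seg_lo + 1
        ex_len = max(1, int(seg_len * rng.uniform(0.1, 0.5)))
        if i == 0:
            lo = seg_lo
        elif i == n_exons - 1:
            lo = seg_hi - ex_len + 1
        else:
            lo = seg_lo + int(rng.integers(0, max(1, seg_len - ex_len)))
        exons.append((start + lo, start + lo + ex_len - 1))
    return tuple(exons)


def generate_annotation(
    cfg: SyntheticConfig,
) -> tuple[list[GeneModel], list[TargetAllele]]:
    """Non-overlapping gene models on ``n_chromosomes`` chromosomes, plus
    sampled DEL/TRAP target alleles each guaranteed >= ``min_neighbors``
    genes within the +/-500 kb window."""
    rng = np.random.default_rng(cfg.seed)
    mean_len = math.exp(cfg.gene_length_log_mean + cfg.gene_length_log_sd**2 / 2)
    mean_spacing = 1e6 / cfg.genes_per_mb
    mean_gap = max(200.0, mean_spacing - mean_len)

    genes: list[GeneModel] = []
    gid = 0
    for c in range(1, cfg.n_chromosomes + 1):
        cursor = 1 + int(rng.exponential(mean_gap / 2))
        while True:
            length = int(np.clip(
                rng.lognormal(cfg.gene_length_log_mean, cfg.gene_length_log_sd),
                1_000, 400_000,
            ))
            if cursor + length - 1 > cfg.chromosome_length:
                break
            gid += 1
            n_exons = int(rng.integers(3, 11))
            biotype = "miRNA" if rng.random() < 0.05 else "protein_coding"
            if biotype == "miRNA":
                length = min(length, 2_000)
                n_exons = min(n_exons, 3)
            start, end = cursor, cursor + length - 1
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    chromosome=f"chr{c}",
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=_make_exons(rng, start, end, n_exons),
                    biotype=biotype,
                )
            )
            cursor = end + 1 + int(rng.exponential(mean_gap)) + 200

    # target sampling: enough neighbors, enough exons, spaced windows
    centrums = np.array([gene_centrum(g) for g in genes])
    chroms = np.array([g.chromosome for g in genes])
    n_neighbors = np.array([
        int(((chroms == g.chromosome)
             & (np.abs(centrums - gene_centrum(g)) <= WINDOW)).sum()) - 1
        for g in genes
    ])
    candidates = [
        i for i, g in enumerate(genes)
        if n_neighbors[i] >= cfg.min_neighbors and g.n_exons >= 4
        and g.biotype == "protein_coding"
    ]
    rng.shuffle(candidates)
    chosen: list[int] = []
    for i in candidates:
        if all(
            chroms[i] != chroms[j] or abs(centrums[i] - centrums[j]) > 2 * WINDOW + 200_000
            for j in chosen
        ):
            chosen.append(i)
        if len(chosen) == cfg.n_targets_del + cfg.n_targets_trap:
            break
    if len(chosen) < cfg.n_targets_del + cfg.n_targets_trap:
        raise ValueError(
            f"gene density too low: only {len(chosen)} candidate targets with "
            f">= {cfg.min_neighbors} neighbors"
        )

    alleles: list[TargetAllele] = []
    for rank, i in enumerate(chosen):
        g = genes[i]
        if rank < cfg.n_targets_del:
            if rng.random() < 0.8:
                deleted = (1, g.n_exons)  # full ORF deletion
            else:
                deleted = (1, int(rng.integers(2, g.n_exons)))  # large gene: 5' only
            alleles.append(
                TargetAllele(gene_id=g.gene_id, allele_class=DEL,
                             deleted_exons=deleted, neo_promoter="hUBC")
            )
        else:
            intron = int(rng.integers(1, min(4, g.n_exons)))
            alleles.append(
                TargetAllele(gene_id=g.gene_id, allele_class=TRAP,
                             trap_insertion_intron=intron, neo_promoter="hACTB")
            )
    return genes, alleles


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-8)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_counts(
    cfg: SyntheticConfig,
    genes: Sequence[GeneModel],
    alleles: Sequence[TargetAllele],
) -> tuple[pd.DataFrame, list[LibraryMeta], list[tuple[str, str]], pd.DataFrame]:
    """Paired HOM/WT NB count libraries for every line and tissue.

    Returns (counts, library metadata, HOM/WT pairs, truth record). The truth
    record lists every planted neighbor effect as
    (line, gene_id, direction, centrum_distance, log2_effect); planted
    effects are shared across that line's tissues, as local cis effects are.
    """
    rng = np.random.default_rng((cfg.seed + 1) * 100_003)
    by_id = {g.gene_id: g for g in genes}
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)

    mu = np.clip(
        rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_genes),
        0.05, 1e5,
    )
    tissue_mult = rng.lognormal(0.0, 0.3, size=(n_genes, cfg.n_tissues))
    tissues = [f"tissue{t + 1}" for t in range(cfg.n_tissues)]

    truth_rows = []
    effect_by_line: dict[str, np.ndarray] = {}
    idx = {gid: i for i, gid in enumerate(gene_ids)}
    for allele in alleles:
        target = by_id[allele.gene_id]
        eff = np.ones(n_genes)
        eff[idx[target.gene_id]] = cfg.knockdown_factor
        for j, g in enumerate(genes):
            if g.gene_id == target.gene_id or g.chromosome != target.chromosome:
                continue
            d = strand_adjusted_distance(target, g)
            if abs(d) > WINDOW:
                continue
            decay = math.exp(-abs(d) / cfg.distance_decay)
            side = cfg.bias_3prime if d > 0 else (1.0 - cfg.bias_3prime)
            p_up = min(0.95, cfg.p_local_up * decay * 2.0 * side)
            p_down = cfg.p_local_down * decay
            u = rng.random()
            if u < p_up:
                eff[j] = 2.0**cfg.effect_size_log2
                direction = "up"
            elif u < p_up + p_down:
                eff[j] = 2.0**-cfg.effect_size_log2
                direction = "down"
            else:
                continue
            truth_rows.append(
                {
                    "line": target.gene_id,
                    "gene_id": g.gene_id,
                    "direction": direction,
                    "centrum_distance": d,
                    "log2_effect": math.copysign(cfg.effect_size_log2, eff[j] - 1.0),
                }
            )
        effect_by_line[target.gene_id] = eff

    columns: dict[str, np.ndarray] = {}
    meta: list[LibraryMeta] = []
    pairs: list[tuple[str, str]] = []
    for allele in alleles:
        line = allele.gene_id
        eff = effect_by_line[line]
        for t, tissue in enumerate(tissues):
            base = mu * tissue_mult[:, t]
            wt_id = library_id(line, tissue, "WT")
            hom_id = library_id(line, tissue, "HOM")
            columns[wt_id] = _nb_draw(rng, base, cfg.dispersion)
            columns[hom_id] = _nb_draw(rng, base * eff, cfg.dispersion)
            meta.append(LibraryMeta(wt_id, line, tissue, "WT"))
            meta.append(LibraryMeta(hom_id, line, tissue, "HOM"))
            pairs.append((hom_id, wt_id))

    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(
        truth_rows,
        columns=["line", "gene_id", "direction", "centrum_distance", "log2_effect"],
    )
    return counts, meta, pairs, truth


# ---------------------------------------------------------------------------
# exon profiles for the QC classifier

QC_SCENARIOS = (
    "confirmed_null", "trap_complete", "splice_around", "uniform_hypomorph",
    "distal_retention", "intronic_only", "failed_targeting", "indeterminate",
)


def scenario_compatible(scenario: str, allele: TargetAllele, model: GeneModel) -> bool:
    """Whether (allele, model) can realize the named verdict scenario."""
    if scenario not in QC_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario in ("trap_complete", "splice_around", "uniform_hypomorph"):
        if allele.allele_class != TRAP:
            return False
        post = model.n_exons - allele.trap_insertion_intron
        if scenario == "splice_around" and post < 2:
            return False
        return True
    if scenario in ("distal_retention",):
        return allele.allele_class == DEL and allele.deleted_exons[1] < model.n_exons
    if scenario in ("intronic_only", "failed_targeting", "confirmed_null"):
        # a fully silent TRAP HOM reads as trap_complete, so the plain
        # confirmed_null pattern is realizable only on DEL alleles
        return allele.allele_class == DEL
    return True  # indeterminate: any allele


def generate_exon_profiles(
    cfg: SyntheticConfig,
    model: GeneModel,
    allele: TargetAllele,
    scenario: str,
    noise: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExonProfile, ExonProfile]:
    """HOM/WT exon-count profile pair realizing the named QC scenario,
    with optional Poisson noise around the scenario means."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not scenario_compatible(scenario, allele, model):
        raise ValueError(
            f"scenario {scenario!r} incompatible with {allele.allele_class} allele "
            f"on {model.gene_id}"
        )
    n = model.n_exons
    wt_means = np.full(n, cfg.qc_wt_total / n)
    hom_means = np.zeros(n)
    hom_intronic = 0.0
    wt_intronic = 0.0

    if scenario == "indeterminate":
        wt_means = np.zeros(n)
    elif scenario == "confirmed_null":
        pass  # HOM silent
    elif scenario == "failed_targeting":
        hom_means = wt_means.copy()
    elif scenario == "intronic_only":
        hom_intronic = cfg.qc_wt_total
    elif scenario == "distal_retention":
        hi = allele.deleted_exons[1]
        hom_means[hi:] = 2.0 * wt_means[hi:]
    elif scenario == "trap_complete":
        k = allele.trap_insertion_intron
        hom_means[:k] = 0.6 * wt_means[:k]
    elif scenario == "splice_around":
        k = allele.trap_insertion_intron
        post = n - k
        skipped = min(max(1, post // 2), post - 1)
        hom_means[:k] = 0.6 * wt_means[:k]
        hom_means[k + skipped:] = 0.4 * wt_means[k + skipped:]
    elif scenario == "uniform_hypomorph":
        hom_means = 0.3 * wt_means

    def realize(means: np.ndarray, intronic: float):
        if noise:
            return rng.poisson(means).astype(float), float(rng.poisson(intronic))
        return means.copy(), intronic

    h_counts, h_intr = realize(hom_means, hom_intronic)
    w_counts, w_intr = realize(wt_means, wt_intronic)
    hom = ExonProfile(model.gene_id, f"{model.gene_id}:HOM", tuple(h_counts), h_intr)
    wt = ExonProfile(model.gene_id, f"{model.gene_id}:WT", tuple(w_counts), w_intr)
    return hom, wt


# ---------------------------------------------------------------------------
# regulatory-element fixtures

def generate_reg_annotation(
    cfg: SyntheticConfig,
    genes: Sequence[GeneModel],
    alleles: Sequence[TargetAllele],
    p_disrupt_del: float = 0.586,
    p_disrupt_trap: float = 0.067,
    rng: Optional[np.random.Generator] = None,
) -> tuple[RegAnnotation, dict[str, bool]]:
    """TFBS and ChIP-peak intervals planted so each target is disrupted with
    the class-specific probability. Returns the annotation and the planted
    truth (target -> disrupted)."""
    from .reg_disruption import _post_trap_region, deleted_span

    if rng is None:
        rng = np.random.default_rng((cfg.seed + 7) * 99_991)
    by_id = {g.gene_id: g for g in genes}
    tfbs: list[TfbsSite] = []
    peaks: list[ChipPeak] = []
    truth: dict[str, bool] = {}

    def put_sites(chrom, lo, hi, n, confidence):
        for _ in range(n):
            w = min(12, max(4, hi - lo))
            s = int(rng.integers(lo, max(lo + 1, hi - w)))
            tfbs.append(TfbsSite(chrom, s, s + w - 1, confidence))

    for allele in alleles:
        g = by_id[allele.gene_id]
        if allele.allele_class == TRAP:
            disrupted = bool(rng.random() < p_disrupt_trap)
            lo, hi = _post_trap_region(allele, g)
            if disrupted:
                put_sites(g.chromosome, lo, hi, int(rng.integers(2, 5)), "high")
            else:
                # at most one high-confidence distal site, maybe low-confidence ones
                put_sites(g.chromosome, lo, hi, int(rng.integers(0, 2)), "high")
                put_sites(g.chromosome, lo, hi, int(rng.integers(0, 3)), "low")
        else:
            disrupted = bool(rng.random() < p_disrupt_del)
            lo, hi = deleted_span(allele, g)
            if disrupted:
                put_sites(g.chromosome, lo, hi, int(rng.integers(2, 5)), "high")
                for _ in range(int(rng.integers(1, 3))):
                    w = min(400, max(50, hi - lo))
                    s = int(rng.integers(lo, max(lo + 1, hi - w)))
                    factor = ["Pol2", "CTCF", "p300"][int(rng.integers(0, 3))]
                    peaks.append(ChipPeak(g.chromosome, s, s + w - 1, factor, "liver"))
            else:
                # miss one of the two requirements
                if rng.random() < 0.5:
                    put_sites(g.chromosome, lo, hi, int(rng.integers(0, 2)), "high")
                else:
                    put_sites(g.chromosome, lo, hi, int(rng.integers(2, 4)), "high")
                    # no corroborating peak
        truth[allele.gene_id] = disrupted
    return RegAnnotation(tfbs=tuple(tfbs), peaks=tuple(peaks)), truth
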