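"""Domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout (GTF convention). BED inputs
are converted on read. Exon lists are stored in ascending genomic order;
exon *ordinals* (trap introns, deleted-exon ranges, exon profiles) count in
transcription direction, so ordinal 1 is the rightmost exon of a minus-strand
gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True)
class GeneModel:
    """A gene's span, strand and exon structure on one chromosome."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has zero exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) inverted")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_transcription_order(self) -> tuple[tuple[int, int], ...]:
        """Exons ordered 5'->3' in transcription direction."""
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass(frozen=True)
class LibraryMeta:
    """One sequenced cDNA library: a (line, tissue, genotype) cell."""

    library_id: str
    line: str
    tissue: str
    genotype: str  # HOM | WT

    def __post_init__(self) -> None:
        if self.genotype not in ("HOM", "WT"):
            raise ValueError(f"genotype must be HOM or WT, got {self.genotype!r}")


#: allele classes
TRAP = "TRAP"
DEL = "DEL"


@dataclass(frozen=True)
class TargetAllele:
    """Description of the targeting event for one mutant line.

    TRAP: a gene-trap cassette inserted in intron ``trap_insertion_intron``
    (intron i lies between transcription-order exons i and i+1).
    DEL: ``deleted_exons`` is the inclusive range of transcription-order exon
    ordinals removed by the deletion.
    """

    gene_id: str
    allele_class: str
    trap_insertion_intron: Optional[int] = None
    deleted_exons: Optional[tuple[int, int]] = None
    neo_promoter: str = "hACTB"

    def __post_init__(self) -> None:
        if self.allele_class not in (TRAP, DEL):
            raise ValueError(f"allele_class must be TRAP or DEL, got {self.allele_class!r}")
        if self.allele_class == TRAP:
            if self.trap_insertion_intron is None or self.deleted_exons is not None:
                raise ValueError(f"{self.gene_id}: TRAP allele needs trap_insertion_intron only")
            if self.trap_insertion_intron < 1:
                raise ValueError(f"{self.gene_id}: intron ordinal must be >= 1")
        else:
            if self.deleted_exons is None or self.trap_insertion_intron is not None:
                raise ValueError(f"{self.gene_id}: DEL allele needs deleted_exons only")
            lo, hi = self.deleted_exons
            if not 1 <= lo <= hi:
                raise ValueError(f"{self.gene_id}: bad deleted exon range ({lo},{hi})")

    def validate_against(self, model: GeneModel) -> None:
        if model.gene_id != self.gene_id:
            raise ValueError(f"allele {self.gene_id} does not match model {model.gene_id}")
        if self.allele_class == TRAP:
            if self.trap_insertion_intron > model.n_exons - 1:
                raise ValueError(
                    f"{self.gene_id}: intron {self.trap_insertion_intron} beyond "
                    f"{model.n_exons - 1} introns"
                )
        else:
            if self.deleted_exons[1] > model.n_exons:
                raise ValueError(
                    f"{self.gene_id}: deleted exon {self.deleted_exons[1]} beyond "
                    f"{model.n_exons} exons"
                )


@dataclass(frozen=True)
class S1Row:
    """One row of the supplementary-table dialect: a neighbor (or target) gene
    in one library pair, with stored normalized counts and the stored p-value."""

    line: str
    synonym: str
    tissue: str
    chromosome: str
    gene: str
    start: int
    end: int
    centrum_distance: int
    strand: str
    hom: float
    wt: float
    p_value: Optional[float]
    hom_wt_ratio: Optional[float]
    log2: Optional[float]

    def __post_init__(self) -> None:
        if abs(self.centrum_distance) > 500_000:
            raise ValueError(
                f"{self.line}/{self.gene}: centrum distance {self.centrum_distance} "
                "outside +/-500 kb"
            )
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.line}/{self.gene}: p-value {self.p_value} outside [0,1]")


@dataclass(frozen=True)
class DispersionModel:
    """Mean-dispersion trend alpha(mu) = a0 + a1/mu, floored at alpha_min.

    NB parameterization: Var(K) = mu + alpha * mu^2.
    """

    a0: float
    a1: float
    alpha_min: float = 0.01

    def alpha(self, mu):
        import numpy as np

        mu = np.asarray(mu, dtype=float)
        with np.errstate(divide="ignore"):
            a = self.a0 + self.a1 / np.maximum(mu, 1e-300)
        return np.maximum(a, self.alpha_min)


@dataclass(frozen=True)
class NeighborGene:
    """A flanking gene with its signed, strand-adjusted centrum distance.

    Negative distances are 5' of the target's transcription direction,
    positive 3'.
    """

    gene_id: str
    centrum_distance: int


@dataclass
class NeighborhoodSummary:
    """Per-target roll-up of dysregulated flanking genes across libraries."""

    target: str
    allele_class: str
    n_genes_in_window: int
    library_flags: dict  # tissue -> {"has_up": bool, "has_down": bool}
    dysregulated: list = field(default_factory=list)
    # entries: dict(gene_id, tissue, direction, centrum_distance)

    @property
    def has_up(self) -> bool:
        return any(f["has_up"] for f in self.library_flags.values())

    @property
    def has_down(self) -> bool:
        return any(f["has_down"] for f in self.library_flags.values())


@dataclass(frozen=True)
class NullFrequency:
    """Genome-wide background rate of dysregulated genes near down-regulated genes.

    ``n_effective`` is the effective sample size of the frequency estimates:
    a (gene, library) call appears once per down-regulated focal gene whose
    window covers it, so instances are clustered and the Monte-Carlo variance
    is p(1-p)/n_effective with n_effective = (sum w)^2 / sum w^2 over the
    per-call multiplicities w, not p(1-p)/n_neighbor_instances.
    """

    f_up: float
    f_down: float
    n_focal: int
    n_neighbor_instances: int
    n_effective: float = 0.0


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    observed: tuple
    expected: tuple


@dataclass(frozen=True)
class ExonProfile:
    """Normalized read counts per exon (5'->3' transcription order) plus
    reads falling in introns."""

    gene_id: str
    library_id: str
    exon_counts: tuple[float, ...]
    intronic_reads: float = 0.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.exon_counts) or self.intronic_reads < 0:
            raise ValueError(f"{self.gene_id}/{self.library_id}: negative read counts")

    @property
    def total(self) -> float:
        return float(sum(self.exon_counts))


#: QC verdicts, most specific structural evidence first (cascade order)
VERDICTS = (
    "confirmed_null",
    "trap_complete",
    "splice_around",
    "uniform_hypomorph",
    "distal_retention",
    "intronic_only",
    "failed_targeting",
    "indeterminate",
)


@dataclass(frozen=True)
class QcClassification:
    target: str
    library_id: str
    verdict: str
    evidence: dict

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


@dataclass(frozen=True)
class TfbsSite:
    chromosome: str
    start: int
    end: int
    confidence: str  # high | low


@dataclass(frozen=True)
class ChipPeak:
    chromosome: str
    start: int
    end: int
    factor: str  # Pol2 | CTCF | p300
    tissue: str = ""


@dataclass(frozen=True)
class RegAnnotation:
    """User-supplied regulatory-element intervals (1-based inclusive)."""

    tfbs: tuple[TfbsSite, ...] = ()
    peaks: tuple[ChipPeak, ...] = ()


@dataclass(frozen=True)
class RegDisruptionCall:
    target: str
    disrupted: bool
    n_tfbs_affected: int
    n_chip_corroborating: int

    def __post_init__(self) -> None:
        if self.disrupted and self.n_tfbs_affected < 2:
            raise ValueError("disrupted call requires >= 2 affected TFBS")
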