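"""Readers and writers for gene models, count tables, allele descriptions,
regulatory intervals (BED) and the supplementary-table dialect.

Every format written here round-trips through its reader. Genomic
coordinates are 1-based inclusive; BED input (0-based half-open) is
converted on read.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd

from .models import (
    DEL,
    TRAP,
    ChipPeak,
    ExonProfile,
    GeneModel,
    LibraryMeta,
    RegAnnotation,
    S1Row,
    TargetAllele,
    TfbsSite,
)

# ---------------------------------------------------------------------------
# gene models


def gene_centrum(g: GeneModel) -> int:
    """Midpoint of the gene span, floor of the arithmetic mean."""
    return (g.start + g.end) // 2


def _validate_gff_lines(path: str) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 8:
                raise ValueError(f"{path}: malformed record at line {i}")


def _models_from_db(db: gffutils.FeatureDB) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    chroms: dict[str, str] = {}
    biotypes: dict[str, str] = {}
    spans: dict[str, tuple[int, int]] = {}

    def gene_id_of(feat) -> str:
        for key in ("gene_id", "ID", "Parent", "gene"):
            if key in feat.attributes:
                val = feat.attributes[key][0]
                return val.split(":")[-1] if key == "Parent" else val
        raise ValueError(f"feature at {feat.seqid}:{feat.start} lacks a gene identifier")

    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype == "gene":
            gid = gene_id_of(feat)
            spans[gid] = (feat.start, feat.end)
            strands[gid] = feat.strand
            chroms[gid] = feat.seqid
            for key in ("gene_biotype", "gene_type", "biotype"):
                if key in feat.attributes:
                    biotypes[gid] = feat.attributes[key][0]
                    break
        elif ftype == "exon":
            gid = gene_id_of(feat)
            exons.setdefault(gid, []).append((feat.start, feat.end))
            strands.setdefault(gid, feat.strand)
            chroms.setdefault(gid, feat.seqid)

    models = []
    for gid in sorted(set(chroms)):
        ex = sorted(exons.get(gid, []))
        if not ex:
            raise ValueError(f"gene {gid} has zero exons")
        merged: list[tuple[int, int]] = []
        for s, e in ex:  # transcripts may repeat exons; merge overlaps
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        start, end = spans.get(gid, (merged[0][0], merged[-1][1]))
        start = min(start, merged[0][0])
        end = max(end, merged[-1][1])
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=chroms[gid],
                start=start,
                end=end,
                strand=strands[gid],
                exons=tuple(merged),
                biotype=biotypes.get(gid, "protein_coding"),
            )
        )
    return models


def read_gene_models(path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF, GFF3 or the package's TSV dialect.

    Returns one :class:`GeneModel` per gene, exons merged and sorted.
    """
    path = str(path)
    if format == "tsv":
        return _read_gene_models_tsv(path)
    if format not in ("gtf", "gff3"):
        raise ValueError(f"unknown annotation format {format!r}")
    _validate_gff_lines(path)
    # fix the dialect explicitly: per-file inference is unreliable on files
    # where most records carry a single attribute
    if format == "gtf":
        dialect = {
            "leading semicolon": False, "trailing semicolon": True,
            "quoted GFF2 values": True, "field separator": "; ",
            "semicolon in quotes": False, "keyval separator": " ",
            "multival separator": ",", "fmt": "gtf", "repeated keys": False,
            "order": ["gene_id", "transcript_id"],
        }
    else:
        dialect = dict(gffutils.constants.dialect)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        dialect=dialect,
    )
    return _models_from_db(db)


def _read_gene_models_tsv(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chromosome", "start", "end", "strand", "biotype", "exons"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    models = []
    for i, row in df.iterrows():
        try:
            exons = tuple(
                (int(p.split("-")[0]), int(p.split("-")[1]))
                for p in str(row["exons"]).split(";")
            )
            models.append(
                GeneModel(
                    gene_id=row["gene_id"],
                    chromosome=row["chromosome"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    exons=exons,
                    biotype=row["biotype"],
                )
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed record at line {i + 2}: {exc}") from exc
    return sorted(models, key=lambda g: g.gene_id)


def write_gene_models_tsv(models: Iterable[GeneModel], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chromosome": g.chromosome,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "biotype": g.biotype,
            "exons": ";".join(f"{s}-{e}" for s, e in g.exons),
        }
        for g in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gtf(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in models:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chromosome}\tflankscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chromosome}\tflankscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# count tables


def library_id(line: str, tissue: str, genotype: str) -> str:
    return f"{line}:{tissue}:{genotype}"


def parse_library_id(lib_id: str) -> LibraryMeta:
    parts = lib_id.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"library id {lib_id!r} is not line:tissue:genotype; supply a metadata sidecar"
        )
    return LibraryMeta(lib_id, *parts)


def read_counts(path, meta_path=None) -> tuple[pd.DataFrame, list[LibraryMeta]]:
    """Read a gene x library count matrix (TSV, first column gene_id).

    Library metadata comes from a sidecar TSV (columns library_id, line,
    tissue, genotype) or, absent that, from ``line:tissue:genotype`` library
    ids in the header.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing cells in count matrix")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative count")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t", dtype=str)
        meta = [
            LibraryMeta(r["library_id"], r["line"], r["tissue"], r["genotype"])
            for _, r in mdf.iterrows()
        ]
    else:
        meta = [parse_library_id(c) for c in df.columns]
    return df, meta


def write_counts(counts: pd.DataFrame, path, meta: Optional[list[LibraryMeta]] = None,
                 meta_path=None) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")
    if meta is not None and meta_path is not None:
        pd.DataFrame(
            [
                {"library_id": m.library_id, "line": m.line, "tissue": m.tissue,
                 "genotype": m.genotype}
                for m in meta
            ]
        ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele tables


def read_allele_table(path) -> list[TargetAllele]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "allele_class", "trap_insertion_intron", "deleted_exon_first",
                "deleted_exon_last", "neo_promoter"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    alleles = []
    for _, r in df.iterrows():
        if r["allele_class"] == TRAP:
            alleles.append(
                TargetAllele(
                    gene_id=r["gene_id"],
                    allele_class=TRAP,
                    trap_insertion_intron=int(r["trap_insertion_intron"]),
                    neo_promoter=r["neo_promoter"],
                )
            )
        else:
            alleles.append(
                TargetAllele(
                    gene_id=r["gene_id"],
                    allele_class=DEL,
                    deleted_exons=(int(r["deleted_exon_first"]), int(r["deleted_exon_last"])),
                    neo_promoter=r["neo_promoter"],
                )
            )
    return alleles


def write_allele_table(alleles: Iterable[TargetAllele], path) -> None:
    rows = []
    for a in alleles:
        rows.append(
            {
                "gene_id": a.gene_id,
                "allele_class": a.allele_class,
                "trap_insertion_intron": a.trap_insertion_intron or "",
                "deleted_exon_first": a.deleted_exons[0] if a.deleted_exons else "",
                "deleted_exon_last": a.deleted_exons[1] if a.deleted_exons else "",
                "neo_promoter": a.neo_promoter,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# supplementary-table dialect

S1_COLUMNS = {
    "line": "line",
    "synonym": "synonym",
    "tissue": "tissue",
    "chromosome": "chromosome",
    "gene": "gene",
    "start": "start",
    "end": "end",
    "centrum distance": "centrum_distance",
    "centrum_distance": "centrum_distance",
    "strand": "strand",
    "hom": "hom",
    "wt": "wt",
    "p value": "p_value",
    "p_value": "p_value",
    "hom/wt": "hom_wt_ratio",
    "hom_wt_ratio": "hom_wt_ratio",
    "log2": "log2",
}

_S1_REQUIRED = (
    "line", "tissue", "chromosome", "gene", "start", "end",
    "centrum_distance", "strand", "hom", "wt", "p_value",
)


def read_s1_table(path, sep: Optional[str] = None) -> list[S1Row]:
    """Read a delimited export of the supplementary workbook.

    Blank p-values (genes DESeq2 did not test) are preserved as None.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in S1_COLUMNS:
            rename[col] = S1_COLUMNS[key]
    df = df.rename(columns=rename)
    missing = [c for c in _S1_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    def opt_float(v) -> Optional[float]:
        if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
            return None
        return float(v)

    rows = []
    for _, r in df.iterrows():
        rows.append(
            S1Row(
                line=r["line"],
                synonym=str(r.get("synonym", "") or ""),
                tissue=r["tissue"],
                chromosome=str(r["chromosome"]),
                gene=r["gene"],
                start=int(float(r["start"])),
                end=int(float(r["end"])),
                centrum_distance=int(float(r["centrum_distance"])),
                strand=r["strand"],
                hom=float(r["hom"]),
                wt=float(r["wt"]),
                p_value=opt_float(r["p_value"]),
                hom_wt_ratio=opt_float(r.get("hom_wt_ratio")),
                log2=opt_float(r.get("log2")),
            )
        )
    return rows


def write_s1_table(rows: Iterable[S1Row], path) -> None:
    recs = []
    for r in rows:
        recs.append(
            {
                "Line": r.line,
                "Synonym": r.synonym,
                "Tissue": r.tissue,
                "Chromosome": r.chromosome,
                "Gene": r.gene,
                "Start": r.start,
                "End": r.end,
                "Centrum Distance": r.centrum_distance,
                "Strand": r.strand,
                "HOM": r.hom,
                "WT": r.wt,
                "P Value": "" if r.p_value is None else r.p_value,
                "HOM/WT": "" if r.hom_wt_ratio is None else r.hom_wt_ratio,
                "Log2": "" if r.log2 is None else r.log2,
            }
        )
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# exon profiles (gene, library, exon ordinal 5'->3', count, intronic reads)


def read_exon_profiles(path) -> list[ExonProfile]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "library_id", "exon_ordinal", "count", "intronic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    profiles = []
    for (gid, lib), sub in df.groupby(["gene_id", "library_id"], sort=True):
        sub = sub.sort_values("exon_ordinal")
        ords = sub["exon_ordinal"].to_numpy()
        if not (ords == range(1, len(ords) + 1)).all():
            raise ValueError(f"{path}: {gid}/{lib}: exon ordinals not 1..n")
        profiles.append(
            ExonProfile(
                gene_id=gid,
                library_id=lib,
                exon_counts=tuple(float(c) for c in sub["count"]),
                intronic_reads=float(sub["intronic"].iloc[0]),
            )
        )
    return profiles


def write_exon_profiles(profiles: Iterable[ExonProfile], path) -> None:
    rows = []
    for p in profiles:
        for i, c in enumerate(p.exon_counts, start=1):
            rows.append(
                {"gene_id": p.gene_id, "library_id": p.library_id,
                 "exon_ordinal": i, "count": c, "intronic": p.intronic_reads}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals (0-based half-open on disk -> 1-based inclusive in memory)


def read_bed_tfbs(path) -> tuple[TfbsSite, ...]:
    """BED with a 4th column giving confidence (high|low)."""
    sites = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {i}: need chrom, start, end, confidence")
            conf = parts[3].lower()
            if conf not in ("high", "low"):
                raise ValueError(f"{path}: line {i}: confidence must be high|low")
            sites.append(TfbsSite(parts[0], int(parts[1]) + 1, int(parts[2]), conf))
    return tuple(sites)


def read_bed_peaks(path) -> tuple[ChipPeak, ...]:
    """BED with 4th column factor (Pol2|CTCF|p300) and optional 5th tissue."""
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {i}: need chrom, start, end, factor")
            tissue = parts[4] if len(parts) > 4 else ""
            peaks.append(ChipPeak(parts[0], int(parts[1]) + 1, int(parts[2]), parts[3], tissue))
    return tuple(peaks)


def write_bed_tfbs(sites: Iterable[TfbsSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chromosome}\t{s.start - 1}\t{s.end}\t{s.confidence}\n")


def write_bed_peaks(peaks: Iterable[ChipPeak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chromosome}\t{p.start - 1}\t{p.end}\t{p.factor}\t{p.tissue}\n")
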