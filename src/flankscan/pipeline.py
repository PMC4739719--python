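"""End-to-end orchestration: differential calls -> neighborhoods -> cohort
statistics -> empirical null, plus the supplementary-table bypass that
recomputes every table-derivable quantity from stored normalized counts and
p-values."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import de_test, neighborhood as nb, empirical_null as enull, targeting_qc as qc
from .annotation_io import gene_centrum
from .models import (
    DEL,
    TRAP,
    GeneModel,
    LibraryMeta,
    NeighborhoodSummary,
    S1Row,
    TargetAllele,
)


def analyze_cohort(
    genes: Sequence[GeneModel],
    alleles: Sequence[TargetAllele],
    counts: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    meta: Sequence[LibraryMeta],
    alpha: float = 0.05,
    window: int = nb.WINDOW,
    bin_width_kb: int = nb.BIN_WIDTH_KB,
    dedupe: str = "pair",
    calls: Optional[pd.DataFrame] = None,
) -> dict:
    """Run calls + neighborhood + cohort statistics + genome-wide null.

    ``pairs`` are (HOM, WT) library ids; each pair belongs to the line of its
    HOM library (from ``meta``). Pass precomputed ``calls`` to skip the DE
    stage. Returns a dict of stage outputs.
    """
    by_id = {g.gene_id: g for g in genes}
    lib_meta = {m.library_id: m for m in meta}
    if calls is None:
        calls = de_test.call_differential(counts, list(pairs), alpha=alpha)

    summaries: list[NeighborhoodSummary] = []
    flags: list[dict] = []
    norm = de_test.normalize(counts)
    for allele in alleles:
        target = by_id[allele.gene_id]
        line_pairs = [
            (hom, wt) for hom, wt in pairs if lib_meta[hom].line == allele.gene_id
        ]
        labels = {hom: lib_meta[hom].tissue for hom, _ in line_pairs}
        neighbors = nb.extract_neighborhood(target, genes, window=window)
        summaries.append(
            nb.summarize_target(target, allele.allele_class, neighbors, calls,
                                line_pairs, pair_labels=labels)
        )
        flags.append(
            {
                "target": allele.gene_id,
                "allele_class": allele.allele_class,
                "library_flags": [
                    qc.flag_for_inspection(
                        float(norm.loc[allele.gene_id, hom]),
                        float(norm.loc[allele.gene_id, wt]),
                    )
                    for hom, wt in line_pairs
                ],
            }
        )

    frequencies = {}
    for cls in (DEL, TRAP):
        if any(s.allele_class == cls for s in summaries):
            frequencies[cls] = {
                "target": nb.cohort_frequencies(summaries, by="target", allele_class=cls),
                "library": nb.cohort_frequencies(summaries, by="library", allele_class=cls),
            }
    bins, medians = nb.topography(summaries, bin_width_kb=bin_width_kb,
                                  window=window, dedupe=dedupe)
    density = nb.gene_density_contrast(summaries)
    try:
        null = enull.genome_wide_null(calls, genes, window=window, alpha=alpha)
    except ValueError:
        null = None

    comparisons = {}
    if null is not None:
        for cls, freq in frequencies.items():
            n = freq["target"]["n"]
            for direction, f_exp in (("up", null.f_up), ("down", null.f_down)):
                k = round(freq["target"][f"pct_{direction}"] / 100.0 * n)
                if 0 < f_exp < 1:
                    comparisons[f"{cls}_{direction}"] = enull.chisq_gof(
                        (k, n - k), f_exp
                    )
    return {
        "calls": calls,
        "summaries": summaries,
        "frequencies": frequencies,
        "topography_bins": bins,
        "topography_medians": medians,
        "density": density,
        "null": null,
        "null_comparisons": comparisons,
        "flags": flags,
    }


def estimate_3prime_bias(
    genes: Sequence[GeneModel],
    alleles: Sequence[TargetAllele],
    calls: pd.DataFrame,
    meta: Sequence[LibraryMeta],
    padj_threshold: float = 0.05,
    window: int = nb.WINDOW,
) -> dict:
    """Fraction of confidently up-regulated flanking genes lying 3' of their
    target, over unique (target, neighbor) pairs.

    Only calls that stay significant after BH adjustment contribute: at the
    nominal unadjusted threshold, chance calls across the many neighbor
    instances would otherwise dilute the spatial signal toward 1/2.
    """
    by_id = {g.gene_id: g for g in genes}
    lib_meta = {m.library_id: m for m in meta}
    up = calls[(calls["direction"] == "up") & (calls["p_adjusted"] < padj_threshold)]
    events: dict[tuple[str, str], int] = {}
    for allele in alleles:
        target = by_id[allele.gene_id]
        dist = {
            n.gene_id: n.centrum_distance
            for n in nb.extract_neighborhood(target, genes, window=window)
        }
        sub = up[up["gene_id"].isin(dist)]
        for r in sub.itertuples():
            if lib_meta[r.hom_library].line != allele.gene_id:
                continue
            events[(allele.gene_id, r.gene_id)] = dist[r.gene_id]
    n = len(events)
    frac = sum(1 for d in events.values() if d > 0) / n if n else None
    return {"frac_3prime": frac, "n_events": n}


# ---------------------------------------------------------------------------
# supplementary-table bypass


def _s1_direction(row: S1Row, alpha: float) -> str:
    if row.p_value is None or row.p_value >= alpha:
        return "ns"
    if row.hom > row.wt:
        return "up"
    if row.hom < row.wt:
        return "down"
    return "ns"


def summaries_from_s1(
    rows: Sequence[S1Row],
    allele_classes: dict[str, str],
    alpha: float = 0.05,
) -> list[NeighborhoodSummary]:
    """Rebuild per-target summaries from stored counts and p-values. The
    target gene's own rows (gene == line) are excluded from neighbor sets."""
    by_line: dict[str, list[S1Row]] = {}
    for r in rows:
        by_line.setdefault(r.line, []).append(r)
    summaries = []
    for line, line_rows in sorted(by_line.items()):
        tissues = sorted({r.tissue for r in line_rows})
        library_flags = {t: {"has_up": False, "has_down": False} for t in tissues}
        dysregulated = []
        neighbor_genes = set()
        for r in line_rows:
            if r.gene == line:
                continue
            neighbor_genes.add(r.gene)
            direction = _s1_direction(r, alpha)
            if direction == "ns":
                continue
            library_flags[r.tissue][f"has_{direction}"] = True
            dysregulated.append(
                {
                    "gene_id": r.gene,
                    "tissue": r.tissue,
                    "direction": direction,
                    "centrum_distance": r.centrum_distance,
                }
            )
        summaries.append(
            NeighborhoodSummary(
                target=line,
                allele_class=allele_classes.get(line, DEL),
                n_genes_in_window=len(neighbor_genes),
                library_flags=library_flags,
                dysregulated=dysregulated,
            )
        )
    return summaries


def reproduce_from_s1(
    rows: Sequence[S1Row],
    allele_classes: dict[str, str],
    alpha: float = 0.05,
) -> dict:
    """Recompute every table-derivable printed quantity from an S1 export:
    per-target and per-library dysregulation frequencies by allele class,
    the DEL topography medians and 3' fraction, total dysregulated pairs
    under both dedupe conventions, gene-density means, and QC flag
    fractions."""
    summaries = summaries_from_s1(rows, allele_classes, alpha=alpha)
    out: dict = {}
    for cls in (DEL, TRAP):
        sub = [s for s in summaries if s.allele_class == cls]
        if not sub:
            continue
        key = cls.lower()
        t = nb.cohort_frequencies(sub, by="target")
        l = nb.cohort_frequencies(sub, by="library")
        out[f"{key}_pct_targets_up"] = t["pct_up"]
        out[f"{key}_pct_targets_down"] = t["pct_down"]
        out[f"{key}_n_targets"] = t["n"]
        out[f"{key}_pct_libraries_up"] = l["pct_up"]
        out[f"{key}_pct_libraries_down"] = l["pct_down"]
        out[f"{key}_n_libraries"] = l["n"]

    del_summaries = [s for s in summaries if s.allele_class == DEL]
    if del_summaries:
        _, med = nb.topography(del_summaries, dedupe="pair")
        out["del_median_abs_down_kb"] = med["median_abs_down_kb"]
        out["del_median_3p_up_kb"] = med["median_3p_up_kb"]
        out["del_median_abs_5p_up_kb"] = med["median_abs_5p_up_kb"]
        out["del_frac_up_3prime"] = med["frac_up_3prime"]

    for dedupe in ("pair", "instance"):
        _, med = nb.topography(summaries, dedupe=dedupe)
        out[f"n_dysregulated_{dedupe}s"] = med["n_dysregulated"]

    density = nb.gene_density_contrast(summaries)
    out["mean_genes_with_effects"] = density["mean_with_effects"]
    out["mean_genes_without_effects"] = density["mean_without_effects"]
    out["n_with_effects"] = density["n_with_effects"]
    out["n_without_effects"] = density["n_without_effects"]

    # QC flag fractions from the stored target-gene totals
    flags_by_line: dict[str, list[bool]] = {}
    for r in rows:
        if r.gene == r.line:
            flags_by_line.setdefault(r.line, []).append(
                qc.flag_for_inspection(r.hom, r.wt)
            )
    for cls in (DEL, TRAP):
        lines = [ln for ln, c in allele_classes.items() if c == cls and ln in flags_by_line]
        if lines:
            flagged = sum(any(flags_by_line[ln]) for ln in lines)
            out[f"{cls.lower()}_pct_flagged"] = 100.0 * flagged / len(lines)
    return out


def s1_rows_from_run(
    genes: Sequence[GeneModel],
    alleles: Sequence[TargetAllele],
    calls: pd.DataFrame,
    meta: Sequence[LibraryMeta],
    window: int = nb.WINDOW,
) -> list[S1Row]:
    """Export a finished run in the supplementary-table dialect: for each
    library pair, the target gene plus every neighbor in the window, with
    normalized counts and the unadjusted p-value."""
    by_id = {g.gene_id: g for g in genes}
    lib_meta = {m.library_id: m for m in meta}
    call_ix = calls.set_index(["gene_id", "hom_library"])
    rows: list[S1Row] = []
    for allele in alleles:
        target = by_id[allele.gene_id]
        neighbors = nb.extract_neighborhood(target, genes, window=window)
        members = [(target.gene_id, 0)] + [
            (n.gene_id, n.centrum_distance) for n in neighbors
        ]
        hom_libs = sorted(
            {h for (_, h) in call_ix.index if lib_meta[h].line == allele.gene_id}
        )
        for hom in hom_libs:
            tissue = lib_meta[hom].tissue
            for gid, d in members:
                g = by_id[gid]
                c = call_ix.loc[(gid, hom)]
                hom_n, wt_n = float(c["hom_norm"]), float(c["wt_norm"])
                rows.append(
                    S1Row(
                        line=allele.gene_id,
                        synonym="",
                        tissue=tissue,
                        chromosome=g.chromosome,
                        gene=gid,
                        start=g.start,
                        end=g.end,
                        centrum_distance=d,
                        strand=g.strand,
                        hom=hom_n,
                        wt=wt_n,
                        p_value=float(c["p_unadjusted"]),
                        hom_wt_ratio=hom_n / wt_n if wt_n > 0 else None,
                        log2=float(c["log2_ratio"]),
                    )
                )
    return rows


# ---------------------------------------------------------------------------
# file-driven run with a machine-readable log


@dataclass
class RunConfig:
    """Paths and stage parameters for a file-driven pipeline run."""

    annotation: str
    annotation_format: str = "tsv"
    counts: str = ""
    meta: str = ""
    alleles: str = ""
    out_dir: str = "flankscan_out"
    alpha: float = 0.05
    window: int = nb.WINDOW
    bin_width_kb: int = nb.BIN_WIDTH_KB
    dedupe: str = "pair"
    stages: tuple[str, ...] = ("de", "neighborhood", "null")

    def params(self) -> dict:
        return {
            "alpha": self.alpha,
            "window": self.window,
            "bin_width_kb": self.bin_width_kb,
            "dedupe": self.dedupe,
            "stages": list(self.stages),
        }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages from files and write TSV reports plus a
    JSON run log with the resolved parameters and per-stage record counts."""
    from . import annotation_io as aio

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"parameters": cfg.params(), "stages": {}}

    def stage(name):
        return name in cfg.stages

    try:
        genes = aio.read_gene_models(cfg.annotation, format=cfg.annotation_format)
        alleles = aio.read_allele_table(cfg.alleles)
        counts, meta = aio.read_counts(cfg.counts, cfg.meta or None)
        lib_meta = {m.library_id: m for m in meta}
        lines = {m.line for m in meta}
        pairs = []
        for line in sorted(lines):
            tissues = sorted({m.tissue for m in meta if m.line == line})
            for t in tissues:
                from .annotation_io import library_id

                hom, wt = library_id(line, t, "HOM"), library_id(line, t, "WT")
                if hom in counts.columns and wt in counts.columns:
                    pairs.append((hom, wt))
        log["stages"]["input"] = {
            "n_genes": len(genes), "n_libraries": counts.shape[1], "n_pairs": len(pairs)
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc

    results: dict = {}
    try:
        results = analyze_cohort(
            genes, alleles, counts, pairs, meta,
            alpha=cfg.alpha, window=cfg.window,
            bin_width_kb=cfg.bin_width_kb, dedupe=cfg.dedupe,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'analysis' failed: {exc}") from exc

    if stage("de"):
        results["calls"].to_csv(out / "differential_calls.tsv", sep="\t", index=False)
        log["stages"]["de"] = {"n_calls": len(results["calls"])}
    if stage("neighborhood"):
        freq_rows = []
        for cls, freq in results["frequencies"].items():
            for by, f in freq.items():
                freq_rows.append({"allele_class": cls, "by": by, **f})
        pd.DataFrame(freq_rows).to_csv(out / "frequencies.tsv", sep="\t", index=False)
        results["topography_bins"].to_csv(out / "topography_bins.tsv", sep="\t", index=False)
        pd.DataFrame([results["topography_medians"]]).to_csv(
            out / "topography_medians.tsv", sep="\t", index=False
        )
        pd.DataFrame([results["density"]]).to_csv(
            out / "gene_density.tsv", sep="\t", index=False
        )
        log["stages"]["neighborhood"] = {"n_targets": len(results["summaries"])}
    if stage("null") and results["null"] is not None:
        null = results["null"]
        pd.DataFrame(
            [
                {
                    "f_up": null.f_up,
                    "f_down": null.f_down,
                    "n_focal": null.n_focal,
                    "n_neighbor_instances": null.n_neighbor_instances,
                }
            ]
        ).to_csv(out / "genome_wide_null.tsv", sep="\t", index=False)
        comp_rows = [
            {"comparison": k, "statistic": v.statistic, "df": v.df, "p": v.p}
            for k, v in results["null_comparisons"].items()
        ]
        pd.DataFrame(comp_rows).to_csv(out / "null_comparisons.tsv", sep="\t", index=False)
        log["stages"]["null"] = {"n_focal": null.n_focal}

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    results["log"] = log
    return results
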