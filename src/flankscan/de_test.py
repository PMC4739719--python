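"""HOM-vs-WT differential calls for pooled, no-replicate library pairs.

The study design pools biological replicates before sequencing, so each
(line, tissue) contributes exactly one HOM and one WT library. With n=1 per
group, a per-gene dispersion cannot be estimated; instead the two members of
each pair are treated as pseudo-replicates of a common null mean and a
mean-dispersion trend alpha(mu) = a0 + a1/mu is fitted across genes (the
"blind" strategy of the DESeq family). Each gene is then tested with a
two-sided exact negative-binomial test conditional on the pair total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import DispersionModel

LibraryPair = tuple[str, str]  # (HOM library_id, WT library_id)


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (normalized count = raw / factor)."""
    if counts.shape[1] < 2:
        raise ValueError("need at least two libraries")
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in every library")
    sub = mat[all_nonzero]
    geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    return counts / size_factors


def fit_dispersion_trend(
    counts: pd.DataFrame,
    pairs: list[LibraryPair],
    alpha_min: float = 0.01,
    size_factors: pd.Series | None = None,
    n_bins: int = 20,
) -> DispersionModel:
    """Fit alpha(mu) = a0 + a1/mu from paired pseudo-replicates.

    For each gene in each pair, with normalized counts (x, y), the pooled
    mean is m = (x+y)/2 and (x-y)^2/2 estimates the within-pair variance.
    Genes are binned by m; per bin a method-of-moments dispersion is formed
    as (mean variance - mean m) / mu^2, where mu^2 = mean(m^2) - mean(var)/2
    corrects the noise inflation of m^2. The trend is a weighted least-squares
    fit to the bin estimates with nonnegative coefficients, floored at
    ``alpha_min``.
    """
    norm = normalize(counts, size_factors)
    ms, vs = [], []
    for hom, wt in pairs:
        x = norm[hom].to_numpy(dtype=float)
        y = norm[wt].to_numpy(dtype=float)
        m = (x + y) / 2.0
        keep = m > 0
        ms.append(m[keep])
        vs.append(((x - y) ** 2 / 2.0)[keep])
    m = np.concatenate(ms)
    v = np.concatenate(vs)
    if m.size < 20:
        raise ValueError(f"only {m.size} genes with nonzero mean; need >= 20")

    order = np.argsort(m)
    m, v = m[order], v[order]
    edges = np.unique(np.quantile(m, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, m, side="right") - 1, 0, len(edges) - 2)

    mu_bin, alpha_bin, w_bin = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() < 5:
            continue
        mb, vb = m[sel], v[sel]
        mu2 = np.mean(mb**2) - np.mean(vb) / 2.0
        if mu2 <= 0:
            continue
        alpha_bin.append((np.mean(vb) - np.mean(mb)) / mu2)
        mu_bin.append(np.mean(mb))
        w_bin.append(sel.sum())
    if not mu_bin:
        return DispersionModel(a0=0.0, a1=0.0, alpha_min=alpha_min)

    mu_bin = np.asarray(mu_bin)
    alpha_bin = np.asarray(alpha_bin)
    w = np.sqrt(np.asarray(w_bin, dtype=float))
    X = np.column_stack([np.ones_like(mu_bin), 1.0 / mu_bin])
    coef, *_ = np.linalg.lstsq(X * w[:, None], alpha_bin * w, rcond=None)
    a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    return DispersionModel(a0=a0, a1=a1, alpha_min=alpha_min)


def _nb_logpmf(k: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p)


def nb_pair_test(
    k_hom: float,
    k_wt: float,
    s_hom: float,
    s_wt: float,
    disp: DispersionModel,
    _max_full_enum: int = 20_000,
) -> float:
    """Two-sided exact NB test of a single HOM/WT count pair.

    Under the null both counts share a common normalized mean m, estimated
    as the average of the two normalized counts. Conditional on the observed
    total S = k_hom + k_wt, the distribution of the HOM count over outcomes
    (a, S-a) is enumerated from the NB model with dispersion alpha(m) from
    the trend; the p-value doubles the smaller tail (point included), capped
    at 1. For large totals the enumeration is restricted to a +/-50-SD window
    around the conditional centre; the excluded mass is negligible.
    """
    k_hom, k_wt = int(round(k_hom)), int(round(k_wt))
    if k_hom < 0 or k_wt < 0 or s_hom <= 0 or s_wt <= 0:
        raise ValueError("counts must be >= 0 and size factors > 0")
    S = k_hom + k_wt
    if S == 0:
        return 1.0
    m = (k_hom / s_hom + k_wt / s_wt) / 2.0
    alpha = float(disp.alpha(m))
    mu_h, mu_w = s_hom * m, s_wt * m

    if S <= _max_full_enum:
        a = np.arange(S + 1)
    else:
        centre = S * mu_h / (mu_h + mu_w)
        sd = np.sqrt(mu_h + alpha * mu_h**2)
        lo = int(max(0, min(centre - 50 * sd, k_hom - 1)))
        hi = int(min(S, max(centre + 50 * sd, k_hom + 1)))
        a = np.arange(lo, hi + 1)

    logp = _nb_logpmf(a, mu_h, alpha) + _nb_logpmf(S - a, mu_w, alpha)
    logp -= logp.max()
    pmf = np.exp(logp)
    total = pmf.sum()
    below = a <= k_hom
    p_low = pmf[below].sum() / total
    p_high = pmf[~(a < k_hom)].sum() / total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def call_differential(
    counts: pd.DataFrame,
    pairs: list[LibraryPair],
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    disp: DispersionModel | None = None,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """One differential call per (gene, HOM/WT pair).

    Returns a DataFrame with columns gene_id, hom_library, wt_library,
    hom_norm, wt_norm, log2_ratio, p_unadjusted, p_adjusted, direction.
    Direction uses the unadjusted p at the given significance level; the
    BH-adjusted p (within pair) is carried for reporting only.
    """
    for hom, wt in pairs:
        for lib in (hom, wt):
            if lib not in counts.columns:
                raise ValueError(f"unknown library {lib!r} in pair ({hom}, {wt})")
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    if disp is None:
        disp = fit_dispersion_trend(counts, pairs, size_factors=size_factors)

    frames = []
    genes = counts.index.to_numpy()
    for hom, wt in pairs:
        s_h = float(size_factors[hom])
        s_w = float(size_factors[wt])
        kh = counts[hom].to_numpy(dtype=float)
        kw = counts[wt].to_numpy(dtype=float)
        p = np.array([nb_pair_test(a, b, s_h, s_w, disp) for a, b in zip(kh, kw)])
        p_adj = multipletests(p, method="fdr_bh")[1]
        hom_norm = kh / s_h
        wt_norm = kw / s_w
        direction = np.where(
            (p < alpha) & (hom_norm > wt_norm),
            "up",
            np.where((p < alpha) & (hom_norm < wt_norm), "down", "ns"),
        )
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "hom_library": hom,
                    "wt_library": wt,
                    "hom_norm": hom_norm,
                    "wt_norm": wt_norm,
                    "log2_ratio": np.log2((hom_norm + pseudocount) / (wt_norm + pseudocount)),
                    "p_unadjusted": p,
                    "p_adjusted": p_adj,
                    "direction": direction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
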