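"""Signal-detection calling of differentially (informative) methylated sites.

A site (or region) is called at significance level alpha when the
probability of the methylation noise background producing a divergence at
least as large — one minus the fitted null CDF — falls below alpha.  No
multiple-testing adjustment is applied to these calls; the threshold is a
false-positive probability in the signal-detection sense.  Fisher's exact
test on read counts is provided as the classical comparator (optionally
Benjamini-Hochberg adjusted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dist_models import FitResult
from .info_measures import divergence_track
from .methylome_io import MethylMatrix

__all__ = [
    "call_dimps",
    "fisher_dmp",
    "fisher_dmps",
    "call_dimrs",
    "density_profile",
]


def _p_exceed(values: np.ndarray, fit: FitResult) -> np.ndarray:
    """P(D > d0) under the fitted null; 1 where d0 is at/below the location."""
    return 1.0 - np.asarray(fit.cdf(values), dtype=float)


def call_dimps(
    matrix: MethylMatrix,
    kind: str,
    alpha: float,
    null_fit: FitResult,
    ref: int | str = 0,
    query: int | str = 1,
) -> pd.DataFrame:
    """Call differentially informative methylated positions for a sample pair.

    ``null_fit`` must be a converged fit of the same divergence ``kind`` made
    on this pair's site divergences.  Sites MISSING in either sample are
    skipped.  Returns the site table with ``divergence``, ``p_exceed`` and
    ``is_dimp`` columns.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not null_fit.converged:
        raise ValueError("null fit did not converge; refusing to call DIMPs")
    if null_fit.kind is not None and null_fit.kind != kind:
        raise ValueError(
            f"null fit is for kind {null_fit.kind!r}, calls requested for {kind!r}"
        )
    track = divergence_track(matrix, ref, query, kind)
    observed = track["divergence"].notna().to_numpy()
    out = track.loc[observed].reset_index(drop=True)
    d0 = out["divergence"].to_numpy(dtype=float)
    # Infinite KL divergences sit beyond any fitted support: certain calls.
    finite = np.isfinite(d0)
    p_exc = np.ones_like(d0)
    p_exc[finite] = _p_exceed(d0[finite], null_fit)
    p_exc[~finite] = 0.0
    out["p_exceed"] = p_exc
    out["is_dimp"] = p_exc < alpha
    return out


def fisher_dmp(
    n_meth_a: int, n_total_a: int, n_meth_b: int, n_total_b: int,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two-sided Fisher's exact test on one site's 2x2 methylation table.

    Table rows are (methylated, unmethylated) reads per sample.  Returns
    ``(p_value, called)`` with the unadjusted ``p < alpha`` decision.
    """
    if n_total_a == 0 or n_total_b == 0:
        raise ValueError("Fisher test requires positive coverage in both samples")
    table = [
        [n_meth_a, n_total_a - n_meth_a],
        [n_meth_b, n_total_b - n_meth_b],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), bool(p < alpha)


def fisher_dmps(
    matrix: MethylMatrix,
    alpha: float = 0.05,
    ref: int | str = 0,
    query: int | str = 1,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Fisher's exact test across all co-covered sites of a sample pair.

    Zero-coverage sites on either side are skipped (flagged by omission).
    ``bh_adjust`` switches the decision to Benjamini-Hochberg adjusted
    p-values; the default mirrors an unadjusted comparator.
    """
    i = matrix.sample_index(ref) if isinstance(ref, str) else ref
    j = matrix.sample_index(query) if isinstance(query, str) else query
    cov_a = matrix.coverages[:, i]
    cov_b = matrix.coverages[:, j]
    lev_a = matrix.levels[:, i]
    lev_b = matrix.levels[:, j]
    ok = (cov_a > 0) & (cov_b > 0)
    out = matrix.sites.loc[ok].reset_index(drop=True)
    meth_a = np.rint(lev_a[ok] * cov_a[ok]).astype(int)
    meth_b = np.rint(lev_b[ok] * cov_b[ok]).astype(int)
    tot_a = cov_a[ok].astype(int)
    tot_b = cov_b[ok].astype(int)
    pvals = np.empty(len(out))
    for idx in range(len(out)):
        pvals[idx], _ = fisher_dmp(
            meth_a[idx], tot_a[idx], meth_b[idx], tot_b[idx], alpha
        )
    out["p_value"] = pvals
    if bh_adjust:
        out["p_adjusted"] = _bh_adjust(pvals)
        out["is_dmp"] = out["p_adjusted"] < alpha
    else:
        out["is_dmp"] = pvals < alpha
    return out


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_dimrs(
    regions: pd.DataFrame,
    alpha: float,
    null_fit: FitResult,
    divergence_column: str = "HD",
) -> pd.DataFrame:
    """Call differentially informative methylated regions.

    ``regions`` is a tile-info table (one row per same-size region, with the
    summed divergence in ``divergence_column``); ``null_fit`` must come from
    the same partition.  Mixed nominal region sizes are an error — the null
    CDF is only valid within one partition.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not null_fit.converged:
        raise ValueError("null fit did not converge; refusing to call DIMRs")
    full = regions.loc[~regions.get("partial", False)] if "partial" in regions else regions
    sizes = (full["end"] - full["start"] + 1).unique()
    if len(sizes) > 1:
        raise ValueError(
            f"regions have mixed sizes {sorted(sizes)}; one partition required"
        )
    out = full.reset_index(drop=True).copy()
    d_r = out[divergence_column].to_numpy(dtype=float)
    p_exc = _p_exceed(d_r, null_fit)
    out["p_exceed"] = p_exc
    out["is_dimr"] = p_exc < alpha
    return out


def density_profile(
    calls: pd.DataFrame,
    anchors: pd.DataFrame,
    window: int,
    bin_size: int,
) -> pd.DataFrame:
    """Call density around stranded anchors (e.g. gene start/end sites).

    ``calls`` needs chrom/pos columns; ``anchors`` needs chrom/pos/strand.
    Each call within ``window`` bp of an anchor contributes to the bin of its
    anchor-relative, strand-oriented offset; counts are normalized by the
    number of anchors.  Returns (bin_start, bin_center, count, density).
    """
    if len(anchors) == 0:
        raise ValueError("no anchors provided")
    if not window > bin_size > 0:
        raise ValueError("require window > bin > 0")
    edges = np.arange(-window, window + bin_size, bin_size)
    counts = np.zeros(len(edges) - 1)
    by_chrom = {c: g["pos"].to_numpy() for c, g in calls.groupby("chrom")}
    for row in anchors.itertuples(index=False):
        pos_arr = by_chrom.get(row.chrom)
        if pos_arr is None:
            continue
        rel = pos_arr - int(row.pos)
        if getattr(row, "strand", "+") == "-":
            rel = -rel
        rel = rel[(rel >= -window) & (rel < window)]
        if rel.size:
            counts += np.histogram(rel, bins=edges)[0]
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_center": edges[:-1] + bin_size / 2.0,
            "count": counts.astype(int),
            "density": counts / len(anchors),
        }
    )
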