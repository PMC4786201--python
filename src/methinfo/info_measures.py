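"""Entropy, information content, Landauer energy and information divergences.

All logarithms are base 2, so entropies, information and Kullback-Leibler
divergences are in bits.  Missing methylation levels (NaN) contribute zero
entropy by convention and are excluded from divergences, which require both
samples observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .methylome_io import GenomicRegion, MethylMatrix

__all__ = [
    "BOLTZMANN_K",
    "entropy",
    "region_information",
    "landauer_energy",
    "site_divergence",
    "region_divergence",
    "divergence_track",
    "tile_info_table",
    "EnergyValue",
]

BOLTZMANN_K = 1.380649e-23  # J/K (exact, 2019 SI)

DIVERGENCE_KINDS = ("TV", "KL", "HD")


def _as_levels(p, allow_missing: bool = True) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError("methylation levels must lie in [0, 1]")
    if not allow_missing and np.isnan(arr).any():
        raise ValueError("MISSING level not allowed here")
    return arr


def entropy(p) -> np.ndarray | float:
    """Binary Shannon entropy of a methylation level, in bits.

    ``0 * log2(0)`` is taken as 0, and a MISSING level (NaN) has entropy 0.
    Accepts scalars or arrays.
    """
    arr = _as_levels(p)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.zeros_like(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        for q in (arr, 1.0 - arr):
            term = -q * np.log2(q)
            out += np.where(np.isfinite(term), term, 0.0)
    out[np.isnan(arr)] = 0.0
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def region_information(before, after) -> float:
    """Absolute difference of summed site entropies between two states (bits).

    ``before`` and ``after`` must index the same sites (equal lengths);
    MISSING entries contribute zero entropy.  The single-site case yields the
    per-site information I_k.
    """
    b = np.atleast_1d(_as_levels(before))
    a = np.atleast_1d(_as_levels(after))
    if b.shape != a.shape:
        raise ValueError(
            f"before/after site vectors differ in shape: {b.shape} vs {a.shape}"
        )
    return float(abs(np.sum(entropy(a)) - np.sum(entropy(b))))


@dataclass(frozen=True)
class EnergyValue:
    """Minimum dissipated energy for a given number of bits at temperature T."""

    joules: float
    temperature_K: float
    bits: float


def landauer_energy(bits: float, temperature_K: float = 298.15) -> EnergyValue:
    """Minimum energy (J) to irreversibly process ``bits`` of information.

    E = bits * k_B * T * ln 2.
    """
    if bits < 0:
        raise ValueError("bits must be non-negative")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    joules = bits * BOLTZMANN_K * temperature_K * np.log(2.0)
    return EnergyValue(joules=float(joules), temperature_K=float(temperature_K),
                       bits=float(bits))


def _kl_bernoulli(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Bernoulli KL divergence in bits; +inf where q is degenerate and p is not."""
    out = np.zeros(np.broadcast(p, q).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        for pp, qq in ((p, q), (1.0 - p, 1.0 - q)):
            term = pp * (np.log2(pp) - np.log2(qq))
            term = np.where(pp == 0.0, 0.0, term)  # 0 * log(0/q) := 0
            out = out + term
    return out


def site_divergence(p, q, kind: str = "HD") -> np.ndarray | float:
    """Divergence between two Bernoulli methylation levels.

    Kinds
    -----
    ``TV``
        total variation ``|p - q|``
    ``KL``
        Kullback-Leibler in bits.  A degenerate ``q`` (0 or 1) with a
        non-matching ``p`` yields +inf — reported as a sentinel, never raised —
        so that downstream CDF fitting can exclude it.
    ``HD``
        squared Hellinger distance
        ``(sqrt(p) - sqrt(q))**2 + (sqrt(1-p) - sqrt(1-q))**2``, bounded by 2.

    MISSING (NaN) in either argument propagates to NaN: a divergence needs
    both samples observed.
    """
    if kind not in DIVERGENCE_KINDS:
        raise ValueError(f"unknown divergence kind {kind!r}")
    pa = _as_levels(p)
    qa = _as_levels(q)
    scalar = pa.ndim == 0 and qa.ndim == 0
    pa, qa = np.atleast_1d(pa), np.atleast_1d(qa)
    if kind == "TV":
        out = np.abs(pa - qa)
    elif kind == "KL":
        out = _kl_bernoulli(pa, qa)
    else:
        out = (np.sqrt(pa) - np.sqrt(qa)) ** 2 + (
            np.sqrt(1.0 - pa) - np.sqrt(1.0 - qa)
        ) ** 2
    missing = np.isnan(pa) | np.isnan(qa)
    out = np.where(missing, np.nan, out)
    return float(out[0]) if scalar else out


def region_divergence(site_divs, kind: str | None = None) -> float:
    """Sum of site divergences over a region; the empty region sums to 0.

    NaN entries (MISSING sites) are skipped.  Kind mixing is the caller's
    responsibility when passing raw arrays; pass a ``kinds`` sequence to
    assert homogeneity.
    """
    if isinstance(site_divs, Sequence) and site_divs and isinstance(site_divs[0], tuple):
        kinds = {k for _, k in site_divs}
        if len(kinds) > 1:
            raise ValueError(f"mixed divergence kinds in region: {sorted(kinds)}")
        site_divs = [v for v, _ in site_divs]
    arr = np.asarray(site_divs, dtype=float)
    if arr.size == 0:
        return 0.0
    return float(np.nansum(arr))


def divergence_track(
    matrix: MethylMatrix, ref: int | str, query: int | str, kind: str = "HD"
) -> pd.DataFrame:
    """Per-site divergences between two samples of a matrix.

    Returns the site table with a ``divergence`` column; MISSING on either
    side yields NaN.  The ``I`` kind is the per-site information
    |H(query) - H(ref)|.
    """
    i = matrix.sample_index(ref) if isinstance(ref, str) else ref
    j = matrix.sample_index(query) if isinstance(query, str) else query
    p = matrix.levels[:, i]
    q = matrix.levels[:, j]
    if kind == "I":
        vals = np.abs(entropy(q) - entropy(p))
        vals = np.where(np.isnan(p) | np.isnan(q), np.nan, vals)
    else:
        vals = site_divergence(p, q, kind)
    out = matrix.sites.copy()
    out["divergence"] = vals
    return out


def tile_info_table(
    matrix: MethylMatrix,
    tiles: Sequence[GenomicRegion],
    ref: int | str,
    query: int | str,
    temperature_K: float = 298.15,
) -> pd.DataFrame:
    """Summarize information and divergences per genome tile.

    One row per tile: chrom, start, end, partial flag, number of co-observed
    sites, I_R (bits), E_R (J at ``temperature_K``), and the summed TV, KL
    and HD divergences.  Infinite KL site values are excluded from KL_R and
    counted in ``n_kl_inf``.
    """
    i = matrix.sample_index(ref) if isinstance(ref, str) else ref
    j = matrix.sample_index(query) if isinstance(query, str) else query
    p_all = matrix.levels[:, i]
    q_all = matrix.levels[:, j]
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()

    rows = []
    for tile in tiles:
        mask = (chroms == tile.chrom) & (pos >= tile.start) & (pos <= tile.end)
        p, q = p_all[mask], q_all[mask]
        i_r = region_information(p, q) if p.size else 0.0
        co = ~(np.isnan(p) | np.isnan(q))
        tv = region_divergence(site_divergence(p[co], q[co], "TV"))
        kl_site = site_divergence(p[co], q[co], "KL") if co.any() else np.array([])
        kl_fin = kl_site[np.isfinite(kl_site)] if kl_site.size else kl_site
        hd = region_divergence(site_divergence(p[co], q[co], "HD"))
        rows.append(
            {
                "chrom": tile.chrom,
                "start": tile.start,
                "end": tile.end,
                "partial": tile.partial,
                "n_sites": int(mask.sum()),
                "n_co_observed": int(co.sum()),
                "I": i_r,
                "E": landauer_energy(i_r, temperature_K).joules,
                "TV": tv,
                "KL": float(np.sum(kl_fin)) if kl_site.size else 0.0,
                "n_kl_inf": int(np.sum(~np.isfinite(kl_site))) if kl_site.size else 0,
                "HD": hd,
            }
        )
    return pd.DataFrame(rows)
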