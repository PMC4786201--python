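"""Synthetic methylomes and forward models with known ground truth.

Every generator is deterministic under an explicit seed.  The simulator
targets the statistical structure assumed by the analysis modules — beta-
distributed levels, negative-binomial coverage, a Weibull divergence noise
background with optional spiked signal, linear/exponential scale trends and
exponential word-length spectra — not the biology of any real methylome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dist_models import WeibullParams, weibull_rvs
from .info_measures import site_divergence
from .methyl_language import BinaryMethylome
from .methylome_io import MethylomeSample, MethylMatrix, build_matrix
from .polymer_mechanics import LambdaTrend, LN2, NM_PER_BP

__all__ = [
    "SimSpec",
    "SignalSpec",
    "simulate_methylome",
    "simulate_pair",
    "simulate_lambda_trend",
    "simulate_pwf_string",
]

DEFAULT_BETA = {
    "CG": (0.4, 0.4),    # bimodal, CpG-like
    "CHG": (0.5, 2.0),
    "CHH": (0.3, 3.0),
}


@dataclass
class SimSpec:
    """Ground-truth description of a synthetic methylome."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    n_sites: int = 10_000                       # per chromosome
    context_props: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.4, "CHG": 0.3, "CHH": 0.3}
    )
    coverage_mean: float = 20.0
    coverage_dispersion: float = 5.0            # NB size parameter
    zero_coverage_fraction: float = 0.0
    beta_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BETA)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if not 0 <= self.zero_coverage_fraction < 1:
            raise ValueError("zero_coverage_fraction must lie in [0, 1)")
        total = sum(self.context_props.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"context proportions must sum to 1, got {total}")
        for ctx, (a, b) in self.beta_params.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"beta parameters for {ctx} must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size < self.n_sites:
                raise ValueError(
                    f"{chrom}: cannot place {self.n_sites} distinct sites in "
                    f"{size} bp"
                )


@dataclass
class SignalSpec:
    """Spiked-signal description for a sample pair."""

    noise: WeibullParams = field(
        default_factory=lambda: WeibullParams(alpha=1.0, lambda_scale=0.3, mu=0.01)
    )
    n_spiked: int = 0
    effect: float | None = None   # spike divergence; default mu + 5 lambda
    kind: str = "HD"              # divergence whose law the background follows

    def spike_divergence(self) -> float:
        if self.effect is not None:
            return self.effect
        return self.noise.mu + 5.0 * self.noise.lambda_scale


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _draw_coverage(spec: SimSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    size = spec.coverage_dispersion
    p = size / (size + spec.coverage_mean)
    cov = stats.nbinom(size, p).rvs(size=n, random_state=rng)
    cov = np.maximum(cov, 1)
    if spec.zero_coverage_fraction > 0:
        drop = rng.random(n) < spec.zero_coverage_fraction
        cov[drop] = 0
    return cov


def simulate_methylome(
    spec: SimSpec, seed: int | None = None, sample_id: str = "sim"
) -> MethylomeSample:
    """Draw one synthetic methylome under ``spec``.

    Sites sit at sorted distinct random positions; coverage is negative
    binomial (with an optional zero-coverage fraction yielding MISSING
    levels); the methylation level is beta per context and read counts are
    binomial given the level.
    """
    rng = _rng(seed if seed is not None else spec.seed)
    contexts = sorted(spec.context_props)
    probs = np.array([spec.context_props[c] for c in contexts])
    frames = []
    for chrom, size in spec.chrom_sizes.items():
        pos = np.sort(rng.choice(size, size=spec.n_sites, replace=False)) + 1
        ctx_idx = rng.choice(len(contexts), size=spec.n_sites, p=probs)
        ctx = np.array(contexts, dtype=object)[ctx_idx]
        strand = np.where(rng.random(spec.n_sites) < 0.5, "+", "-")
        cov = _draw_coverage(spec, spec.n_sites, rng)
        levels = np.empty(spec.n_sites)
        for k, c in enumerate(contexts):
            mask = ctx_idx == k
            a, b = spec.beta_params.get(c, (1.0, 1.0))
            levels[mask] = rng.beta(a, b, size=int(mask.sum()))
        n_meth = rng.binomial(cov, levels)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": strand,
                    "context": ctx,
                    "n_meth": n_meth,
                    "n_total": cov,
                }
            )
        )
    return MethylomeSample(sample_id, pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Divergence-structured sample pairs
# ---------------------------------------------------------------------------

def _hd(p: float, q: float) -> float:
    return (math.sqrt(p) - math.sqrt(q)) ** 2 + (
        math.sqrt(1 - p) - math.sqrt(1 - q)
    ) ** 2


def _div_fn(p: float, kind: str):
    def dv(q: float) -> float:
        if kind == "HD":
            return _hd(p, q)
        return float(site_divergence(p, q, kind))

    return dv


def _max_divergence(p: float, kind: str) -> float:
    dv = _div_fn(p, kind)
    # KL blows up at the boundary; cap the search just inside it
    left = 1e-12 if kind == "KL" else 0.0
    right = 1.0 - 1e-12 if kind == "KL" else 1.0
    return max(dv(left), dv(right))


def _invert_divergence(
    p: float, target: float, kind: str, rng: np.random.Generator
) -> float | None:
    """Find q with divergence(p, q) = target, or None when unattainable.

    The divergence increases monotonically as q moves away from p on either
    side; a feasible side is chosen at random when both attain the target.
    """
    dv = _div_fn(p, kind)
    left = 1e-12 if kind == "KL" else 0.0
    right = 1.0 - 1e-12 if kind == "KL" else 1.0

    sides = []
    if p > left and dv(left) >= target:
        sides.append((left, p))
    if p < right and dv(right) >= target:
        sides.append((p, right))
    if not sides:
        return None
    lo, hi = sides[rng.integers(len(sides))] if len(sides) > 1 else sides[0]
    # root of dv(q) - target on the chosen side (dv is monotone there)
    f_lo, f_hi = dv(lo) - target, dv(hi) - target
    if f_lo * f_hi > 0:
        return None
    return float(optimize.brentq(lambda q: dv(q) - target, lo, hi, xtol=1e-12))


def simulate_pair(
    spec: SimSpec,
    signal: SignalSpec | None = None,
    seed: int | None = None,
    max_redraws: int = 100,
    exact_level_denominator: int | None = None,
) -> tuple[MethylomeSample, MethylomeSample, pd.DataFrame]:
    """Generate a (reference, query) pair with a known divergence structure.

    The reference methylome is drawn from ``spec``.  For each covered site a
    background divergence is drawn from the Weibull noise law and the query
    level solved so that the chosen divergence between the *observed* levels
    equals it; ``n_spiked`` randomly chosen sites get the spike divergence
    instead.  When a drawn divergence is unattainable from the reference
    level the draw is repeated (up to ``max_redraws``, then the maximum
    attainable divergence is used).

    ``exact_level_denominator`` fixes the query coverage at a large constant
    so the realized level quantization error is negligible; by default the
    query coverage follows the spec's coverage law.

    Returns (reference, query, truth) where ``truth`` maps each site key to
    ``is_signal`` and the target divergence.
    """
    signal = signal or SignalSpec()
    if signal.effect is not None and signal.effect <= signal.noise.lambda_scale:
        import warnings

        warnings.warn(
            "signal effect does not exceed the background scale; spikes are "
            "undetectable by construction",
            stacklevel=2,
        )
    rng = _rng(seed)
    ref = simulate_methylome(spec, seed=int(rng.integers(2**31)), sample_id="ref")
    p_levels = ref.levels
    n = len(ref)
    covered = np.isfinite(p_levels)

    is_signal = np.zeros(n, dtype=bool)
    covered_idx = np.flatnonzero(covered)
    spike_d0 = signal.spike_divergence()
    if signal.n_spiked > 0:
        # spikes must actually reach the target divergence, which bounds the
        # usable reference levels (e.g. HD(p, .) maxes out below 2 for
        # mid-range p); sample spiked sites from the attainable pool
        attainable = np.array(
            [
                _max_divergence(float(p_levels[idx]), signal.kind) >= spike_d0
                for idx in covered_idx
            ]
        )
        pool = covered_idx[attainable]
        if signal.n_spiked > pool.size:
            raise ValueError(
                f"only {pool.size} covered sites can attain the spike "
                f"divergence {spike_d0:.3g}; requested {signal.n_spiked}"
            )
        spiked = rng.choice(pool, size=signal.n_spiked, replace=False)
        is_signal[spiked] = True

    target = np.full(n, np.nan)
    q_levels = np.full(n, np.nan)
    n_redraw_exhausted = 0
    for idx in covered_idx:
        p = float(p_levels[idx])
        if is_signal[idx]:
            t = spike_d0
            q = _invert_divergence(p, t, signal.kind, rng)
            if q is None:  # not reachable despite the pool screen (numeric edge)
                d_max = _max_divergence(p, signal.kind)
                q = _invert_divergence(p, d_max * (1 - 1e-9), signal.kind, rng)
                t = d_max
        else:
            q = None
            t = np.nan
            for _ in range(max_redraws):
                t = float(weibull_rvs(signal.noise, 1, rng)[0])
                q = _invert_divergence(p, t, signal.kind, rng)
                if q is not None:
                    break
            if q is None:
                n_redraw_exhausted += 1
                q, t = p, 0.0
        target[idx] = t
        q_levels[idx] = q

    query_sites = ref.sites.copy()
    if exact_level_denominator is not None:
        cov_q = np.where(covered, exact_level_denominator, 0)
        meth_q = np.where(
            covered, np.rint(np.nan_to_num(q_levels) * cov_q), 0
        ).astype(int)
    else:
        rng_cov = _rng(int(rng.integers(2**31)))
        cov_q = _draw_coverage(spec, n, rng_cov)
        cov_q = np.where(covered, cov_q, 0)
        meth_q = np.where(
            cov_q > 0, np.rint(np.nan_to_num(q_levels) * cov_q), 0
        ).astype(int)
    query_sites["n_meth"] = meth_q
    query_sites["n_total"] = cov_q
    query = MethylomeSample("query", query_sites)

    truth = ref.sites[["chrom", "pos", "strand", "context"]].copy()
    truth["is_signal"] = is_signal
    truth["target_divergence"] = target
    truth.attrs["n_redraw_exhausted"] = n_redraw_exhausted
    return ref, query, truth


def simulate_lambda_trend(
    model: str,
    lp_nm: float,
    l_grid,
    coeff: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    length_unit: str = "nm",
) -> LambdaTrend:
    """Forward-model a scale trend lambda(l) with known persistence length.

    ``linear``: lambda = (1 - b)/ln2 + b l / (Lp ln2) with ``coeff`` = b.
    ``exponential``: lambda = a exp(1.5 l / Lp) with ``coeff`` = a.
    Multiplicative Gaussian noise of relative sd ``noise_sd`` is applied when
    positive.  The grid must be in the requested ``length_unit`` (nm for the
    model formulas; bp grids are converted internally and reported in bp).
    """
    if lp_nm <= 0:
        raise ValueError("persistence length must be positive")
    l_arr = np.asarray(l_grid, dtype=float)
    l_nm = l_arr * NM_PER_BP if length_unit == "bp" else l_arr
    if model == "linear":
        b = coeff
        lam = (1.0 - b) / LN2 + b * l_nm / (lp_nm * LN2)
    elif model == "exponential":
        lam = coeff * np.exp(1.5 * l_nm / lp_nm)
    else:
        raise ValueError(f"unknown trend model {model!r}")
    if noise_sd > 0:
        rng = _rng(seed)
        lam = lam * (1.0 + noise_sd * rng.standard_normal(lam.shape))
        lam = np.maximum(lam, 1e-12)
    sd = np.full(lam.shape, np.nan)
    n = np.ones(lam.shape, dtype=int)
    return LambdaTrend(l_arr, lam, sd, n, length_unit=length_unit)


# ---------------------------------------------------------------------------
# Binary word strings
# ---------------------------------------------------------------------------

def _random_word(length: int, d: int, rng: np.random.Generator) -> str:
    """A random valid word of ``length`` digits at threshold ``d``."""
    if length == 1:
        return "1"
    if d == 1:
        return "1" * length
    digits = ["1"] + ["0"] * (length - 2) + ["1"]
    for i in range(1, length - 1):
        digits[i] = "1" if rng.random() < 0.5 else "0"
    # break any zero-run longer than d - 1 by forcing a 1 at its midpoint
    run_start = None
    i = 1
    while i < length - 1:
        if digits[i] == "0":
            if run_start is None:
                run_start = i
            if i - run_start + 1 > d - 1:
                digits[run_start + (i - run_start) // 2] = "1"
                run_start = None
                i = 0  # rescan; lengths here are tiny
        else:
            run_start = None
        i += 1
    return "".join(digits)


def simulate_pwf_string(
    n_words: int,
    gamma: float,
    d: int,
    seed: int | None = None,
    min_len: int = 1,
    max_len: int = 200,
    chrom: str = "chr1",
) -> tuple[BinaryMethylome, np.ndarray]:
    """Concatenate random words with exponentially distributed lengths.

    Word lengths are drawn with P(l) proportional to exp(-gamma l) on
    [min_len, max_len]; words are separated by zero-runs of length >= d so
    that partitioning at threshold ``d`` recovers exactly the generated
    words.  Returns the binary methylome (every position a site) and the
    generated length array.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = _rng(seed)
    lengths = np.arange(min_len, max_len + 1)
    probs = np.exp(-gamma * lengths)
    probs /= probs.sum()
    drawn = rng.choice(lengths, size=n_words, p=probs)
    parts: list[str] = []
    for i, l in enumerate(drawn):
        if i > 0:
            parts.append("0" * (d + int(rng.integers(0, 3))))
        parts.append(_random_word(int(l), d, rng))
    s = "".join(parts)
    digits = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
    positions = np.arange(1, len(s) + 1, dtype=np.int64)
    return (
        BinaryMethylome({chrom: positions}, {chrom: digits.astype(np.uint8)}),
        drawn,
    )


def matrix_from_pair(ref: MethylomeSample, query: MethylomeSample) -> MethylMatrix:
    """Convenience: two-sample matrix with the reference in column 0."""
    return build_matrix([ref, query])
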