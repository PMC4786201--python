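"""Binary methylation words: partition, sentence decomposition and decay law.

The pooled binary methylome assigns 1 to a cytosine site methylated (level
greater than zero) in at least one sample and 0 otherwise.  At a threshold
``d`` the digit string splits into maximal word frameworks (PWFs) — runs
starting and ending in 1 whose internal zero-runs are all shorter than
``d`` — separated by zero-runs of length >= d.  Word length frequencies
follow an exponential decay ``f_l = phi * exp(-gamma * l)`` whose partition-
function form yields a Helmholtz free energy ``dF = R T ln(N0 / phi)``.

Word length is counted in digits (cytosine sites); the genomic span in bp is
recorded alongside, since the two coincide only where every position is a
cytosine.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.constants import R as GAS_CONSTANT_R  # J/(mol K)

from .dist_models import FitResult, fit_cdf
from .info_measures import entropy
from .methylome_io import MethylMatrix

__all__ = [
    "BinaryMethylome",
    "PWF",
    "SentenceComponent",
    "DecayFit",
    "binarize",
    "partition_string",
    "partition_pwf",
    "decompose_sentence",
    "length_spectrum",
    "fit_decay",
    "pwf_information",
]


@dataclass
class BinaryMethylome:
    """Per-chromosome binary methylation strings over ordered site positions."""

    positions: dict[str, np.ndarray]  # chrom -> strictly increasing 1-based positions
    digits: dict[str, np.ndarray]     # chrom -> uint8 array of 0/1, same length

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            dig = np.asarray(self.digits[chrom], dtype=np.uint8)
            if pos.shape != dig.shape:
                raise ValueError(f"{chrom}: positions/digits length mismatch")
            if pos.size and (np.diff(pos) <= 0).any():
                raise ValueError(f"{chrom}: positions not strictly increasing")
            if dig.size and not np.isin(dig, (0, 1)).all():
                raise ValueError(f"{chrom}: digits must be 0 or 1")
            self.positions[chrom] = pos
            self.digits[chrom] = dig

    def string(self, chrom: str) -> str:
        return "".join("1" if b else "0" for b in self.digits[chrom])


def binarize(matrix: MethylMatrix) -> BinaryMethylome:
    """Pool a matrix into one digit per union site.

    A site gets 1 when its level is greater than zero in at least one sample;
    MISSING observations count as no positive evidence.
    """
    lv = matrix.levels
    with np.errstate(invalid="ignore"):
        dig_all = np.any(np.nan_to_num(lv, nan=0.0) > 0, axis=1).astype(np.uint8)
    positions: dict[str, np.ndarray] = {}
    digits: dict[str, np.ndarray] = {}
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        # A site may appear on both strands at one position; pool to a single
        # digit per distinct position (1 if either strand is methylated).
        p = pos[mask]
        d = dig_all[mask]
        uniq, inv = np.unique(p, return_inverse=True)
        pooled = np.zeros(uniq.size, dtype=np.uint8)
        np.maximum.at(pooled, inv, d)
        positions[chrom] = uniq
        digits[chrom] = pooled
    return BinaryMethylome(positions, digits)


@dataclass(frozen=True)
class PWF:
    """A word framework: a binary string starting and ending in 1 whose
    internal zero-runs are all <= d - 1."""

    digits: str
    d: int
    chrom: str = ""
    start_index: int = 0           # 0-based offset of the first digit in the string
    start_pos: int = 0             # genomic position of the first 1
    end_pos: int = 0               # genomic position of the last 1

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("threshold d must be >= 1")
        if not self.digits or self.digits[0] != "1" or self.digits[-1] != "1":
            raise ValueError("a PWF must start and end with 1")
        runs = [len(m) for m in re.findall(r"0+", self.digits)]
        if runs and max(runs) > self.d - 1:
            raise ValueError(
                f"internal zero-run of {max(runs)} exceeds d - 1 = {self.d - 1}"
            )

    @property
    def length(self) -> int:
        """Word length in digits (cytosine sites)."""
        return len(self.digits)

    @property
    def span_bp(self) -> int:
        """Genomic span end - start + 1 in bp (0 when coordinates unset)."""
        if self.end_pos < self.start_pos:
            return 0
        return self.end_pos - self.start_pos + 1

    @property
    def max_zero_run(self) -> int:
        runs = [len(m) for m in re.findall(r"0+", self.digits)]
        return max(runs) if runs else 0


def partition_string(s: str, d: int) -> list[tuple[str, str]]:
    """Split a binary string into alternating ('pwf'|'zeros', substring) segments.

    Zero-runs of length >= d separate words; shorter internal runs stay
    inside a word.  Leading and trailing zeros (and all-zero strings) come
    out as 'zeros' segments.  Concatenating the substrings in order
    reproduces ``s`` exactly.
    """
    if d < 1:
        raise ValueError("threshold d must be >= 1")
    if any(c not in "01" for c in s):
        raise ValueError("string must be binary")
    if not s:
        return []
    ones = [i for i, c in enumerate(s) if c == "1"]
    if not ones:
        return [("zeros", s)]
    segments: list[tuple[str, str]] = []
    if ones[0] > 0:
        segments.append(("zeros", s[: ones[0]]))
    word_start = ones[0]
    prev_one = ones[0]
    for i in ones[1:]:
        gap = i - prev_one - 1
        if gap >= d:
            segments.append(("pwf", s[word_start : prev_one + 1]))
            segments.append(("zeros", s[prev_one + 1 : i]))
            word_start = i
        prev_one = i
    segments.append(("pwf", s[word_start : prev_one + 1]))
    if prev_one + 1 < len(s):
        segments.append(("zeros", s[prev_one + 1 :]))
    return segments


def partition_pwf(binary: BinaryMethylome, d: int) -> list[PWF]:
    """Partition every chromosome's digit string into PWFs at threshold ``d``.

    Word coordinates carry the genomic positions of their first and last 1.
    """
    words: list[PWF] = []
    for chrom in binary.positions:
        s = binary.string(chrom)
        pos = binary.positions[chrom]
        offset = 0
        for tag, sub in partition_string(s, d):
            if tag == "pwf":
                words.append(
                    PWF(
                        digits=sub,
                        d=d,
                        chrom=chrom,
                        start_index=offset,
                        start_pos=int(pos[offset]) if pos.size else 0,
                        end_pos=int(pos[offset + len(sub) - 1]) if pos.size else 0,
                    )
                )
            offset += len(sub)
    return words


@dataclass(frozen=True)
class SentenceComponent:
    """One piece of a sentence: a sub-word (with its partition index k) or a
    separating zero-run of length d - 1."""

    kind: str                 # {"pwf", "zeros"}
    digits: str
    k: int | None = None      # partition index of a sub-word; None for zeros


def decompose_sentence(pwf: PWF) -> list[SentenceComponent]:
    """Decompose a word from partition S_d into sub-words and zero-runs.

    Long words are sentences: splitting at every maximal zero-run of length
    exactly d - 1 yields sub-words from finer partitions, each annotated with
    its own index ``k`` = (max internal zero-run) + 1 (k = 1 for words
    without zeros).  At d = 1 the decomposition is the word itself.
    Concatenating the component digits reproduces the parent word.
    """
    d = pwf.d
    if d == 1:
        return [SentenceComponent("pwf", pwf.digits, k=1)]
    sep = "0" * (d - 1)
    components: list[SentenceComponent] = []
    pieces = re.split(f"(?<=1)({sep})(?=1)", pwf.digits)
    for piece in pieces:
        if not piece:
            continue
        if piece == sep:
            components.append(SentenceComponent("zeros", piece))
        else:
            runs = [len(m) for m in re.findall(r"0+", piece)]
            k = (max(runs) + 1) if runs else 1
            components.append(SentenceComponent("pwf", piece, k=k))
    assert "".join(c.digits for c in components) == pwf.digits
    return components


def length_spectrum(pwfs: Sequence[PWF] | Iterable[int]) -> pd.DataFrame:
    """Frequency table of word lengths (digits), sorted by length."""
    lengths = [p.length if isinstance(p, PWF) else int(p) for p in pwfs]
    if not lengths:
        return pd.DataFrame({"l": pd.Series(dtype=int), "f": pd.Series(dtype=int)})
    vals, counts = np.unique(np.asarray(lengths, dtype=int), return_counts=True)
    return pd.DataFrame({"l": vals, "f": counts})


@dataclass(frozen=True)
class DecayFit:
    """Exponential length-spectrum fit f_l = phi exp(-gamma l) and its
    free-energy summary dF = R T ln(N0 / phi)."""

    phi: float
    gamma: float
    n0: int
    z: float                  # N0 / phi, the estimated partition function
    delta_f: float            # J/mol
    temperature_K: float
    r2: float
    valid: bool
    message: str = ""


def fit_decay(
    spectrum: pd.DataFrame,
    min_l: int | None = None,
    max_l: int | None = None,
    temperature_K: float = 298.15,
) -> DecayFit:
    """Fit the exponential decay law to a word length spectrum.

    Nonlinear least squares on raw counts ``f_l = phi exp(-gamma l)`` over
    lengths in [min_l, max_l] (at least 4 distinct lengths).  ``N0`` is the
    total word count of the full spectrum; ``dF = R T ln(N0/phi)``.  A
    non-decaying spectrum (gamma <= 0) is flagged invalid, not raised.
    """
    if len(spectrum) == 0:
        raise ValueError("empty length spectrum")
    n0 = int(spectrum["f"].sum())
    sel = spectrum
    if min_l is not None:
        sel = sel[sel["l"] >= min_l]
    if max_l is not None:
        sel = sel[sel["l"] <= max_l]
    if sel["l"].nunique() < 4:
        raise ValueError("need >= 4 distinct lengths in the fitting range")
    l_arr = sel["l"].to_numpy(dtype=float)
    f_arr = sel["f"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(l_arr, np.log(np.maximum(f_arr, 0.5)), 1)

    def residuals(theta):
        phi, gamma = theta
        return phi * np.exp(-gamma * l_arr) - f_arr

    sol = optimize.least_squares(
        residuals, [math.exp(intercept), -slope], xtol=1e-15, ftol=1e-15,
        gtol=1e-15, max_nfev=5000,
    )
    phi, gamma = (float(v) for v in sol.x)
    fhat = phi * np.exp(-gamma * l_arr)
    ss_res = float(np.sum((f_arr - fhat) ** 2))
    ss_tot = float(np.sum((f_arr - f_arr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if gamma <= 0 or phi <= 0:
        return DecayFit(phi, gamma, n0, float("nan"), float("nan"),
                        temperature_K, r2, valid=False,
                        message="non-decaying spectrum")
    z = n0 / phi
    delta_f = GAS_CONSTANT_R * temperature_K * math.log(z)
    return DecayFit(phi, gamma, n0, z, delta_f, temperature_K, r2, valid=True)


def pwf_information(
    pwfs: Sequence[PWF],
    matrix: MethylMatrix,
    ref: int | str,
    query: int | str,
    min_count: int = 20,
    min_value: float = 1e-8,
) -> tuple[pd.DataFrame, dict[int, FitResult]]:
    """Per-length Weibull fits of word information content.

    For every word the information ``I = |sum H(query) - sum H(ref)|`` over
    its sites is computed against the designated reference sample.  Lengths
    with at least ``min_count`` words get a Weibull CDF fit whose scale
    estimate feeds the short-fragment persistence model (length converted to
    nm downstream at 0.34 nm/digit).  Lengths with fewer words are skipped.

    Returns the per-length summary frame and a dict length -> FitResult.
    """
    i = matrix.sample_index(ref) if isinstance(ref, str) else ref
    j = matrix.sample_index(query) if isinstance(query, str) else query
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    h_ref = entropy(matrix.levels[:, i])
    h_query = entropy(matrix.levels[:, j])

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        order = np.argsort(pos[mask], kind="mergesort")
        by_chrom[chrom] = (
            pos[mask][order], h_ref[mask][order], h_query[mask][order]
        )

    values_by_length: dict[int, list[float]] = {}
    for w in pwfs:
        if w.chrom not in by_chrom:
            continue
        p_arr, hr, hq = by_chrom[w.chrom]
        lo = np.searchsorted(p_arr, w.start_pos, side="left")
        hi = np.searchsorted(p_arr, w.end_pos, side="right")
        info = float(abs(np.sum(hq[lo:hi]) - np.sum(hr[lo:hi])))
        values_by_length.setdefault(w.length, []).append(info)

    rows = []
    fits: dict[int, FitResult] = {}
    for length in sorted(values_by_length):
        vals = np.asarray(values_by_length[length])
        usable = vals[np.isfinite(vals) & (vals >= min_value)]
        if usable.size < min_count:
            continue
        try:
            fit = fit_cdf(usable, model="weibull", min_value=min_value,
                          kind="I", region_length=float(length))
        except ValueError:
            continue
        fits[length] = fit
        rows.append(
            {
                "l": length,
                "n_words": int(usable.size),
                "alpha": fit.params.alpha,
                "lambda": fit.params.lambda_scale,
                "mu": fit.params.mu,
                "r2": fit.r2,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows), fits
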