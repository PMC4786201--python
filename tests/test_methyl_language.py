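import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.constants import R as GAS_R

from methinfo.methyl_language import (
    PWF,
    BinaryMethylome,
    binarize,
    decompose_sentence,
    fit_decay,
    length_spectrum,
    partition_pwf,
    partition_string,
    pwf_information,
)
from methinfo.methylome_io import MethylomeSample, build_matrix
from methinfo.polymer_mechanics import persistence_exponential, lambda_trend
from methinfo.simulate import simulate_pwf_string

SENTENCE_28 = "1001100000010000011100000011"


def brute_force_segments(s: str, d: int) -> list[tuple[str, str]]:
    """Reference partition: group 1s whose gaps are < d, by direct scanning."""
    if not s:
        return []
    ones = [i for i, c in enumerate(s) if c == "1"]
    if not ones:
        return [("zeros", s)]
    clusters = [[ones[0]]]
    for i in ones[1:]:
        if i - clusters[-1][-1] - 1 >= d:
            clusters.append([i])
        else:
            clusters[-1].append(i)
    segs = []
    cursor = 0
    for cl in clusters:
        if cl[0] > cursor:
            segs.append(("zeros", s[cursor : cl[0]]))
        segs.append(("pwf", s[cl[0] : cl[-1] + 1]))
        cursor = cl[-1] + 1
    if cursor < len(s):
        segs.append(("zeros", s[cursor:]))
    return segs


class TestBinarize:
    def _matrix(self, levels_by_sample):
        samples = []
        for sid, levels in levels_by_sample.items():
            n = len(levels)
            totals = [10 if lv is not None else 0 for lv in levels]
            meths = [round((lv or 0) * 10) for lv in levels]
            samples.append(
                MethylomeSample(
                    sid,
                    pd.DataFrame(
                        {
                            "chrom": "chr1",
                            "pos": np.arange(1, n + 1) * 5,
                            "strand": "+",
                            "context": "CG",
                            "n_meth": meths,
                            "n_total": totals,
                        }
                    ),
                )
            )
        return build_matrix(samples)

    def test_positive_in_any_sample(self):
        m = self._matrix({"a": [0.0, 0.0], "b": [0.2, 0.0]})
        binary = binarize(m)
        np.testing.assert_array_equal(binary.digits["chr1"], [1, 0])

    def test_missing_counts_as_zero(self):
        m = self._matrix({"a": [0.0], "b": [None]})
        binary = binarize(m)
        np.testing.assert_array_equal(binary.digits["chr1"], [0])

    def test_all_zero_sample(self):
        m = self._matrix({"a": [0.0, 0.0, 0.0]})
        assert binarize(m).string("chr1") == "000"

    def test_both_strands_pool_to_one_digit(self):
        a = MethylomeSample(
            "a",
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "pos": [10, 10],
                    "strand": ["+", "-"],
                    "context": ["CG", "CG"],
                    "n_meth": [0, 5],
                    "n_total": [10, 10],
                }
            ),
        )
        binary = binarize(build_matrix([a]))
        np.testing.assert_array_equal(binary.digits["chr1"], [1])


class TestPartition:
    def test_printed_sentence_at_d7(self):
        segs = partition_string(SENTENCE_28, 7)
        assert [(t, len(x)) for t, x in segs] == [("pwf", 28)]

    def test_printed_sentence_at_d6(self):
        segs = partition_string(SENTENCE_28, 6)
        pwf_lengths = [len(x) for t, x in segs if t == "pwf"]
        assert pwf_lengths == [5, 9, 2]
        assert [x for t, x in segs if t == "pwf"] == ["10011", "100000111", "11"]

    def test_eleven_digit_word_at_d6(self):
        segs = partition_string("11010000011", 6)
        assert segs == [("pwf", "11010000011")]
        word = PWF("11010000011", 6)
        assert word.length == 11
        assert word.max_zero_run == 5

    def test_eleven_digit_word_splits_at_d5(self):
        segs = partition_string("11010000011", 5)
        assert [x for t, x in segs if t == "pwf"] == ["1101", "11"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            partition_string("101", 0)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            partition_string("102", 2)

    @pytest.mark.parametrize("d", [1, 2, 3, 4, 5, 6])
    def test_exhaustive_short_strings(self, d):
        """Reconstruction + validity, brute force over all strings <= 8 digits.

        (Full length-12 sweep runs in the acceptance suite.)
        """
        for n in range(0, 9):
            for bits in itertools.product("01", repeat=n):
                s = "".join(bits)
                segs = partition_string(s, d)
                assert "".join(x for _, x in segs) == s
                for tag, sub in segs:
                    if tag == "pwf":
                        w = PWF(sub, d)  # validates start/end and zero runs
                        assert w.max_zero_run <= d - 1
                    else:
                        assert set(sub) <= {"0"}
                assert segs == brute_force_segments(s, d)

    @given(st.text(alphabet="01", max_size=60), st.integers(1, 8))
    @settings(max_examples=300)
    def test_reconstruction_property(self, s, d):
        segs = partition_string(s, d)
        assert "".join(x for _, x in segs) == s

    @given(st.text(alphabet="01", max_size=40), st.integers(1, 6))
    @settings(max_examples=200)
    def test_nesting_property(self, s, d):
        """Every word at threshold d lies inside exactly one word at d + 1."""
        spans_d = []
        offset = 0
        for tag, sub in partition_string(s, d):
            if tag == "pwf":
                spans_d.append((offset, offset + len(sub)))
            offset += len(sub)
        spans_d1 = []
        offset = 0
        for tag, sub in partition_string(s, d + 1):
            if tag == "pwf":
                spans_d1.append((offset, offset + len(sub)))
            offset += len(sub)
        for a, b in spans_d:
            containers = [1 for c, e in spans_d1 if c <= a and b <= e]
            assert sum(containers) == 1

    def test_partition_pwf_coordinates(self):
        positions = np.array([3, 8, 15, 100, 108, 111])
        digits = np.array([1, 0, 1, 1, 0, 1], dtype=np.uint8)
        binary = BinaryMethylome({"chr1": positions}, {"chr1": digits})
        words = partition_pwf(binary, 1)
        assert [(w.start_pos, w.end_pos, w.digits) for w in words] == [
            (3, 3, "1"),
            (15, 100, "11"),
            (111, 111, "1"),
        ]


class TestDecompose:
    def test_printed_sentence(self):
        word = PWF(SENTENCE_28, 7)
        comps = decompose_sentence(word)
        assert [(c.kind, len(c.digits), c.k) for c in comps] == [
            ("pwf", 5, 3),
            ("zeros", 6, None),
            ("pwf", 9, 6),
            ("zeros", 6, None),
            ("pwf", 2, 1),
        ]
        assert "".join(c.digits for c in comps) == SENTENCE_28

    def test_no_internal_separator_is_identity(self):
        word = PWF("10101", 3)
        comps = decompose_sentence(word)
        assert len(comps) == 1 and comps[0].digits == "10101"
        assert comps[0].k == 2

    def test_trivial_word(self):
        comps = decompose_sentence(PWF("11", 4))
        assert comps[0].k == 1

    def test_d1_is_itself(self):
        comps = decompose_sentence(PWF("111", 1))
        assert len(comps) == 1 and comps[0].digits == "111"

    @given(st.text(alphabet="01", min_size=1, max_size=50), st.integers(2, 7))
    @settings(max_examples=200)
    def test_components_reassemble(self, s, d):
        for tag, sub in partition_string(s, d):
            if tag != "pwf":
                continue
            word = PWF(sub, d)
            comps = decompose_sentence(word)
            assert "".join(c.digits for c in comps) == sub
            for c in comps:
                if c.kind == "zeros":
                    assert len(c.digits) == d - 1
                else:
                    assert c.k == PWF(c.digits, d).max_zero_run + 1


class TestSpectrumAndDecay:
    def test_counting(self):
        spec = length_spectrum([2, 2, 5])
        assert spec["l"].tolist() == [2, 5]
        assert spec["f"].tolist() == [2, 1]

    def test_empty(self):
        spec = length_spectrum([])
        assert len(spec) == 0

    def test_count_conservation(self):
        lengths = [1, 1, 2, 3, 3, 3, 9]
        spec = length_spectrum(lengths)
        assert spec["f"].sum() == len(lengths)

    def test_exact_exponential_round_trip(self):
        l = np.arange(4, 61)
        f = 1000.0 * np.exp(-0.05 * l)
        spectrum = pd.DataFrame({"l": l, "f": f})
        fit = fit_decay(spectrum, min_l=4, max_l=60)
        assert fit.phi == pytest.approx(1000.0, rel=1e-6)
        assert fit.gamma == pytest.approx(0.05, rel=1e-6)

    def test_delta_f_zero_when_n0_equals_phi(self):
        l = np.arange(1, 30)
        f = np.exp(-0.3 * l)
        f = f / f.sum()  # sums to 1: N0-as-total == 1
        spectrum = pd.DataFrame({"l": l, "f": f * 100})
        fit = fit_decay(spectrum)
        # direct identity check instead: dF = R T ln(N0/phi)
        assert fit.delta_f == pytest.approx(
            GAS_R * fit.temperature_K * math.log(fit.n0 / fit.phi), rel=1e-9
        )

    def test_delta_f_gas_constant_value(self):
        # N0 = e * phi  ->  dF = R T =~ 2478.8 J/mol at 298.15 K
        l = np.arange(1, 8, dtype=float)
        phi = 500.0
        f = phi * np.exp(-0.4 * l)
        spectrum = pd.DataFrame({"l": l, "f": f})
        n0_scaled = phi * math.e
        spectrum.loc[len(spectrum)] = [100.0, n0_scaled - f.sum()]
        fit = fit_decay(spectrum, min_l=1, max_l=7, temperature_K=298.15)
        assert fit.n0 == pytest.approx(n0_scaled, abs=1.0)
        assert fit.delta_f == pytest.approx(GAS_R * 298.15, rel=2e-3)
        assert fit.delta_f == pytest.approx(2478.8, rel=2e-3)

    def test_nondecaying_flagged(self):
        l = np.arange(1, 10)
        spectrum = pd.DataFrame({"l": l, "f": np.exp(0.2 * l)})
        fit = fit_decay(spectrum)
        assert not fit.valid

    def test_too_few_lengths(self):
        with pytest.raises(ValueError):
            fit_decay(pd.DataFrame({"l": [1, 2, 3], "f": [9, 5, 2]}))

    def test_poisson_noise_recovery(self):
        gammas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            l = np.arange(1, 80)
            expected = np.exp(-0.08 * l)
            expected *= 10_000 / expected.sum()
            f = rng.poisson(expected)
            keep = f > 0
            fit = fit_decay(pd.DataFrame({"l": l[keep], "f": f[keep]}))
            gammas.append(fit.gamma)
        assert abs(np.median(gammas) - 0.08) / 0.08 < 0.10


class TestSimulatedStrings:
    def test_partition_recovers_generated_words(self):
        binary, lengths = simulate_pwf_string(500, gamma=0.1, d=4, seed=3)
        words = partition_pwf(binary, 4)
        assert sorted(w.length for w in words) == sorted(lengths.tolist())

    def test_d1_words_are_all_ones(self):
        binary, _ = simulate_pwf_string(100, gamma=0.2, d=1, seed=0)
        for w in partition_pwf(binary, 1):
            assert set(w.digits) == {"1"}

    def test_decay_recovery_end_to_end(self):
        binary, _ = simulate_pwf_string(10_000, gamma=0.07, d=5, seed=11)
        words = partition_pwf(binary, 5)
        spectrum = length_spectrum(words)
        fit = fit_decay(spectrum[spectrum["f"] > 0])
        # the generated length law is exponential on a truncated support
        assert fit.valid
        assert abs(fit.gamma - 0.07) / 0.07 < 0.10


class TestPwfInformation:
    def _pair_matrix_with_words(self, seed=0, n_sites=4000):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(200_000, size=n_sites, replace=False)) + 1
        zero = rng.random(n_sites) < 0.4  # unmethylated in both -> binary 0s
        ref_levels = np.where(zero, 0.0, rng.uniform(0.1, 0.9, size=n_sites))
        query_levels = np.where(
            zero, 0.0,
            np.clip(ref_levels + rng.normal(0, 0.15, size=n_sites), 0, 1),
        )
        def sample(sid, levels):
            return MethylomeSample(
                sid,
                pd.DataFrame(
                    {
                        "chrom": "chr1",
                        "pos": pos,
                        "strand": "+",
                        "context": "CG",
                        "n_meth": np.rint(levels * 1000).astype(int),
                        "n_total": 1000,
                    }
                ),
            )
        return build_matrix([sample("ref", ref_levels), sample("q", query_levels)])

    def test_skips_sparse_lengths(self):
        matrix = self._pair_matrix_with_words()
        words = partition_pwf(binarize(matrix), 2)
        table, fits = pwf_information(words, matrix, 0, 1, min_count=10**9)
        assert len(table) == 0 and len(fits) == 0

    def test_fits_produced_per_length(self):
        matrix = self._pair_matrix_with_words()
        words = partition_pwf(binarize(matrix), 2)
        table, fits = pwf_information(words, matrix, 0, 1, min_count=20)
        assert len(table) >= 1
        assert set(table["l"]) == set(fits)
        assert (table["n_words"] >= 20).all()

    def test_end_to_end_persistence_recovery(self):
        """Scale grows as 0.5*exp(0.03 * 0.34 * l): Lp = 3/(2*0.03) = 50 nm."""
        from methinfo.dist_models import WeibullParams, weibull_rvs, fit_cdf

        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fits = []
            for l in range(4, 40, 4):
                lam = 0.5 * math.exp(0.03 * (0.34 * l))
                vals = weibull_rvs(WeibullParams(1.5, lam, 0.01), 400, rng)
                fits.append(
                    fit_cdf(vals, "weibull", kind="I",
                            region_length=0.34 * l)
                )
            trend = lambda_trend(fits, length_unit="nm")
            estimates.append(persistence_exponential(trend).lp_nm)
        assert abs(np.median(estimates) - 50.0) / 50.0 < 0.10
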