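"""Band ratios, classification, z-scores, embeddings, correlations, stats."""

import numpy as np
import pytest

import filmspec as fs
from filmspec.datatypes import Spectrum, SpectrumTable
from filmspec.errors import ConfigError
from filmspec.profiling import (
    LIPOLYTIC_RATIO,
    PROTEOLYTIC_RATIO,
    RatioSpec,
    band_ratio,
    classify_groups,
    compare_groups,
    correlation_chords,
    embed_and_distance,
    p_to_stars,
    zscore_profile,
)


class TestBandRatio:
    def test_identical_bands_give_one(self, axis64, rng):
        spec = Spectrum(rng.uniform(0.5, 1.5, 64), axis64)
        assert band_ratio(spec, RatioSpec(1649, 1649)) == pytest.approx(1.0)

    def test_scale_invariance(self, axis64, rng):
        values = rng.uniform(0.5, 1.5, 64)
        r1 = band_ratio(Spectrum(values, axis64), PROTEOLYTIC_RATIO)
        r2 = band_ratio(Spectrum(5.0 * values, axis64), PROTEOLYTIC_RATIO)
        assert r1 == pytest.approx(r2)

    def test_ffa_vs_tag_ordering(self, axis64, refs64):
        """A pure-FFA organelle has a strictly higher 1711/1741 ratio than a
        pure-TAG organelle (constructed ordering oracle)."""
        ffa = Spectrum(refs64.spectrum("ffa").intensities + 1e-6, axis64)
        tag = Spectrum(refs64.spectrum("tag").intensities + 1e-6, axis64)
        assert band_ratio(ffa, LIPOLYTIC_RATIO) > band_ratio(tag, LIPOLYTIC_RATIO)

    def test_stack_map_and_invalid_denominator(self, axis64):
        data = np.ones((2, 2, 64))
        data[0, 0, :] = 0.0  # zero denominator pixel
        stack = fs.HyperStack(data, axis64)
        ratio_map = band_ratio(stack, LIPOLYTIC_RATIO)
        assert np.isnan(ratio_map[0, 0])
        assert ratio_map[1, 1] == pytest.approx(1.0)

    def test_out_of_span_wavenumber_rejected(self, axis64):
        spec = Spectrum(np.ones(64), axis64)
        with pytest.raises(ValueError):
            band_ratio(spec, RatioSpec(500, 1649))


class TestClassification:
    def test_median_cells(self):
        p = np.array([1.0, 3.0, 1.0, 3.0])
        l = np.array([1.0, 1.0, 3.0, 3.0])
        out = classify_groups(p, l)
        assert out.group == ["low_both", "high_proteolytic", "high_lipolytic", "high_both"]

    def test_exact_threshold_falls_low(self):
        out = classify_groups(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]),
                              thresholds=(2.0, 2.0))
        assert out.group[1] == "low_both"  # exactly at both thresholds
        assert out.group[2] == "high_both"

    def test_partition_exhaustive_and_exclusive(self, rng):
        p = rng.uniform(0, 2, 40)
        l = rng.uniform(0, 2, 40)
        out = classify_groups(p, l)
        cells = {"high_both", "high_proteolytic", "high_lipolytic", "low_both"}
        assert set(out.group) <= cells
        assert len(out.group) == 40

    def test_designed_subpopulations_recovered(self, refs64, axis64):
        """Three designed subpopulations (high proteolytic / high lipolytic /
        high both) recovered at >= 95 % accuracy with median thresholds."""
        rng = np.random.default_rng(17)
        names = refs64.names
        base = np.zeros(8)
        base[names.index("protein")] = 0.45
        base[names.index("tag")] = 0.45
        base[names.index("glycogen")] = 0.10

        def population(aa, ffa, n):
            comps = []
            for _ in range(n):
                c = base.copy()
                shift_aa = aa * rng.uniform(0.8, 1.2)
                shift_ffa = ffa * rng.uniform(0.8, 1.2)
                c[names.index("amino_acids")] += shift_aa
                c[names.index("protein")] -= shift_aa
                c[names.index("ffa")] += shift_ffa
                c[names.index("tag")] -= shift_ffa
                comps.append(c / c.sum())
            return np.array(comps)

        high, low = 0.30, 0.05
        comps = np.vstack([
            population(high, low, 40),   # high proteolytic
            population(low, high, 40),   # high lipolytic
            population(high, high, 40),  # high both
            population(low, low, 40),    # low both
        ])
        truth = (["high_proteolytic"] * 40 + ["high_lipolytic"] * 40
                 + ["high_both"] * 40 + ["low_both"] * 40)
        spectra = comps @ refs64.spectra
        spectra *= 1 + rng.normal(0, 0.02, spectra.shape)  # 2 % multiplicative noise
        table = SpectrumTable(
            axis=axis64, intensities=spectra,
            ids=[f"o{i}" for i in range(160)],
            size_px=np.full(160, 10), dc_mean=np.ones(160),
        )
        out = classify_groups(
            band_ratio(table, PROTEOLYTIC_RATIO), band_ratio(table, LIPOLYTIC_RATIO)
        )
        accuracy = np.mean([g == t for g, t in zip(out.group, truth)])
        assert accuracy >= 0.95

    def test_constant_ratio_degenerate_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            classify_groups(np.ones(4), np.array([1.0, 2, 3, 4.0]))


class TestZScore:
    def test_single_group_is_zero(self, rng):
        mat = rng.uniform(0, 1, (10, 20))
        z = zscore_profile({"all": mat})
        np.testing.assert_allclose(z["all"], 0.0, atol=1e-12)

    def test_two_equal_groups_antisymmetric(self, rng):
        a = rng.uniform(0, 1, (8, 15))
        b = rng.uniform(0, 1, (8, 15))
        z = zscore_profile({"a": a, "b": b})
        np.testing.assert_allclose(z["a"], -z["b"], atol=1e-12)

    def test_sizeweighted_mean_identity(self, rng):
        groups = {"a": rng.uniform(0, 1, (5, 12)), "b": rng.uniform(0, 1, (9, 12)),
                  "c": rng.uniform(0, 1, (3, 12))}
        z = zscore_profile(groups)
        weighted = sum(groups[g].shape[0] * z[g] for g in groups) / 17
        np.testing.assert_allclose(weighted, 0.0, atol=1e-12)

    def test_zero_variance_bin_flagged(self):
        mat = np.ones((4, 3))
        mat[:, 2] = [1, 2, 3, 4]
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_profile({"a": mat[:2], "b": mat[2:]})
        assert z["a"][0] == 0.0

    def test_scale_invariance_of_ratios_and_zscores(self, rng):
        mat = rng.uniform(0.5, 1.5, (6, 10))
        z1 = zscore_profile({"a": mat[:3], "b": mat[3:]})
        z2 = zscore_profile({"a": 4.2 * mat[:3], "b": 4.2 * mat[3:]})
        np.testing.assert_allclose(z1["a"], z2["a"], atol=1e-12)


class TestEmbedding:
    def test_duplicated_spectra_zero_intra_distance(self):
        x = np.tile(np.linspace(0, 1, 12), (6, 1))
        with pytest.warns(UserWarning, match="identical"):
            res = embed_and_distance(x, ["g"] * 6, seed=0, perplexity=2)
        assert res.intra_spectral["g"] == 0.0

    def test_separated_clusters_inter_exceeds_intra(self, rng):
        a = rng.normal(0, 0.1, (15, 10))
        b = rng.normal(5, 0.1, (15, 10))
        res = embed_and_distance(np.vstack([a, b]), ["a"] * 15 + ["b"] * 15, seed=1)
        assert res.inter_spectral > max(res.intra_spectral.values())
        assert res.inter_embedding > max(res.intra_embedding.values())

    def test_seeded_determinism(self, rng):
        x = rng.uniform(0, 1, (12, 8))
        r1 = embed_and_distance(x, ["a"] * 6 + ["b"] * 6, seed=3)
        r2 = embed_and_distance(x, ["a"] * 6 + ["b"] * 6, seed=3)
        np.testing.assert_array_equal(r1.embedding, r2.embedding)

    def test_too_few_spectra_config_error(self):
        with pytest.raises(ConfigError):
            embed_and_distance(np.ones((2, 5)), ["a", "b"], seed=0)
        with pytest.raises(ConfigError):
            embed_and_distance(np.ones((5, 5)), ["a"] * 5, seed=0, perplexity=10)


class TestChords:
    def test_perfect_correlations(self, rng):
        base = rng.uniform(0, 1, 30)
        mat = np.column_stack([base, 2 * base, 1 - base + 0j.real])
        chords = correlation_chords(mat, component_names=["a", "b", "c"])
        as_dict = {(i, j): r for i, j, r in chords}
        assert as_dict[("a", "b")] == pytest.approx(1.0)
        assert as_dict[("a", "c")] == pytest.approx(-1.0)

    def test_independent_components_yield_empty_set(self):
        rng = np.random.default_rng(123)
        mat = rng.uniform(0, 1, (200, 5))
        assert correlation_chords(mat) == []

    def test_symmetric_pairs_emitted_once(self, rng):
        mat = rng.uniform(0, 1, (20, 4))
        chords = correlation_chords(mat, threshold=-0.1 + 0)  # retain everything
        pairs = {frozenset((a, b)) for a, b, _ in chords}
        assert len(pairs) == len(chords) == 6

    def test_zero_variance_component_skipped(self, rng):
        mat = rng.uniform(0, 1, (10, 3))
        mat[:, 1] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            chords = correlation_chords(mat, threshold=-0.1)
        assert all("component_1" not in (a, b) for a, b, _ in chords)


class TestCompareGroups:
    def test_identical_groups_ns(self):
        out = compare_groups(np.ones(5), np.ones(5))
        assert out.p_value == 1.0
        assert out.stars == "ns"

    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, "ns"), (0.03, "*"), (0.005, "**"), (0.0005, "***"), (0.00002, "****")],
    )
    def test_star_binning(self, p, stars):
        assert p_to_stars(p) == stars

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.array([1.0]), np.array([1.0, 2.0]))

    def test_power_at_two_sigma_shift(self):
        """Power-simulation oracle: delta = 2 sigma, n = 30 per group gives
        p < 0.001 in >= 99 % of seeded replicates."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, 30)
            b = rng.normal(2.0, 1.0, 30)
            if compare_groups(a, b).p_value < 0.001:
                hits += 1
        assert hits >= 0.99 * n_rep

    def test_welch_matches_scipy(self, rng):
        from scipy import stats

        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 2, 20)
        out = compare_groups(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert out.statistic == pytest.approx(ref.statistic)
        assert out.p_value == pytest.approx(ref.pvalue)
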