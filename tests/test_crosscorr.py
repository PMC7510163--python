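import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandcc import (
    CCProfile,
    CrossCorrelation,
    GenomeSpec,
    merge_profiles,
    mscc_profile,
    ncc_profile,
)
from strandcc.mappability import MappabilityMask
from conftest import density_from_bools, naive_mscc, naive_ncc


def _random_density(rng, length=400, p=0.15):
    f = rng.random(length) < p
    g = rng.random(length) < p
    return f, g, density_from_bools(f, g)


class TestNCC:
    def test_self_correlation_is_one_at_zero_shift(self, rng):
        f = rng.random(200) < 0.3
        d = density_from_bools(f, f)
        prof = ncc_profile(d, shifts=[0])
        assert prof.r["chr1"][0] == pytest.approx(1.0, abs=1e-12)

    def test_shifted_copy_peaks_at_the_shift(self):
        f = np.array([1, 0, 0, 1, 0, 1, 0, 0] * 4, dtype=bool)
        g = np.zeros_like(f)
        g[3:] = f[:-3]  # g is f shifted right by 3
        d = density_from_bools(f, g)
        shifts = list(range(0, 8))
        prof = ncc_profile(d, shifts=shifts)
        oracle = naive_ncc(f, g, shifts)
        assert prof.r["chr1"][3] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(prof.r["chr1"], oracle, atol=1e-12)

    def test_matches_naive_pearson_on_random_instances(self, rng):
        shifts = list(range(0, 40))
        for _ in range(25):
            f, g, d = _random_density(rng, length=int(rng.integers(50, 400)))
            if not (f.any() and g.any()):
                continue
            prof = ncc_profile(d, shifts=shifts)
            oracle = naive_ncc(f, g, shifts)
            np.testing.assert_allclose(prof.r["chr1"], oracle, atol=1e-12)

    def test_all_zero_strand_is_undefined_everywhere(self):
        g = np.zeros(100, dtype=bool)
        g[[5, 30]] = True
        d = density_from_bools(np.zeros(100, dtype=bool), g)
        prof = ncc_profile(d, shifts=10)
        assert np.isnan(prof.r["chr1"]).all()

    def test_global_estimator_close_to_exact_for_sparse_data(self, rng):
        """The Bernoulli approximation: |exact - global| small for M << L."""
        length = 20_000
        f = np.zeros(length, dtype=bool)
        g = np.zeros(length, dtype=bool)
        f[rng.choice(length, 60, replace=False)] = True
        g[rng.choice(length, 60, replace=False)] = True
        d = density_from_bools(f, g)
        shifts = list(range(0, 20))
        exact = ncc_profile(d, shifts=shifts, estimator="exact").r["chr1"]
        approx = ncc_profile(d, shifts=shifts, estimator="global").r["chr1"]
        assert np.nanmax(np.abs(exact - approx)) <= 1e-3

    def test_coefficients_stay_in_unit_interval(self, rng):
        for _ in range(10):
            f, g, d = _random_density(rng)
            r = ncc_profile(d, shifts=30).r["chr1"]
            ok = np.isfinite(r)
            assert np.all(np.abs(r[ok]) <= 1.0 + 1e-12)


class TestMSCC:
    def test_all_ones_mask_reproduces_ncc(self, rng):
        """An unrestricted mask makes MSCC collapse to NCC bitwise.

        With read length 1 the placement-fit trimming at the chromosome
        ends vanishes, so the index sets coincide exactly; with longer
        reads the all-ones mask still loses the R-1 edge placements by
        construction, which the index-set oracle test covers.
        """
        f, g, _ = _random_density(rng, length=300)
        shifts = list(range(0, 30))
        d1 = density_from_bools(f, g, read_length=1)
        mask1 = MappabilityMask.all_mappable(d1.genome, 1)
        ncc1 = ncc_profile(d1, shifts=shifts).r["chr1"]
        mscc1 = mscc_profile(d1, mask1, shifts=shifts).r["chr1"]
        np.testing.assert_array_equal(ncc1, mscc1)

    def test_zero_mask_is_undefined_everywhere(self, rng):
        f, g, d = _random_density(rng, length=100)
        genome = d.genome
        mask = MappabilityMask(
            genome, d.read_length, {"chr1": np.zeros(100, dtype=bool)}
        )
        prof = mscc_profile(d, mask, shifts=10)
        assert np.isnan(prof.r["chr1"]).all()

    def test_matches_index_set_pearson_oracle(self, rng):
        shifts = list(range(0, 25))
        for _ in range(15):
            f, g, d = _random_density(rng, length=250)
            base = rng.random(250) < 0.5
            mask = MappabilityMask(d.genome, d.read_length, {"chr1": base})
            prof = mscc_profile(d, mask, shifts=shifts)
            oracle = naive_mscc(
                f, g, mask.forward["chr1"], mask.reverse["chr1"], shifts
            )
            np.testing.assert_allclose(prof.r["chr1"], oracle, atol=1e-12)

    def test_read_length_mismatch_rejected(self, rng):
        f, g, d = _random_density(rng, length=100)
        mask = MappabilityMask.all_mappable(d.genome, d.read_length + 1)
        with pytest.raises(ValueError, match="read length"):
            mscc_profile(d, mask, shifts=5)


class TestMerge:
    def test_single_chromosome_merge_is_identity(self, rng):
        f, g, d = _random_density(rng)
        prof = merge_profiles(ncc_profile(d, shifts=20))
        ok = np.isfinite(prof.r["chr1"])
        np.testing.assert_allclose(
            prof.merged[ok], prof.r["chr1"][ok], atol=1e-12
        )

    def test_identical_coefficients_merge_to_themselves(self):
        genome = GenomeSpec(("a", "b"), (100, 300))
        prof = CCProfile(
            shifts=np.array([0, 1]), genome=genome, read_length=5,
            mode="NCC", estimator="exact",
            r={"a": np.array([0.2, 0.4]), "b": np.array([0.2, 0.4])},
            counts={"a": np.array([100, 99]), "b": np.array([300, 299])},
        )
        merge_profiles(prof)
        np.testing.assert_allclose(prof.merged, [0.2, 0.4], atol=1e-12)

    def test_weighted_fisher_average_matches_hand_calculation(self):
        # oracle: z = arctanh(r), zbar = (997 z1 + 2997 z2)/3994, tanh(zbar)
        genome = GenomeSpec(("a", "b"), (2000, 4000))
        prof = CCProfile(
            shifts=np.array([0]), genome=genome, read_length=5,
            mode="NCC", estimator="exact",
            r={"a": np.array([0.1]), "b": np.array([0.3])},
            counts={"a": np.array([1000]), "b": np.array([3000])},
        )
        merge_profiles(prof)
        assert prof.merged[0] == pytest.approx(0.25177037121475054, abs=1e-12)

    def test_undefined_chromosomes_are_excluded_per_shift(self):
        genome = GenomeSpec(("a", "b"), (100, 100))
        prof = CCProfile(
            shifts=np.array([0, 1]), genome=genome, read_length=5,
            mode="NCC", estimator="exact",
            r={"a": np.array([0.5, np.nan]), "b": np.array([np.nan, np.nan])},
            counts={"a": np.array([50, 50]), "b": np.array([50, 50])},
        )
        merge_profiles(prof)
        assert prof.merged[0] == pytest.approx(0.5, abs=1e-12)
        assert math.isnan(prof.merged[1])

    def test_perfect_correlation_is_clamped_with_warning(self):
        genome = GenomeSpec(("a",), (100,))
        prof = CCProfile(
            shifts=np.array([0]), genome=genome, read_length=5,
            mode="NCC", estimator="exact",
            r={"a": np.array([1.0])}, counts={"a": np.array([50])},
        )
        with pytest.warns(UserWarning, match="clamping"):
            merge_profiles(prof)
        assert prof.merged[0] == pytest.approx(1.0, abs=1e-6)

    def test_merged_lies_within_contributing_range(self, rng):
        genome = GenomeSpec(("a", "b", "c"), (500, 500, 500))
        for _ in range(20):
            rs = rng.uniform(-0.8, 0.8, 3)
            counts = rng.integers(10, 500, 3)
            prof = CCProfile(
                shifts=np.array([0]), genome=genome, read_length=5,
                mode="NCC", estimator="exact",
                r={c: np.array([rs[i]]) for i, c in enumerate("abc")},
                counts={c: np.array([counts[i]]) for i, c in enumerate("abc")},
            )
            merge_profiles(prof)
            assert rs.min() - 1e-12 <= prof.merged[0] <= rs.max() + 1e-12


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), length=st.integers(30, 200),
       max_shift=st.integers(0, 50))
def test_exact_estimator_equals_oracle_property(seed, length, max_shift):
    """Property form of the oracle equivalence over random instances."""
    rng = np.random.default_rng(seed)
    f = rng.random(length) < 0.3
    g = rng.random(length) < 0.3
    if not (f.any() and g.any()):
        return
    shifts = list(range(0, min(max_shift, length - 4) + 1))
    d = density_from_bools(f, g)
    prof = ncc_profile(d, shifts=shifts)
    oracle = naive_ncc(f, g, shifts)
    np.testing.assert_allclose(prof.r["chr1"], oracle, atol=1e-12)


class TestProfileIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        genome = GenomeSpec(("chr1", "chr2"), (500, 400))
        f1 = rng.random(500) < 0.2
        g1 = rng.random(500) < 0.2
        from strandcc import BinaryDensity

        d = BinaryDensity(
            genome=genome, read_length=10,
            forward={"chr1": np.flatnonzero(f1),
                     "chr2": np.flatnonzero(rng.random(400) < 0.2)},
            reverse={"chr1": np.flatnonzero(g1),
                     "chr2": np.flatnonzero(rng.random(400) < 0.2)},
        )
        prof = merge_profiles(ncc_profile(d, shifts=30))
        path = str(tmp_path / "profile.tsv")
        prof.to_tsv(path)
        back = CCProfile.from_tsv(path)
        assert back.mode == "NCC" and back.read_length == 10
        np.testing.assert_allclose(back.merged, prof.merged, rtol=1e-10)
        for c in ("chr1", "chr2"):
            np.testing.assert_allclose(back.r[c], prof.r[c], rtol=1e-10)
            np.testing.assert_array_equal(back.counts[c], prof.counts[c])


class TestModelAPI:
    def test_fit_returns_profiles_and_summary(self, rng):
        f, g, d = _random_density(rng, length=800)
        mask = MappabilityMask.all_mappable(d.genome, d.read_length)
        res = CrossCorrelation(d, mask, shifts=40).fit()
        assert res.ncc.merged is not None
        assert res.mscc is not None
        assert "MSCC" in res.summary()
        assert res.primary is res.mscc
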