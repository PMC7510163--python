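import numpy as np
import pytest

from strandcc import (
    GenomeSpec,
    ModelParams,
    compute_exact_mappability,
    simulate_experiment,
    simulate_genome,
    simulate_mappability,
    simulate_reads,
    simulate_sites,
)
from strandcc.simulate import apply_mappability, read_fasta, sample_without_replacement, write_fasta


class TestSampling:
    @pytest.mark.parametrize("n,k", [(100, 0), (100, 5), (100, 100), (10**6, 50)])
    def test_without_replacement_properties(self, n, k):
        rng = np.random.default_rng(7)
        out = sample_without_replacement(rng, n, k)
        assert out.size == k
        assert np.unique(out).size == k
        if k:
            assert out.min() >= 0 and out.max() < n

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            sample_without_replacement(np.random.default_rng(0), 10, 11)

    def test_deterministic_given_seed(self):
        a = sample_without_replacement(np.random.default_rng(3), 10**6, 100)
        b = sample_without_replacement(np.random.default_rng(3), 10**6, 100)
        assert np.array_equal(a, b)


class TestSites:
    def test_single_site_geometry(self):
        genome = GenomeSpec(("c",), (10_000,))
        layout = simulate_sites(genome, 1, w=100, d=200, seed=4)
        assert layout.n == 1
        a = layout.anchors["c"][0]
        ef = layout.forward_positions("c")
        eg = layout.reverse_positions("c")
        assert ef.size == eg.size == 100
        assert ef[0] == a and ef[-1] == a + 99
        assert eg[0] == a + 300  # gap d between E_f end and E_g start
        # paired 5' ends sit exactly d + w apart
        np.testing.assert_array_equal(eg - ef, np.full(100, 300))

    def test_empty_layout(self):
        genome = GenomeSpec(("c",), (10_000,))
        assert simulate_sites(genome, 0, seed=0).n == 0

    def test_footprints_are_disjoint_exhaustively(self):
        genome = GenomeSpec(("c",), (200_000,))
        layout = simulate_sites(genome, 200, w=100, d=200, seed=11)
        ivals = layout.peak_intervals("c")
        # brute-force pairwise overlap check
        for i in range(len(ivals)):
            for j in range(i + 1, len(ivals)):
                s = max(ivals[i, 0], ivals[j, 0])
                e = min(ivals[i, 1], ivals[j, 1])
                assert s >= e, "footprints overlap"

    def test_too_many_sites_rejected(self):
        genome = GenomeSpec(("c",), (10_000,))
        with pytest.raises(ValueError, match="reduce n"):
            simulate_sites(genome, 20, w=100, d=200, seed=0)

    def test_multi_chromosome_apportioning(self):
        genome = GenomeSpec(("a", "b"), (100_000, 300_000))
        layout = simulate_sites(genome, 40, seed=5)
        assert layout.n == 40
        assert layout.anchors["b"].size == 30  # proportional to length


class TestReads:
    def setup_method(self):
        self.genome = GenomeSpec(("c",), (100_000,))

    def test_deterministic_counts_match_allocation(self):
        """M=1000, alpha=0.2: exactly 100 signal + 400 noise per strand."""
        params = ModelParams(G=100_000, n=20, w=100, d=200, alpha=0.2, M=1000)
        layout = simulate_sites(self.genome, 20, seed=1)
        d = simulate_reads(layout, params, seed=2)
        ef = set(layout.forward_positions("c"))
        eg = set(layout.reverse_positions("c"))
        f = d.forward["c"]
        g = d.reverse["c"]
        # 500 distinct draws per strand, minus rare signal/noise collisions
        assert 497 <= f.size <= 500 and 497 <= g.size <= 500
        assert sum(1 for p in f if p in ef) >= 100  # 100 signal + noise hits
        assert sum(1 for p in g if p in eg) >= 100
        assert d.n_records == 1000

    def test_alpha_one_places_all_reads_in_regions(self):
        params = ModelParams(G=100_000, n=20, w=100, d=200, alpha=1.0, M=1000)
        layout = simulate_sites(self.genome, 20, seed=1)
        d = simulate_reads(layout, params, seed=3)
        ef = set(layout.forward_positions("c"))
        eg = set(layout.reverse_positions("c"))
        assert all(p in ef for p in d.forward["c"])
        assert all(p in eg for p in d.reverse["c"])

    def test_alpha_zero_is_uniform_noise(self):
        params = ModelParams(G=100_000, n=20, w=100, d=200, alpha=0.0, M=1000)
        layout = simulate_sites(self.genome, 20, seed=1)
        d = simulate_reads(layout, params, seed=4)
        assert d.forward["c"].size == 500  # M/2 per strand, distinct
        assert d.reverse["c"].size == 500

    def test_per_strand_totals_equal_pre_collapse(self):
        """The model's first identity: both strands carry M/2 reads; only
        cross-component duplicate positions may collapse."""
        params = ModelParams(G=100_000, n=20, w=100, d=200, alpha=0.4, M=2000)
        layout = simulate_sites(self.genome, 20, seed=1)
        d = simulate_reads(layout, params, seed=5)
        assert 995 <= d.forward["c"].size <= 1000
        assert 995 <= d.reverse["c"].size <= 1000
        assert d.n_records == 2000  # M/2 per strand before binarisation

    def test_saturated_regime_fills_the_regions(self):
        params = ModelParams(G=100_000, n=5, w=100, d=200, alpha=1.0, M=10_000)
        layout = simulate_sites(self.genome, 5, seed=1)
        d = simulate_reads(layout, params, seed=6)
        assert np.array_equal(d.forward["c"], layout.forward_positions("c"))
        assert d.n_positions == 1000  # 2 * n * w distinct positions
        assert d.n_records == 10_000  # surplus reads are duplicates

    def test_multinomial_allocation_varies_counts(self):
        params = ModelParams(G=100_000, n=20, w=100, d=200, alpha=0.5, M=2000)
        layout = simulate_sites(self.genome, 20, seed=1)
        sizes = {
            simulate_reads(layout, params, seed=s, allocation="multinomial")
            .forward["c"]
            .size
            for s in range(5)
        }
        assert len(sizes) > 1  # binomial signal split actually varies

    def test_layout_params_mismatch_rejected(self):
        params = ModelParams(G=100_000, n=19, w=100, d=200, alpha=0.5, M=1000)
        layout = simulate_sites(self.genome, 20, seed=1)
        with pytest.raises(ValueError, match="disagree"):
            simulate_reads(layout, params, seed=0)


class TestGenomeSim:
    def test_repeat_free_genome_is_fully_mappable(self):
        seqs = simulate_genome({"c": 2000}, repeat_fraction=0.0, seed=8)
        mask = compute_exact_mappability(seqs, 50)
        assert mask.forward["c"][: 2000 - 49].all()

    def test_saturating_repeats_kill_mappability(self):
        seqs = simulate_genome(
            {"c": 2000}, repeat_fraction=1.0, repeat_unit_length=40, seed=8
        )
        mask = compute_exact_mappability(seqs, 50)
        assert mask.forward["c"].mean() < 0.05

    def test_mixed_genome_unmappable_fraction_tracks_request(self):
        frac = 0.4
        seqs = simulate_genome(
            {"c": 5000}, repeat_fraction=frac, repeat_unit_length=100, seed=9
        )
        mask = compute_exact_mappability(seqs, 30)
        zero_frac = 1.0 - mask.forward["c"][: 5000 - 29].mean()
        # repeat copies may overlap, so coverage lands near but not at frac
        assert abs(zero_frac - frac) <= 0.15

    def test_fasta_round_trip(self, tmp_path):
        seqs = simulate_genome({"a": 137, "b": 71}, seed=1)
        path = str(tmp_path / "g.fa")
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs


class TestMaskSimAndFilter:
    def test_synthetic_mask_hits_requested_fraction(self):
        genome = GenomeSpec(("c",), (200_000,))
        mask = simulate_mappability(genome, 50, unmappable_fraction=0.3, seed=2)
        # constructor trims the tail, so compare on the valid span
        frac = 1.0 - mask.forward["c"][: 200_000 - 49].mean()
        assert abs(frac - 0.3) < 0.05

    def test_apply_mappability_drops_masked_positions(self):
        genome = GenomeSpec(("c",), (100_000,))
        params = ModelParams(G=100_000, n=20, w=100, d=200, alpha=0.5, M=2000)
        mask = simulate_mappability(genome, 50, unmappable_fraction=0.5, seed=3)
        _, dens = simulate_experiment(genome, params, seed=4, mask=mask)
        assert mask.forward["c"][dens.forward["c"]].all()
        assert mask.reverse["c"][dens.reverse["c"]].all()
        # roughly half the reads survive a half-unmappable genome
        assert 0.25 < dens.n_positions / 2000 < 0.75

    def test_filter_preserves_read_length_and_genome(self):
        genome = GenomeSpec(("c",), (50_000,))
        params = ModelParams(G=50_000, n=10, w=100, d=200, alpha=0.5, M=1000)
        layout = simulate_sites(genome, 10, seed=1)
        dens = simulate_reads(layout, params, seed=1)
        mask = simulate_mappability(genome, 50, unmappable_fraction=0.2, seed=1)
        out = apply_mappability(dens, mask)
        assert out.read_length == dens.read_length
        assert out.genome is dens.genome
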