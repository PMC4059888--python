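"""Coverage binning, profiles, clustering, correlation and bivalence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cobind import (
    CoverageTrack,
    DensityMatrix,
    GeneUniverse,
    PeakSet,
    ReadSet,
    build_coverage,
    call_bivalent_sites,
    kmeans_cluster,
    metagene_profile,
    normalize_to_input,
    peak_density_correlation,
    peak_matrix,
    simulate_binding_peaks,
    simulate_reads,
    tss_matrix,
)

SIZES = {"c1": 100_000}


def _reads(rows, read_length=50):
    return ReadSet(
        reads=pd.DataFrame(rows, columns=["chrom", "pos", "strand"]),
        read_length=read_length,
    )


class TestBuildCoverage:
    def test_plus_read_extends_rightward_over_8_bins(self):
        track = build_coverage(_reads([("c1", 0, "+")]), SIZES, extension=200, bin_size=25)
        assert track.bins["c1"][:8].tolist() == [1] * 8
        assert track.bins["c1"][8:].sum() == 0

    def test_minus_read_extends_leftward_symmetrically(self):
        track = build_coverage(_reads([("c1", 199, "-")]), SIZES, extension=200, bin_size=25)
        assert track.bins["c1"][:8].tolist() == [1] * 8
        assert track.bins["c1"][8:].sum() == 0

    def test_total_tag_conservation(self):
        rng = np.random.default_rng(0)
        rows = [("c1", int(p), s) for p, s in zip(
            rng.integers(1_000, 99_000, 500), rng.choice(["+", "-"], 500))]
        track = build_coverage(_reads(rows), SIZES)
        # each 200-bp extension covers 8 or 9 25-bp bins
        assert 8 * 500 <= track.total_tags <= 9 * 500

    def test_uniform_reads_poisson_rate(self):
        rng = np.random.default_rng(1)
        n = 4_000
        rows = [("c1", int(p), "+") for p in rng.integers(0, 99_800, n)]
        track = build_coverage(_reads(rows), SIZES)
        interior = track.bins["c1"][10:-10]
        lam = interior.mean()
        # a 25-bp bin is overlapped by extensions starting in a 224-bp span
        expected = n * (200 + 25 - 1) / 100_000
        assert abs(lam - expected) < 4 * np.sqrt(expected / len(interior)) + 0.1

    def test_read_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            build_coverage(_reads([("c1", 100_000, "+")]), SIZES)

    def test_extension_must_cover_read(self):
        with pytest.raises(ValueError, match="extension"):
            build_coverage(_reads([("c1", 0, "+")], read_length=300), SIZES, extension=200)


class TestNormalize:
    def _track(self, values):
        arr = np.asarray(values, dtype=float)
        return CoverageTrack(bin_size=25, bins={"c1": arr}, extension=200,
                             total_tags=float(arr.sum()))

    def test_self_ratio_is_one_and_log2_zero(self):
        t = self._track([4, 8, 2, 6])
        assert np.allclose(normalize_to_input(t, t).bins["c1"], 1.0)
        assert np.allclose(normalize_to_input(t, t, log2=True).bins["c1"], 0.0)

    def test_zero_input_bin_stays_finite(self):
        ip = self._track([10, 10])
        inp = self._track([0, 20])
        out = normalize_to_input(ip, inp, pseudocount=1.0)
        assert np.isfinite(out.bins["c1"]).all()

    def test_depth_scale_invariance(self):
        # exact without the additive pseudocount (which deliberately does
        # not scale with depth), near-exact at realistic counts with it
        ip = self._track([30, 90, 60, 120])
        inp = self._track([20, 40, 80, 60])
        doubled = self._track([60, 180, 120, 240])
        a = normalize_to_input(ip, inp, pseudocount=0.0).bins["c1"]
        b = normalize_to_input(doubled, inp, pseudocount=0.0).bins["c1"]
        assert np.allclose(a, b)
        a1 = normalize_to_input(ip, inp, pseudocount=1.0).bins["c1"]
        b1 = normalize_to_input(doubled, inp, pseudocount=1.0).bins["c1"]
        assert np.allclose(a1, b1, rtol=0.05)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            normalize_to_input(self._track([1, 2]), self._track([1, 2, 3]))


class TestMatrices:
    def _delta_track(self, center, size=100_000, value=5.0):
        arr = np.zeros(size // 25)
        arr[center // 25] = value
        return CoverageTrack(bin_size=25, bins={"c1": arr}, extension=200, total_tags=value)

    def _one_gene(self, strand, tss=50_000):
        tts = tss + 10_000 if strand == "+" else tss - 10_000
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["c1"], "strand": [strand], "tss": [tss], "tts": [tts]}
        )
        return GeneUniverse(genes=genes, chrom_sizes={"c1": 100_000})

    def test_signal_at_tss_lands_in_center_column(self):
        u = self._one_gene("+")
        m = tss_matrix(self._delta_track(50_000), u, flank=2_000)
        assert m.values.shape == (1, 160)
        assert np.nanargmax(m.values[0]) == 80

    def test_minus_strand_row_mirrors_plus(self):
        offset = 500  # signal 500 bp right of the TSS
        track = self._delta_track(50_000 + offset)
        plus = tss_matrix(track, self._one_gene("+"), flank=2_000).values[0]
        minus = tss_matrix(track, self._one_gene("-"), flank=2_000).values[0]
        assert np.allclose(np.nan_to_num(minus), np.nan_to_num(plus[::-1]))

    def test_edge_rows_are_nan_padded(self):
        u = self._one_gene("+", tss=100)
        m = tss_matrix(self._delta_track(100), u, flank=2_000)
        assert np.isnan(m.values[0][:70]).all()  # bins left of the chromosome start

    def test_peak_matrix_centers_on_summits(self):
        peaks = PeakSet("f", pd.DataFrame(
            [{"chrom": "c1", "start": 49_900, "end": 50_100, "summit": 50_000,
              "tag_density": 1.0, "score": 1.0}]))
        m = peak_matrix(self._delta_track(50_000), peaks, flank=1_000)
        assert np.nanargmax(m.values[0]) == 40

    def test_factor_profile_shapes_point_vs_downstream(self, universe_small):
        peaks, _ = simulate_binding_peaks(
            universe_small, n_peaks=120, feature_mix=(1.0, 0.0, 0.0), seed=3
        )
        strands = ["+"] * len(peaks)
        kw = dict(chrom_sizes=universe_small.chrom_sizes, seed=4, strands=strands)
        sharp = build_coverage(
            simulate_reads(peaks, 40, profile_shape="point", **kw),
            universe_small.chrom_sizes)
        spread = build_coverage(
            simulate_reads(peaks, 40, profile_shape="downstream_spread", spread_scale=600, **kw),
            universe_small.chrom_sizes)
        m_sharp = peak_matrix(sharp, peaks, flank=2_000).mean_profile()
        m_spread = peak_matrix(spread, peaks, flank=2_000).mean_profile()
        center = len(m_sharp) // 2
        assert abs(int(np.argmax(m_sharp)) - center) <= 2
        # downstream-spread mass sits right of center
        com_spread = np.average(np.arange(len(m_spread)), weights=m_spread)
        assert com_spread > center + 2


class TestMetagene:
    def test_uniform_coverage_flat_profile(self, universe_small):
        bins = {c: np.full(int(np.ceil(s / 25)), 3.0)
                for c, s in universe_small.chrom_sizes.items()}
        track = CoverageTrack(bin_size=25, bins=bins, extension=200, total_tags=1.0)
        prof = metagene_profile(track, universe_small)
        assert np.allclose(prof, 3.0)

    def test_gene_body_only_signal_elevates_gb_bins(self, universe_small):
        bins = {c: np.zeros(int(np.ceil(s / 25)))
                for c, s in universe_small.chrom_sizes.items()}
        for row in universe_small.genes.itertuples(index=False):
            lo, hi = sorted((row.tss, row.tts))
            bins[row.chrom][lo // 25: hi // 25 + 1] = 2.0
        track = CoverageTrack(bin_size=25, bins=bins, extension=200, total_tags=1.0)
        prof = metagene_profile(track, universe_small, up=1_000, down=1_000, gb_bins=40)
        gb = prof[40:80]
        flanks = np.concatenate([prof[:30], prof[-30:]])  # clear of boundary bins
        assert gb.mean() > 1.9
        assert flanks.mean() < 0.5

    def test_length_invariant_rescaling(self):
        # two genes, lengths 10 kb and 50 kb, same relative signal pattern
        sizes = {"c1": 200_000}
        genes = pd.DataFrame(
            {"gene_id": ["a", "b"], "chrom": ["c1", "c1"], "strand": ["+", "+"],
             "tss": [20_000, 100_000], "tts": [30_000, 150_000]}
        )
        u = GeneUniverse(genes=genes, chrom_sizes=sizes)
        bins = np.zeros(8_000)
        for tss, tts in ((20_000, 30_000), (100_000, 150_000)):
            length = tts - tss
            # signal in the first half of the body only
            bins[tss // 25: (tss + length // 2) // 25] = 4.0
        track = CoverageTrack(bin_size=25, bins={"c1": bins}, extension=200, total_tags=1.0)
        single = []
        for gid in ("a", "b"):
            sub = GeneUniverse(genes=genes[genes["gene_id"] == gid].reset_index(drop=True),
                               chrom_sizes=sizes)
            single.append(metagene_profile(track, sub, gb_bins=20))
        # identical scaled body profiles despite 5x length difference
        assert np.allclose(single[0][40:60], single[1][40:60], atol=0.5)


class TestKMeans:
    def _planted(self, n_rows=60, n_cols=40, seed=0):
        rng = np.random.default_rng(seed)
        a = np.abs(rng.normal(0.1, 0.02, (n_rows // 2, n_cols)))
        a[:, n_cols // 2] += 5.0  # sharp center archetype
        b = np.abs(rng.normal(0.1, 0.02, (n_rows - n_rows // 2, n_cols)))
        b[:, 3 * n_cols // 4:] += 5.0  # downstream archetype
        vals = np.vstack([a, b])
        truth = np.array([0] * (n_rows // 2) + [1] * (n_rows - n_rows // 2))
        m = DensityMatrix(values=vals, row_ids=[f"r{i}" for i in range(n_rows)],
                          flank=n_cols * 25 // 2, bin_size=25)
        return m, truth

    def test_separable_archetypes_recovered_exactly(self):
        m, truth = self._planted()
        ca = kmeans_cluster([m], k=2, seed=1)
        assert adjusted_rand_score(truth, ca.labels) == 1.0

    def test_k1_gives_global_mean_profile(self):
        m, _ = self._planted()
        ca = kmeans_cluster([m], k=1, seed=0)
        assert set(ca.labels) == {1}
        scaled = m.values / m.values.mean()
        assert np.allclose(ca.cluster_profiles[0], scaled.mean(axis=0))

    def test_fixed_seed_and_row_order_invariance(self):
        m, _ = self._planted()
        a = kmeans_cluster([m], k=2, seed=5).labels
        b = kmeans_cluster([m], k=2, seed=5).labels
        assert (a == b).all()
        perm = np.random.default_rng(0).permutation(len(a))
        m_perm = DensityMatrix(values=m.values[perm], row_ids=[m.row_ids[i] for i in perm],
                               flank=m.flank, bin_size=m.bin_size)
        c = kmeans_cluster([m_perm], k=2, seed=5).labels
        assert (c == a[perm]).all()

    def test_k_exceeding_rows_rejected(self):
        m, _ = self._planted(n_rows=4)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster([m], k=10, seed=0)


class TestCorrelation:
    def _tracks_with_rho(self, rho, n=5_000, seed=0):
        rng = np.random.default_rng(seed)
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([5, 5], cov, size=n)
        bins_a = np.zeros(n)
        bins_b = np.zeros(n)
        bins_a[:] = 2.0 ** xy[:, 0]
        bins_b[:] = 2.0 ** xy[:, 1]
        sizes = {"c1": n * 25}
        ta = CoverageTrack(bin_size=25, bins={"c1": bins_a}, extension=200,
                           total_tags=float(bins_a.sum()), normalized=True, log2=False)
        tb = CoverageTrack(bin_size=25, bins={"c1": bins_b}, extension=200,
                           total_tags=float(bins_b.sum()), normalized=True, log2=False)
        peaks = PeakSet("f", pd.DataFrame(
            {"chrom": "c1", "start": np.arange(n) * 25, "end": np.arange(n) * 25 + 25,
             "summit": np.arange(n) * 25 + 12, "tag_density": 1.0, "score": 1.0}))
        return ta, tb, peaks

    def test_identical_tracks_r_one(self):
        ta, _, peaks = self._tracks_with_rho(0.0)
        r, p, _ = peak_density_correlation(ta, ta, peaks)
        assert r == pytest.approx(1.0)

    def test_planted_correlation_recovered(self):
        # log2 of the densities is bivariate normal with rho = 0.5
        ta, tb, peaks = self._tracks_with_rho(0.5, seed=2)
        la = CoverageTrack(25, {"c1": np.log2(ta.bins["c1"])}, 200, 1.0, True, True)
        lb = CoverageTrack(25, {"c1": np.log2(tb.bins["c1"])}, 200, 1.0, True, True)
        r, p, _ = peak_density_correlation(la, lb, peaks)
        assert r == pytest.approx(0.5, abs=0.03)
        assert p < 1e-100

    def test_constant_vector_rejected(self):
        n = 10
        const = CoverageTrack(25, {"c1": np.full(n, 2.0)}, 200, 2.0 * n)
        var = CoverageTrack(25, {"c1": np.arange(n, dtype=float)}, 200, 45.0)
        peaks = PeakSet("f", pd.DataFrame(
            {"chrom": "c1", "start": np.arange(n) * 25, "end": np.arange(n) * 25 + 25,
             "summit": np.arange(n) * 25 + 12, "tag_density": 1.0, "score": 1.0}))
        with pytest.raises(ValueError, match="constant"):
            peak_density_correlation(const, var, peaks)


class TestBivalence:
    def _matrix(self, means, seed=0, n_cols=20):
        rng = np.random.default_rng(seed)
        vals = np.abs(rng.normal(0, 0.01, (len(means), n_cols))) + np.asarray(means)[:, None]
        return DensityMatrix(values=vals, row_ids=[f"s{i}" for i in range(len(means))],
                             flank=n_cols * 25 // 2, bin_size=25)

    def test_planted_bivalent_rows_recovered_exactly(self):
        high = [2.0, 2.0, 0.1, 2.0]
        marks = {
            "H3K4me3": self._matrix(high, seed=1),
            "H3K27me3": self._matrix([2.0, 0.1, 2.0, 2.0], seed=2),
            "Ezh2": self._matrix([2.0, 2.0, 2.0, 2.0], seed=3),
        }
        out = call_bivalent_sites(marks, threshold=1.0)
        assert out["bivalent"].tolist() == [True, False, False, True]

    def test_all_background_zero_calls(self):
        marks = {m: self._matrix([0.05] * 6, seed=i) for i, m in
                 enumerate(["H3K4me3", "H3K27me3", "Ezh2"])}
        out = call_bivalent_sites(marks, threshold=1.0)
        assert not out["bivalent"].any()

    def test_missing_mark_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            call_bivalent_sites({"H3K4me3": self._matrix([1.0])}, threshold=0.5)

    def test_factor_cooccurrence_counts_recovered(self):
        # planted: sites 0,1 bivalent; factor A bound at 0,2; A-only bivalent = {0}
        marks = {m: self._matrix([2, 2, 0.1, 0.1], seed=i)
                 for i, m in enumerate(["H3K4me3", "H3K27me3", "Ezh2"])}
        factors = {"A": self._matrix([2, 0.1, 2, 0.1], seed=7),
                   "B": self._matrix([0.1, 2, 0.1, 0.1], seed=8)}
        out = call_bivalent_sites(marks, threshold=1.0, factor_matrices=factors)
        a_only_biv = out["bivalent"] & out["A_bound"] & ~out["B_bound"]
        assert a_only_biv.tolist() == [True, False, False, False]
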