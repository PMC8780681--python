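import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragend.fragmentomics import (
    DEFAULT_EPS,
    N_POSITIONS,
    EndProfile,
    PeakPair,
    assemble_features,
    build_profile,
    detect_all_peaks,
    detect_peaks,
    fragmentation_score,
    motif_frequencies,
    read_peaks_tsv,
    write_peaks_tsv,
)
from fragend.synthetic import MOTIFS, CohortConfig, generate_cohort


def oracle_profile(positions):
    """Independent counting loop."""
    counts = [0] * N_POSITIONS
    for p in positions:
        counts[int(p)] += 1
    return counts


def oracle_fs(counts, p1, p2, w, eps):
    """Brute-force windowed summation + log ratio."""
    c1 = sum(counts[max(0, p1 - w) : min(300, p1 + w) + 1])
    c2 = sum(counts[max(0, p2 - w) : min(300, p2 + w) + 1])
    return math.log2((c1 + eps) / (c2 + eps))


class TestBuildProfile:
    def test_simple_tally(self):
        prof = build_profile([50, 50, 180])
        assert prof.counts[50] == 2
        assert prof.counts[180] == 1
        assert prof.total == 3

    def test_empty_is_zero_profile(self):
        prof = build_profile([])
        assert prof.total == 0
        assert prof.counts.shape == (N_POSITIONS,)

    def test_matches_naive_tally_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pos = rng.integers(0, 301, size=rng.integers(0, 500))
            assert build_profile(pos).counts.tolist() == oracle_profile(pos)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            build_profile([301])


class TestDetectPeaks:
    def test_spikes_on_zero_background(self):
        counts = np.zeros(N_POSITIONS, dtype=int)
        counts[50] = 100
        counts[180] = 80
        peaks = detect_peaks(EndProfile("R", counts), smooth_halfwidth=0)
        assert (peaks.peak1_pos, peaks.peak2_pos) == (50, 180)

    def test_uniform_profile_low_tie_break(self):
        counts = np.ones(N_POSITIONS, dtype=int)
        peaks = detect_peaks(EndProfile("R", counts), smooth_halfwidth=0)
        assert (peaks.peak1_pos, peaks.peak2_pos) == (0, 100)

    def test_all_zero_window_midpoint(self, caplog):
        counts = np.zeros(N_POSITIONS, dtype=int)
        counts[150] = 10
        with caplog.at_level("WARNING"):
            peaks = detect_peaks(EndProfile("R", counts), smooth_halfwidth=0)
        assert peaks.peak1_pos == 49  # midpoint of [0, 99]
        assert peaks.peak2_pos == 150
        assert "all-zero" in caplog.text

    def test_smoothing_prefers_broad_peak(self):
        # single-bin spike vs. a broad 5-bin hill with more mass
        counts = np.zeros(N_POSITIONS, dtype=int)
        counts[20] = 30
        counts[58:63] = 25
        peaks = detect_peaks(EndProfile("R", counts), smooth_halfwidth=2)
        assert abs(peaks.peak1_pos - 60) <= 1

    def test_planted_mode_recovery(self):
        """Pooled synthetic profiles: detected peaks within 3 bp of planted modes."""
        cfg = CohortConfig(
            n_regions=10, n_informative_regions=0, n_healthy=2, n_cancer=2,
            batch_sizes=(4,), molecules_per_region_mean=25000.0, seed=1,
        )
        records, truth, _ = generate_cohort(cfg)
        peaks = detect_all_peaks(records, sorted(truth.region_models))
        for rid, model in truth.region_models.items():
            assert abs(peaks[rid].peak1_pos - model.mu1) <= 3
            assert abs(peaks[rid].peak2_pos - model.mu2) <= 3


class TestFragmentationScore:
    @staticmethod
    def _profile_from_window_counts(c1, c2, p1=50, p2=180, w=5):
        counts = np.zeros(N_POSITIONS, dtype=int)
        counts[p1] = c1
        counts[p2] = c2
        return EndProfile("R", counts), PeakPair("R", p1, p2, w)

    def test_equal_counts_zero_score(self):
        prof, peaks = self._profile_from_window_counts(40, 40)
        assert fragmentation_score(prof, peaks) == pytest.approx(0.0)

    def test_80_20_ratio_approaches_two(self):
        prof, peaks = self._profile_from_window_counts(80, 20)
        assert fragmentation_score(prof, peaks, eps=1e-12) == pytest.approx(2.0)

    def test_matches_windowed_count_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            counts = rng.poisson(3.0, size=N_POSITIONS)
            p1 = int(rng.integers(0, 100))
            p2 = int(rng.integers(100, 301))
            w = int(rng.integers(0, 12))
            prof = EndProfile("R", counts)
            peaks = PeakPair("R", p1, p2, w)
            assert fragmentation_score(prof, peaks) == pytest.approx(
                oracle_fs(counts.tolist(), p1, p2, w, DEFAULT_EPS)
            )

    @given(
        c1=st.integers(0, 10_000),
        c2=st.integers(0, 10_000),
        eps=st.floats(1e-6, 10.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_antisymmetry(self, c1, c2, eps):
        """Exchanging the two window counts negates the score."""
        prof, peaks = self._profile_from_window_counts(c1, c2)
        prof_swapped, _ = self._profile_from_window_counts(c2, c1)
        fwd = fragmentation_score(prof, peaks, eps=eps)
        rev = fragmentation_score(prof_swapped, peaks, eps=eps)
        assert fwd == pytest.approx(-rev, abs=1e-9)

    @given(k=st.integers(2, 100))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_depth_invariance(self, k):
        """Scaling all counts by k changes FS only at O(eps) order."""
        prof, peaks = self._profile_from_window_counts(60, 25)
        scaled, _ = self._profile_from_window_counts(60 * k, 25 * k)
        fs1 = fragmentation_score(prof, peaks, eps=1e-9)
        fs2 = fragmentation_score(scaled, peaks, eps=1e-9)
        assert fs1 == pytest.approx(fs2, abs=1e-6)

    def test_empty_profile_zero_score(self):
        prof, peaks = self._profile_from_window_counts(0, 0)
        assert fragmentation_score(prof, peaks) == 0.0

    def test_window_clipping_at_support_edges(self):
        counts = np.zeros(N_POSITIONS, dtype=int)
        counts[0] = 10
        counts[300] = 10
        prof = EndProfile("R", counts)
        peaks = PeakPair("R", 2, 298, 5)  # windows clip to [0,7] and [293,300]
        assert fragmentation_score(prof, peaks) == pytest.approx(0.0)


class TestMotifFrequencies:
    def test_single_motif(self):
        freq = motif_frequencies(["CC"] * 4)
        assert freq[MOTIFS.index("CC")] == 1.0
        assert freq.sum() == pytest.approx(1.0)

    def test_two_motifs_half_each(self):
        freq = motif_frequencies(["CC", "CC", "AA", "AA"])
        assert freq[MOTIFS.index("CC")] == 0.5
        assert freq[MOTIFS.index("AA")] == 0.5

    def test_nn_excluded_from_denominator(self):
        freq = motif_frequencies(["CC", "NN", "NN"])
        assert freq[MOTIFS.index("CC")] == 1.0

    def test_all_nn_uniform_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            freq = motif_frequencies(["NN", "NN"])
        assert np.allclose(freq, 1 / 16)
        assert "no valid end motifs" in caplog.text

    def test_planted_multinomial_recovery(self):
        """Cancer samples' most frequent motif is the planted CC enrichment."""
        cfg = CohortConfig(
            n_regions=4, n_informative_regions=0, cc_shift=0.05,
            n_healthy=2, n_cancer=2, batch_sizes=(4,),
            molecules_per_region_mean=2000.0, seed=5,
        )
        records, _, meta = generate_cohort(cfg)
        for sid in meta.loc[meta["label"] == "cancer", "sample_id"]:
            motifs = records.loc[records["sample_id"] == sid, "end_dinucleotide"]
            freq = motif_frequencies(motifs.astype(str))
            assert MOTIFS[int(np.argmax(freq))] == "CC"


class TestAssembleFeatures:
    def test_96_region_panel_gives_112_columns(self):
        peaks = {f"R{i:03d}": PeakPair(f"R{i:03d}", 50, 180) for i in range(96)}
        records = pd.DataFrame(
            {
                "sample_id": ["S1"],
                "region_id": ["R000"],
                "rel_end_pos": [50],
                "end_dinucleotide": ["CC"],
            }
        )
        X = assemble_features(records, peaks)
        assert X.shape == (1, 112)

    def test_column_order_fixed_and_stable(self, tmp_path):
        peaks = {"R2": PeakPair("R2", 50, 180), "R1": PeakPair("R1", 40, 200)}
        records = pd.DataFrame(
            {
                "sample_id": ["S1", "S1"],
                "region_id": ["R1", "R2"],
                "rel_end_pos": [40, 50],
                "end_dinucleotide": ["CC", "AA"],
            }
        )
        X = assemble_features(records, peaks)
        assert list(X.columns) == ["FS_R1", "FS_R2"] + list(MOTIFS)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        X.to_csv(p1)
        assemble_features(records, peaks).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_region_pure_pseudocount_fs_zero(self):
        peaks = {"R1": PeakPair("R1", 50, 180), "R2": PeakPair("R2", 50, 180)}
        records = pd.DataFrame(
            {
                "sample_id": ["S1"],
                "region_id": ["R1"],
                "rel_end_pos": [50],
                "end_dinucleotide": ["CC"],
            }
        )
        X = assemble_features(records, peaks)
        assert X.loc["S1", "FS_R2"] == 0.0
        assert X.loc["S1", "FS_R1"] > 0.0

    def test_duplicate_sample_id_raises(self):
        peaks = {"R1": PeakPair("R1", 50, 180)}
        records = pd.DataFrame(
            {"sample_id": ["S1"], "region_id": ["R1"], "rel_end_pos": [50],
             "end_dinucleotide": ["CC"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            assemble_features(records, peaks, sample_ids=["S1", "S1"])

    def test_vectorized_path_matches_per_profile_scores(self, tiny_cohort):
        """The fast windowed-count path must agree exactly with computing
        fragmentation_score per sample-region profile."""
        records, truth, meta = tiny_cohort
        region_ids = sorted(truth.region_models)
        peaks = detect_all_peaks(records, region_ids)
        X = assemble_features(records, peaks)
        for sid in meta["sample_id"].iloc[:4]:
            sample = records[records["sample_id"] == sid]
            for rid in region_ids:
                pos = sample.loc[sample["region_id"] == rid, "rel_end_pos"].to_numpy()
                expected = fragmentation_score(build_profile(pos, rid), peaks[rid])
                assert X.loc[sid, f"FS_{rid}"] == pytest.approx(expected)
            freq = motif_frequencies(sample["end_dinucleotide"].astype(str))
            assert np.allclose(X.loc[sid, list(MOTIFS)].to_numpy(dtype=float), freq)

    def test_motif_block_is_probability_distribution(self, tiny_cohort):
        records, truth, _ = tiny_cohort
        peaks = detect_all_peaks(records, sorted(truth.region_models))
        X = assemble_features(records, peaks)
        motif_block = X[list(MOTIFS)].to_numpy()
        assert np.allclose(motif_block.sum(axis=1), 1.0, atol=1e-9)
        assert (motif_block >= 0).all() and (motif_block <= 1).all()


class TestPeaksIO:
    def test_round_trip(self, tmp_path):
        peaks = {
            "R1": PeakPair("R1", 42, 170, 5),
            "R2": PeakPair("R2", 63, 240, 5),
        }
        path = tmp_path / "peaks.tsv"
        write_peaks_tsv(peaks, path)
        assert read_peaks_tsv(path) == peaks
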