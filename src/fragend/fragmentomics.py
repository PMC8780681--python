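"""End profiles, peak detection, fragmentation scores and motif features.

For each target region, the relative end positions of deduplicated
molecules form an integer histogram over 0-300 bp (the end profile).
Pooled over training samples, each region shows two characteristic
cleavage peaks: Peak1 in the sub-nucleosomal window 0-99 bp and Peak2 in
the mono-nucleosomal window 100-300 bp. The fragmentation score (FS) of
a sample at a region is the log2 ratio of end densities in fixed windows
around those two peaks:

    FS = log2((c1 + eps) / (c2 + eps))

where c1, c2 are window counts and eps a pseudocount. Peak positions are
frozen on pooled training data only and then applied unchanged to test
samples. Per-sample features are the raw FS of every region plus the 16
dinucleotide end-motif frequencies; standardization happens inside the
classifier with training-set statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fragend.synthetic import MAX_REL_POS, MOTIFS

logger = logging.getLogger(__name__)

N_POSITIONS = MAX_REL_POS + 1

PEAK1_RANGE = (0, 99)        # inclusive search window for Peak1
PEAK2_RANGE = (100, MAX_REL_POS)  # inclusive search window for Peak2

DEFAULT_WINDOW_HALFWIDTH = 5
DEFAULT_EPS = 0.5
DEFAULT_SMOOTH_HALFWIDTH = 2


@dataclass
class EndProfile:
    """Histogram of relative end positions for one region."""

    region_id: str
    counts: np.ndarray  # length 301, index = rel_end_pos

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_POSITIONS,):
            raise ValueError(f"counts must have length {N_POSITIONS}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PeakPair:
    """Frozen Peak1/Peak2 positions and window half-width for one region."""

    region_id: str
    peak1_pos: int
    peak2_pos: int
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH

    def __post_init__(self) -> None:
        if not PEAK1_RANGE[0] <= self.peak1_pos <= PEAK1_RANGE[1]:
            raise ValueError(f"peak1_pos {self.peak1_pos} outside {PEAK1_RANGE}")
        if not PEAK2_RANGE[0] <= self.peak2_pos <= PEAK2_RANGE[1]:
            raise ValueError(f"peak2_pos {self.peak2_pos} outside {PEAK2_RANGE}")
        if self.window_halfwidth < 0:
            raise ValueError("window_halfwidth must be >= 0")

    def window(self, which: int) -> tuple[int, int]:
        """Inclusive window bounds around peak ``which`` (1 or 2), clipped
        to the profile support."""
        pos = self.peak1_pos if which == 1 else self.peak2_pos
        return max(0, pos - self.window_halfwidth), min(
            MAX_REL_POS, pos + self.window_halfwidth
        )


def build_profile(positions, region_id: str = "") -> EndProfile:
    """Exact integer histogram of relative end positions.

    ``positions`` is any iterable of integers in [0, 300]; each molecule
    counts once regardless of its read multiplicity. Empty input yields
    a zero profile.
    """
    pos = np.asarray(list(positions) if not isinstance(positions, np.ndarray) else positions)
    if pos.size == 0:
        return EndProfile(region_id, np.zeros(N_POSITIONS, dtype=np.int64))
    if pos.min() < 0 or pos.max() > MAX_REL_POS:
        raise ValueError(f"positions outside [0, {MAX_REL_POS}]")
    return EndProfile(region_id, np.bincount(pos, minlength=N_POSITIONS).astype(np.int64))


def _moving_average(counts: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available span."""
    if halfwidth == 0:
        return counts.astype(float)
    kernel = np.ones(2 * halfwidth + 1)
    sums = np.convolve(counts, kernel, mode="same")
    norms = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return sums / norms


def detect_peaks(
    pooled: EndProfile,
    smooth_halfwidth: int = DEFAULT_SMOOTH_HALFWIDTH,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> PeakPair:
    """Most prominent peak in each search window of a pooled profile.

    Counts are smoothed with a centered moving average; the argmax of the
    smoothed profile over 0-99 bp gives Peak1 and over 100-300 bp gives
    Peak2, ties resolved toward the smaller position. Call this on a
    profile pooled over training samples only, then freeze the result.
    """
    smoothed = _moving_average(pooled.counts, smooth_halfwidth)
    positions = []
    for lo, hi in (PEAK1_RANGE, PEAK2_RANGE):
        window = smoothed[lo : hi + 1]
        if window.sum() == 0:
            pos = lo + (hi - lo) // 2
            logger.warning(
                "region %s: all-zero counts in [%d, %d]; peak set to midpoint %d",
                pooled.region_id, lo, hi, pos,
            )
        else:
            pos = lo + int(np.argmax(window))  # argmax returns first max: low tie-break
        positions.append(pos)
    return PeakPair(pooled.region_id, positions[0], positions[1], window_halfwidth)


def fragmentation_score(
    profile: EndProfile, peaks: PeakPair, eps: float = DEFAULT_EPS
) -> float:
    """Raw fragmentation score: log2 of the Peak1/Peak2 density ratio.

    Densities are windowed count fractions d_i = (c_i + eps) / (total +
    2 eps); their ratio reduces to (c1 + eps) / (c2 + eps), so the score
    is well-defined even for empty profiles. Cross-sample normalization
    is deferred to the classifier's standardization step.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    lo1, hi1 = peaks.window(1)
    lo2, hi2 = peaks.window(2)
    c1 = float(profile.counts[lo1 : hi1 + 1].sum())
    c2 = float(profile.counts[lo2 : hi2 + 1].sum())
    return float(np.log2((c1 + eps) / (c2 + eps)))


def motif_frequencies(motifs) -> np.ndarray:
    """Frequencies of the 16 dinucleotide end motifs for one sample.

    ``motifs`` is an iterable of dinucleotide strings; NN (ambiguous)
    records are excluded from the denominator. A sample with no valid
    motifs gets the uniform vector 1/16 with a warning.
    """
    counts = pd.Series(motifs, dtype="object").value_counts()
    vec = np.array([counts.get(m, 0) for m in MOTIFS], dtype=float)
    total = vec.sum()
    n_ambiguous = int(counts.sum() - total)
    if n_ambiguous:
        logger.debug("excluded %d ambiguous (NN) end motifs", n_ambiguous)
    if total == 0:
        logger.warning("no valid end motifs; returning uniform frequencies")
        return np.full(16, 1.0 / 16)
    return vec / total


def pooled_profiles(records: pd.DataFrame, region_ids: list[str]) -> dict[str, EndProfile]:
    """End profiles pooled over all samples present in ``records``."""
    out = {}
    by_region = records.groupby("region_id", observed=True)
    for rid in region_ids:
        if rid in by_region.groups:
            pos = by_region.get_group(rid)["rel_end_pos"].to_numpy()
        else:
            pos = np.empty(0, dtype=int)
        out[rid] = build_profile(pos, rid)
    return out


def detect_all_peaks(
    records: pd.DataFrame,
    region_ids: list[str],
    smooth_halfwidth: int = DEFAULT_SMOOTH_HALFWIDTH,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> dict[str, PeakPair]:
    """Freeze Peak1/Peak2 per region from pooled (training) records."""
    pooled = pooled_profiles(records, region_ids)
    return {
        rid: detect_peaks(prof, smooth_halfwidth, window_halfwidth)
        for rid, prof in pooled.items()
    }


def assemble_features(
    records: pd.DataFrame,
    peaks: dict[str, PeakPair],
    eps: float = DEFAULT_EPS,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample feature matrix: one raw FS per region + 16 motif freqs.

    Rows are samples (index sample_id), columns are ``FS_<region_id>``
    for every region in ``peaks`` (sorted by region_id) followed by the
    16 dinucleotides in lexicographic order — a fixed, reproducible
    layout. A sample missing a region entirely gets the pure-pseudocount
    score FS = 0 for it. Window counting is vectorized over all records;
    it agrees exactly with the per-profile :func:`fragmentation_score`
    path (asserted in the test suite).
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    region_ids = sorted(peaks)
    if sample_ids is None:
        sample_ids = sorted(records["sample_id"].unique())
    sample_ids = [str(s) for s in sample_ids]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in feature assembly")

    n, m = len(sample_ids), len(region_ids)
    s_index = {s: i for i, s in enumerate(sample_ids)}
    r_index = {r: j for j, r in enumerate(region_ids)}

    windows = np.array(
        [[*peaks[r].window(1), *peaks[r].window(2)] for r in region_ids], dtype=np.int64
    )  # columns: w1_lo, w1_hi, w2_lo, w2_hi

    si_s = records["sample_id"].map(s_index)
    ri_s = records["region_id"].map(r_index)
    known = (si_s.notna() & ri_s.notna()).to_numpy()
    recs = records if known.all() else records.iloc[np.flatnonzero(known)]
    si = si_s.to_numpy(dtype=float)[known].astype(np.int64)
    ri = ri_s.to_numpy(dtype=float)[known].astype(np.int64)
    pos = recs["rel_end_pos"].to_numpy()

    c1 = np.zeros((n, m))
    c2 = np.zeros((n, m))
    in1 = (pos >= windows[ri, 0]) & (pos <= windows[ri, 1])
    in2 = (pos >= windows[ri, 2]) & (pos <= windows[ri, 3])
    np.add.at(c1, (si[in1], ri[in1]), 1)
    np.add.at(c2, (si[in2], ri[in2]), 1)
    fs = np.log2((c1 + eps) / (c2 + eps))

    motifs = np.zeros((n, 16))
    motif_counts = (
        recs.groupby("sample_id", observed=True)["end_dinucleotide"]
        .value_counts()
        .unstack(fill_value=0)
    )
    for motif in MOTIFS:
        if motif not in motif_counts.columns:
            motif_counts[motif] = 0
    motif_counts = motif_counts[list(MOTIFS)]
    for sid, row in motif_counts.iterrows():
        if str(sid) in s_index:
            motifs[s_index[str(sid)]] = row.to_numpy(dtype=float)
    totals = motifs.sum(axis=1, keepdims=True)
    empty = totals.ravel() == 0
    if empty.any():
        logger.warning(
            "%d sample(s) without valid end motifs; uniform frequencies used",
            int(empty.sum()),
        )
    motifs = np.where(totals > 0, motifs / np.where(totals == 0, 1, totals), 1.0 / 16)

    columns = [f"FS_{rid}" for rid in region_ids] + list(MOTIFS)
    out = pd.DataFrame(np.hstack([fs, motifs]), index=pd.Index(sample_ids, name="sample_id"), columns=columns)
    return out


def write_peaks_tsv(peaks: dict[str, PeakPair], path) -> None:
    """Persist frozen peak definitions (region_id, peak1_pos, peak2_pos, w)."""
    df = pd.DataFrame(
        [
            (p.region_id, p.peak1_pos, p.peak2_pos, p.window_halfwidth)
            for p in (peaks[r] for r in sorted(peaks))
        ],
        columns=["region_id", "peak1_pos", "peak2_pos", "w"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_peaks_tsv(path) -> dict[str, PeakPair]:
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    return {
        str(r.region_id): PeakPair(
            str(r.region_id), int(r.peak1_pos), int(r.peak2_pos), int(r.w)
        )
        for r in df.itertuples(index=False)
    }
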