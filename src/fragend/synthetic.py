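"""Synthetic cfDNA cohort simulator.

Generates cohorts of fragment records with the statistical structure the
fragment-end analysis assumes, so every downstream stage can be tested
without patient data. Per region, relative end positions are drawn from a
three-component mixture: a discretized Gaussian in the sub-nucleosomal
window (Peak1, mode in 0-99 bp), a second discretized Gaussian in the
mono-nucleosomal window (Peak2, mode in 100-300 bp), and a uniform
background over [0, 300]. Cancer is planted as a shift of the Peak1
mixture weight at a subset of informative regions — a density-ratio
effect, matching what the fragmentation score measures — plus a shift of
the CC dinucleotide end-motif frequency. Molecule counts per
sample-region are negative-binomial; PCR resampling adds Poisson
duplicate reads tagged with (optionally error-corrupted) UMIs.

All randomness flows from a single seed; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fragend.regions import TargetRegion

#: Dinucleotide alphabet in fixed lexicographic order (AA, AC, ..., TT).
MOTIFS = tuple(a + b for a in "ACGT" for b in "ACGT")

#: Inclusive relative end-position support (bp from the primer anchor).
MAX_REL_POS = 300

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Healthy-plasma dinucleotide end-motif frequencies: C-led motifs dominate,
# CC most frequent, as seen in deep cfDNA end-motif profiling.
_HEALTHY_MOTIF_PROBS = {
    "AA": 0.068, "AC": 0.055, "AG": 0.058, "AT": 0.050,
    "CA": 0.080, "CC": 0.101, "CG": 0.040, "CT": 0.075,
    "GA": 0.055, "GC": 0.050, "GG": 0.058, "GT": 0.055,
    "TA": 0.060, "TC": 0.065, "TG": 0.060, "TT": 0.070,
}


def healthy_motif_probs() -> np.ndarray:
    """Default healthy end-motif multinomial over :data:`MOTIFS`."""
    p = np.array([_HEALTHY_MOTIF_PROBS[m] for m in MOTIFS])
    return p / p.sum()


def shifted_motif_probs(base: np.ndarray, cc_shift: float) -> np.ndarray:
    """Add ``cc_shift`` to the CC frequency, rescaling the rest to sum 1."""
    p = np.asarray(base, dtype=float).copy()
    i = MOTIFS.index("CC")
    new_cc = np.clip(p[i] + cc_shift, 0.0, 1.0)
    other = 1.0 - p[i]
    if other > 0:
        p *= (1.0 - new_cc) / other
    p[i] = new_cc
    return p / p.sum()


@dataclass(frozen=True)
class RegionFragModel:
    """Per-region end-position mixture parameters."""

    region_id: str
    mu1: int          # Peak1 mode, bp in [0, 99]
    mu2: int          # Peak2 mode, bp in [100, 300]
    sigma1: float
    sigma2: float
    w1_healthy: float  # Peak1 mixture weight in healthy samples
    background_frac: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.mu1 <= 99:
            raise ValueError(f"{self.region_id}: mu1 must be in [0, 99]")
        if not 100 <= self.mu2 <= MAX_REL_POS:
            raise ValueError(f"{self.region_id}: mu2 must be in [100, {MAX_REL_POS}]")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError(f"{self.region_id}: sigmas must be positive")
        if not 0 <= self.w1_healthy + self.background_frac <= 1:
            raise ValueError(f"{self.region_id}: w1 + background must be in [0, 1]")


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    Defaults reflect the study design this simulator emulates: 96 target
    regions, 60 healthy and 115 cancer samples (COAD and RCC in roughly
    equal numbers) in two batches of 116 and 59, a Peak1-weight shift of
    +0.25 at 24 informative regions, and a +0.05 CC end-motif shift in
    cancer.
    """

    n_regions: int = 96
    n_informative_regions: int = 24
    effect_delta: float = 0.25
    cc_shift: float = 0.05
    motif_probs_healthy: np.ndarray | None = None
    motif_probs_cancer: np.ndarray | None = None
    n_healthy: int = 60
    n_cancer: int = 115
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: {"I": 0.25, "II": 0.25, "III": 0.25, "IV": 0.25}
    )
    cancer_type_distribution: dict[str, float] = field(
        default_factory=lambda: {"COAD": 58 / 115, "RCC": 57 / 115}
    )
    stage_effect_scale: dict[str, float] | None = None
    molecules_per_region_mean: float = 100.0
    molecules_per_region_dispersion: float = 10.0
    pcr_duplication_mean: float = 2.0
    umi_length: int = 10
    umi_error_rate: float = 0.0
    batch_sizes: tuple[int, ...] = (116, 59)
    batch_motif_shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if not 0 <= self.n_informative_regions <= self.n_regions:
            raise ValueError("n_informative_regions must be in [0, n_regions]")
        if self.n_healthy < 0 or self.n_cancer < 0:
            raise ValueError("sample counts must be >= 0")
        for name, dist in (
            ("stage_distribution", self.stage_distribution),
            ("cancer_type_distribution", self.cancer_type_distribution),
        ):
            if any(v < 0 for v in dist.values()) or abs(sum(dist.values()) - 1) > 1e-9:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if sum(self.batch_sizes) != self.n_healthy + self.n_cancer:
            raise ValueError(
                f"batch_sizes sum {sum(self.batch_sizes)} != total samples "
                f"{self.n_healthy + self.n_cancer}"
            )
        for p in (self.motif_probs_healthy, self.motif_probs_cancer):
            if p is not None:
                p = np.asarray(p, dtype=float)
                if p.shape != (16,) or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
                    raise ValueError("motif probability vectors must be 16 nonnegative reals summing to 1")
        if self.molecules_per_region_mean <= 0 or self.molecules_per_region_dispersion <= 0:
            raise ValueError("molecule count mean and dispersion must be positive")
        if self.pcr_duplication_mean < 0 or not 0 <= self.umi_error_rate <= 1:
            raise ValueError("invalid PCR duplication or UMI error parameters")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")

    def resolve_motif_probs(self) -> tuple[np.ndarray, np.ndarray]:
        healthy = (
            np.asarray(self.motif_probs_healthy, dtype=float)
            if self.motif_probs_healthy is not None
            else healthy_motif_probs()
        )
        cancer = (
            np.asarray(self.motif_probs_cancer, dtype=float)
            if self.motif_probs_cancer is not None
            else shifted_motif_probs(healthy, self.cc_shift)
        )
        return healthy, cancer


@dataclass
class GroundTruth:
    """Planted parameters and identities behind a generated cohort."""

    samples: pd.DataFrame              # sample_id, label, cancer_type, stage, batch
    region_models: dict[str, RegionFragModel]
    informative_regions: list[str]
    molecule_counts: pd.DataFrame      # sample_id, region_id, n_molecules


def make_region_models(n_regions: int, rng: np.random.Generator) -> list[RegionFragModel]:
    """Draw plausible per-region mixture parameters.

    Peak1 modes ~U[30, 80] bp, Peak2 modes ~U[130, 260] bp, spreads of
    5-10 and 8-16 bp (cleavage hotspots at nucleosome boundaries are
    sharp enough for bp-resolution peak calling at assay depth), healthy
    Peak1 weights of 0.35-0.55 on a 5% uniform background.
    """
    models = []
    for i in range(n_regions):
        models.append(
            RegionFragModel(
                region_id=f"R{i + 1:03d}",
                mu1=int(rng.integers(30, 81)),
                mu2=int(rng.integers(130, 261)),
                sigma1=float(rng.uniform(5, 10)),
                sigma2=float(rng.uniform(8, 16)),
                w1_healthy=float(rng.uniform(0.35, 0.55)),
            )
        )
    return models


def make_panel(
    n_regions: int,
    chrom: str = "chrS",
    region_span: int = 500,
    primer_len: int = 25,
    spacing: int = 2000,
) -> list[TargetRegion]:
    """Build a synthetic target panel on one synthetic chromosome.

    Regions alternate primer strand so both orientations of the
    relative-coordinate arithmetic are exercised. For ``+`` primers the
    primer sits near the region's left edge (extension rightward); for
    ``-`` primers near the right edge (extension leftward), leaving the
    full 0-300 bp window inside the region either way.
    """
    panel = []
    for i in range(n_regions):
        start = 1000 + i * spacing
        end = start + region_span
        if i % 2 == 0:
            p_start, p_end, strand = start + 50, start + 50 + primer_len, "+"
        else:
            p_start, p_end, strand = end - 50 - primer_len, end - 50, "-"
        panel.append(
            TargetRegion(
                region_id=f"R{i + 1:03d}",
                chrom=chrom,
                region_start=start,
                region_end=end,
                primer_start=p_start,
                primer_end=p_end,
                primer_strand=strand,
                cancer_type_label="COAD" if i < n_regions // 2 else "RCC",
            )
        )
    return panel


def _draw_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_total = config.n_healthy + config.n_cancer
    sample_ids = [f"H{i + 1:03d}" for i in range(config.n_healthy)] + [
        f"C{i + 1:03d}" for i in range(config.n_cancer)
    ]
    labels = ["healthy"] * config.n_healthy + ["cancer"] * config.n_cancer
    stages = [""] * config.n_healthy + list(
        rng.choice(
            list(config.stage_distribution),
            size=config.n_cancer,
            p=list(config.stage_distribution.values()),
        )
    )
    types = [""] * config.n_healthy + list(
        rng.choice(
            list(config.cancer_type_distribution),
            size=config.n_cancer,
            p=list(config.cancer_type_distribution.values()),
        )
    )
    batch = np.empty(n_total, dtype=int)
    order = rng.permutation(n_total)
    bounds = np.cumsum((0,) + tuple(config.batch_sizes))
    for b, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        batch[order[lo:hi]] = b
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "label": labels,
            "cancer_type": types,
            "stage": stages,
            "batch": batch,
        }
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Generate molecule-level fragment records for a whole cohort.

    Returns ``(records, ground_truth, metadata)`` where ``records`` has
    one row per original cfDNA molecule with columns sample_id,
    region_id, rel_end_pos, end_dinucleotide. Reproducible from
    ``config.seed`` alone.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    metadata = _draw_metadata(config, rng)
    models = make_region_models(config.n_regions, rng)
    region_ids = [m.region_id for m in models]
    informative = sorted(
        rng.choice(region_ids, size=config.n_informative_regions, replace=False)
    )
    informative_set = set(informative)

    n_samples = len(metadata)
    is_cancer = (metadata["label"] == "cancer").to_numpy()
    stage_scale = np.ones(n_samples)
    if config.stage_effect_scale is not None:
        for stage, scale in config.stage_effect_scale.items():
            stage_scale[(metadata["stage"] == stage).to_numpy()] = scale

    mean = config.molecules_per_region_mean
    disp = config.molecules_per_region_dispersion
    nb_p = disp / (disp + mean)

    sample_col, region_col, pos_col = [], [], []
    count_rows = []
    for m in models:
        counts = rng.negative_binomial(disp, nb_p, size=n_samples)
        total = int(counts.sum())
        count_rows.append(counts)

        w1 = np.full(n_samples, m.w1_healthy)
        if m.region_id in informative_set:
            w1 = np.where(
                is_cancer,
                np.clip(
                    m.w1_healthy + config.effect_delta * stage_scale,
                    0.0,
                    1.0 - m.background_frac,
                ),
                w1,
            )
        sample_idx = np.repeat(np.arange(n_samples), counts)
        u = rng.random(total)
        w1_mol = w1[sample_idx]
        bg = u < m.background_frac
        peak1 = ~bg & (u < m.background_frac + w1_mol)
        pos = np.where(
            peak1,
            rng.normal(m.mu1, m.sigma1, size=total),
            rng.normal(m.mu2, m.sigma2, size=total),
        )
        pos[bg] = rng.uniform(0, MAX_REL_POS + 1, size=int(bg.sum()))
        pos = np.clip(np.rint(pos), 0, MAX_REL_POS).astype(np.int16)

        sample_col.append(sample_idx)
        region_col.append(np.full(total, region_ids.index(m.region_id), dtype=np.int32))
        pos_col.append(pos)

    sample_idx = np.concatenate(sample_col)
    region_idx = np.concatenate(region_col)
    positions = np.concatenate(pos_col)
    n_mols = len(positions)

    # end motifs: one multinomial per (class, batch) group
    p_healthy, p_cancer = config.resolve_motif_probs()
    batches = metadata["batch"].to_numpy()
    motif_codes = np.empty(n_mols, dtype=np.int8)
    mol_cancer = is_cancer[sample_idx]
    mol_batch = batches[sample_idx]
    for b in np.unique(batches):
        shift = config.batch_motif_shift * (b - 1)
        for cancer_flag, base in ((False, p_healthy), (True, p_cancer)):
            sel = (mol_batch == b) & (mol_cancer == cancer_flag)
            if not sel.any():
                continue
            probs = shifted_motif_probs(base, shift) if shift else base
            motif_codes[sel] = rng.choice(16, size=int(sel.sum()), p=probs)

    records = pd.DataFrame(
        {
            "sample_id": pd.Categorical.from_codes(
                sample_idx, categories=metadata["sample_id"]
            ),
            "region_id": pd.Categorical.from_codes(region_idx, categories=region_ids),
            "rel_end_pos": positions,
            "end_dinucleotide": pd.Categorical.from_codes(
                motif_codes, categories=list(MOTIFS)
            ),
        }
    )

    counts_df = pd.DataFrame(
        np.column_stack(count_rows), index=metadata["sample_id"], columns=region_ids
    ).reset_index().melt(
        id_vars="sample_id", var_name="region_id", value_name="n_molecules"
    )
    truth = GroundTruth(
        samples=metadata.copy(),
        region_models={m.region_id: m for m in models},
        informative_regions=list(informative),
        molecule_counts=counts_df,
    )
    return records, truth, metadata


def add_pcr_duplicates(
    records: pd.DataFrame, config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Expand molecule-level records into read-level records with UMIs.

    Each molecule gets a random UMI of ``config.umi_length`` bases and is
    emitted ``1 + D`` times with ``D ~ Poisson(pcr_duplication_mean)``;
    every emitted copy's UMI is independently corrupted per base at
    ``config.umi_error_rate``. A ``molecule_id`` column preserves ground
    -truth identity.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(records)
    L = config.umi_length
    umi_codes = rng.integers(0, 4, size=(n, L), dtype=np.uint8)
    dups = rng.poisson(config.pcr_duplication_mean, size=n)
    reps = 1 + dups
    read_mol = np.repeat(np.arange(n), reps)
    read_codes = umi_codes[read_mol]
    if config.umi_error_rate > 0:
        err = rng.random(read_codes.shape) < config.umi_error_rate
        n_err = int(err.sum())
        if n_err:
            read_codes = read_codes.copy()
            read_codes[err] = (
                read_codes[err] + rng.integers(1, 4, size=n_err, dtype=np.uint8)
            ) % 4
    umis = _codes_to_strings(read_codes)
    reads = records.iloc[read_mol].reset_index(drop=True)
    reads["umi"] = umis
    reads["molecule_id"] = read_mol
    return reads


def _codes_to_strings(codes: np.ndarray) -> np.ndarray:
    """Convert an (n, L) array of base codes 0-3 to an array of strings."""
    ascii_arr = np.ascontiguousarray(_BASES[codes])
    return ascii_arr.view(f"S{codes.shape[1]}").ravel().astype(str)


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


FRAGMENT_TSV_COLUMNS = ["sample_id", "region_id", "rel_end_pos", "end_dinucleotide", "umi"]


def emit_fragment_tsv(records: pd.DataFrame, path) -> None:
    """Write fragment records as TSV (sample_id, region_id, rel_end_pos,
    end_dinucleotide, umi); the umi column is empty for molecule-level
    records."""
    out = records.copy()
    if "umi" not in out.columns:
        out["umi"] = ""
    out[FRAGMENT_TSV_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fragment_tsv(path) -> pd.DataFrame:
    """Read fragment records written by :func:`emit_fragment_tsv`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "sample_id": str,
            "region_id": str,
            "rel_end_pos": np.int32,
            "end_dinucleotide": str,
            "umi": str,
        },
        keep_default_na=False,
    )
    missing = [c for c in FRAGMENT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing fragment TSV columns {missing}")
    return df


def emit_bam(
    reads: pd.DataFrame,
    panel: list[TargetRegion],
    path,
    read_len: int = 50,
    umi_tag: str = "RX",
) -> None:
    """Write read-level records as a coordinate-sorted, indexed BAM.

    Each record becomes an aligned proper pair on a synthetic reference:
    read 2 sits on the primer site; read 1's alignment start (``+``
    primers) or end (``-`` primers) is offset from the primer anchor by
    the relative end position. Read 1 carries the end dinucleotide as its
    first two fragment-strand bases; both mates carry the UMI in
    ``umi_tag``. Running the resulting BAM through the preprocessing
    module recovers the input records exactly (for error-free UMIs).
    """
    import pysam

    regions = {r.region_id: r for r in panel}
    chrom_len: dict[str, int] = {}
    for r in panel:
        chrom_len[r.chrom] = max(chrom_len.get(r.chrom, 0), r.region_end + 400)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(chrom_len.items())],
    }
    chrom_tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}

    path = str(path)
    unsorted_path = path + ".unsorted.bam"
    filler = "A" * read_len
    with pysam.AlignmentFile(unsorted_path, "wb", header=header) as bam:
        for i, row in enumerate(reads.itertuples(index=False)):
            region = regions[str(row.region_id)]
            tid = chrom_tid[region.chrom]
            motif = str(row.end_dinucleotide)
            umi = str(row.umi) if "umi" in reads.columns else ""
            rel = int(row.rel_end_pos)
            if region.primer_strand == "+":
                r1_start = region.primer_start + rel
                r2_start = region.primer_start
                r1_reverse, r2_reverse = False, True
                r1_seq = motif + filler[2:] if "N" not in motif else filler
            else:
                r1_start = region.primer_end - rel - read_len
                r2_start = region.primer_end - read_len
                r1_reverse, r2_reverse = True, False
                r1_seq = filler[2:] + (revcomp(motif) if "N" not in motif else "AA")
            qname = f"{row.sample_id}.{i:08d}"
            for is_read1, start, reverse, mate_start, mate_reverse, seq in (
                (True, r1_start, r1_reverse, r2_start, r2_reverse, r1_seq),
                (False, r2_start, r2_reverse, r1_start, r1_reverse, filler),
            ):
                a = pysam.AlignedSegment()
                a.query_name = qname
                a.query_sequence = seq
                a.reference_id = tid
                a.reference_start = start
                a.mapping_quality = 60
                a.cigartuples = [(0, read_len)]
                a.next_reference_id = tid
                a.next_reference_start = mate_start
                a.is_paired = True
                a.is_proper_pair = True
                a.is_read1 = is_read1
                a.is_read2 = not is_read1
                a.is_reverse = reverse
                a.mate_is_reverse = mate_reverse
                a.template_length = 0
                a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
                if umi:
                    a.set_tag(umi_tag, umi)
                bam.write(a)
    pysam.sort("-o", path, unsorted_path)
    import os

    os.remove(unsorted_path)
    pysam.index(path)
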