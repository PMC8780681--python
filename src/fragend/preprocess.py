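"""From aligned read pairs to deduplicated fragment records.

The anchored-PCR assay sequences each captured molecule as a proper pair:
read 2 starts from the gene-specific primer, read 1 starts from the
universal adapter ligated to the preserved cfDNA fragment end. A pair is
kept only if it is flagged proper, both mates clear the mapping-quality
cutoff, and read 2 covers the primer's 3'-terminal base — extension
products necessarily include the extension start, so this is the
tightest defensible reading of "overlaps the primer site".

Read 1's alignment start (``+`` primers) or end (``-`` primers), offset
from the primer anchor, is the molecule's relative end position; the
first two fragment-strand bases of read 1 are its end dinucleotide. PCR
duplicates are collapsed by UMI within each (region, end position)
group, either exactly or with the directional count-ratio network rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fragend.regions import TargetRegion
from fragend.synthetic import MAX_REL_POS, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 30

_VALID_BASES = frozenset("ACGT")


@dataclass
class ReadPair:
    """Minimal mate-pair view used by the filtering and extraction steps."""

    qname: str
    chrom: str
    r1_start: int
    r1_end: int
    r1_reverse: bool
    r1_mapq: int
    r2_start: int
    r2_end: int
    r2_mapq: int
    proper_pair: bool
    umi: str = ""
    r1_seq: str | None = None


def filter_pairs(
    pairs: list[ReadPair],
    region: TargetRegion,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[list[ReadPair], Counter]:
    """Retain proper pairs whose read 2 covers the primer 3'-terminal base.

    Returns ``(retained, dropped)`` where ``dropped`` counts exclusions
    by cause (not_proper, low_mapq, no_primer_overlap).
    """
    if region.primer_start is None or region.primer_end is None:
        raise ValueError(f"region {region.region_id} has no primer coordinates")
    anchor_base = region.primer_three_prime_base
    retained: list[ReadPair] = []
    dropped: Counter = Counter()
    for p in pairs:
        if not p.proper_pair:
            dropped["not_proper"] += 1
        elif p.r1_mapq < min_mapq or p.r2_mapq < min_mapq:
            dropped["low_mapq"] += 1
        elif not (p.r2_start <= anchor_base < p.r2_end):
            dropped["no_primer_overlap"] += 1
        else:
            retained.append(p)
    return retained, dropped


def to_relative_end(pair: ReadPair, region: TargetRegion) -> int:
    """Relative end position of the preserved fragment end, in bp.

    Measured from the primer anchor in the extension direction, so 0
    means the fragment end coincides with the anchor. May be negative
    (fragment end upstream of the anchor); callers flag and exclude
    such records.
    """
    if region.primer_strand == "+":
        return pair.r1_start - region.primer_start
    return region.primer_end - pair.r1_end


def end_motif(pair: ReadPair, ref=None, region: TargetRegion | None = None) -> str:
    """Dinucleotide at the preserved fragment end, 5'->3' on the fragment strand.

    Uses read 1's sequence when available: the leading two bases for a
    forward read 1, or the reverse complement of the trailing two bases
    for a reverse read 1 (BAM stores reverse reads reference-strand).
    Falls back to a reference lookup (``ref`` must support
    ``fetch(chrom, start, end)``) when the read carries no sequence.
    Returns ``"NN"`` on any ambiguity; NN records are excluded from
    motif frequencies downstream.
    """
    seq = pair.r1_seq
    if seq:
        motif = revcomp(seq[-2:]) if pair.r1_reverse else seq[:2]
    elif ref is not None and region is not None:
        if pair.r1_reverse:
            raw = ref.fetch(region.chrom, pair.r1_end - 2, pair.r1_end).upper()
            motif = revcomp(raw) if len(raw) == 2 else "NN"
        else:
            motif = ref.fetch(region.chrom, pair.r1_start, pair.r1_start + 2).upper()
    else:
        return "NN"
    if len(motif) != 2 or any(b not in _VALID_BASES for b in motif):
        return "NN"
    return motif


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _directional_components(counts: dict[str, int], hamming_max: int) -> list[list[str]]:
    """Connected components under the directional count-ratio rule.

    Two UMIs are linked when their Hamming distance is within
    ``hamming_max`` and the more abundant one has at least
    ``2 * count(less) - 1`` supporting reads — the standard network rule
    for separating true co-occurring molecules from sequencing-error
    satellites of an abundant UMI.
    """
    umis = sorted(counts)  # lexicographic: deterministic component traversal
    parent = {u: u for u in umis}

    def find(u: str) -> str:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, a in enumerate(umis):
        for b in umis[i + 1 :]:
            ca, cb = counts[a], counts[b]
            hi, lo = (ca, cb) if ca >= cb else (cb, ca)
            if hi >= 2 * lo - 1 and _hamming(a, b) <= hamming_max:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for u in umis:
        groups.setdefault(find(u), []).append(u)
    return list(groups.values())


def dedup_umis(
    reads: pd.DataFrame,
    mode: str = "exact",
    hamming_max: int = 1,
) -> pd.DataFrame:
    """Collapse read-level records to molecules by UMI.

    ``reads`` needs columns region_id, rel_end_pos, umi, end_dinucleotide
    (and optionally sample_id, carried through). UMIs are compared only
    within a (sample, region, end position) group: identical UMIs at
    different end positions are distinct molecules by construction of
    the assay.

    exact mode: one molecule per distinct UMI string. directional mode:
    UMIs within ``hamming_max`` are merged when the count-ratio rule
    holds, each component collapsing to its most abundant UMI
    (lexicographically smallest on ties). Output columns: the group key,
    end_dinucleotide (modal within the molecule), umi (consensus) and
    multiplicity (supporting reads).
    """
    if mode not in ("exact", "directional"):
        raise ValueError(f"unknown dedup mode {mode!r}")
    key = [c for c in ("sample_id", "region_id", "rel_end_pos") if c in reads.columns]
    if "umi" not in reads.columns:
        raise ValueError("reads must carry a umi column")
    if reads.empty:
        return pd.DataFrame(columns=key + ["end_dinucleotide", "umi", "multiplicity"])
    lengths = reads["umi"].str.len()
    if lengths.nunique() > 1:
        raise ValueError("UMIs of unequal length in input")

    grouped = (
        reads.groupby(key + ["umi"], observed=True, sort=True)
        .agg(
            multiplicity=("umi", "size"),
            end_dinucleotide=("end_dinucleotide", lambda s: s.mode().iloc[0]),
        )
        .reset_index()
    )
    if mode == "exact":
        return grouped

    out_rows = []
    for _, group in grouped.groupby(key, observed=True, sort=True):
        counts = dict(zip(group["umi"], group["multiplicity"]))
        motif_by_umi = dict(zip(group["umi"], group["end_dinucleotide"]))
        template = group.iloc[0]
        for component in _directional_components(counts, hamming_max):
            # highest count wins; lexicographic on ties
            rep = min(component, key=lambda u: (-counts[u], u))
            row = {k: template[k] for k in key}
            row["end_dinucleotide"] = motif_by_umi[rep]
            row["umi"] = rep
            row["multiplicity"] = sum(counts[u] for u in component)
            out_rows.append(row)
    return pd.DataFrame(out_rows, columns=key + ["end_dinucleotide", "umi", "multiplicity"])


def _umi_from_read(read, umi_tag: str) -> str:
    if read.has_tag(umi_tag):
        return str(read.get_tag(umi_tag))
    token = read.query_name.rsplit(":", 1)
    if len(token) == 2 and token[1] and set(token[1]) <= set("ACGTN"):
        return token[1]
    return ""


def collect_pairs(bam, region: TargetRegion, umi_tag: str = "RX") -> list[ReadPair]:
    """Fetch and mate reads overlapping a region from an open BAM."""
    mates: dict[str, dict] = {}
    margin = MAX_REL_POS + 200
    start = max(0, region.region_start - margin)
    for read in bam.fetch(region.chrom, start, region.region_end + margin):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        slot = mates.setdefault(read.query_name, {})
        slot["r1" if read.is_read1 else "r2"] = read
    pairs = []
    for qname in sorted(mates):
        slot = mates[qname]
        if "r1" not in slot or "r2" not in slot:
            continue
        r1, r2 = slot["r1"], slot["r2"]
        if r1.reference_name != r2.reference_name:
            continue
        pairs.append(
            ReadPair(
                qname=qname,
                chrom=r1.reference_name,
                r1_start=r1.reference_start,
                r1_end=r1.reference_end,
                r1_reverse=r1.is_reverse,
                r1_mapq=r1.mapping_quality,
                r2_start=r2.reference_start,
                r2_end=r2.reference_end,
                r2_mapq=r2.mapping_quality,
                proper_pair=r1.is_proper_pair and r2.is_proper_pair,
                umi=_umi_from_read(r1, umi_tag),
                r1_seq=r1.query_sequence,
            )
        )
    return pairs


def extract_bam(
    bam_path,
    panel: list[TargetRegion],
    sample_id: str,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    dedup_mode: str = "exact",
    hamming_max: int = 1,
    umi_tag: str = "RX",
    ref=None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full preprocessing chain on one sample's BAM.

    filter (proper pair, MAPQ, primer overlap) -> relative end position
    and end motif -> UMI dedup. Returns molecule-level records
    (sample_id, region_id, rel_end_pos, end_dinucleotide, umi,
    multiplicity) and a QC dict with read conservation accounting:
    ``pairs_in == pairs_kept + sum(dropped_*)`` and positional
    exclusions (upstream_of_anchor, out_of_window) tallied separately.
    """
    import pysam

    qc: Counter = Counter()
    rows = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for region in panel:
            pairs = collect_pairs(bam, region, umi_tag=umi_tag)
            qc["pairs_in"] += len(pairs)
            kept, dropped = filter_pairs(pairs, region, min_mapq=min_mapq)
            for cause, n in dropped.items():
                qc[f"dropped_{cause}"] += n
            qc["pairs_kept"] += len(kept)
            for pair in kept:
                rel = to_relative_end(pair, region)
                if rel < 0:
                    qc["upstream_of_anchor"] += 1
                    continue
                if rel > MAX_REL_POS:
                    qc["out_of_window"] += 1
                    continue
                rows.append(
                    (
                        sample_id,
                        region.region_id,
                        rel,
                        end_motif(pair, ref=ref, region=region),
                        pair.umi,
                    )
                )
    reads = pd.DataFrame(
        rows, columns=["sample_id", "region_id", "rel_end_pos", "end_dinucleotide", "umi"]
    )
    if reads.empty:
        molecules = reads.assign(multiplicity=pd.Series(dtype=int))
    else:
        molecules = dedup_umis(reads, mode=dedup_mode, hamming_max=hamming_max)
    qc["molecules_out"] = len(molecules)
    qc["reads_used"] = len(reads)
    qc["dedup_rate"] = (
        round(1.0 - len(molecules) / len(reads), 6) if len(reads) else 0.0
    )
    return molecules, dict(qc)
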