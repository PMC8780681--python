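"""Target-region panels and cancer-type-specific region selection.

A target region is an open-chromatin interval with a single gene-specific
primer anchored inside it; relative fragment-end positions are measured
from the primer in its extension direction. Panels are stored as a
BED-like TSV (0-based half-open coordinates) extended with primer columns.

Region selection operates on a peak-by-cancer-type accessibility score
matrix (e.g. derived from ATAC-seq): for a target cancer type, peaks are
ranked by specificity — the target-type score minus the best off-target
score — so that a highly accessible but ubiquitous peak ranks below a
moderately accessible but type-exclusive one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

PANEL_COLUMNS = [
    "chrom",
    "start",
    "end",
    "region_id",
    "primer_start",
    "primer_end",
    "primer_strand",
    "label",
]


class PanelError(ValueError):
    """Malformed or invalid region panel."""


@dataclass(frozen=True)
class TargetRegion:
    """A genomic target with its primer binding site.

    Coordinates are 0-based half-open (BED convention). The primer site
    must lie inside the region; ``primer_strand`` gives the extension
    direction and hence the orientation of relative end positions.
    """

    region_id: str
    chrom: str
    region_start: int
    region_end: int
    primer_start: int
    primer_end: int
    primer_strand: str
    cancer_type_label: str = ""

    def __post_init__(self) -> None:
        if self.region_start >= self.region_end:
            raise PanelError(
                f"region {self.region_id}: region_start must be < region_end "
                f"({self.region_start} >= {self.region_end})"
            )
        if self.primer_start >= self.primer_end:
            raise PanelError(
                f"region {self.region_id}: primer_start must be < primer_end "
                f"({self.primer_start} >= {self.primer_end})"
            )
        if self.primer_start < self.region_start or self.primer_end > self.region_end:
            raise PanelError(
                f"region {self.region_id}: primer [{self.primer_start}, "
                f"{self.primer_end}) not contained in region "
                f"[{self.region_start}, {self.region_end})"
            )
        if self.primer_strand not in ("+", "-"):
            raise PanelError(
                f"region {self.region_id}: primer_strand must be '+' or '-', "
                f"got {self.primer_strand!r}"
            )

    @property
    def primer_anchor(self) -> int:
        """Coordinate from which relative end positions are measured.

        For a ``+`` primer this is ``primer_start``; for a ``-`` primer,
        ``primer_end`` (positions increase in the extension direction).
        """
        return self.primer_start if self.primer_strand == "+" else self.primer_end

    @property
    def primer_three_prime_base(self) -> int:
        """0-based coordinate of the primer's 3'-terminal base.

        The base from which polymerase extension starts; a retained
        read pair's primer-side read must cover it.
        """
        return self.primer_end - 1 if self.primer_strand == "+" else self.primer_start


def read_regions(path) -> list[TargetRegion]:
    """Read a target-region panel from a BED-like TSV with header.

    Expected columns (in order): chrom, start, end, region_id,
    primer_start, primer_end, primer_strand, label. Raises
    :class:`PanelError` naming the offending line or region on malformed
    input; an empty panel is returned (with a warning) for a header-only
    file.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise PanelError(f"{path}: empty file, expected a header line") from None
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing columns {missing}")
    regions: list[TargetRegion] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            region = TargetRegion(
                region_id=str(row.region_id),
                chrom=str(row.chrom),
                region_start=int(row.start),
                region_end=int(row.end),
                primer_start=int(row.primer_start),
                primer_end=int(row.primer_end),
                primer_strand=str(row.primer_strand),
                cancer_type_label="" if pd.isna(row.label) else str(row.label),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, PanelError):
                raise
            raise PanelError(f"{path}: malformed row at line {i}: {exc}") from exc
        if region.region_id in seen:
            raise PanelError(f"{path}: duplicate region_id {region.region_id!r}")
        seen.add(region.region_id)
        regions.append(region)
    if not regions:
        logger.warning("%s: panel is empty", path)
    return regions


def write_regions(regions: list[TargetRegion], path) -> None:
    """Write a panel to TSV in the documented column order."""
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.region_start for r in regions],
            "end": [r.region_end for r in regions],
            "region_id": [r.region_id for r in regions],
            "primer_start": [r.primer_start for r in regions],
            "primer_end": [r.primer_end for r in regions],
            "primer_strand": [r.primer_strand for r in regions],
            "label": [r.cancer_type_label for r in regions],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_score_matrix(path) -> pd.DataFrame:
    """Read a peak-by-cancer-type accessibility score matrix from TSV.

    First four columns are peak_id, chrom, start, end; remaining columns
    are one score column per cancer type. Returns a DataFrame indexed by
    peak_id with the positional columns preserved.
    """
    df = pd.read_csv(path, sep="\t")
    expected = ["peak_id", "chrom", "start", "end"]
    if list(df.columns[:4]) != expected:
        raise PanelError(f"{path}: first four columns must be {expected}")
    if df.shape[1] < 6:
        raise PanelError(f"{path}: need at least 2 cancer-type score columns")
    return df.set_index("peak_id")


def select_specific_regions(matrix: pd.DataFrame, target_type: str, k: int) -> list[str]:
    """Select the k peaks most specific to ``target_type``.

    ``matrix`` is indexed by peak_id; score columns are every column not
    named chrom/start/end. Specificity of a peak is its target-type score
    minus the maximum score over all other cancer types. Peaks are ranked
    by descending specificity, ties broken by descending target score,
    then ascending peak_id — fully deterministic and invariant to row
    order.
    """
    score_cols = [c for c in matrix.columns if c not in ("chrom", "start", "end")]
    if target_type not in score_cols:
        raise KeyError(f"unknown cancer type {target_type!r}; available: {score_cols}")
    if len(score_cols) < 2:
        raise ValueError("need at least 2 cancer-type columns to define specificity")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of peaks ({len(matrix)})")
    scores = matrix[score_cols]
    target = scores[target_type]
    others = scores.drop(columns=[target_type]).max(axis=1)
    specificity = target - others
    ranking = pd.DataFrame(
        {
            "specificity": specificity.to_numpy(),
            "target": target.to_numpy(),
            "pid": [str(p) for p in scores.index],
        }
    ).sort_values(
        by=["specificity", "target", "pid"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return list(ranking["pid"].iloc[:k])
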