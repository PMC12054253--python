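"""Exact-match spacer counting from FASTQ and count-table persistence.

Reads are assigned by the exact 20-mer at a fixed offset; no mismatch
tolerance (synthetic reads are error-free and a mismatch budget is out of
scope).  Spacers shared by two library records are counted once per spacer;
every record carrying the spacer inherits the count and is flagged
ambiguous, so gene-level aggregation sees the occurrence for every
annotated target.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import GuideLibrary
from .screen import ScreenCountSet

SPACER_LENGTH = 20


@dataclasses.dataclass
class SpacerIndex:
    """Exact-match index: spacer sequence -> guide_ids carrying it."""

    spacer_to_guides: dict[str, list[str]]
    offset: int

    @classmethod
    def build(cls, library: GuideLibrary, offset: int = 0) -> "SpacerIndex":
        if offset < 0:
            raise ValueError("offset must be non-negative")
        mapping: dict[str, list[str]] = {}
        for row in library.records.itertuples():
            mapping.setdefault(row.spacer, []).append(row.guide_id)
        return cls(spacer_to_guides=mapping, offset=offset)

    def is_ambiguous(self, spacer: str) -> bool:
        return len(self.spacer_to_guides.get(spacer, ())) > 1


@dataclasses.dataclass
class SpacerCounts:
    """Result of counting one FASTQ: per-spacer counts plus unassigned reads."""

    spacer_counts: dict[str, int]
    unassigned: int
    total_reads: int

    def per_guide(self, index: SpacerIndex) -> pd.DataFrame:
        """Expand spacer counts to guide records.

        Each record inherits its spacer's count; records whose spacer is
        shared by another record are flagged ambiguous.
        """
        rows = []
        for spacer, guides in index.spacer_to_guides.items():
            c = self.spacer_counts.get(spacer, 0)
            for g in guides:
                rows.append((g, spacer, c, len(guides) > 1))
        df = pd.DataFrame(rows, columns=["guide_id", "spacer", "count", "ambiguous"])
        return df.set_index("guide_id")


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_spacers(
    fastq_path: str | Path, library: GuideLibrary, offset: int = 0
) -> SpacerCounts:
    """Count exact spacer matches in a (optionally gzipped) FASTQ file.

    A read increments exactly one spacer's count when its 20-mer at
    ``offset`` exactly matches a library spacer, otherwise the unassigned
    counter; assigned + unassigned always equals the number of reads.
    """
    index = SpacerIndex.build(library, offset=offset)
    spacer_counts: dict[str, int] = {}
    unassigned = 0
    total = 0
    end = offset + SPACER_LENGTH
    with _open_maybe_gzip(fastq_path) as fh:
        try:
            for total, (_title, seq, _qual) in enumerate(FastqGeneralIterator(fh), start=1):
                if len(seq) < end:
                    raise ValueError(
                        f"read {total} is {len(seq)} nt, shorter than offset+{SPACER_LENGTH}"
                    )
                kmer = seq[offset:end]
                if kmer in index.spacer_to_guides:
                    spacer_counts[kmer] = spacer_counts.get(kmer, 0) + 1
                else:
                    unassigned += 1
        except ValueError as exc:
            if "Lengths of sequence and quality" in str(exc) or "FASTQ" in str(exc):
                raise ValueError(f"malformed FASTQ record near read {total + 1}: {exc}") from exc
            raise
    return SpacerCounts(spacer_counts=spacer_counts, unassigned=unassigned, total_reads=total)


def guide_count_series(counts: SpacerCounts, library: GuideLibrary, offset: int = 0) -> pd.Series:
    """Per-guide counts (ambiguous records inherit the shared spacer's count)."""
    index = SpacerIndex.build(library, offset=offset)
    per_guide = counts.per_guide(index)["count"]
    return per_guide.reindex(library.guide_ids).fillna(0).astype(int)


# ---- count-table persistence -------------------------------------------


def write_counts(countset: ScreenCountSet, counts_path: str | Path, meta_path: str | Path) -> None:
    """Write a count set as two TSVs: guides x samples counts, and sample metadata."""
    countset.counts.to_csv(counts_path, sep="\t")
    countset.meta.to_csv(meta_path, sep="\t", index=False)


def read_counts(
    counts_path: str | Path, meta_path: str | Path, library: GuideLibrary
) -> ScreenCountSet:
    """Read a count set back; validates guide ids, sample ids and integer counts."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="guide_id")
    meta = pd.read_csv(meta_path, sep="\t")
    empty = counts.columns[counts.isna().all(axis=0)]
    if len(empty):
        raise ValueError(f"empty sample column(s): {list(empty)}")
    if counts.isna().any().any():
        raise ValueError("missing values in count table")
    arr = counts.to_numpy()
    if (arr != arr.astype(int)).any():
        raise ValueError("counts must be integers")
    counts = counts.astype(int)
    return ScreenCountSet(counts, meta, library)
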