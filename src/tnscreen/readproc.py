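"""FASTQ -> per-site read counts: demultiplex, tag mapping, site enumeration.

Tags are mapped by exact search against both strands of the genome, anchored
at TA sites: the index stores, for every TA position, the forward tag
(genome substring starting at the TA) and the reverse tag (reverse
complement of the substring ending at the TA), so a lookup is a single
dictionary probe.  Tags matching more than one (site, orientation) are
flagged ambiguous and never silently resolved; ambiguous and unmapped reads
are discarded from counting but always reported in the summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import GenomeModel, TASiteIndex
from .simulate import revcomp

logger = logging.getLogger(__name__)

Read = tuple[str, str, str]  # (name, sequence, quality)


def read_fastq(path) -> Iterator[Read]:
    """Stream 4-line FASTQ records (Phred+33) as (name, seq, qual) tuples."""
    with open(path) as fh:
        for name, seq, qual in FastqGeneralIterator(fh):
            yield name, seq, qual


@dataclass
class TagIndex:
    """Exact lookup from tag sequence to (ta_position, orientation).

    ``lookup`` holds tags with a unique hit; ``ambiguous`` holds tags that
    occur at more than one (site, orientation), kept with all their hits.
    """

    tag_length: int
    lookup: dict[str, tuple[int, str]]
    ambiguous: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.lookup) + len(self.ambiguous)


def build_tag_index(
    genome: GenomeModel, ta_index: TASiteIndex, tag_length: int
) -> TagIndex:
    """Index every TA-anchored tag of the genome on both strands.

    A (+) tag at TA position p is ``genome[p : p+tag_length]``; a (-) tag is
    the reverse complement of ``genome[p+2-tag_length : p+2]``.  Windows that
    run off the genome or contain N are not indexed.
    """
    seq, L = genome.sequence, genome.length
    hits: dict[str, list[tuple[int, str]]] = {}
    for p in ta_index.positions:
        p = int(p)
        if p + tag_length <= L:
            tag = seq[p : p + tag_length]
            if "N" not in tag:
                hits.setdefault(tag, []).append((p, "+"))
        if p + 2 - tag_length >= 0:
            window = seq[p + 2 - tag_length : p + 2]
            if "N" not in window:
                hits.setdefault(revcomp(window), []).append((p, "-"))
    lookup = {t: h[0] for t, h in hits.items() if len(h) == 1}
    ambiguous = {t: h for t, h in hits.items() if len(h) > 1}
    if ambiguous:
        logger.warning("%d ambiguous tags in index (multi-site)", len(ambiguous))
    return TagIndex(tag_length, lookup, ambiguous)


def map_tag(tag: str, index: TagIndex) -> tuple[str, tuple[int, str] | None]:
    """Map one tag: ('mapped', (pos, orient)) | ('ambiguous', None) | ('unmapped', None).

    Tags containing non-ACGT characters are unmapped, not an error.
    """
    if len(tag) != index.tag_length:
        raise ValueError(
            f"tag length {len(tag)} != index tag length {index.tag_length}"
        )
    hit = index.lookup.get(tag)
    if hit is not None:
        return "mapped", hit
    if tag in index.ambiguous:
        return "ambiguous", None
    return "unmapped", None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class DemuxResult:
    """Per-group read streams plus accounting of rejected reads."""

    assigned: dict[str, list[Read]]
    rejected: int
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.rejected


def demultiplex(
    reads: Iterable[Read],
    barcode_map: Mapping[str, str],
    max_mismatches: int = 0,
) -> DemuxResult:
    """Assign each read to the unique group barcode within ``max_mismatches``.

    The barcode is the read prefix; it is stripped from assigned reads so
    downstream stages see the bare genomic tag.  Barcodes must be equal
    length with pairwise Hamming distance > 2 x max_mismatches, which makes
    assignment unambiguous.
    """
    barcodes = list(barcode_map.items())
    blen = {len(b) for _, b in barcodes}
    if len(blen) != 1:
        raise ValueError("barcodes must all have the same length")
    blen = blen.pop()
    for i, (ga, a) in enumerate(barcodes):
        for gb, b in barcodes[i + 1 :]:
            d = _hamming(a, b)
            if d <= 2 * max_mismatches:
                raise ValueError(
                    f"barcodes {ga!r}/{gb!r} at Hamming distance {d} collide "
                    f"under max_mismatches={max_mismatches}"
                )
    exact = {b: g for g, b in barcodes}
    assigned: dict[str, list[Read]] = {g: [] for g in barcode_map}
    counts = {g: 0 for g in barcode_map}
    rejected = 0
    for name, seq, qual in reads:
        prefix = seq[:blen]
        group = exact.get(prefix)
        if group is None and max_mismatches > 0:
            for g, b in barcodes:
                if _hamming(prefix, b) <= max_mismatches:
                    group = g
                    break
        if group is None:
            rejected += 1
            continue
        assigned[group].append((name, seq[blen:], qual[blen:]))
        counts[group] += 1
    logger.info(
        "demultiplex: %s assigned, %d rejected",
        {g: n for g, n in counts.items()}, rejected,
    )
    return DemuxResult(assigned, rejected, counts)


@dataclass
class MapSummary:
    mapped_unique: int = 0
    ambiguous: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.mapped_unique + self.ambiguous + self.unmapped


def map_reads(
    reads: Iterable[Read], index: TagIndex
) -> tuple[list[tuple[int, str]], MapSummary]:
    """Map a stream of barcode-stripped reads; returns unique hits + accounting."""
    hits: list[tuple[int, str]] = []
    summary = MapSummary()
    for _name, seq, _qual in reads:
        tag = seq[: index.tag_length]
        if len(tag) < index.tag_length:
            summary.unmapped += 1
            continue
        status, hit = map_tag(tag, index)
        if status == "mapped":
            hits.append(hit)
            summary.mapped_unique += 1
        elif status == "ambiguous":
            summary.ambiguous += 1
        else:
            summary.unmapped += 1
    return hits, summary


@dataclass
class SiteCountTable:
    """Reads per insertion site per sample.

    ``per_site``: index (ta_position, orientation), one int column per
    sample.  ``collapsed()`` sums the two orientations of a TA site, the
    form the per-feature statistics consume.
    """

    per_site: pd.DataFrame

    def collapsed(self) -> pd.DataFrame:
        if self.per_site.empty:
            return self.per_site.reset_index(drop=True)
        out = self.per_site.groupby(level="ta_position").sum()
        return out

    def sample_totals(self) -> pd.Series:
        return self.per_site.sum(axis=0)

    def write_tsv(self, path) -> None:
        self.per_site.reset_index().to_csv(path, sep="\t", index=False)

    def write_track(self, path, sample: str) -> None:
        """Per-position count track (position<TAB>count) for browser inspection."""
        col = self.collapsed()[sample]
        col[col > 0].rename("count").reset_index().to_csv(path, sep="\t", index=False)


def count_sites(mapped: Mapping[str, list[tuple[int, str]]]) -> SiteCountTable:
    """Enumerate reads per (ta_position, orientation) for each sample."""
    frames = {}
    for sample, hits in mapped.items():
        if hits:
            df = pd.DataFrame(hits, columns=["ta_position", "orientation"])
            frames[sample] = df.value_counts().sort_index()
        else:
            frames[sample] = pd.Series(
                dtype=np.int64,
                index=pd.MultiIndex.from_arrays(
                    [[], []], names=["ta_position", "orientation"]
                ),
            )
    table = pd.DataFrame(frames).fillna(0).astype(np.int64)
    table.index.names = ["ta_position", "orientation"]
    return SiteCountTable(table.sort_index())
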