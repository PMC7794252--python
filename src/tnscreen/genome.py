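"""Genome coordinate frame: sequence, TA-site index, and a feature catalog.

Conventions used throughout the package:

* Coordinates are 0-based, half-open ``[start, end)``.
* A TA site is identified by the forward-strand position of its ``T``.
  TA is its own reverse complement, so the same index serves both strands
  (a site at ``p`` on the forward strand is the site at ``L - 2 - p`` after
  coordinate reflection).
* Genes plus constructed intergenic regions tile the genome exactly; every
  TA site therefore belongs to exactly one feature.  An insertion is
  assigned to the feature containing the ``T`` of its TA site.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_DNA = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class GenomeModel:
    """A single-chromosome genome sequence.

    The sequence is stored uppercase; only A/C/G/T/N are accepted.  Windows
    containing N yield neither TA sites nor junction tags.
    """

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if not _VALID_DNA.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"genome {self.id!r} contains non-DNA characters: {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def revcomp(self) -> "GenomeModel":
        return GenomeModel(self.id, str(Seq(self.sequence).reverse_complement()))


@dataclass(frozen=True)
class TASiteIndex:
    """Ordered 0-based positions p with sequence[p:p+2] == 'TA'."""

    positions: np.ndarray  # int64, strictly increasing

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.size and not np.all(np.diff(pos) > 0):
            raise ValueError("TA positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return int(self.positions.size)

    def __contains__(self, p: int) -> bool:
        i = np.searchsorted(self.positions, p)
        return i < self.positions.size and self.positions[i] == p


@dataclass(frozen=True)
class Feature:
    """A gene or constructed intergenic region, 0-based half-open."""

    feature_id: str
    kind: str  # "gene" | "intergenic"
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.kind not in ("gene", "intergenic"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeatureCatalog:
    """Genes + intergenic regions tiling ``[0, genome_length)`` exactly."""

    features: list[Feature]
    genome_id: str
    genome_length: int
    _starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        feats = sorted(self.features, key=lambda f: f.start)
        cursor = 0
        for f in feats:
            if f.start != cursor:
                raise ValueError(
                    f"catalog does not tile the genome: gap/overlap at {cursor} "
                    f"(next feature {f.feature_id!r} starts at {f.start})"
                )
            cursor = f.end
        if cursor != self.genome_length:
            raise ValueError(
                f"catalog ends at {cursor}, genome length is {self.genome_length}"
            )
        self.features = feats
        self._starts = np.array([f.start for f in feats], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.features)

    def feature_index_of(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised locate: catalog index of the feature containing each position."""
        pos = np.asarray(positions, dtype=np.int64)
        if pos.size and (pos.min() < 0 or pos.max() >= self.genome_length):
            raise ValueError("position out of genome range")
        return np.searchsorted(self._starts, pos, side="right") - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.features],
                "kind": [f.kind for f in self.features],
                "start": [f.start for f in self.features],
                "end": [f.end for f in self.features],
                "strand": [f.strand for f in self.features],
                "length": [f.length for f in self.features],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def find_ta_sites(genome: GenomeModel) -> TASiteIndex:
    """Enumerate every TA dinucleotide (mariner insertion site) in the genome.

    Overlapping occurrences ("TATA" -> 0 and 2) are all reported.  An empty
    sequence yields an empty index.
    """
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    if arr.size < 2:
        return TASiteIndex(np.empty(0, dtype=np.int64))
    hits = np.nonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))[0]
    return TASiteIndex(hits.astype(np.int64))


def build_intergenic_regions(
    genes: Sequence[Feature], genome_length: int
) -> list[Feature]:
    """Construct intergenic features as maximal gaps between consecutive genes.

    Intergenic ids are ``IG_<left-gene>_<right-gene>`` with ``start`` / ``end``
    sentinels for the leading and trailing gaps, so ids are deterministic.
    Genes must be overlap-free (see :func:`resolve_overlaps`).
    """
    genes = sorted(genes, key=lambda f: f.start)
    for a, b in zip(genes, genes[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping genes after resolution: {a.feature_id!r} "
                f"[{a.start},{a.end}) and {b.feature_id!r} [{b.start},{b.end})"
            )
    if genes and genes[-1].end > genome_length:
        raise ValueError("gene extends beyond genome end")

    out: list[Feature] = []
    prev_end, prev_id = 0, "start"
    for g in genes:
        if g.start > prev_end:
            out.append(
                Feature(f"IG_{prev_id}_{g.feature_id}", "intergenic", prev_end, g.start)
            )
        prev_end, prev_id = g.end, g.feature_id
    if prev_end < genome_length:
        out.append(Feature(f"IG_{prev_id}_end", "intergenic", prev_end, genome_length))
    return out


def resolve_overlaps(genes: Sequence[Feature]) -> list[Feature]:
    """Make gene annotations mutually non-overlapping.

    Annotated genes on a bacterial chromosome frequently overlap by a few bp;
    the tiling invariant the Dval normalisation relies on requires disjoint
    features.  Policy: the later-starting gene is truncated to begin at the
    earlier gene's end; genes fully contained in another are dropped with a
    warning.
    """
    genes = sorted(genes, key=lambda f: (f.start, f.end))
    out: list[Feature] = []
    for g in genes:
        if not out or g.start >= out[-1].end:
            out.append(g)
            continue
        prev = out[-1]
        if g.end <= prev.end:
            logger.warning(
                "gene %s [%d,%d) contained in %s [%d,%d); dropped",
                g.feature_id, g.start, g.end, prev.feature_id, prev.start, prev.end,
            )
            continue
        logger.warning(
            "gene %s truncated: start %d -> %d (overlaps %s)",
            g.feature_id, g.start, prev.end, prev.feature_id,
        )
        out.append(Feature(g.feature_id, g.kind, prev.end, g.end, g.strand))
    return out


def locate_feature(position: int, catalog: FeatureCatalog) -> Feature:
    """Return the unique feature whose half-open interval contains ``position``."""
    if not (0 <= position < catalog.genome_length):
        raise ValueError(
            f"position {position} outside genome [0, {catalog.genome_length})"
        )
    return catalog.features[int(catalog.feature_index_of(np.array([position]))[0])]


def build_catalog(
    genes: Sequence[Feature], genome_id: str, genome_length: int
) -> FeatureCatalog:
    """Resolve overlaps, construct intergenic regions, and assemble the tiling catalog."""
    resolved = resolve_overlaps(genes)
    inter = build_intergenic_regions(resolved, genome_length)
    return FeatureCatalog(list(resolved) + inter, genome_id, genome_length)


# ---------------------------------------------------------------------------
# I/O


def read_genome_fasta(path) -> GenomeModel:
    """Read a single-chromosome genome from FASTA; multi-record files are rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(
            f"{path} contains {len(records)} sequences; this pipeline models a "
            "single chromosome — supply one record"
        )
    rec = records[0]
    return GenomeModel(rec.id, str(rec.seq))


def write_genome_fasta(genome: GenomeModel, path) -> None:
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta")


def read_gene_features(path) -> list[Feature]:
    """Read ``type == gene`` records from a GFF3 file.

    GFF3 coordinates are 1-based inclusive; they are converted to the internal
    0-based half-open convention here.  Feature ids come from the ID attribute
    (falling back to Name, locus_tag, then a positional id).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    out = []
    for i, rec in enumerate(db.features_of_type("gene", order_by="start")):
        fid = (
            rec.attributes.get("ID", [None])[0]
            or rec.attributes.get("Name", [None])[0]
            or rec.attributes.get("locus_tag", [None])[0]
            or f"gene_{i:05d}"
        )
        strand = rec.strand if rec.strand in ("+", "-") else "."
        out.append(Feature(fid, "gene", rec.start - 1, rec.end, strand))
    return out


def write_gene_gff3(genes: Iterable[Feature], genome: GenomeModel, path) -> None:
    """Write gene features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for g in genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(
                f"{genome.id}\ttnscreen\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{strand}\t.\tID={g.feature_id};Name={g.feature_id}\n"
            )
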