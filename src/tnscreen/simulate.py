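"""Forward simulation of a mariner Tn-seq selection screen.

The generative model is a standard hierarchical counting chain:

1. **Library** — each TA site independently carries an insertion clone with
   probability ``saturation``; orientation uniform; initial clone abundances
   log-normal (sigma 0.5 on the natural log) around a common mean, emulating
   a nearly random insertion distribution without large gaps or hot spots.
2. **Selection** — a clone's expected abundance after the 3-h treatment is
   ``abundance x growth_factor`` (control) or ``abundance x survival x
   multiplier(feature)`` (treated); realised abundances are Poisson about
   the expectation, independently per replicate.
3. **Colony bottleneck** — survivors are plated and a fixed number of
   colonies pooled: a multinomial sample with probabilities proportional to
   post-selection abundances.
4. **Sequencing** — reads are drawn multinomially over clones proportional
   to abundance; each read is ``barcode ++ genomic tag``, the tag anchored
   at the clone's TA site.

Every stage is deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .config import GROUPS, DEFAULT_BARCODES, ScreenConfig, sample_name
from .genome import FeatureCatalog, GenomeModel, TASiteIndex

logger = logging.getLogger(__name__)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


@dataclass
class CloneTable:
    """One record per insertion clone: TA position, orientation, abundance.

    ``frame`` columns: ``ta_position`` (int), ``orientation`` ('+'/'-'),
    ``feature_idx`` (int index into the catalog, -1 if unassigned),
    ``abundance`` (float before bottleneck sampling, integer after).
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_abundance(self) -> float:
        return float(self.frame["abundance"].sum())

    def with_abundance(self, abundance: np.ndarray, drop_zero: bool = True) -> "CloneTable":
        new = self.frame.copy()
        new["abundance"] = abundance
        if drop_zero:
            new = new[new["abundance"] > 0].reset_index(drop=True)
        return CloneTable(new)

    def write_tsv(self, path, catalog: FeatureCatalog | None = None) -> None:
        out = self.frame.copy()
        if catalog is not None:
            ids = np.array([f.feature_id for f in catalog.features])
            out["feature_id"] = np.where(
                out["feature_idx"].to_numpy() >= 0,
                ids[np.clip(out["feature_idx"].to_numpy(), 0, None)],
                "NA",
            )
        out.to_csv(path, sep="\t", index=False)


@dataclass
class FitnessMap:
    """Per-feature survival multipliers under treatment.

    1.0 is neutral; a multiplier of 30 means the insertion mutant survives
    the treatment 30-fold better than baseline (a resistance determinant).
    Multipliers act only under treatment; the control is neutral for all
    features.  ``multiplier x baseline survival`` is clipped at 1 (a clone
    cannot out-survive certainty).
    """

    multipliers: Mapping[str, float] = field(default_factory=dict)
    default: float = 1.0

    def __post_init__(self):
        for fid, m in self.multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier for {fid!r} must be > 0, got {m}")

    def multiplier(self, feature_id: str) -> float:
        return float(self.multipliers.get(feature_id, self.default))

    def as_array(self, catalog: FeatureCatalog) -> np.ndarray:
        return np.array(
            [self.multiplier(f.feature_id) for f in catalog.features], dtype=float
        )

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"feature_id": list(self.multipliers), "multiplier": list(self.multipliers.values())}
        ).to_csv(path, sep="\t", index=False)


def simulate_library(
    ta_index: TASiteIndex,
    config: ScreenConfig,
    rng: np.random.Generator,
    catalog: FeatureCatalog | None = None,
    mean_abundance: float = 100.0,
) -> CloneTable:
    """Draw the insertion library over the TA-site index.

    Each TA site carries a clone with probability ``config.saturation``;
    orientation is uniform; initial abundance is log-normal with sigma 0.5
    around ``mean_abundance`` cells per clone.
    """
    if len(ta_index) == 0:
        raise ValueError("TA-site index is empty")
    occupied = rng.random(len(ta_index)) < config.saturation
    pos = ta_index.positions[occupied]
    orient = np.where(rng.random(pos.size) < 0.5, "+", "-")
    abundance = mean_abundance * np.exp(
        rng.normal(0.0, config.abundance_sigma, pos.size)
    )
    fidx = (
        catalog.feature_index_of(pos).astype(np.int64)
        if catalog is not None
        else np.full(pos.size, -1, dtype=np.int64)
    )
    frame = pd.DataFrame(
        {
            "ta_position": pos,
            "orientation": orient,
            "feature_idx": fidx,
            "abundance": abundance,
        }
    )
    return CloneTable(frame)


def simulate_selection(
    clones: CloneTable,
    fitness: FitnessMap,
    config: ScreenConfig,
    group: str,
    rng: np.random.Generator,
    catalog: FeatureCatalog | None = None,
) -> CloneTable:
    """One replicate of the 3-h selection: Poisson growth/kill per clone."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if clones.total_abundance <= 0:
        raise ValueError("clone table has no abundance to select from")
    base = config.survival(group)
    abundance = clones.frame["abundance"].to_numpy(dtype=float)
    if group == "control":
        expected = abundance * base
    else:
        mult = _clone_multipliers(clones, fitness, catalog)
        per_clone_survival = base * mult
        over = per_clone_survival > 1.0
        if over.any():
            logger.warning(
                "%d clones with survival x multiplier > 1; clipped to 1", int(over.sum())
            )
            per_clone_survival = np.minimum(per_clone_survival, 1.0)
        expected = abundance * per_clone_survival
    realized = rng.poisson(expected).astype(float)
    return clones.with_abundance(realized)


def _clone_multipliers(
    clones: CloneTable, fitness: FitnessMap, catalog: FeatureCatalog | None
) -> np.ndarray:
    fidx = clones.frame["feature_idx"].to_numpy()
    if catalog is None or (fidx < 0).all():
        return np.full(len(clones), fitness.default)
    table = fitness.as_array(catalog)
    mult = np.where(fidx >= 0, table[np.clip(fidx, 0, None)], fitness.default)
    return mult


def simulate_colony_bottleneck(
    clones: CloneTable, n_colonies: int, rng: np.random.Generator
) -> CloneTable:
    """Pool ``n_colonies`` plated colonies: multinomial over clone abundances."""
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    total = clones.total_abundance
    if total <= 0:
        raise ValueError("library extinct: zero surviving abundance before plating")
    probs = clones.frame["abundance"].to_numpy(dtype=float) / total
    counts = rng.multinomial(n_colonies, probs)
    return clones.with_abundance(counts.astype(float))


def generate_reads(
    clones: CloneTable,
    genome: GenomeModel,
    config: ScreenConfig,
    barcode: str,
    rng: np.random.Generator,
    sample: str,
    n_reads: int | None = None,
) -> Iterator[tuple[str, str, str]]:
    """Emit junction reads as ``(name, sequence, quality)`` triples.

    Reads are drawn multinomially over clones proportional to abundance.
    Each read is ``barcode ++ tag``; the tag of a (+) clone at TA position
    ``p`` is ``genome[p : p+tag_length]`` and for a (-) clone the reverse
    complement of ``genome[p+2-tag_length : p+2]`` — in both cases the
    sequenced tag starts with the TA of the insertion site.  Clones whose
    tag window runs off the genome end are skipped with a warning (circular
    genomes are not modelled).  Substitution errors are applied at
    ``config.read_error_rate`` per base; the quality string is constant
    Phred+33 'I'.  The true site is recorded in the read name as
    ``sample:position:orientation:serial``.
    """
    n_reads = config.reads_per_sample if n_reads is None else n_reads
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    L, tlen = genome.length, config.tag_length
    pos = clones.frame["ta_position"].to_numpy()
    orient = clones.frame["orientation"].to_numpy()
    ok = np.where(orient == "+", pos + tlen <= L, pos + 2 - tlen >= 0)
    if not ok.all():
        logger.warning(
            "%d clones skipped: tag window outside genome", int((~ok).sum())
        )
    pos, orient = pos[ok], orient[ok]
    abundance = clones.frame["abundance"].to_numpy(dtype=float)[ok]
    total = abundance.sum()
    if total <= 0 or pos.size == 0:
        raise ValueError("no sequenceable clones with positive abundance")

    tags = np.array(
        [
            genome.sequence[p : p + tlen]
            if o == "+"
            else revcomp(genome.sequence[p + 2 - tlen : p + 2])
            for p, o in zip(pos, orient)
        ]
    )
    counts = rng.multinomial(n_reads, abundance / total)
    qual = "I" * (len(barcode) + tlen)
    serial = 0
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in np.nonzero(counts)[0]:
        seq = barcode + tags[i]
        for _ in range(int(counts[i])):
            read = seq
            if config.read_error_rate > 0:
                arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
                hit = np.nonzero(rng.random(arr.size) < config.read_error_rate)[0]
                for j in hit:
                    choices = alphabet[alphabet != arr[j]]
                    arr[j] = choices[rng.integers(len(choices))]
                read = arr.tobytes().decode("ascii")
            name = f"{sample}:{pos[i]}:{orient[i]}:{serial}"
            serial += 1
            yield name, read, qual
    logger.info("sample %s: emitted %d reads over %d clones", sample, n_reads, pos.size)


def write_fastq(reads: Iterator[tuple[str, str, str]], path) -> int:
    """Write 4-line FASTQ records (Phred+33); returns the record count."""
    n = 0
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Statistics-level screen simulation (no FASTQ round trip)


def simulate_sample_counts(
    library: CloneTable,
    fitness: FitnessMap,
    config: ScreenConfig,
    group: str,
    rng: np.random.Generator,
    catalog: FeatureCatalog | None = None,
    n_reads: int | None = None,
) -> np.ndarray:
    """Reads per library clone for one sample: selection -> bottleneck -> sequencing."""
    selected = simulate_selection(library, fitness, config, group, rng, catalog)
    pooled = simulate_colony_bottleneck(
        selected, config.colony_bottlenecks[group], rng
    )
    n_reads = config.reads_per_sample if n_reads is None else n_reads
    probs = pooled.frame["abundance"].to_numpy(float)
    reads = rng.multinomial(n_reads, probs / probs.sum())
    # scatter back onto the library clone order via (position, orientation)
    out = np.zeros(len(library), dtype=np.int64)
    key = pd.MultiIndex.from_frame(library.frame[["ta_position", "orientation"]])
    pkey = pd.MultiIndex.from_frame(pooled.frame[["ta_position", "orientation"]])
    out[key.get_indexer(pkey)] = reads
    return out


def simulate_screen_counts(
    library: CloneTable,
    fitness: FitnessMap,
    config: ScreenConfig,
    rng: np.random.Generator,
    catalog: FeatureCatalog | None = None,
    groups: tuple[str, ...] = GROUPS,
) -> pd.DataFrame:
    """Simulate read counts for all samples of a screen, bypassing FASTQ.

    Returns a collapsed per-position count table (index ``ta_position``,
    one column per ``group_repN`` sample), the same shape the read-processing
    pipeline produces, so the fitness statistics can be exercised directly.
    Replicates are independent selections of the same library.
    """
    cols = {}
    for group in groups:
        for rep in range(1, config.n_replicates + 1):
            cols[sample_name(group, rep)] = simulate_sample_counts(
                library, fitness, config, group, rng, catalog
            )
    table = pd.DataFrame(cols, index=library.frame["ta_position"].to_numpy())
    table.index.name = "ta_position"
    # collapse the two orientations of one TA site onto the position
    return table.groupby(level=0).sum()
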