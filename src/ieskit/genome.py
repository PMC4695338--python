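"""Synthetic micronuclear (MIC) genome models.

A MIC genome is a set of chromosomes, each tiled exactly by alternating
MAC-destined segments (MDS) and internal eliminated sequences (IES).  IESs
are strictly internal: every IES is flanked by MDS on both sides and IESs
never touch each other or a chromosome end.  The total IES content is a
configurable fraction of the genome (about one third in *Tetrahymena*).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import logger, stage_rng

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ParameterError(ValueError):
    """Raised when simulation parameters are invalid or geometrically infeasible."""


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval, 0-based, of kind ``MDS`` or ``IES``."""

    chrom: str
    start: int
    end: int
    kind: str
    id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval {self.id}: start {self.start} >= end {self.end}")
        if self.kind not in ("MDS", "IES"):
            raise ValueError(f"interval {self.id}: kind must be MDS or IES, got {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimulationParams:
    """Knobs for genome construction and read simulation.

    Defaults are the desk-scale study conditions: a 5 Mb genome carrying 300
    IESs occupying one third of it, sequenced as 50-nt reads at 20-fold mean
    coverage, with a 5% micronuclear read contamination in new-MAC samples.
    IES lengths are drawn log-uniformly over ``ies_length_range`` and then
    rescaled once so the IES fraction is met exactly; with the default range
    a large subset of loci falls in the 1-5 kb metagene class.
    """

    seed: int = 0
    genome_length: int = 5_000_000
    n_chromosomes: int = 1
    n_ies: int = 300
    ies_fraction: float | None = 1.0 / 3.0
    ies_length_range: tuple[int, int] = (1_000, 20_000)
    min_mds_length: int = 500
    depth: float = 20.0
    read_length: int = 50
    contamination: float = 0.05
    elimination_status: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_ies < 1:
            raise ParameterError("n_ies must be >= 1")
        lo, hi = self.ies_length_range
        if lo < 1 or hi < lo:
            raise ParameterError(f"bad ies_length_range {self.ies_length_range}")
        if self.ies_fraction is not None and not 0.0 < self.ies_fraction < 1.0:
            raise ParameterError("ies_fraction must lie in (0, 1)")
        if not 0.0 <= self.contamination <= 1.0:
            raise ParameterError("contamination must lie in [0, 1]")
        if self.depth <= 0:
            raise ParameterError("depth must be positive")
        if self.read_length < 1:
            raise ParameterError("read_length must be >= 1")
        if self.min_mds_length < 1:
            raise ParameterError("min_mds_length must be >= 1")
        for ies_id, r in self.elimination_status.items():
            if not 0.0 <= r <= 1.0:
                raise ParameterError(f"retained fraction for {ies_id} outside [0, 1]: {r}")


@dataclass
class GenomeModel:
    """Chromosome sequences plus a partitioning MDS/IES annotation."""

    chromosomes: list[tuple[str, int, str]]  # (name, length, sequence)
    intervals: list[Interval]

    @property
    def genome_length(self) -> int:
        return sum(length for _, length, _ in self.chromosomes)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: length for name, length, _ in self.chromosomes}

    def ies_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind == "IES"]

    def mds_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind == "MDS"]

    @property
    def ies_fraction(self) -> float:
        return sum(iv.length for iv in self.ies_intervals()) / self.genome_length

    def validate(self) -> None:
        """Check the partition invariants: exact tiling, internal IESs, unique ids."""
        lengths = self.chrom_lengths
        seen: set[str] = set()
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            if iv.id in seen:
                raise ValueError(f"duplicate interval id {iv.id}")
            seen.add(iv.id)
            if iv.chrom not in lengths:
                raise ValueError(f"interval {iv.id} on unknown chromosome {iv.chrom}")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            if ivs[0].start != 0 or ivs[-1].end != lengths[chrom]:
                raise ValueError(f"{chrom}: intervals do not span the chromosome")
            for prev, cur in zip(ivs, ivs[1:]):
                if prev.end != cur.start:
                    raise ValueError(f"{chrom}: gap or overlap at {prev.end}/{cur.start}")
            for i, iv in enumerate(ivs):
                if iv.kind == "IES":
                    if i == 0 or i == len(ivs) - 1:
                        raise ValueError(f"IES {iv.id} touches a chromosome end")
                    if ivs[i - 1].kind != "MDS" or ivs[i + 1].kind != "MDS":
                        raise ValueError(f"IES {iv.id} not flanked by MDS on both sides")

    # ------------------------------------------------------------------ IO
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description=f"length={length}")
            for name, length, seq in self.chromosomes
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def to_bed(self, path: str | Path) -> None:
        """Write the annotation as BED6 (name = interval id, strand '.')."""
        with open(path, "w") as fh:
            for iv in sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t.\n")

    @classmethod
    def from_files(cls, fasta: str | Path, bed: str | Path) -> "GenomeModel":
        chromosomes = [
            (rec.id, len(rec.seq), str(rec.seq)) for rec in SeqIO.parse(str(fasta), "fasta")
        ]
        intervals = read_annotation_bed(bed)
        model = cls(chromosomes=chromosomes, intervals=intervals)
        model.validate()
        return model


def read_annotation_bed(path: str | Path) -> list[Interval]:
    """Read a BED6 MDS/IES annotation (kind inferred from the name prefix)."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            kind = "IES" if name.upper().startswith("IES") else "MDS"
            intervals.append(Interval(chrom, start, end, kind, name))
    return intervals


def _split_lengths(total: int, n_parts: int, minimum: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` into n_parts integer parts, each >= minimum, Dirichlet-random."""
    spare = total - n_parts * minimum
    if spare < 0:
        raise ParameterError(
            f"cannot split {total} bp into {n_parts} segments of >= {minimum} bp"
        )
    weights = rng.dirichlet(np.ones(n_parts))
    extra = np.floor(weights * spare).astype(np.int64)
    # distribute the rounding residue deterministically
    residue = spare - int(extra.sum())
    extra[np.argsort(weights)[::-1][:residue]] += 1
    return extra + minimum


def generate_genome(params: SimulationParams) -> GenomeModel:
    """Build a random MIC genome honouring the MDS/IES partition invariants.

    IES lengths are drawn log-uniformly over ``ies_length_range``.  When
    ``ies_fraction`` is set, the drawn lengths are rescaled by a single
    factor so total IES bp equals ``round(ies_fraction * genome_length)``
    exactly; when it is None, lengths are used as drawn.  Deterministic
    given ``params.seed``.
    """
    params.validate()
    rng = stage_rng(params.seed, "genome")
    G = params.genome_length
    lo, hi = params.ies_length_range

    raw = np.exp(rng.uniform(np.log(lo), np.log(hi), size=params.n_ies))
    if params.ies_fraction is not None:
        target = int(round(params.ies_fraction * G))
        lengths = np.maximum(1, np.round(raw * target / raw.sum()).astype(np.int64))
        # nudge the largest loci to hit the target exactly
        diff = target - int(lengths.sum())
        order = np.argsort(lengths)[::-1]
        for i in range(abs(diff)):
            lengths[order[i % len(order)]] += np.sign(diff)
    else:
        lengths = np.round(raw).astype(np.int64)
    total_ies = int(lengths.sum())

    # chromosome sizes: equal split of G
    n_chrom = params.n_chromosomes
    chrom_sizes = np.full(n_chrom, G // n_chrom, dtype=np.int64)
    chrom_sizes[: G % n_chrom] += 1

    # assign IESs to chromosomes proportionally to size (largest remainder)
    quota = chrom_sizes / G * params.n_ies
    n_per_chrom = np.floor(quota).astype(np.int64)
    rem = params.n_ies - int(n_per_chrom.sum())
    n_per_chrom[np.argsort(quota - n_per_chrom)[::-1][:rem]] += 1

    perm = rng.permutation(params.n_ies)
    lengths = lengths[perm]

    intervals: list[Interval] = []
    chromosomes: list[tuple[str, int, str]] = []
    cursor = 0
    ies_counter = 0
    mds_counter = 0
    for ci in range(n_chrom):
        name = f"chr{ci + 1}"
        size = int(chrom_sizes[ci])
        k = int(n_per_chrom[ci])
        ies_here = lengths[cursor : cursor + k]
        cursor += k
        mds_total = size - int(ies_here.sum())
        if mds_total < (k + 1) * params.min_mds_length:
            raise ParameterError(
                f"{name}: requested IES mass ({int(ies_here.sum())} bp) leaves too little "
                f"MDS space for {k + 1} gaps of >= {params.min_mds_length} bp in {size} bp"
            )
        gaps = _split_lengths(mds_total, k + 1, params.min_mds_length, rng)
        pos = 0
        for j in range(k):
            mds_counter += 1
            intervals.append(Interval(name, pos, pos + int(gaps[j]), "MDS", f"MDS_{mds_counter}"))
            pos += int(gaps[j])
            ies_counter += 1
            intervals.append(Interval(name, pos, pos + int(ies_here[j]), "IES", f"IES_{ies_counter}"))
            pos += int(ies_here[j])
        mds_counter += 1
        intervals.append(Interval(name, pos, pos + int(gaps[k]), "MDS", f"MDS_{mds_counter}"))
        seq = _BASES[rng.integers(0, 4, size=size)].tobytes().decode("ascii")
        chromosomes.append((name, size, seq))

    model = GenomeModel(chromosomes=chromosomes, intervals=intervals)
    model.validate()
    logger.info(
        "generated genome: %d bp, %d chromosomes, %d IESs (%.4f IES fraction)",
        model.genome_length, n_chrom, ies_counter, model.ies_fraction,
    )
    return model


def default_elimination(genome: GenomeModel, retained: float) -> dict[str, float]:
    """Uniform elimination map: every IES gets the same retained fraction."""
    return {iv.id: float(retained) for iv in genome.ies_intervals()}
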