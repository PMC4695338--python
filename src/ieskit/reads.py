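"""Coordinate-resolved read simulation (whole-genome and ChIP channels).

Reads are emitted as placed records — (chrom, start, end, source) — rather
than sequences; the downstream statistics operate on mapped counts, so no
aligner is involved.  Three placement laws are used:

* MIC reference / input / contaminant reads: start positions uniform over
  intact MIC coordinates (reads may straddle MDS/IES boundaries).
* somatic new-MAC reads: drawn from the spliced somatic template, in which
  each IES contributes in proportion to its retained fraction and MDS
  contributes fully; a somatic read is confined to its source segment,
  since a read crossing an excision junction would not map contiguously
  back to MIC coordinates.
* ChIP IP reads: read midpoints sampled from a per-bp weight that is the
  fold-enrichment E over IES bodies and the background weight elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._util import logger, stage_rng
from .genome import GenomeModel, ParameterError, SimulationParams


@dataclass
class PlacedReadSet:
    """Arrays of placed reads sharing one sequencing channel.

    ``source`` is 0 for somatic and 1 for contaminant reads; for channels
    without a contamination concept (MIC WGS, IP, input) it is all zeros.
    """

    chrom: np.ndarray  # unicode array of chromosome names
    start: np.ndarray  # int64
    end: np.ndarray  # int64
    source: np.ndarray  # uint8: 0 somatic, 1 contaminant
    channel: str  # WGS | IP | input
    label: str = ""

    SOURCE_NAMES = ("somatic", "contaminant")

    def __post_init__(self) -> None:
        n = len(self.start)
        if not (len(self.chrom) == len(self.end) == len(self.source) == n):
            raise ValueError("ragged read arrays")

    @property
    def n_reads(self) -> int:
        return len(self.start)

    def contaminant_fraction(self) -> float:
        return float(np.mean(self.source == 1)) if self.n_reads else 0.0

    def validate_against(self, genome: GenomeModel) -> None:
        lengths = genome.chrom_lengths
        for name, L in lengths.items():
            mask = self.chrom == name
            if mask.any():
                if self.start[mask].min() < 0 or self.end[mask].max() > L:
                    raise ValueError(f"reads exceed bounds of {name}")
        unknown = ~np.isin(self.chrom, list(lengths))
        if unknown.any():
            raise ValueError(f"{int(unknown.sum())} reads on unknown chromosomes")

    # ------------------------------------------------------------------ IO
    def to_bed(self, path: str | Path) -> None:
        """BED6; the name field encodes read index, source and channel."""
        with open(path, "w") as fh:
            for i in range(self.n_reads):
                src = self.SOURCE_NAMES[int(self.source[i])]
                fh.write(
                    f"{self.chrom[i]}\t{self.start[i]}\t{self.end[i]}\t"
                    f"read{i}|{src}|{self.channel}\t0\t.\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path, channel: str = "WGS", label: str = "") -> "PlacedReadSet":
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        sources: list[int] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                chroms.append(f[0])
                starts.append(int(f[1]))
                ends.append(int(f[2]))
                name = f[3] if len(f) > 3 else ""
                parts = name.split("|")
                sources.append(1 if len(parts) > 1 and parts[1] == "contaminant" else 0)
                if len(parts) > 2:
                    channel = parts[2]
        return cls(
            chrom=np.asarray(chroms, dtype="U32"),
            start=np.asarray(starts, dtype=np.int64),
            end=np.asarray(ends, dtype=np.int64),
            source=np.asarray(sources, dtype=np.uint8),
            channel=channel,
            label=label,
        )

    def to_fastq(self, path: str | Path, genome: GenomeModel) -> None:
        """Optional FASTQ export (interoperability only): sequences sliced
        from the genome, constant quality."""
        seqs = {name: seq for name, _, seq in genome.chromosomes}
        with open(path, "w") as fh:
            for i in range(self.n_reads):
                s, e = int(self.start[i]), int(self.end[i])
                read = seqs[str(self.chrom[i])][s:e]
                fh.write(f"@read{i}|{self.SOURCE_NAMES[int(self.source[i])]}|{self.channel}\n")
                fh.write(read + "\n+\n" + "I" * len(read) + "\n")


def _uniform_reads(
    genome: GenomeModel, n: int, read_length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform start positions over intact chromosomes; returns (chrom_idx, start)."""
    names = [name for name, _, _ in genome.chromosomes]
    spans = np.array(
        [max(0, L - read_length + 1) for _, L, _ in genome.chromosomes], dtype=np.int64
    )
    if spans.sum() == 0:
        raise ParameterError("read_length exceeds every chromosome length")
    offsets = np.concatenate([[0], np.cumsum(spans)])
    u = rng.integers(0, offsets[-1], size=n)
    chrom_idx = np.searchsorted(offsets, u, side="right") - 1
    start = u - offsets[chrom_idx]
    return chrom_idx, start


def _segment_weighted_reads(
    genome: GenomeModel,
    weights_per_bp: np.ndarray,
    n: int,
    read_length: int,
    rng: np.random.Generator,
    confine: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place n reads over annotation segments with per-bp weights.

    confine=True: start uniform within the segment, read clipped to it
    (somatic law).  confine=False: the read *midpoint* is uniform within
    the segment and the read may extend past it (ChIP IP law).
    Returns (chrom_idx, start, end).
    """
    ivs = sorted(genome.intervals, key=lambda iv: (iv.chrom, iv.start))
    names = [name for name, _, _ in genome.chromosomes]
    name_to_idx = {name: i for i, name in enumerate(names)}
    lens = np.array([L for _, L, _ in genome.chromosomes], dtype=np.int64)

    seg_chrom = np.array([name_to_idx[iv.chrom] for iv in ivs], dtype=np.int64)
    seg_start = np.array([iv.start for iv in ivs], dtype=np.int64)
    seg_end = np.array([iv.end for iv in ivs], dtype=np.int64)
    seg_len = seg_end - seg_start
    mass = weights_per_bp * seg_len
    total = mass.sum()
    if total <= 0:
        raise ParameterError("all placement weights are zero")
    # segment choice by inverse CDF on the cumulative mass
    cum = np.cumsum(mass)
    pick = np.searchsorted(cum, rng.random(n) * total, side="right")
    pick = np.minimum(pick, len(ivs) - 1)

    chrom_idx = seg_chrom[pick]
    if confine:
        span = np.maximum(seg_len[pick] - read_length, 0)
        start = seg_start[pick] + (rng.random(n) * (span + 1)).astype(np.int64)
        end = np.minimum(start + read_length, seg_end[pick])
    else:
        mid = seg_start[pick] + (rng.random(n) * seg_len[pick]).astype(np.int64)
        start = mid - read_length // 2
        start = np.clip(start, 0, np.maximum(lens[chrom_idx] - read_length, 0))
        end = start + read_length
    return chrom_idx, start, end


def _read_count(genome: GenomeModel, params: SimulationParams) -> int:
    return int(round(params.depth * genome.genome_length / params.read_length))


def simulate_wgs(
    genome: GenomeModel,
    params: SimulationParams,
    sample: str,
    label: str | None = None,
) -> PlacedReadSet:
    """Simulate whole-genome reads for a ``MIC`` reference or a ``newMAC`` sample.

    For newMAC, a Binomial(N, c) number of reads is contaminant (uniform over
    the intact MIC genome) and the rest are somatic, drawn from the spliced
    template in which IES i carries per-bp weight equal to its retained
    fraction.  Expected somatic coverage on an IES is retained x somatic depth.
    """
    params.validate()
    if sample not in ("MIC", "newMAC"):
        raise ParameterError(f"sample must be MIC or newMAC, got {sample!r}")
    label = label if label is not None else sample
    rng = stage_rng(params.seed, f"wgs:{label}")
    names = np.array([name for name, _, _ in genome.chromosomes], dtype="U32")
    N = _read_count(genome, params)
    rl = params.read_length

    if sample == "MIC":
        chrom_idx, start = _uniform_reads(genome, N, rl, rng)
        return PlacedReadSet(
            chrom=names[chrom_idx],
            start=start,
            end=start + rl,
            source=np.zeros(N, dtype=np.uint8),
            channel="WGS",
            label=label,
        )

    status = dict(params.elimination_status)
    ies_ids = {iv.id for iv in genome.ies_intervals()}
    missing = ies_ids - status.keys()
    if missing:
        raise ParameterError(
            f"elimination_status missing {len(missing)} IES ids (e.g. {sorted(missing)[:3]})"
        )
    unknown = status.keys() - ies_ids
    if unknown:
        raise ParameterError(f"elimination_status references unknown IES ids: {sorted(unknown)[:3]}")

    n_cont = int(rng.binomial(N, params.contamination))
    n_som = N - n_cont

    ivs = sorted(genome.intervals, key=lambda iv: (iv.chrom, iv.start))
    weights = np.array(
        [1.0 if iv.kind == "MDS" else status[iv.id] for iv in ivs], dtype=np.float64
    )
    chrom_idx_s, start_s, end_s = _segment_weighted_reads(
        genome, weights, n_som, rl, rng, confine=True
    )
    chrom_idx_c, start_c = _uniform_reads(genome, n_cont, rl, rng)

    return PlacedReadSet(
        chrom=np.concatenate([names[chrom_idx_s], names[chrom_idx_c]]),
        start=np.concatenate([start_s, start_c]),
        end=np.concatenate([end_s, start_c + rl]),
        source=np.concatenate(
            [np.zeros(n_som, dtype=np.uint8), np.ones(n_cont, dtype=np.uint8)]
        ),
        channel="WGS",
        label=label,
    )


def simulate_chip(
    genome: GenomeModel,
    params: SimulationParams,
    enrichment: float,
    background: float = 1.0,
    label: str = "chip",
) -> tuple[PlacedReadSet, PlacedReadSet]:
    """Simulate an (IP, input) read pair with enrichment confined to IES bodies.

    Input reads are uniform; IP read midpoints follow a per-bp weight equal
    to ``enrichment`` on IES bodies and ``background`` elsewhere.
    """
    params.validate()
    if enrichment < 0 or background < 0:
        raise ParameterError("enrichment and background must be >= 0")
    if enrichment == 0 and background == 0:
        raise ParameterError("enrichment and background cannot both be zero")
    rng = stage_rng(params.seed, f"chip:{label}")
    names = np.array([name for name, _, _ in genome.chromosomes], dtype="U32")
    N = _read_count(genome, params)
    rl = params.read_length

    ivs = sorted(genome.intervals, key=lambda iv: (iv.chrom, iv.start))
    weights = np.array(
        [enrichment if iv.kind == "IES" else background for iv in ivs], dtype=np.float64
    )
    ci_ip, s_ip, e_ip = _segment_weighted_reads(genome, weights, N, rl, rng, confine=False)
    ci_in, s_in = _uniform_reads(genome, N, rl, rng)

    ip = PlacedReadSet(
        chrom=names[ci_ip], start=s_ip, end=e_ip,
        source=np.zeros(N, dtype=np.uint8), channel="IP", label=label,
    )
    inp = PlacedReadSet(
        chrom=names[ci_in], start=s_in, end=s_in + rl,
        source=np.zeros(N, dtype=np.uint8), channel="input", label=label,
    )
    logger.info("simulated ChIP pair '%s': %d IP + %d input reads", label, N, N)
    return ip, inp
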