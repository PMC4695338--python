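"""Run configuration: one YAML file driving the end-to-end experiments."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .genome import ParameterError, SimulationParams


@dataclass
class SampleDef:
    """One new-MAC sample: label, contamination fraction and elimination map.

    ``retained`` is either a scalar applied to every IES or an explicit
    mapping of IES id -> retained fraction.
    """

    label: str
    contamination: float
    retained: float | Mapping[str, float]


@dataclass
class ChipParams:
    enrichment: float = 8.0
    background: float = 1.0
    window: int = 50
    pseudocount: float = 0.5
    body_bins: int = 50
    flank_bp: int = 2_000
    flank_bins: int = 50
    length_filter: tuple[int, int] = (1_000, 5_000)


@dataclass
class RunConfig:
    seed: int
    genome: SimulationParams
    samples: list[SampleDef]
    chip: ChipParams
    outdir: Path
    ri_thresholds: tuple[float, ...] = (0.001, 0.1, 1.0)
    normalization: str = "total"

    def validate(self) -> None:
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            raise ParameterError(f"duplicate sample labels: {labels}")
        self.genome.validate()
        for s in self.samples:
            if not 0.0 <= s.contamination <= 1.0:
                raise ParameterError(f"sample {s.label}: contamination outside [0, 1]")

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        g = raw.get("genome", {})
        genome = SimulationParams(
            seed=int(raw.get("seed", 0)),
            genome_length=int(g.get("length", 5_000_000)),
            n_chromosomes=int(g.get("n_chromosomes", 1)),
            n_ies=int(g.get("n_ies", 300)),
            ies_fraction=g.get("ies_fraction", 1.0 / 3.0),
            ies_length_range=tuple(g.get("ies_length_range", (1_000, 20_000))),
            min_mds_length=int(g.get("min_mds_length", 500)),
            depth=float(g.get("depth", 20.0)),
            read_length=int(g.get("read_length", 50)),
        )
        samples = [
            SampleDef(
                label=str(s["label"]),
                contamination=float(s.get("contamination", 0.05)),
                retained=s.get("retained", 0.0),
            )
            for s in raw.get("samples", [])
        ]
        c = raw.get("chip", {})
        chip = ChipParams(
            enrichment=float(c.get("enrichment", 8.0)),
            background=float(c.get("background", 1.0)),
            window=int(c.get("window", 50)),
            pseudocount=float(c.get("pseudocount", 0.5)),
            body_bins=int(c.get("body_bins", 50)),
            flank_bp=int(c.get("flank_bp", 2_000)),
            flank_bins=int(c.get("flank_bins", 50)),
            length_filter=tuple(c.get("length_filter", (1_000, 5_000))),
        )
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            genome=genome,
            samples=samples,
            chip=chip,
            outdir=Path(raw.get("outdir", "ieskit_out")),
            ri_thresholds=tuple(raw.get("ri_thresholds", (0.001, 0.1, 1.0))),
            normalization=str(raw.get("normalization", "total")),
        )
        cfg.validate()
        return cfg
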