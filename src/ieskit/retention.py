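"""Per-interval read counting and the IES retention index (RI).

The RI of an IES is the ratio of normalized read counts between a new-MAC
sample and a MIC reference:

    RI_i = (n_i^newMAC / N^newMAC) / (n_i^MIC / N^MIC)

A fully eliminated IES has RI 0 in an uncontaminated preparation; reads
contaminating the new-MAC library from intact MIC genomes set a floor at
the contamination fraction c, and a fully retained IES sits near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import logger
from .genome import Interval
from .reads import PlacedReadSet


@dataclass
class CoverageTable:
    """Per-interval raw counts and counts-per-million for one sample.

    ``data`` columns: id, chrom, start, end, kind, length, count, cpm.
    ``total_reads`` is the number of assigned (mapped) reads N; reads on
    unannotated chromosomes are skipped with a logged count.
    """

    data: pd.DataFrame
    sample: str
    total_reads: int
    n_skipped: int = 0
    assignment_rule: str = "midpoint"

    def counts(self, kind: str | None = None) -> pd.Series:
        df = self.data if kind is None else self.data[self.data["kind"] == kind]
        return df.set_index("id")["count"]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class RetentionTable:
    """Per-IES retention indices for a (numerator, reference) sample pair."""

    data: pd.DataFrame  # columns: id, chrom, start, end, length, n_newmac, n_mic, ri
    numerator: str
    reference: str
    n_dropped: int = 0  # IESs with zero reference count, reported as missing

    @property
    def ri(self) -> pd.Series:
        return self.data.set_index("id")["ri"]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def count_reads(
    reads: PlacedReadSet,
    annotation: Sequence[Interval],
    assignment_rule: str = "midpoint",
    sample: str | None = None,
) -> CoverageTable:
    """Assign each read to the unique interval containing its midpoint.

    The midpoint rule partitions the counts exactly (no double counting of
    boundary-straddling reads).  Reads on chromosomes absent from the
    annotation are skipped and counted in ``n_skipped``.
    """
    if assignment_rule != "midpoint":
        raise ValueError(f"unknown assignment rule {assignment_rule!r}")
    ivs = sorted(annotation, key=lambda iv: (iv.chrom, iv.start))
    by_chrom: dict[str, list[Interval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    counts = {iv.id: 0 for iv in ivs}
    n_assigned = 0
    n_skipped = 0
    mid = (reads.start + reads.end) // 2
    for chrom, chrom_ivs in by_chrom.items():
        mask = reads.chrom == chrom
        if not mask.any():
            continue
        starts = np.array([iv.start for iv in chrom_ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in chrom_ivs], dtype=np.int64)
        m = mid[mask]
        idx = np.searchsorted(starts, m, side="right") - 1
        valid = (idx >= 0) & (m < ends[np.clip(idx, 0, None)])
        binc = np.bincount(idx[valid], minlength=len(chrom_ivs))
        for j, iv in enumerate(chrom_ivs):
            counts[iv.id] += int(binc[j])
        n_assigned += int(valid.sum())
        n_skipped += int((~valid).sum())
    unknown = int((~np.isin(reads.chrom, list(by_chrom))).sum())
    n_skipped += unknown
    if n_skipped:
        logger.warning("count_reads: skipped %d reads outside the annotation", n_skipped)

    N = n_assigned
    rows = {
        "id": [iv.id for iv in ivs],
        "chrom": [iv.chrom for iv in ivs],
        "start": [iv.start for iv in ivs],
        "end": [iv.end for iv in ivs],
        "kind": [iv.kind for iv in ivs],
        "length": [iv.length for iv in ivs],
        "count": [counts[iv.id] for iv in ivs],
    }
    df = pd.DataFrame(rows)
    df["cpm"] = df["count"] / max(N, 1) * 1e6
    return CoverageTable(
        data=df,
        sample=sample if sample is not None else reads.label,
        total_reads=N,
        n_skipped=n_skipped,
    )


def _norm_total(table: CoverageTable, mode: str) -> float:
    if mode == "total":
        return float(table.total_reads)
    if mode == "mds":
        return float(table.data.loc[table.data["kind"] == "MDS", "count"].sum())
    raise ValueError(f"unknown normalization mode {mode!r}")


def retention_index(
    newmac: CoverageTable,
    mic: CoverageTable,
    norm: str = "total",
    per_bp: bool = False,
) -> RetentionTable:
    """Compute RI_i = (n_i/N)_newMAC / (n_i/N)_mic for every IES.

    ``norm``: "total" (counts per total mapped reads, default) or "mds"
    (per MDS-assigned reads).  ``per_bp`` divides counts by interval length
    first (mean-coverage mode); the length cancels in the ratio, so both
    modes give identical RIs and the flag exists for interoperability.
    IESs with a zero reference count are dropped and logged, never
    reported as infinite.
    """
    a, b = newmac.data, mic.data
    if len(a) != len(b) or (a["id"].values != b["id"].values).any():
        raise ValueError("annotation mismatch between the two coverage tables")
    Na, Nb = _norm_total(newmac, norm), _norm_total(mic, norm)
    if Na <= 0 or Nb <= 0:
        raise ValueError("cannot normalize: zero mapped reads")

    ies = a["kind"] == "IES"
    df = a.loc[ies, ["id", "chrom", "start", "end", "length"]].copy()
    n_new = a.loc[ies, "count"].to_numpy(dtype=float)
    n_mic = b.loc[ies, "count"].to_numpy(dtype=float)
    if per_bp:
        n_new = n_new / df["length"].to_numpy()
        n_mic = n_mic / df["length"].to_numpy()
    df["n_newmac"] = a.loc[ies, "count"].values
    df["n_mic"] = b.loc[ies, "count"].values
    with np.errstate(divide="ignore", invalid="ignore"):
        ri = (n_new / Na) / (n_mic / Nb)
    keep = n_mic > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "retention_index: dropped %d IESs with zero reference count", n_dropped
        )
    df["ri"] = ri
    df = df.loc[keep].reset_index(drop=True)
    return RetentionTable(
        data=df,
        numerator=newmac.sample,
        reference=mic.sample,
        n_dropped=n_dropped,
    )


def summarize_ri(
    table: RetentionTable,
    thresholds: Sequence[float] = (0.001, 0.1, 1.0),
) -> dict:
    """Order statistics and threshold fractions over finite RIs."""
    ri = table.ri.to_numpy(dtype=float)
    ri = ri[np.isfinite(ri)]
    if len(ri) == 0:
        raise ValueError("no finite retention indices to summarize")
    out = {
        "n_ies": int(len(ri)),
        "n_dropped": int(table.n_dropped),
        "median": float(np.median(ri)),
        "q25": float(np.percentile(ri, 25)),
        "q75": float(np.percentile(ri, 75)),
        "min": float(ri.min()),
        "max": float(ri.max()),
    }
    for t in thresholds:
        out[f"frac_below_{t:g}"] = float(np.mean(ri < t))
        out[f"frac_at_or_above_{t:g}"] = float(np.mean(ri >= t))
    return out
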