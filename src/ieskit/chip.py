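"""ChIP fold-enrichment tracks and the compiled ("modeled IES") metagene.

Fold enrichment is the ratio of IP to input counts-per-million over a
fixed-width window grid, stabilized by a pseudocount.  The metagene
compiles every IES in a length class (default 1-5 kb) onto a common axis:
fixed-width flanks at native scale on both sides and a length-rescaled
body, averaged bin-wise across loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import logger
from .genome import GenomeModel, Interval
from .reads import PlacedReadSet


@dataclass
class EnrichmentTrack:
    """Windowed fold-enrichment values: (IP CPM + pc) / (input CPM + pc).

    ``data`` columns: chrom, start, end, fe, low_confidence (True where the
    input window had zero reads).
    """

    data: pd.DataFrame
    window: int
    pseudocount: float

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="fold_enrichment"\n')
            for row in self.data.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.fe:.6g}\n")


@dataclass
class MetageneProfile:
    """Average fold enrichment over compiled IES loci with flanks.

    ``upstream`` / ``downstream`` are fixed-bp flanks in ``flank_bins`` bins;
    ``body`` holds ``body_bins`` length-normalized bins.  ``n_loci`` is the
    number of IESs passing the length filter and fitting their flanks on
    the chromosome.
    """

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_loci: int
    flank_bp: int
    length_filter: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        fb, bb = len(self.upstream), len(self.body)
        for i, v in enumerate(self.upstream):
            rows.append(("upstream", i, -self.flank_bp + (i + 0.5) * self.flank_bp / fb, v))
        for i, v in enumerate(self.body):
            rows.append(("body", i, (i + 0.5) / bb, v))
        for i, v in enumerate(self.downstream):
            rows.append(("downstream", i, 1 + (i + 0.5) * self.flank_bp / fb, v))
        df = pd.DataFrame(rows, columns=["segment", "bin", "position", "mean_fe"])
        df["n_loci"] = self.n_loci
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def make_windows(chrom_lengths: dict[str, int], width: int = 50) -> pd.DataFrame:
    """Tile each chromosome with fixed-width windows (last one may be short)."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    frames = []
    for chrom, L in chrom_lengths.items():
        starts = np.arange(0, L, width, dtype=np.int64)
        ends = np.minimum(starts + width, L)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


def count_in_windows(reads: PlacedReadSet, windows: pd.DataFrame, width: int) -> np.ndarray:
    """Midpoint-rule read counts per window (same order as ``windows``)."""
    counts = np.zeros(len(windows), dtype=np.int64)
    mid = (reads.start + reads.end) // 2
    offset = 0
    for chrom, grp in windows.groupby("chrom", sort=False):
        n_win = len(grp)
        mask = reads.chrom == chrom
        if mask.any():
            idx = mid[mask] // width
            idx = idx[(idx >= 0) & (idx < n_win)]
            counts[offset : offset + n_win] += np.bincount(idx, minlength=n_win)
        offset += n_win
    return counts


def fold_enrichment(
    ip: PlacedReadSet,
    inp: PlacedReadSet,
    chrom_lengths: dict[str, int],
    window: int = 50,
    pseudocount: float = 0.5,
) -> EnrichmentTrack:
    """Windowed IP/input fold enrichment in CPM units with a pseudocount."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    windows = make_windows(chrom_lengths, window)
    c_ip = count_in_windows(ip, windows, window)
    c_in = count_in_windows(inp, windows, window)
    n_ip, n_in = max(c_ip.sum(), 1), max(c_in.sum(), 1)
    cpm_ip = c_ip / n_ip * 1e6
    cpm_in = c_in / n_in * 1e6
    fe = (cpm_ip + pseudocount) / (cpm_in + pseudocount)
    df = windows.copy()
    df["fe"] = fe
    df["low_confidence"] = c_in == 0
    if df["low_confidence"].any():
        logger.info(
            "fold_enrichment: %d/%d windows have zero input reads (low confidence)",
            int(df["low_confidence"].sum()), len(df),
        )
    return EnrichmentTrack(data=df, window=window, pseudocount=pseudocount)


def fold_enrichment_from_tracks(
    track_ip: pd.DataFrame, track_in: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Ratio of two pre-windowed CPM tables sharing one grid (hard error otherwise)."""
    same = (
        len(track_ip) == len(track_in)
        and (track_ip["chrom"].values == track_in["chrom"].values).all()
        and (track_ip["start"].values == track_in["start"].values).all()
    )
    if not same:
        raise ValueError("window grid mismatch between IP and input tracks")
    out = track_ip[["chrom", "start", "end"]].copy()
    out["fe"] = (track_ip["cpm"] + pseudocount) / (track_in["cpm"] + pseudocount)
    return out


def enrichment_ratio(ip_cov, input_cov) -> float:
    """Aggregate IES/MDS fold-enrichment estimate from per-interval counts.

    Ratio of the input-normalized per-bp IP read density over IES bodies to
    that over MDS.  Unlike the windowed track this estimator uses no
    pseudocount, so it is unbiased for the simulated enrichment factor.
    Takes two :class:`~ieskit.retention.CoverageTable` objects on the same
    MDS/IES annotation.
    """
    a, b = ip_cov.data, input_cov.data
    if (a["id"].values != b["id"].values).any():
        raise ValueError("annotation mismatch between IP and input coverage tables")
    ies, mds = a["kind"] == "IES", a["kind"] == "MDS"

    def density(df, mask):
        return df.loc[mask, "count"].sum() / df.loc[mask, "length"].sum()

    ip_ratio = density(a, ies) / density(a, mds)
    in_ratio = density(b, ies) / density(b, mds)
    return float(ip_ratio / in_ratio)


def modeled_ies(
    track: EnrichmentTrack,
    annotation: Sequence[Interval],
    chrom_lengths: dict[str, int],
    length_filter: tuple[int, int] = (1_000, 5_000),
    body_bins: int = 50,
    flank_bp: int = 2_000,
    flank_bins: int = 50,
) -> MetageneProfile:
    """Compile all IESs in the length class into one average profile.

    The body of each passing locus is rescaled to ``body_bins`` by linear
    interpolation of window values; flanks are sampled at native scale.
    The length filter is inclusive on both ends.  Loci whose flanks would
    overrun a chromosome end are dropped and logged.
    """
    lo, hi = length_filter
    passing = [
        iv for iv in annotation
        if iv.kind == "IES" and lo <= iv.length <= hi
    ]
    usable = [
        iv for iv in passing
        if iv.start - flank_bp >= 0 and iv.end + flank_bp <= chrom_lengths[iv.chrom]
    ]
    if len(usable) < len(passing):
        logger.info(
            "modeled_ies: dropped %d loci whose flanks overrun a chromosome end",
            len(passing) - len(usable),
        )
    if not usable:
        raise ValueError(
            f"no IES passes the length filter [{lo}, {hi}] bp with {flank_bp} bp flanks"
        )

    centers: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    for chrom, grp in track.data.groupby("chrom", sort=False):
        centers[chrom] = ((grp["start"] + grp["end"]) / 2).to_numpy(dtype=float)
        values[chrom] = grp["fe"].to_numpy(dtype=float)

    up = np.zeros(flank_bins)
    body = np.zeros(body_bins)
    down = np.zeros(flank_bins)
    fb_step = flank_bp / flank_bins
    for iv in usable:
        x, y = centers[iv.chrom], values[iv.chrom]
        pos_up = iv.start - flank_bp + (np.arange(flank_bins) + 0.5) * fb_step
        pos_body = iv.start + (np.arange(body_bins) + 0.5) * iv.length / body_bins
        pos_down = iv.end + (np.arange(flank_bins) + 0.5) * fb_step
        up += np.interp(pos_up, x, y)
        body += np.interp(pos_body, x, y)
        down += np.interp(pos_down, x, y)
    n = len(usable)
    return MetageneProfile(
        upstream=up / n,
        body=body / n,
        downstream=down / n,
        n_loci=n,
        flank_bp=flank_bp,
        length_filter=(lo, hi),
    )
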