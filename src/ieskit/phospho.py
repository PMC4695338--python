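"""Phospho-site bookkeeping and net-charge modelling for HP1-like proteins.

The heterochromatin protein Pdd1p carries two chromodomains (CD1, CD2), a
chromoshadow domain (CSD) and non-conserved N-terminal and hinge regions
(NT, HNG1, HNG2) that are heavily phosphorylated during development.  This
module houses the residue-level inventory of phospho-sites, builds
phospho-mimic (Ser/Thr -> Glu, "MIM-k") and charge-compensated (+6 Lys)
mutants, and computes region net charges under a simple fixed-pH charge
table: Asp/Glu -1, Lys/Arg +1, His 0, phosphorylated Ser/Thr -2 by default.
A phosphate contributes about -2 at neutral pH while its Glu mimic
contributes only -1, which is why phospho-mimics only partially reproduce
the charge of the phosphorylated state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: side-chain charges at neutral pH, elementary-charge units
DEFAULT_CHARGE_TABLE: dict[str, float] = {"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0, "H": 0.0}

#: charge added by a phosphate group on Ser/Thr at neutral pH
DEFAULT_PHOSPHO_CHARGE: float = -2.0


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with named regions (1-based inclusive residue ranges)."""

    sequence: str
    regions: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")
        spans = sorted(self.regions.items(), key=lambda kv: kv[1])
        for rname, (s, e) in spans:
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"region {rname} ({s}-{e}) outside sequence bounds")
        for (n1, (_, e1)), (n2, (s2, _)) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"regions {n1} and {n2} overlap")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        return self.sequence[position - 1]

    def region_positions(self, names: str | Sequence[str]) -> list[int]:
        if isinstance(names, str):
            names = [names]
        pos: list[int] = []
        for n in names:
            s, e = self.regions[n]
            pos.extend(range(s, e + 1))
        return sorted(pos)

    @classmethod
    def from_fasta(cls, path: str | Path, regions: Mapping[str, tuple[int, int]] | None = None) -> "ProteinRecord":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(sequence=str(rec.seq), regions=regions or {}, name=rec.id)


@dataclass(frozen=True)
class PhosphoSite:
    position: int
    residue: str
    provenance: frozenset[str]

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"phospho-site residue must be S/T/Y, got {self.residue!r}")


@dataclass(frozen=True)
class PhosphoSiteSet:
    """A set of phosphorylated residues with per-site provenance labels."""

    sites: tuple[PhosphoSite, ...]

    @classmethod
    def build(cls, entries: Iterable[tuple[int, str]], provenance: str) -> "PhosphoSiteSet":
        return cls(tuple(
            PhosphoSite(p, r, frozenset([provenance]))
            for p, r in sorted(entries)
        ))

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.sites)

    def validate_against(self, protein: ProteinRecord) -> None:
        for s in self.sites:
            if not 1 <= s.position <= len(protein):
                raise ValueError(f"site position {s.position} outside sequence")
            if protein.residue(s.position) != s.residue:
                raise ValueError(
                    f"site {s.position}: sequence has {protein.residue(s.position)}, "
                    f"set says {s.residue}"
                )

    def restrict(self, positions: Iterable[int]) -> "PhosphoSiteSet":
        keep = set(positions)
        return PhosphoSiteSet(tuple(s for s in self.sites if s.position in keep))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tresidue\tprovenance\n")
            for s in self.sites:
                fh.write(f"{s.position}\t{s.residue}\t{','.join(sorted(s.provenance))}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhosphoSiteSet":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(
            PhosphoSite(int(r.position), str(r.residue), frozenset(str(r.provenance).split(",")))
            for r in df.itertuples(index=False)
        ))


def merge_site_sets(a: PhosphoSiteSet, b: PhosphoSiteSet) -> PhosphoSiteSet:
    """Set union by residue position with merged provenance.

    |union| = |a| + |b| - |a intersect b|.  A shared position reported with
    different residue letters is a hard error (the two inventories would
    disagree about the sequence itself).
    """
    merged: dict[int, PhosphoSite] = {s.position: s for s in a.sites}
    for s in b.sites:
        if s.position in merged:
            prev = merged[s.position]
            if prev.residue != s.residue:
                raise ValueError(
                    f"conflicting residue letters at position {s.position}: "
                    f"{prev.residue} vs {s.residue}"
                )
            merged[s.position] = PhosphoSite(
                s.position, s.residue, prev.provenance | s.provenance
            )
        else:
            merged[s.position] = s
    return PhosphoSiteSet(tuple(merged[p] for p in sorted(merged)))


@dataclass(frozen=True)
class MutantSpec:
    """Ordered edits against a reference sequence (positions are pre-edit).

    Substitutions are (position, from, to); insertions are
    (after_position, residues) with after_position 0..len meaning the new
    residues go between that position and the next.
    """

    name: str
    substitutions: tuple[tuple[int, str, str], ...] = ()
    insertions: tuple[tuple[int, str], ...] = ()

    @property
    def n_inserted(self) -> int:
        return sum(len(res) for _, res in self.insertions)


def apply_mutations(protein: ProteinRecord, spec: MutantSpec) -> ProteinRecord:
    """Apply a mutant spec; region ranges are shifted consistently past insertions."""
    seq = list(protein.sequence)
    for pos, frm, to in spec.substitutions:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"{spec.name}: substitution position {pos} out of range")
        if seq[pos - 1] != frm:
            raise ValueError(
                f"{spec.name}: expected {frm} at position {pos}, found {seq[pos - 1]}"
            )
        seq[pos - 1] = to
    for after, residues in sorted(spec.insertions, reverse=True):
        if not 0 <= after <= len(protein.sequence):
            raise ValueError(f"{spec.name}: insertion point {after} out of range")
        seq[after:after] = list(residues)

    def shift(p: int) -> int:
        return p + sum(len(res) for a, res in spec.insertions if a < p)

    regions = {
        rname: (shift(s - 1) + 1, shift(e)) for rname, (s, e) in protein.regions.items()
    }
    name = f"{protein.name}:{spec.name}" if protein.name else spec.name
    return ProteinRecord(sequence="".join(seq), regions=regions, name=name)


@dataclass
class ChargeReport:
    """Net charge of a region with its per-residue breakdown."""

    region: str
    net_charge: float
    breakdown: pd.DataFrame  # columns: position, residue, charge, phospho

    def to_tsv(self, path: str | Path) -> None:
        self.breakdown.to_csv(path, sep="\t", index=False)


def net_charge(
    protein: ProteinRecord,
    region: str | Sequence[str] | None = None,
    phospho: PhosphoSiteSet | None = None,
    charge_table: Mapping[str, float] | None = None,
    phospho_charge: float = DEFAULT_PHOSPHO_CHARGE,
) -> ChargeReport:
    """Sum per-residue charges over a region (termini ignored).

    ``region`` may be a region name, a sequence of names, or None for the
    whole chain.  Phosphorylated S/T positions inside the region add
    ``phospho_charge`` each on top of the (zero) side-chain charge.
    """
    table = dict(DEFAULT_CHARGE_TABLE) if charge_table is None else dict(charge_table)
    if region is None:
        positions = list(range(1, len(protein) + 1))
        region_name = "full"
    else:
        positions = protein.region_positions(region)
        region_name = region if isinstance(region, str) else "+".join(region)
    phos_positions = set(phospho.positions) if phospho is not None else set()
    if phospho is not None:
        phospho.validate_against(protein)

    rows = []
    for p in positions:
        aa = protein.residue(p)
        q = table.get(aa, 0.0)
        is_p = p in phos_positions
        if is_p:
            q += phospho_charge
        rows.append((p, aa, q, is_p))
    df = pd.DataFrame(rows, columns=["position", "residue", "charge", "phospho"])
    return ChargeReport(region=region_name, net_charge=float(df["charge"].sum()), breakdown=df)


def charge_rank(
    protein: ProteinRecord,
    mutants: Sequence[MutantSpec],
    region: str | Sequence[str] | None = None,
    charge_table: Mapping[str, float] | None = None,
    include_wt: bool = True,
) -> pd.DataFrame:
    """Rank mutants by region net charge (descending, i.e. least acidic first)."""
    rows = []
    if include_wt:
        rows.append(("WT", net_charge(protein, region, charge_table=charge_table).net_charge))
    for spec in mutants:
        mut = apply_mutations(protein, spec)
        rows.append((spec.name, net_charge(mut, region, charge_table=charge_table).net_charge))
    df = pd.DataFrame(rows, columns=["name", "net_charge"])
    wt_q = rows[0][1] if include_wt else None
    if wt_q is not None:
        df["delta_vs_wt"] = df["net_charge"] - wt_q
    return df.sort_values("net_charge", ascending=False, kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# Synthetic Pdd1p-like fixture
# --------------------------------------------------------------------------

PDD1_REGIONS: dict[str, tuple[int, int]] = {
    "NT": (1, 80),
    "CD1": (81, 140),
    "HNG1": (141, 240),
    "CD2": (241, 300),
    "HNG2": (301, 400),
    "CSD": (401, 480),
}

# placeholder positions: the real site coordinates are not tabulated anywhere,
# only the counts (31 in one study, 10 in another, 8 shared, 33 total) and
# their concentration in NT/HNG1/HNG2
_SITES_STUDY_A = (
    5, 12, 20, 33, 41, 52, 60, 71,            # NT
    95, 120,                                   # CD1
    145, 158, 166, 177, 189, 200, 214, 228,    # HNG1
    255, 280,                                  # CD2
    305, 318, 330, 342, 355, 368, 380, 395,    # HNG2
    410, 430, 450,                             # CSD
)
_SITES_STUDY_B_SHARED = (5, 12, 20, 33, 145, 158, 305, 318)
_SITES_STUDY_B_NOVEL = (220, 390)

#: Lys-insertion points (after-positions, within the hinge regions)
PDD1_INS6K_POINTS = (148, 160, 175, 320, 340, 360)

_QN_POSITIONS = (25, 45, 150, 170, 310, 325)  # Gln/Asn planted for Sub6K


def pdd1_like() -> tuple[ProteinRecord, PhosphoSiteSet, PhosphoSiteSet]:
    """Build the synthetic Pdd1p-like fixture protein and its two site inventories.

    This is a synthetic stand-in with the real domain architecture
    (NT-CD1-HNG1-CD2-HNG2-CSD) and the real site-set cardinalities
    (31 from one inventory, 10 from a second of which 2 are novel, 33
    merged), but placeholder residue coordinates.  Deterministic.
    """
    rng = np.random.default_rng(271828)
    L = 480
    pool = np.array(list("ADEFGIKLKNPQRSDVKEGA"))  # mildly charged background
    seq = pool[rng.integers(0, len(pool), size=L)]
    all_sites = sorted(set(_SITES_STUDY_A) | set(_SITES_STUDY_B_NOVEL))
    for i, p in enumerate(all_sites):
        seq[p - 1] = "S" if i % 2 == 0 else "T"
    for i, p in enumerate(_QN_POSITIONS):
        seq[p - 1] = "Q" if i % 2 == 0 else "N"
    protein = ProteinRecord(sequence="".join(seq), regions=PDD1_REGIONS, name="Pdd1p-like")

    def letter(p: int) -> str:
        return protein.residue(p)

    set_a = PhosphoSiteSet.build([(p, letter(p)) for p in _SITES_STUDY_A], "ms_this_study")
    set_b = PhosphoSiteSet.build(
        [(p, letter(p)) for p in _SITES_STUDY_B_SHARED + _SITES_STUDY_B_NOVEL], "ms_prior_study"
    )
    set_a.validate_against(protein)
    set_b.validate_against(protein)
    return protein, set_a, set_b


def mim_spec(
    protein: ProteinRecord,
    sites: PhosphoSiteSet,
    k: int,
    regions: Sequence[str] = ("NT", "HNG1", "HNG2"),
    name: str | None = None,
) -> MutantSpec:
    """Phospho-mimic mutant: the k most N-terminal S/T sites within the
    given regions are substituted with Glu."""
    allowed = set(protein.region_positions(regions))
    candidates = [s for s in sites.sites if s.position in allowed and s.residue in "ST"]
    if len(candidates) < k:
        raise ValueError(
            f"only {len(candidates)} S/T sites available in {'/'.join(regions)}, need {k}"
        )
    chosen = sorted(candidates, key=lambda s: s.position)[:k]
    return MutantSpec(
        name=name or f"MIM{k}",
        substitutions=tuple((s.position, s.residue, "E") for s in chosen),
    )


def with_lys_insertions(
    spec: MutantSpec, points: Sequence[int] = PDD1_INS6K_POINTS, name: str | None = None
) -> MutantSpec:
    """Add single-Lys insertions (default: the six hinge points, 'Ins6K')."""
    return MutantSpec(
        name=name or f"{spec.name}+Ins{len(points)}K",
        substitutions=spec.substitutions,
        insertions=spec.insertions + tuple((p, "K") for p in sorted(points)),
    )


def with_lys_substitutions(
    spec: MutantSpec,
    protein: ProteinRecord,
    n: int = 6,
    regions: Sequence[str] = ("NT", "HNG1", "HNG2"),
    name: str | None = None,
) -> MutantSpec:
    """Substitute the first n Gln/Asn in the given regions with Lys ('Sub6K')."""
    taken = {p for p, _, _ in spec.substitutions}
    candidates = [
        p for p in protein.region_positions(regions)
        if protein.residue(p) in "QN" and p not in taken
    ]
    if len(candidates) < n:
        raise ValueError(f"only {len(candidates)} Q/N residues available, need {n}")
    subs = tuple((p, protein.residue(p), "K") for p in candidates[:n])
    return MutantSpec(
        name=name or f"{spec.name}+Sub{n}K",
        substitutions=spec.substitutions + subs,
        insertions=spec.insertions,
    )


def pdd1_mutant_series(
    protein: ProteinRecord, merged_sites: PhosphoSiteSet
) -> dict[str, MutantSpec]:
    """The standard phospho-mimic series MIM10/14/18/22 and the two
    charge-compensated MIM22 variants."""
    series = {f"MIM{k}": mim_spec(protein, merged_sites, k) for k in (10, 14, 18, 22)}
    series["MIM22+Ins6K"] = with_lys_insertions(series["MIM22"])
    series["MIM22+Sub6K"] = with_lys_substitutions(series["MIM22"], protein)
    return series
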