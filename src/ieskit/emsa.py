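"""Equilibrium RNA-protein binding: simulation and Kd estimation.

The model is n_sites independent, identical protein-binding sites per RNA
molecule, each following the 1:1 law theta = P_free / (Kd + P_free).  With
ligand depletion enabled, P_free solves the mass balance
P_free = P_total - n_sites * R_total * theta (a quadratic with a unique
root in [0, P_total]); otherwise P_free is approximated by P_total.

"Fraction bound" is the probability that an RNA molecule carries at least
one protein, f = 1 - (1 - theta)^n_sites, matching gel-shift quantification
in which every shifted species counts as bound.  The per-shift-class
occupancy distribution is Binomial(n_sites, theta) — RNAs carrying k
proteins migrate as the k-th shifted band, so multiple bands indicate more
than one protein bound per RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import stage_rng

#: protein-concentration ladder used in the gel-shift titrations, nM
STANDARD_LADDER: tuple[float, ...] = (0.0, 10.4, 26.3, 52.5, 78.3, 104.0, 158.0, 210.0, 420.0, 630.0)

#: probe ssRNA concentration in the titrations, nM
STANDARD_RNA_NM: float = 10.4

#: reported dissociation constants (nM) for full-length protein variants
#: binding the EGFP ssRNA probe
REPORTED_KD: dict[str, float] = {
    "WT_FL": 65.0,
    "MIM14_FL": 340.0,
    "MIM22+Ins6K_FL": 347.0,
}

_LOG10_KD_BOUNDS = (-2.0, 5.0)  # Kd search window, log10 nM


@dataclass(frozen=True)
class BindingModel:
    """Independent-identical-sites equilibrium binding model."""

    kd: float  # nM
    n_sites: int = 1
    depletion: bool = True

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def free_protein(model: BindingModel, p_total, r_total) -> np.ndarray:
    """Free protein concentration under the mass balance (vectorized over P)."""
    P = np.asarray(p_total, dtype=float)
    if not model.depletion:
        return P
    S = model.n_sites * float(r_total)  # total site concentration
    b = model.kd + S - P
    # positive root of Pf^2 + b*Pf - Kd*P = 0
    return 0.5 * (-b + np.sqrt(b * b + 4.0 * model.kd * P))


def site_occupancy(model: BindingModel, p_total, r_total) -> np.ndarray:
    pf = free_protein(model, p_total, r_total)
    return pf / (model.kd + pf)


def fraction_bound(model: BindingModel, p_total, r_total) -> np.ndarray:
    """Fraction of RNA molecules with at least one occupied site."""
    theta = site_occupancy(model, p_total, r_total)
    return 1.0 - (1.0 - theta) ** model.n_sites


def occupancy_distribution(model: BindingModel, p_total: float, r_total: float) -> np.ndarray:
    """Probability of each shift class k = 0..n_sites (Binomial(n, theta))."""
    theta = float(site_occupancy(model, p_total, r_total))
    return stats.binom.pmf(np.arange(model.n_sites + 1), model.n_sites, theta)


@dataclass
class TitrationSeries:
    """An EMSA titration: protein ladder vs fraction of RNA shifted."""

    rna_conc: float  # nM
    protein: np.ndarray  # nM, total
    fraction: np.ndarray  # fraction bound in [0, 1]
    label: str = ""

    def __post_init__(self) -> None:
        self.protein = np.asarray(self.protein, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.protein.shape != self.fraction.shape:
            raise ValueError("protein and fraction arrays differ in length")
        if (self.protein < 0).any():
            raise ValueError("protein concentrations must be >= 0")
        if ((self.fraction < 0) | (self.fraction > 1)).any():
            raise ValueError("fraction bound must lie in [0, 1]")
        pos = self.protein[self.protein > 0]
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError("ladder must be strictly increasing after the zero point")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"protein_nM": self.protein, "fraction_bound": self.fraction}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, rna_conc: float = STANDARD_RNA_NM) -> "TitrationSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(
            rna_conc=rna_conc,
            protein=df.iloc[:, 0].to_numpy(),
            fraction=df.iloc[:, 1].to_numpy(),
        )


def simulate_titration(
    model: BindingModel,
    ladder: Sequence[float] = STANDARD_LADDER,
    rna_conc: float = STANDARD_RNA_NM,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> TitrationSeries:
    """Fraction-bound values from the binding law plus truncated Gaussian noise.

    noise_sd = 0 returns exact model values; otherwise independent Gaussian
    noise is added to each point and the result clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    P = np.asarray(ladder, dtype=float)
    if (P < 0).any():
        raise ValueError("ladder values must be >= 0")
    f = fraction_bound(model, P, rna_conc)
    if noise_sd > 0:
        rng = stage_rng(seed, f"titration:{label}")
        f = np.clip(f + rng.normal(0.0, noise_sd, size=f.shape), 0.0, 1.0)
    return TitrationSeries(rna_conc=rna_conc, protein=P, fraction=f, label=label)


@dataclass
class KdFit:
    """Result of a least-squares Kd fit.

    ``no_binding`` is True when the series shows no measurable shift; then
    ``kd`` is None and ``kd_lower_bound`` gives the smallest Kd compatible
    with the detection threshold at the top of the ladder.
    """

    kd: float | None
    residual_ss: float | None
    n_sites: int
    depletion: bool
    converged: bool
    no_binding: bool = False
    kd_lower_bound: float | None = None
    ci95: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "kd_nM": self.kd,
            "residual_ss": self.residual_ss,
            "n_sites": self.n_sites,
            "depletion": self.depletion,
            "converged": self.converged,
            "no_binding": self.no_binding,
            "kd_lower_bound_nM": self.kd_lower_bound,
            "ci95_nM": list(self.ci95) if self.ci95 else None,
        }


def _sse(log10_kd: float, P: np.ndarray, f_obs: np.ndarray, r: float, n_sites: int, depletion: bool) -> float:
    model = BindingModel(kd=10.0 ** log10_kd, n_sites=n_sites, depletion=depletion)
    return float(np.sum((fraction_bound(model, P, r) - f_obs) ** 2))


def fit_kd(
    series: TitrationSeries,
    n_sites: int = 1,
    depletion: bool = True,
    no_binding_threshold: float = 0.02,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> KdFit:
    """Estimate Kd by least squares over log10(Kd) in [1e-2, 1e5] nM.

    Requires at least 3 distinct positive protein concentrations.  A series
    in which no point exceeds ``no_binding_threshold`` is reported as an
    explicit no-binding result with a Kd lower bound rather than a numeric
    estimate.  Optional bootstrap (resampling points with replacement)
    yields a percentile 95% CI.
    """
    P, f = series.protein, series.fraction
    if len(np.unique(P[P > 0])) < 3:
        raise ValueError("need at least 3 distinct positive protein concentrations")

    if float(np.max(f)) < no_binding_threshold:
        # smallest Kd that would keep the top ladder point below threshold
        pmax = float(np.max(P))
        lb = pmax * (1.0 - no_binding_threshold) / no_binding_threshold
        return KdFit(
            kd=None, residual_ss=None, n_sites=n_sites, depletion=depletion,
            converged=True, no_binding=True, kd_lower_bound=lb,
        )

    def solve(Pv: np.ndarray, fv: np.ndarray) -> tuple[float, float, bool]:
        grid = np.linspace(*_LOG10_KD_BOUNDS, 71)
        sse = [_sse(g, Pv, fv, series.rna_conc, n_sites, depletion) for g in grid]
        x0 = grid[int(np.argmin(sse))]
        res = optimize.minimize_scalar(
            _sse,
            bounds=(max(_LOG10_KD_BOUNDS[0], x0 - 1.0), min(_LOG10_KD_BOUNDS[1], x0 + 1.0)),
            args=(Pv, fv, series.rna_conc, n_sites, depletion),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return 10.0 ** float(res.x), float(res.fun), bool(res.success)

    kd, rss, ok = solve(P, f)
    ci = None
    if n_bootstrap > 0:
        rng = stage_rng(seed, "kd_bootstrap")
        boots = []
        idx_pool = np.arange(len(P))
        for _ in range(n_bootstrap):
            idx = rng.choice(idx_pool, size=len(P), replace=True)
            if len(np.unique(P[idx][P[idx] > 0])) < 3:
                continue
            boots.append(solve(P[idx], f[idx])[0])
        if boots:
            ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return KdFit(
        kd=kd, residual_ss=rss, n_sites=n_sites, depletion=depletion,
        converged=ok, ci95=ci,
    )
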