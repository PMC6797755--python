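"""Cell-level spatial statistics.

Per-embryo marker-positive frequencies in AP bins (each embryo, not the
pooled cell population, is the unit of analysis), nuclear/cytoplasmic
intensity ratios, box-plot style group summaries, and an exact two-sided
2×2 Fisher test computed with integer arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .gradient_profile import APSpec

__all__ = [
    "BinnedFrequency",
    "NCMeasurement",
    "validate_cell_table",
    "bin_frequencies",
    "nc_ratio",
    "fisher_exact_2x2",
    "summarize",
    "sign_test_one_sided",
]

CELL_COLUMNS = ("embryo_id", "x", "y", "is_population", "is_marker")


@dataclass(frozen=True)
class BinnedFrequency:
    """Per-AP-bin marker frequencies, anterior → posterior."""

    per_embryo: tuple[tuple[float, ...], ...]  # one tuple of embryo values per bin
    means: np.ndarray
    sems: np.ndarray
    n_embryos: np.ndarray
    n_cells: np.ndarray
    edges: np.ndarray  # n_bins+1 AP coordinates

    @property
    def n_bins(self) -> int:
        return len(self.means)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "mean_frequency": self.means,
                "sem": self.sems,
                "n_embryos": self.n_embryos,
                "n_cells": self.n_cells,
            }
        )


@dataclass(frozen=True)
class NCMeasurement:
    """Nuclear and cytoplasmic mean intensities for one cell."""

    cell_id: int
    nuclear_mean: float
    cytoplasmic_mean: float

    @property
    def ratio(self) -> float:
        return self.nuclear_mean / self.cytoplasmic_mean


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table lacks columns: {missing}")
    bad = cells["is_marker"].astype(bool) & ~cells["is_population"].astype(bool)
    if bad.any():
        raise ValueError("marker-positive cells must belong to the population")
    return cells


def bin_frequencies(
    cells: pd.DataFrame, spec: APSpec = APSpec(), n_bins: int = 5
) -> BinnedFrequency:
    """Marker-positive frequency per embryo per AP bin, then mean ± SEM.

    Bins partition the AP extent of the population cells into ``n_bins``
    equal-width intervals (the posterior-most edge is inclusive).  An embryo
    with no population cell in a bin contributes no value there.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    validate_cell_table(cells)
    pop = cells[cells["is_population"].astype(bool)].copy()
    if pop.empty:
        raise ValueError("no population cells")
    for emb, grp in pop.groupby("embryo_id"):
        if grp.empty:  # pragma: no cover - groupby never yields empty groups
            raise ValueError(f"embryo {emb} has no population cells")
    coord = pop["x"] if spec.ap_axis[0] == "x" else pop["y"]
    coord = coord.astype(float)
    if spec.ap_axis[1] == "-":
        coord = -coord  # posterior-ness increases with the bin index
    lo, hi = coord.min(), coord.max()
    if hi == lo:
        hi = lo + 1.0  # all cells at one coordinate: a single occupied bin
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges[1:-1], coord, side="right"), 0, n_bins - 1)
    pop["_bin"] = idx

    per_embryo: list[list[float]] = [[] for _ in range(n_bins)]
    n_cells = np.zeros(n_bins, dtype=int)
    for _, grp in pop.groupby("embryo_id"):
        counts = grp.groupby("_bin").agg(
            n=("is_marker", "size"), k=("is_marker", "sum")
        )
        for b, row in counts.iterrows():
            per_embryo[int(b)].append(float(row["k"] / row["n"]))
            n_cells[int(b)] += int(row["n"])
    means = np.full(n_bins, np.nan)
    sems = np.full(n_bins, np.nan)
    n_embryos = np.zeros(n_bins, dtype=int)
    for b, vals in enumerate(per_embryo):
        if vals:
            arr = np.asarray(vals)
            means[b] = arr.mean()
            sems[b] = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
            n_embryos[b] = len(arr)
    return BinnedFrequency(
        per_embryo=tuple(tuple(v) for v in per_embryo),
        means=means,
        sems=sems,
        n_embryos=n_embryos,
        n_cells=n_cells,
        edges=edges,
    )


def nc_ratio(
    image: np.ndarray,
    nuclear_mask: np.ndarray,
    cyto_mask: np.ndarray,
    labels: np.ndarray,
) -> list[NCMeasurement]:
    """Per-cell nuclear/cytoplasmic mean-intensity measurements.

    ``labels`` assigns pixels to cells (0 = background); the nuclear and
    cytoplasmic masks must be disjoint.  Cells whose cytoplasmic mean is zero
    (or that lack pixels in either compartment) are omitted with a warning.
    """
    image = np.asarray(image, dtype=float)
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    cyto_mask = np.asarray(cyto_mask, dtype=bool)
    labels = np.asarray(labels)
    if (nuclear_mask & cyto_mask).any():
        raise ValueError("nuclear and cytoplasmic masks overlap")
    out: list[NCMeasurement] = []
    for cid in np.unique(labels):
        if cid == 0:
            continue
        cell = labels == cid
        nuc = image[cell & nuclear_mask]
        cyt = image[cell & cyto_mask]
        if nuc.size == 0 or cyt.size == 0 or cyt.mean() == 0:
            warnings.warn(
                f"cell {cid}: undefined N/C ratio (empty compartment or zero "
                "cytoplasmic mean); omitted",
                stacklevel=2,
            )
            continue
        out.append(NCMeasurement(int(cid), float(nuc.mean()), float(cyt.mean())))
    return out


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table, exact arithmetic.

    With margins fixed, sums the hypergeometric probabilities of all tables
    whose probability does not exceed the observed table's (the
    minimum-likelihood two-sided convention used by common desktop tools).
    Comparisons are made on integer numerators over the common denominator
    C(n, c1), so ties are resolved exactly.  A zero margin returns p = 1 with
    a warning.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError("table must be 2×2")
    flat = []
    for v in t.ravel():
        if v != int(v) or int(v) < 0:
            raise ValueError("table entries must be nonnegative integers")
        flat.append(int(v))
    a, b, c, d = flat
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        warnings.warn("degenerate 2×2 table (zero margin); p = 1 by convention",
                      stacklevel=2)
        return 1.0
    klo, khi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(klo, khi + 1)]
    observed = weights[a - klo]
    num = sum(w for w in weights if w <= observed)
    return float(Fraction(num, math.comb(n, c1)))


def summarize(values: Sequence[float]) -> dict:
    """Box-plot style summary: quartiles (linear interpolation), extremes,
    mean and SEM.  A single value yields SEM 0."""
    arr = np.sort(np.asarray(values, dtype=float))  # exact permutation invariance
    if arr.size == 0:
        raise ValueError("empty group")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return {
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "sem": sem,
    }


def sign_test_one_sided(n_wins: int, n_losses: int) -> float:
    """Exact one-sided sign test: P(X >= n_wins), X ~ Binomial(n, 1/2).

    Ties are excluded before calling (standard sign-test practice)."""
    if n_wins < 0 or n_losses < 0:
        raise ValueError("counts must be nonnegative")
    n = n_wins + n_losses
    if n == 0:
        return 1.0
    num = sum(math.comb(n, k) for k in range(n_wins, n + 1))
    return float(Fraction(num, 2**n))
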