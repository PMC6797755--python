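"""Mosaic-specific differential-expression gating.

Given per-gene statistics for two contrasts against a common reference —
mosaically perturbed cells vs unperturbed, and ubiquitously perturbed vs
unperturbed — extract the genes responding only in the mosaic contrast.
These are the candidates attributable to the *introduction* of scattered
unfit cells rather than to the signalling perturbation itself.  Significance
is an FDR cut (default < 0.1); "not in Ubiquitous" means not significant at
the same threshold, with no effect-size requirement.  Gated sets can be
annotated against supplied gene panels (e.g. a Smad-target list).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .synthetic_scene import MOSAIC, UBIQUITOUS

__all__ = ["GateResult", "gate", "annotate", "RECORD_COLUMNS"]

RECORD_COLUMNS = ("gene_id", "contrast", "log2_fold_change", "fdr")


@dataclass(frozen=True)
class GateResult:
    """Gated gene sets plus panel annotations.

    ``mosaic_specific_up`` / ``_down`` / ``shared`` are pairwise disjoint.
    """

    mosaic_specific_up: frozenset[str]
    mosaic_specific_down: frozenset[str]
    shared: frozenset[str]
    fdr_threshold: float
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = (self.mosaic_specific_up, self.mosaic_specific_down, self.shared)
        total = len(self.mosaic_specific_up | self.mosaic_specific_down | self.shared)
        if total != sum(len(s) for s in sets):
            raise ValueError("gated sets must be pairwise disjoint")


def gate(records: pd.DataFrame, fdr_threshold: float = 0.1) -> GateResult:
    """Extract mosaic-specific (by direction) and shared significant genes.

    A gene is mosaic-specific-up when its mosaic-contrast FDR is below the
    threshold with a positive log2 fold change while it is *not* significant
    in the ubiquitous contrast; -down analogously for negative fold changes.
    Genes significant in both contrasts are "shared".  Genes missing a
    contrast row (or with a missing FDR) count as not significant there.
    Duplicate (gene, contrast) rows are an error.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must lie in (0, 1)")
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"DE table lacks columns: {missing}")
    known = {MOSAIC, UBIQUITOUS}
    unknown = set(records["contrast"].unique()) - known
    if unknown:
        raise ValueError(f"unknown contrasts {sorted(unknown)}; expected {sorted(known)}")
    dup = records.duplicated(subset=["gene_id", "contrast"], keep=False)
    if dup.any():
        offenders = sorted(
            records.loc[dup, ["gene_id", "contrast"]]
            .itertuples(index=False, name=None)
        )
        raise ValueError(f"duplicate (gene, contrast) rows: {offenders}")

    wide_fdr = records.pivot(index="gene_id", columns="contrast", values="fdr")
    wide_lfc = records.pivot(
        index="gene_id", columns="contrast", values="log2_fold_change"
    )
    for w in (wide_fdr, wide_lfc):
        for contrast in known:
            if contrast not in w.columns:
                w[contrast] = float("nan")
    sig_m = wide_fdr[MOSAIC] < fdr_threshold  # NaN compares False: not significant
    sig_u = wide_fdr[UBIQUITOUS] < fdr_threshold
    lfc_m = wide_lfc[MOSAIC]
    up = sig_m & ~sig_u & (lfc_m > 0)
    down = sig_m & ~sig_u & (lfc_m < 0)
    shared = sig_m & sig_u
    return GateResult(
        mosaic_specific_up=frozenset(wide_fdr.index[up]),
        mosaic_specific_down=frozenset(wide_fdr.index[down]),
        shared=frozenset(wide_fdr.index[shared]),
        fdr_threshold=fdr_threshold,
    )


def annotate(result: GateResult, panel_name: str, gene_list: Iterable[str]) -> dict:
    """Intersect each gated set with a gene panel (case-insensitive match).

    Returns the annotation entry and records it on ``result.annotations``
    under ``panel_name``.
    """
    panel = {g.casefold() for g in gene_list}
    if not panel:
        raise ValueError("empty panel")
    entry = {}
    for set_name in ("mosaic_specific_up", "mosaic_specific_down", "shared"):
        members = sorted(
            g for g in getattr(result, set_name) if g.casefold() in panel
        )
        entry[set_name] = {"members": members, "count": len(members)}
    result.annotations[panel_name] = entry
    return entry
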