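"""Interactor classification and set intersections.

Contrast tables become biological calls here:

* cysteine-dependent interactors -- enriched with WT bait over the
  catalytic-dead CPRS bait (default gate: log2FC > 1 and raw p < 0.05);
* peroxidatic-cysteine-dependent interactors -- enriched with the CRS
  bait over CPRS (the resolving cysteine is dispensable);
* isoform-specific interactors -- enriched in one isoform's baits over
  all other isoforms pooled (default gate uses BH-adjusted p);
* relay mechanism -- WT binders that also bind the CRS bait can engage
  via the sulfenylated peroxidatic cysteine (``SOH``); WT binders lost in
  CRS require the Cp-S-S-Cr disulfide (``SS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd


def classify_enriched(
    contrast: pd.DataFrame,
    delta_min: float = 1.0,
    alpha: float = 0.05,
    p_mode: str = "raw",
) -> set[str]:
    """Ids with delta > delta_min and (raw or BH-adjusted) p < alpha.

    Only positive fold change counts: enrichment direction is toward the
    first condition of the contrast (the bait expected to bind).
    """
    if delta_min < 0:
        raise ValueError("delta_min must be >= 0")
    if p_mode not in ("raw", "bh"):
        raise ValueError("p_mode must be 'raw' or 'bh'")
    if contrast.empty:
        return set()
    pcol = "p" if p_mode == "raw" else "q"
    hit = (contrast["delta"] > delta_min) & (contrast[pcol] < alpha)
    return set(contrast.index[hit])


def classify_cysteine_dependent(
    contrast_wt_vs_cprs: pd.DataFrame,
    delta_min: float = 1.0,
    alpha: float = 0.05,
    p_mode: str = "raw",
) -> set[str]:
    """WT-over-CPRS enriched proteins: cysteine-dependent binders."""
    return classify_enriched(contrast_wt_vs_cprs, delta_min, alpha, p_mode)


def classify_isoform_specific(
    contrasts_iso_vs_rest: Mapping[str, pd.DataFrame],
    delta_min: float = 1.0,
    alpha: float = 0.05,
    p_mode: str = "bh",
) -> dict[str, set[str]]:
    """Per-isoform sets enriched against all other isoforms pooled."""
    return {
        iso: classify_enriched(tab, delta_min, alpha, p_mode)
        for iso, tab in contrasts_iso_vs_rest.items()
    }


@dataclass
class MechanismSplit:
    """Partition of WT binders by relay mechanism."""

    soh: set[str]
    ss: set[str]
    crs_only: set[str]  # bind the CRS mutant but not WT; reported, not classified
    ss_percent: float | None  # None when there are no WT binders

    @property
    def mechanism(self) -> dict[str, str]:
        out = {pid: "SOH" for pid in self.soh}
        out.update({pid: "SS" for pid in self.ss})
        return out


def classify_mechanism(wt_set: set[str], crs_set: set[str]) -> MechanismSplit:
    """Split WT binders into SOH-capable (also bind CRS) vs disulfide-only.

    ``SOH = wt & crs`` (the peroxidatic cysteine suffices), ``SS = wt - crs``
    (binding requires the Cp-S-S-Cr disulfide).  Proteins binding the CRS
    mutant only are excluded from the percentage and reported separately.
    """
    soh = set(wt_set) & set(crs_set)
    ss = set(wt_set) - set(crs_set)
    crs_only = set(crs_set) - set(wt_set)
    n_wt = len(wt_set)
    ss_percent = (100.0 * len(ss) / n_wt) if n_wt else None
    return MechanismSplit(soh=soh, ss=ss, crs_only=crs_only, ss_percent=ss_percent)


@dataclass
class IntersectionTable:
    """Exclusive membership patterns over a family of named sets."""

    patterns: dict[frozenset, set[str]] = field(default_factory=dict)
    set_names: tuple[str, ...] = ()

    @property
    def counts(self) -> dict[frozenset, int]:
        return {pat: len(ids) for pat, ids in self.patterns.items()}

    @property
    def union_size(self) -> int:
        return sum(len(ids) for ids in self.patterns.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pat in sorted(self.patterns, key=lambda p: (-len(p), sorted(p))):
            rows.append(
                {
                    "pattern": "&".join(sorted(pat)),
                    "degree": len(pat),
                    "count": len(self.patterns[pat]),
                    "ids": ";".join(sorted(self.patterns[pat])),
                }
            )
        return pd.DataFrame(rows, columns=["pattern", "degree", "count", "ids"])


def set_intersections(sets: Mapping[str, set[str]]) -> IntersectionTable:
    """Exclusive-intersection counts for every non-empty membership pattern.

    Each element of the union is assigned to exactly the pattern of sets
    containing it, so pattern counts sum to the union size (the UpSet
    layout).
    """
    if not sets:
        raise ValueError("need at least one set")
    names = tuple(sets)
    patterns: dict[frozenset, set[str]] = {}
    universe = set().union(*sets.values())
    for pid in universe:
        pat = frozenset(name for name in names if pid in sets[name])
        patterns.setdefault(pat, set()).add(pid)
    return IntersectionTable(patterns=patterns, set_names=names)


def pairwise_overlap(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Venn-style pairwise overlap counts (diagonal = set sizes)."""
    names = list(sets)
    out = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for name in names:
        out.loc[name, name] = len(sets[name])
    for a, b in combinations(names, 2):
        n = len(sets[a] & sets[b])
        out.loc[a, b] = out.loc[b, a] = n
    return out
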