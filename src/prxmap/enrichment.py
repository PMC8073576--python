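"""Annotation overlap: redox-sensitivity reference and compartment enrichment."""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: marker for fractions/folds that cannot be computed (empty set, empty background)
UNDEFINED = float("nan")


def redox_overlap(
    sets: Mapping[str, set[str]],
    reference_ids: set[str],
    universe_ids: set[str],
) -> pd.DataFrame:
    """Percentage of each interactor set previously reported redox-sensitive.

    The universe (all quantified proteins surviving the filters) provides
    the baseline percentage; rows report observed %, baseline % and their
    ratio.  An ``overall`` row pools the union of all sets.
    """
    for name, ids in sets.items():
        if not ids <= universe_ids:
            raise ValueError(f"set {name!r} is not contained in the universe")
    baseline = (
        100.0 * len(universe_ids & reference_ids) / len(universe_ids)
        if universe_ids
        else UNDEFINED
    )
    rows = []
    pooled: set[str] = set()
    for name, ids in sets.items():
        pooled |= ids
        pct = 100.0 * len(ids & reference_ids) / len(ids) if ids else UNDEFINED
        rows.append((name, pct, baseline, len(ids)))
    pct_all = 100.0 * len(pooled & reference_ids) / len(pooled) if pooled else UNDEFINED
    rows.append(("overall", pct_all, baseline, len(pooled)))
    out = pd.DataFrame(
        rows, columns=["set", "redox_sensitive_pct", "background_pct", "n"]
    )
    out["fold_enrichment"] = np.where(
        out["background_pct"] > 0,
        out["redox_sensitive_pct"] / out["background_pct"],
        UNDEFINED,
    )
    return out


def localization_enrichment(
    interactor_sets: Mapping[str, set[str]],
    contrasts: Mapping[str, pd.DataFrame],
    compartment_table: pd.DataFrame,
    fold_min: float = 10.0,
    compartments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Compartment fold-enrichment of each isoform's strongest interactors.

    Set members with a WT-over-CPRS fold change above ``fold_min`` (i.e.
    ``delta > log2(fold_min)``) are matched to their subcellular
    neighborhood; per compartment, fold enrichment is the fraction among
    the selected proteins over the fraction in the full annotation table.
    Compartments absent from the background get an undefined (NaN) fold;
    unannotated selected proteins are counted as ``n_missing``.
    """
    if fold_min <= 0:
        raise ValueError("fold_min must be > 0")
    delta_min = math.log2(fold_min)
    comp_of = dict(
        zip(compartment_table["protein_id"], compartment_table["compartment"])
    )
    background = compartment_table["compartment"].value_counts(normalize=True)
    if compartments is None:
        compartments = list(background.index)

    rows = []
    for iso, ids in interactor_sets.items():
        contrast = contrasts[iso]
        present = [pid for pid in ids if pid in contrast.index]
        selected = [pid for pid in present if contrast.loc[pid, "delta"] > delta_min]
        annotated = [pid for pid in selected if pid in comp_of]
        n_missing = len(selected) - len(annotated)
        counts = pd.Series([comp_of[pid] for pid in annotated]).value_counts()
        for comp in compartments:
            obs_frac = (
                counts.get(comp, 0) / len(annotated) if annotated else UNDEFINED
            )
            bg_frac = float(background.get(comp, 0.0))
            fold = obs_frac / bg_frac if bg_frac > 0 else UNDEFINED
            rows.append(
                {
                    "isoform": iso,
                    "compartment": comp,
                    "observed_fraction": obs_frac,
                    "background_fraction": bg_frac,
                    "fold_enrichment": fold,
                    "n_selected": len(selected),
                    "n_annotated": len(annotated),
                    "n_missing": n_missing,
                }
            )
    return pd.DataFrame(rows)
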