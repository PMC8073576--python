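"""Label-randomization calibration of the log2 fold-change threshold.

The WT-enrichment threshold is calibrated empirically: WT / catalytic-dead
(CPRS) labels are shuffled within each isoform (replicate structure kept),
the dropout model is refit, and the resulting null |log2 fold changes| are
pooled across permutations and isoforms.  The threshold tau is the
(1 - alpha) quantile of that pooled null, i.e. the fold change at which
alpha of the randomized data would still be called enriched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExperimentDesign, IntensityMatrix
from .dropout import ProbabilisticDropoutModel

UNDEFINED_FDR = float("nan")


@dataclass
class CalibrationResult:
    """Permutation-calibrated fold-change threshold and FDR curve."""

    tau: float
    alpha: float
    n_perm: int
    perm_deltas: np.ndarray  # pooled |delta| over permutations x isoforms
    real_deltas: np.ndarray  # pooled unpermuted |delta|
    included_fraction_real: float
    seed: int
    metadata: dict = field(default_factory=dict)

    def fdr_at(self, tau_prime: float) -> "FdrEstimate":
        return fdr_at_threshold(self.real_deltas, self.perm_deltas, tau_prime, self.n_perm)


@dataclass
class FdrEstimate:
    fdr: float  # NaN marks "undefined" (no real discoveries)
    n_real_included: int
    n_perm_included_mean: float
    included_fraction_real: float
    included_fraction_perm: float


def fdr_at_threshold(
    real_deltas: np.ndarray,
    perm_deltas: np.ndarray,
    tau_prime: float,
    n_perm: int,
) -> FdrEstimate:
    """Empirical FDR: mean per-permutation exceedances over real exceedances."""
    if tau_prime < 0:
        raise ValueError("threshold must be non-negative")
    real = np.abs(np.asarray(real_deltas, dtype=float))
    perm = np.abs(np.asarray(perm_deltas, dtype=float))
    n_real = int((real > tau_prime).sum())
    mean_perm = float((perm > tau_prime).sum()) / n_perm
    if n_real == 0:
        fdr = UNDEFINED_FDR
    else:
        fdr = min(mean_perm / n_real, 1.0)
    return FdrEstimate(
        fdr=fdr,
        n_real_included=n_real,
        n_perm_included_mean=mean_perm,
        included_fraction_real=n_real / len(real) if len(real) else 0.0,
        included_fraction_perm=float((perm > tau_prime).mean()) if len(perm) else 0.0,
    )


def _shuffled_design(
    design: ExperimentDesign,
    rng: np.random.Generator,
    genotype_a: str,
    genotype_b: str,
) -> ExperimentDesign:
    """Shuffle genotype labels between the two contrasted genotypes, per isoform."""
    relabel: dict[str, str] = {}
    tab = design.table
    for iso in design.isoforms:
        mask = (tab["isoform"] == iso) & tab["genotype"].isin([genotype_a, genotype_b])
        sids = list(tab.index[mask])
        labels = list(tab.loc[sids, "genotype"])
        perm = rng.permutation(len(labels))
        for sid, k in zip(sids, perm):
            relabel[sid] = labels[k]
    return design.relabel(relabel)


def randomize_labels_fdr(
    matrix: IntensityMatrix,
    design: ExperimentDesign,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    genotype_a: str = "WT",
    genotype_b: str = "CPRS",
    isoforms: Sequence[str] | None = None,
) -> CalibrationResult:
    """Calibrate tau by refitting the dropout model on label-shuffled data.

    For each permutation the ``genotype_a``/``genotype_b`` labels are
    shuffled within each isoform, the model refit on that isoform's
    samples, and per-protein |delta| collected; ``tau`` is the
    ``1 - alpha`` quantile (linear / type-7 interpolation) of the pooled
    randomized |delta|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if isoforms is None:
        isoforms = design.isoforms
    for iso in isoforms:
        for gt in (genotype_a, genotype_b):
            sids = design.samples_in(f"{iso}:{gt}")
            if len(sids) < 2:
                raise ValueError(f"condition {iso}:{gt} needs at least 2 samples")

    def _deltas(d: ExperimentDesign) -> np.ndarray:
        out = []
        for iso in isoforms:
            cond_a, cond_b = f"{iso}:{genotype_a}", f"{iso}:{genotype_b}"
            sids = d.samples_in(cond_a) + d.samples_in(cond_b)
            sub = IntensityMatrix(matrix.values[sids], scale=matrix.scale)
            res = ProbabilisticDropoutModel(sub, d.subset(sids)).fit(moderate=False)
            out.append(np.abs(res.contrast(cond_a, cond_b)["delta"].to_numpy()))
        return np.concatenate(out)

    real = _deltas(design)
    rng = np.random.default_rng([int(seed), 97])
    perm_chunks = []
    for _ in range(n_perm):
        perm_chunks.append(_deltas(_shuffled_design(design, rng, genotype_a, genotype_b)))
    perm = np.concatenate(perm_chunks)

    tau = float(np.quantile(perm, 1.0 - alpha))  # numpy default = type-7 linear
    included = float((real > tau).mean()) if len(real) else 0.0
    return CalibrationResult(
        tau=tau,
        alpha=alpha,
        n_perm=n_perm,
        perm_deltas=perm,
        real_deltas=real,
        included_fraction_real=included,
        seed=seed,
        metadata={
            "genotypes": (genotype_a, genotype_b),
            "isoforms": list(isoforms),
            "shuffle_scope": "within-isoform",
            "pooling": "across-isoforms",
        },
    )


def calibration_report(result: CalibrationResult) -> pd.DataFrame:
    """Threshold -> inclusion/FDR table for a grid of candidate cutoffs."""
    taus = np.unique(np.concatenate([[0.0, result.tau, 1.0], np.linspace(0, 4, 41)]))
    rows = []
    for tp in taus:
        est = result.fdr_at(float(tp))
        rows.append(
            {
                "tau": tp,
                "fdr": est.fdr,
                "included_fraction_real": est.included_fraction_real,
                "included_fraction_perm": est.included_fraction_perm,
            }
        )
    return pd.DataFrame(rows)
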