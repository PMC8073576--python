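"""Planted-truth synthetic IP-MS experiments.

Emulates the statistical structure of a label-free co-immunoprecipitation
screen against peroxiredoxin baits: five isoforms (PRDX1-5), three bait
genotypes per isoform (wild type, resolving-cysteine mutant C_R->S, and the
catalytic-dead double mutant C_PR->S), three biological replicates, and a
sigmoidal intensity-dependent dropout process producing on the order of a
third missing values per sample.

Every generated dataset carries its ground truth: which proteins bind which
isoform, whether binding requires the catalytic cysteines, and through
which relay mechanism (condensation with the sulfenylated peroxidatic
cysteine, ``SOH``, versus exchange with the Cp-S-S-Cr disulfide, ``SS``).
The mechanism determines which bait genotypes show the enrichment:

================  ======  =======  =======
binding class       WT      CRS      CPRS
================  ======  =======  =======
non-cys-dependent  yes      yes      yes
SOH-mediated       yes      yes      no
SS-mediated        yes      no       no
================  ======  =======  =======
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .containers import GENOTYPES, ISOFORMS, ExperimentDesign, IntensityMatrix, ProteinTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# fixed per-operation offsets so partial regeneration from one seed is stable
_STREAM_TRUTH = 11
_STREAM_LFQ = 23
_STREAM_SEQ = 37
_STREAM_COMPARTMENT = 41


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated protein."""

    protein_id: str
    baseline_abundance: float
    binds_isoforms: tuple[str, ...] = ()
    cys_dependent: dict[str, bool] = field(default_factory=dict)
    mechanism: dict[str, str] = field(default_factory=dict)  # isoform -> SOH|SS|none
    effect_size: float = 0.0
    is_decoy: bool = False
    decoy_kind: str | None = None  # "reverse" | "contaminant"
    n_unique_peptides: int = 3
    redox_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.is_decoy and self.binds_isoforms:
            raise ValueError("decoys cannot bind isoforms")
        for iso in self.binds_isoforms:
            mech = self.mechanism.get(iso, "none")
            if mech not in ("SOH", "SS", "none"):
                raise ValueError(f"unknown mechanism {mech!r}")
            if mech != "none" and not self.cys_dependent.get(iso, False):
                raise ValueError("mechanism requires cysteine dependence")

    def effect_in(self, isoform: str, genotype: str) -> float:
        """Log2 enrichment this protein shows in the given bait condition."""
        if isoform not in self.binds_isoforms:
            return 0.0
        if not self.cys_dependent.get(isoform, False):
            return self.effect_size
        mech = self.mechanism[isoform]
        if mech == "SOH":
            return self.effect_size if genotype in ("WT", "CRS") else 0.0
        return self.effect_size if genotype == "WT" else 0.0  # SS: WT only


@dataclass
class TruthConfig:
    """Generator settings for :func:`generate_interactome_truth`.

    Defaults mirror the screen the pipeline targets: most interactors bind
    through the catalytic cysteines, a 70/30 split between the SOH- and
    disulfide-relay mechanisms, and a planted log2 enrichment of 4 (a
    16-fold pull-down enrichment, comfortably above the log2FC > 1 gate).
    """

    n_background: int = 800
    n_interactors: int = 200
    n_reverse_decoys: int = 20
    n_contaminants: int = 20
    effect_size: float = 4.0
    frac_cys_dependent: float = 0.85
    mechanism_mix: Mapping[str, float] = field(
        default_factory=lambda: {"SOH": 0.7, "SS": 0.3}
    )
    frac_isoform_specific: float = 0.6
    isoforms: Sequence[str] = ISOFORMS
    baseline_mean: float = 25.0
    baseline_sd: float = 3.0
    low_peptide_fraction: float = 0.05
    redox_sensitive_frac_binders: float = 0.4
    redox_sensitive_frac_background: float = 0.13
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_background", "n_interactors", "n_reverse_decoys", "n_contaminants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = sum(self.mechanism_mix.values())
        if total > 1 + 1e-9 or any(v < 0 for v in self.mechanism_mix.values()):
            raise ValueError("mechanism_mix proportions must be >= 0 and sum to <= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def generate_interactome_truth(config: TruthConfig) -> list[SyntheticTruth]:
    """Draw the planted interactome truth table.

    Interactors are isoform-specific (bind exactly one isoform) with
    probability ``frac_isoform_specific``, otherwise they bind a random
    subset of 2+ isoforms.  Mechanisms are drawn per bound isoform from
    ``mechanism_mix`` for cysteine-dependent binders.
    """
    config.validate()
    rng = _rng(config.seed, _STREAM_TRUTH)
    isoforms = list(config.isoforms)
    mix_names = list(config.mechanism_mix)
    mix_p = np.array([config.mechanism_mix[m] for m in mix_names], dtype=float)
    if mix_p.sum() > 0:
        mix_p = mix_p / mix_p.sum()

    truths: list[SyntheticTruth] = []

    def _peptides() -> int:
        if rng.random() < config.low_peptide_fraction:
            return int(rng.integers(1, 3))
        return int(3 + rng.poisson(7.0))

    def _baseline() -> float:
        return float(rng.normal(config.baseline_mean, config.baseline_sd))

    for i in range(config.n_interactors):
        if len(isoforms) == 1 or rng.random() < config.frac_isoform_specific:
            bound = (isoforms[rng.integers(len(isoforms))],)
        else:
            k = int(rng.integers(2, len(isoforms) + 1))
            bound = tuple(sorted(rng.choice(isoforms, size=k, replace=False)))
        cys: dict[str, bool] = {}
        mech: dict[str, str] = {}
        for iso in bound:
            dep = bool(rng.random() < config.frac_cys_dependent)
            cys[iso] = dep
            mech[iso] = mix_names[rng.choice(len(mix_names), p=mix_p)] if dep else "none"
        truths.append(
            SyntheticTruth(
                protein_id=f"INT{i:04d}",
                baseline_abundance=_baseline(),
                binds_isoforms=bound,
                cys_dependent=cys,
                mechanism=mech,
                effect_size=config.effect_size,
                n_unique_peptides=_peptides(),
                redox_sensitive=bool(rng.random() < config.redox_sensitive_frac_binders),
            )
        )
    for i in range(config.n_background):
        truths.append(
            SyntheticTruth(
                protein_id=f"BG{i:04d}",
                baseline_abundance=_baseline(),
                n_unique_peptides=_peptides(),
                redox_sensitive=bool(
                    rng.random() < config.redox_sensitive_frac_background
                ),
            )
        )
    for i in range(config.n_reverse_decoys):
        truths.append(
            SyntheticTruth(
                protein_id=f"REV__D{i:04d}",
                baseline_abundance=_baseline(),
                is_decoy=True,
                decoy_kind="reverse",
                n_unique_peptides=_peptides(),
            )
        )
    for i in range(config.n_contaminants):
        truths.append(
            SyntheticTruth(
                protein_id=f"CON__C{i:04d}",
                baseline_abundance=_baseline(),
                is_decoy=True,
                decoy_kind="contaminant",
                n_unique_peptides=_peptides(),
            )
        )
    return truths


@dataclass
class DropoutSpec:
    """Sigmoidal dropout process: P(missing | value y) = Phi((rho - y)/zeta).

    ``rho`` is the log2 intensity at which half the values drop out and
    ``zeta`` the width of the transition.  If ``target_missing_fraction``
    is set, ``rho`` is solved per sample so the expected missing fraction
    matches it; ``rho = -inf`` disables dropout entirely.
    """

    rho: float | None = None
    zeta: float = 1.0
    target_missing_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be > 0")
        if self.target_missing_fraction is not None and not (
            0 <= self.target_missing_fraction <= 1
        ):
            raise ValueError("target_missing_fraction must be in [0, 1]")
        if self.rho is None and self.target_missing_fraction is None:
            raise ValueError("either rho or target_missing_fraction is required")

    def solve_rho(self, values: np.ndarray) -> float:
        """Find rho so that mean Phi((rho - y)/zeta) equals the target."""
        if self.target_missing_fraction is None:
            assert self.rho is not None
            return self.rho
        t = self.target_missing_fraction
        if t == 0:
            return -np.inf
        if t == 1:
            return np.inf

        def gap(rho: float) -> float:
            return float(norm.cdf((rho - values) / self.zeta).mean() - t)

        lo = float(values.min()) - 10 * self.zeta
        hi = float(values.max()) + 10 * self.zeta
        return float(brentq(gap, lo, hi, xtol=1e-8))


def simulate_lfq_experiment(
    truths: Sequence[SyntheticTruth],
    design: ExperimentDesign,
    dropout: DropoutSpec,
    noise_sd: float = 0.8,
    seed: int = 0,
) -> tuple[IntensityMatrix, ProteinTable]:
    """Simulate one LFQ screen on the log2 scale.

    Each cell is ``baseline + planted effect + Normal(0, noise_sd)``; the
    planted effect follows the mechanism table of the module docstring.
    Cells then drop out with probability ``Phi((rho_j - y)/zeta)`` where
    ``rho_j`` is shared or solved per sample.  Returns a log2-scale
    :class:`IntensityMatrix` (missing = NaN) and the protein metadata
    table, including decoy flags.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = _rng(seed, _STREAM_LFQ)
    sample_ids = design.sample_ids
    n, m = len(truths), len(sample_ids)

    base = np.array([t.baseline_abundance for t in truths], dtype=float)
    effects = np.zeros((n, m))
    for j, sid in enumerate(sample_ids):
        row = design.table.loc[sid]
        iso, gt = row["isoform"], row["genotype"]
        for i, t in enumerate(truths):
            effects[i, j] = t.effect_in(iso, gt)

    y = base[:, None] + effects + rng.normal(0.0, noise_sd, size=(n, m))

    miss = np.zeros((n, m), dtype=bool)
    for j in range(m):
        rho_j = dropout.solve_rho(y[:, j])
        if np.isneginf(rho_j):
            continue
        p_miss = norm.cdf((rho_j - y[:, j]) / dropout.zeta)
        miss[:, j] = rng.random(n) < p_miss

    values = pd.DataFrame(
        np.where(miss, np.nan, y),
        index=[t.protein_id for t in truths],
        columns=sample_ids,
    )
    ptable = ProteinTable(
        pd.DataFrame(
            {
                "protein_id": [t.protein_id for t in truths],
                "gene_name": [t.protein_id for t in truths],
                "n_unique_peptides": [t.n_unique_peptides for t in truths],
                "reverse": [t.decoy_kind == "reverse" for t in truths],
                "contaminant": [t.decoy_kind == "contaminant" for t in truths],
            }
        )
    )
    return IntensityMatrix(values, scale="log2"), ptable


@dataclass
class PlantedMotif:
    """Residue enrichment planted at a fixed offset from cysteines.

    ``offset`` is relative to the cysteine (negative = N-terminal side),
    restricted to the +/-4 window the downstream analysis inspects.
    ``target_isoform`` limits planting to binders of that isoform
    (``None`` plants in every truth protein).
    """

    residue: str
    offset: int
    probability: float = 0.5
    target_isoform: str | None = None

    def __post_init__(self) -> None:
        if not (-4 <= self.offset <= 4) or self.offset == 0:
            raise ValueError("motif offset must be in [-4, 4] and non-zero")
        if self.residue not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {self.residue!r}")
        if not (0 <= self.probability <= 1):
            raise ValueError("probability must be in [0, 1]")


def generate_protein_sequences(
    truths: Sequence[SyntheticTruth],
    motif_spec: Sequence[PlantedMotif] = (),
    seed: int = 0,
    min_length: int = 120,
    max_length: int = 400,
) -> dict[str, str]:
    """Random protein sequences with guaranteed cysteines.

    Residues are drawn uniformly over the 20 standard amino acids; every
    sequence is forced to contain at least one cysteine.  Planted motifs
    overwrite the residue at ``offset`` from each cysteine of targeted
    proteins with the configured probability.
    """
    if min_length < 9:
        raise ValueError("sequences must be at least 9 residues")
    rng = _rng(seed, _STREAM_SEQ)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    seqs: dict[str, str] = {}
    for t in truths:
        length = int(rng.integers(min_length, max_length + 1))
        chars = rng.choice(aa, size=length)
        if not (chars == b"C").any():
            chars[rng.integers(length)] = b"C"
        for motif in motif_spec:
            if motif.target_isoform is not None and (
                motif.target_isoform not in t.binds_isoforms
            ):
                continue
            cys_pos = np.flatnonzero(chars == b"C")
            for pos in cys_pos:
                tgt = pos + motif.offset
                if 0 <= tgt < length and rng.random() < motif.probability:
                    if chars[tgt] != b"C":  # never destroy a window center
                        chars[tgt] = motif.residue.encode()
        seqs[t.protein_id] = chars.tobytes().decode()
    return seqs


def generate_compartment_table(
    truths: Sequence[SyntheticTruth],
    compartments: Sequence[str],
    seed: int = 0,
    bias: Mapping[str, tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Assign one subcellular neighborhood per protein.

    Background proteins are uniform over ``compartments``.  ``bias`` maps
    an isoform to ``(compartment, fold)``: binders of that isoform get the
    compartment's probability multiplied by ``fold`` before renormalizing,
    emulating e.g. a mitochondrial bias of PRDX3 interactors.
    """
    if not compartments:
        raise ValueError("compartment list must be non-empty")
    rng = _rng(seed, _STREAM_COMPARTMENT)
    comp = list(compartments)
    base_p = np.full(len(comp), 1.0 / len(comp))
    rows = []
    for t in truths:
        p = base_p.copy()
        if bias:
            for iso, (target, fold) in bias.items():
                if iso in t.binds_isoforms and target in comp:
                    p[comp.index(target)] *= fold
        p = p / p.sum()
        rows.append((t.protein_id, comp[rng.choice(len(comp), p=p)]))
    return pd.DataFrame(rows, columns=["protein_id", "compartment"])


# -- truth serialization ----------------------------------------------------

def truth_to_json(truths: Sequence[SyntheticTruth], path) -> None:
    records = []
    for t in truths:
        rec = dataclasses.asdict(t)
        rec["binds_isoforms"] = list(t.binds_isoforms)
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def truth_from_json(path) -> list[SyntheticTruth]:
    with open(path) as fh:
        records = json.load(fh)
    out = []
    for rec in records:
        rec["binds_isoforms"] = tuple(rec["binds_isoforms"])
        out.append(SyntheticTruth(**rec))
    return out


def cys_dependent_ids(
    truths: Sequence[SyntheticTruth], isoform: str, genotype: str = "WT"
) -> set[str]:
    """Planted positives: proteins enriched in `genotype` over CPRS baits."""
    out = set()
    for t in truths:
        if t.effect_in(isoform, genotype) > t.effect_in(isoform, "CPRS"):
            out.add(t.protein_id)
    return out
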