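"""End-to-end orchestration: from a proteinGroups table (or a synthetic
scenario) to classified interactor sets, calibrated thresholds, enrichments
and sequence statistics, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import calibration_report, randomize_labels_fdr
from .containers import ExperimentDesign, IntensityMatrix, ProteinTable
from .dropout import ProbabilisticDropoutModel, estimate_dropout_curves
from .enrichment import localization_enrichment, redox_overlap
from .io import (
    filter_proteins,
    read_compartment_table,
    read_fasta,
    read_protein_groups,
    read_reference_list,
    write_fasta,
    write_protein_groups,
    write_reference_list,
)
from .normalize import log2_transform, quantile_normalize
from .sets import (
    classify_cysteine_dependent,
    classify_isoform_specific,
    classify_mechanism,
    pairwise_overlap,
    set_intersections,
)
from .seq import (
    aa_composition_enrichment,
    extract_all_windows,
    motif_x,
    shuffle_background,
    window_frame,
)
from .synthetic import (
    DropoutSpec,
    PlantedMotif,
    TruthConfig,
    cys_dependent_ids,
    generate_compartment_table,
    generate_interactome_truth,
    generate_protein_sequences,
    simulate_lfq_experiment,
    truth_to_json,
)

log = logging.getLogger("prxmap")


@dataclass
class PipelineConfig:
    """Validated run configuration; exactly one of inputs/synthetic."""

    seed: int = 0
    inputs: dict | None = None
    synthetic: dict | None = None
    thresholds: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    sequence: dict = field(default_factory=dict)

    DEFAULT_THRESHOLDS = {
        "delta_min": 1.0,
        "alpha": 0.05,
        "p_mode_cys": "raw",
        "p_mode_isoform": "bh",
        "fold_min": 10.0,
    }
    DEFAULT_CALIBRATION = {"n_perm": 100, "alpha": 0.05}
    DEFAULT_SEQUENCE = {"n_shuffles": 100, "min_support": 10, "p_fix": 1e-4}

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("config needs exactly one of 'inputs' or 'synthetic'")
        self.thresholds = {**self.DEFAULT_THRESHOLDS, **self.thresholds}
        self.calibration = {**self.DEFAULT_CALIBRATION, **self.calibration}
        self.sequence = {**self.DEFAULT_SEQUENCE, **self.sequence}
        for key in ("delta_min", "alpha", "fold_min"):
            if self.thresholds[key] <= 0 and key != "delta_min":
                raise ValueError(f"threshold {key} must be positive")
        if self.thresholds["delta_min"] < 0:
            raise ValueError("delta_min must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "inputs": self.inputs,
            "synthetic": self.synthetic,
            "thresholds": self.thresholds,
            "calibration": self.calibration,
            "sequence": self.sequence,
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def generate_synthetic_inputs(config: PipelineConfig, outdir: Path) -> dict[str, Any]:
    """Materialize a planted-truth scenario as on-disk pipeline inputs."""
    syn = dict(config.synthetic or {})
    noise_sd = syn.pop("noise_sd", 0.8)
    target_missing = syn.pop("target_missing_fraction", 0.34)
    zeta = syn.pop("dropout_zeta", 1.0)
    n_replicates = syn.pop("n_replicates", 3)
    motif_plants = [PlantedMotif(**m) for m in syn.pop("planted_motifs", [])]
    compartments = syn.pop(
        "compartments", ["cytosol", "mitochondria", "nucleus", "secretory"]
    )
    bias_raw = syn.pop("compartment_bias", {"PRDX3": ["mitochondria", 3.0]})
    bias = {iso: (comp, float(fold)) for iso, (comp, fold) in bias_raw.items()}

    tcfg = TruthConfig(seed=config.seed, **syn)
    truths = generate_interactome_truth(tcfg)
    design = ExperimentDesign.full_design(
        isoforms=tcfg.isoforms, n_replicates=n_replicates
    )
    dropout = DropoutSpec(zeta=zeta, target_missing_fraction=target_missing)
    matrix, ptable = simulate_lfq_experiment(
        truths, design, dropout, noise_sd=noise_sd, seed=config.seed
    )
    seqs = generate_protein_sequences(truths, motif_plants, seed=config.seed)
    comp_table = generate_compartment_table(
        truths, compartments, seed=config.seed, bias=bias
    )
    redox_ids = {t.protein_id for t in truths if t.redox_sensitive}

    outdir.mkdir(parents=True, exist_ok=True)
    write_protein_groups(outdir / "proteinGroups.txt", ptable, matrix)
    write_fasta(outdir / "sequences.fasta", seqs)
    write_reference_list(outdir / "redox_reference.tsv", redox_ids)
    comp_table.to_csv(outdir / "compartments.tsv", sep="\t", index=False)
    truth_to_json(truths, outdir / "truth.json")
    design.table.to_csv(outdir / "design.tsv", sep="\t")
    return {
        "truths": truths,
        "design": design,
        "ptable": ptable,
        "matrix_log2": matrix,
        "seqs": seqs,
        "compartment_table": comp_table,
        "reference_ids": redox_ids,
    }


def _load_inputs(config: PipelineConfig) -> dict[str, Any]:
    paths = config.inputs or {}
    ptable, matrix = read_protein_groups(paths["protein_groups"])
    design = ExperimentDesign(pd.read_csv(paths["design"], sep="\t", index_col=0))
    out: dict[str, Any] = {
        "ptable": ptable,
        "matrix_raw": matrix,
        "design": design,
        "seqs": None,
        "compartment_table": None,
        "reference_ids": None,
        "truths": None,
    }
    if paths.get("fasta"):
        out["seqs"] = read_fasta(paths["fasta"])
    if paths.get("reference_list"):
        out["reference_ids"] = read_reference_list(paths["reference_list"])
    if paths.get("compartment_table"):
        out["compartment_table"] = read_compartment_table(paths["compartment_table"])
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Any]:
    """Execute all stages in fixed order and write the report bundle.

    Stage order: read/generate -> filter -> log2 -> quantile -> dropout
    fit -> contrasts -> calibration -> classifications -> intersections ->
    enrichments -> sequence analyses.  Every output is a TSV/JSON under
    ``outdir``; the manifest records the config hash, seed and decision
    flags so a run is a pure function of (inputs, config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    if config.synthetic is not None:
        log.info("generating synthetic scenario (seed=%d)", config.seed)
        bundle = generate_synthetic_inputs(config, outdir / "inputs")
        ptable, design = bundle["ptable"], bundle["design"]
        # round through the proteinGroups dialect so both paths are identical
        ptable, matrix_raw = read_protein_groups(outdir / "inputs" / "proteinGroups.txt")
    else:
        bundle = _load_inputs(config)
        ptable, design, matrix_raw = bundle["ptable"], bundle["design"], bundle["matrix_raw"]

    log.info("filtering %d proteins", matrix_raw.n_proteins)
    ptable_f, matrix_f, filter_report = filter_proteins(ptable, matrix_raw, design)
    log.info("filter report: %s", filter_report)

    matrix_log2 = log2_transform(matrix_f)
    matrix_norm = quantile_normalize(matrix_log2)
    curves = estimate_dropout_curves(matrix_norm, design)
    curves.to_csv(outdir / "dropout_curves.tsv", sep="\t")

    log.info("fitting dropout model (%d proteins x %d samples)",
             matrix_norm.n_proteins, matrix_norm.n_samples)
    results = ProbabilisticDropoutModel(matrix_norm, design, curves=curves).fit()
    (outdir / "model_summary.txt").write_text(results.summary() + "\n")

    isoforms = design.isoforms
    contrasts_wt: dict[str, pd.DataFrame] = {}
    contrasts_crs: dict[str, pd.DataFrame] = {}
    contrasts_wt_crs: dict[str, pd.DataFrame] = {}
    for iso in isoforms:
        contrasts_wt[iso] = results.contrast(f"{iso}:WT", f"{iso}:CPRS")
        contrasts_crs[iso] = results.contrast(f"{iso}:CRS", f"{iso}:CPRS")
        contrasts_wt_crs[iso] = results.contrast(f"{iso}:WT", f"{iso}:CRS")
        for tag, tab in (
            ("WT_vs_CPRS", contrasts_wt[iso]),
            ("CRS_vs_CPRS", contrasts_crs[iso]),
            ("WT_vs_CRS", contrasts_wt_crs[iso]),
        ):
            tab.to_csv(outdir / f"contrast_{iso}_{tag}.tsv", sep="\t")

    contrasts_iso: dict[str, pd.DataFrame] = {}
    if len(isoforms) >= 2:
        for iso in isoforms:
            groups = design.table["isoform"].where(
                design.table["isoform"] == iso, "other"
            )
            iso_res = ProbabilisticDropoutModel(
                matrix_norm, design, groups=groups, curves=curves
            ).fit()
            contrasts_iso[iso] = iso_res.contrast(iso, "other")
            contrasts_iso[iso].to_csv(outdir / f"contrast_{iso}_vs_rest.tsv", sep="\t")
    else:
        log.info("single-isoform design: isoform-vs-rest stage skipped")

    log.info("calibrating fold-change threshold (%d permutations)",
             config.calibration["n_perm"])
    calib = randomize_labels_fdr(
        matrix_norm,
        design,
        n_perm=config.calibration["n_perm"],
        alpha=config.calibration["alpha"],
        seed=config.seed,
    )
    calibration_report(calib).to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    (outdir / "calibration.json").write_text(
        json.dumps(
            {
                "tau": calib.tau,
                "alpha": calib.alpha,
                "n_perm": calib.n_perm,
                "included_fraction_real": calib.included_fraction_real,
                "seed": calib.seed,
                **calib.metadata,
            },
            indent=1,
        )
    )

    cys_sets = {
        iso: classify_cysteine_dependent(
            contrasts_wt[iso], th["delta_min"], th["alpha"], th["p_mode_cys"]
        )
        for iso in isoforms
    }
    cp_sets = {
        iso: classify_cysteine_dependent(
            contrasts_crs[iso], th["delta_min"], th["alpha"], th["p_mode_cys"]
        )
        for iso in isoforms
    }
    iso_sets = classify_isoform_specific(
        contrasts_iso, th["delta_min"], th["alpha"], th["p_mode_isoform"]
    )
    for iso in isoforms:
        iso_sets.setdefault(iso, set())
    cys_and_iso = {iso: cys_sets[iso] & iso_sets[iso] for iso in isoforms}

    mechanisms = {iso: classify_mechanism(cys_sets[iso], cp_sets[iso]) for iso in isoforms}
    mech_rows = []
    for iso in isoforms:
        m = mechanisms[iso]
        mech_rows.append(
            {
                "isoform": iso,
                "n_wt": len(cys_sets[iso]),
                "n_soh": len(m.soh),
                "n_ss": len(m.ss),
                "n_crs_only": len(m.crs_only),
                "ss_percent": m.ss_percent,
            }
        )
    mech_table = pd.DataFrame(mech_rows)
    mech_table.to_csv(outdir / "mechanism.tsv", sep="\t", index=False)

    for name, sets in (
        ("cys_dependent", cys_sets),
        ("cp_dependent", cp_sets),
        ("isoform_specific", iso_sets),
        ("cys_and_isoform_specific", cys_and_iso),
    ):
        pd.DataFrame(
            [(iso, ";".join(sorted(ids))) for iso, ids in sets.items()],
            columns=["isoform", "protein_ids"],
        ).to_csv(outdir / f"sets_{name}.tsv", sep="\t", index=False)

    intersections = set_intersections(cys_sets)
    intersections.to_frame().to_csv(outdir / "intersections.tsv", sep="\t", index=False)
    pairwise_overlap(cys_sets).to_csv(outdir / "pairwise_overlap.tsv", sep="\t")

    universe = set(matrix_norm.protein_ids)
    enrichments: dict[str, Any] = {}
    if bundle.get("reference_ids"):
        redox = redox_overlap(cys_sets, bundle["reference_ids"], universe)
        redox.to_csv(outdir / "redox_overlap.tsv", sep="\t", index=False)
        enrichments["redox"] = redox
    if bundle.get("compartment_table") is not None:
        loc = localization_enrichment(
            iso_sets, contrasts_wt, bundle["compartment_table"], th["fold_min"]
        )
        loc.to_csv(outdir / "localization_enrichment.tsv", sep="\t", index=False)
        enrichments["localization"] = loc

    seq_outputs: dict[str, Any] = {}
    if bundle.get("seqs"):
        seq_outputs = _sequence_stage(
            bundle["seqs"], iso_sets, mechanisms, config, outdir
        )
    else:
        log.info("no sequences provided; sequence analyses skipped")

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "filter_report": filter_report,
        "thresholds": th,
        "calibration": {"tau": calib.tau, "n_perm": calib.n_perm, **calib.metadata},
        "n_proteins_analyzed": matrix_norm.n_proteins,
        "missing_fraction": matrix_norm.missing_fraction(),
        "sequence_stage_run": bool(bundle.get("seqs")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    out = {
        "config": config,
        "design": design,
        "matrix": matrix_norm,
        "curves": curves,
        "results": results,
        "contrasts_wt": contrasts_wt,
        "contrasts_crs": contrasts_crs,
        "contrasts_wt_crs": contrasts_wt_crs,
        "contrasts_isoform": contrasts_iso,
        "calibration": calib,
        "cys_sets": cys_sets,
        "cp_sets": cp_sets,
        "isoform_sets": iso_sets,
        "mechanisms": mechanisms,
        "mechanism_table": mech_table,
        "intersections": intersections,
        "enrichments": enrichments,
        "sequence": seq_outputs,
        "filter_report": filter_report,
        "manifest": manifest,
    }
    if bundle.get("truths") is not None:
        out["truths"] = bundle["truths"]
        out["recovery"] = truth_recovery_metrics(bundle["truths"], out)
        (outdir / "truth_recovery.json").write_text(
            json.dumps(out["recovery"], indent=1)
        )
    return out


def _sequence_stage(seqs, iso_sets, mechanisms, config, outdir) -> dict[str, Any]:
    sq = config.sequence
    windows_by_iso = {
        iso: extract_all_windows({p: seqs[p] for p in ids if p in seqs})
        for iso, ids in iso_sets.items()
    }
    aa_tables = {}
    for iso, fg in windows_by_iso.items():
        ctrl = [
            w
            for other, ws in windows_by_iso.items()
            if other != iso
            for w in ws
        ]
        if fg and ctrl:
            tab = aa_composition_enrichment(fg, ctrl)
            tab.to_csv(outdir / f"aa_enrichment_{iso}.tsv", sep="\t", index=False)
            aa_tables[iso] = tab

    # mechanism-grouped motif search: each group vs the other as control
    soh_ids = set().union(*(m.soh for m in mechanisms.values()))
    ss_ids = set().union(*(m.ss for m in mechanisms.values()))
    soh_windows = extract_all_windows({p: seqs[p] for p in soh_ids if p in seqs})
    ss_windows = extract_all_windows({p: seqs[p] for p in ss_ids if p in seqs})
    motifs = {}
    if soh_windows and ss_windows:
        motifs["SOH_vs_SS"] = motif_x(
            soh_windows, ss_windows, sq["min_support"], sq["p_fix"]
        )
        motifs["SS_vs_SOH"] = motif_x(
            ss_windows, soh_windows, sq["min_support"], sq["p_fix"]
        )
        rows = [
            {"comparison": name, "motif": m.label(), "support": m.support,
             "fold": m.fold_enrichment, "score": m.score}
            for name, ms in motifs.items()
            for m in ms
        ]
        pd.DataFrame(
            rows, columns=["comparison", "motif", "support", "fold", "score"]
        ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)

    shuffled = shuffle_background(
        {p: seqs[p] for p in sorted(soh_ids | ss_ids) if p in seqs} or seqs,
        n_shuffles=sq["n_shuffles"],
        seed=config.seed,
    )
    window_frame(shuffled[:0]).to_csv(  # header only; full table can be huge
        outdir / "shuffled_windows_head.tsv", sep="\t", index=False
    )
    return {"aa_enrichment": aa_tables, "motifs": motifs, "n_shuffled_windows": len(shuffled)}


def truth_recovery_metrics(truths, out: Mapping[str, Any]) -> dict[str, Any]:
    """Compare recovered classifications against the planted truth."""
    analyzed = set(out["matrix"].protein_ids)
    metrics: dict[str, Any] = {}
    # pooled over all (isoform, protein) binding calls, matching the
    # screen's global binder count
    tp = fp = fn = 0
    for iso, called in out["cys_sets"].items():
        true_pos = cys_dependent_ids(truths, iso) & analyzed
        tp += len(called & true_pos)
        fp += len(called - true_pos)
        fn += len(true_pos - called)
    metrics["cys_sensitivity"] = tp / (tp + fn) if tp + fn else None
    metrics["cys_fdr"] = fp / (tp + fp) if tp + fp else None
    metrics["n_true_binding_events"] = tp + fn
    metrics["n_called_binding_events"] = tp + fp

    # planted vs recovered disulfide-relay fraction among WT binders
    truth_ss = truth_soh = 0
    for t in truths:
        for iso in t.binds_isoforms:
            if t.protein_id not in analyzed:
                continue
            if t.mechanism.get(iso) == "SS":
                truth_ss += 1
            elif t.mechanism.get(iso) == "SOH":
                truth_soh += 1
    rec_ss = sum(len(m.ss) for m in out["mechanisms"].values())
    rec_soh = sum(len(m.soh) for m in out["mechanisms"].values())
    metrics["planted_ss_fraction"] = (
        truth_ss / (truth_ss + truth_soh) if truth_ss + truth_soh else None
    )
    metrics["recovered_ss_fraction"] = (
        rec_ss / (rec_ss + rec_soh) if rec_ss + rec_soh else None
    )
    metrics["tau"] = out["calibration"].tau
    return metrics
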