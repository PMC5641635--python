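"""End-to-end pipeline: simulate -> process -> map -> analyze.

Each stage reads and writes the plain-text interchange files described in
the module docstrings, so stages can be run separately from the CLI; an
in-memory runner (`run_stages_in_memory`) drives the same code without
touching disk, which the test-suite uses for repeated small runs.

Reruns with identical config and seed are byte-identical: floats are
written with a fixed format and the manifest carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as cqio
from .errors import CodonQuantError, ConfigurationError, ValidationError
from .genetics import SENSE_CODONS
from .mapping import build_codon_profiles
from .processing import (FilterThresholds, apply_fdr, assemble_parsimony,
                         assignment_of, filter_psms, quantify)
from .simulate import (CodingSequence, SampleDesign, SimulationConfig,
                       simulate_dataset)
from .stats import (codon_enrichment, compare_all_codons, fold_changes,
                    heatmap_layout, loglog_table, regress_fc_on_aaa,
                    weighted_codon_totals)

logger = logging.getLogger(__name__)

FILES = {
    "cds_fasta": "cds.fasta",
    "protein_fasta": "proteins.fasta",
    "psms": "psms.tsv",
    "design": "design.tsv",
    "truth": "truth.tsv",
    "config_echo": "config.yaml",
    "filtered_psms": "filtered_psms.tsv",
    "exclusion_tally": "exclusion_tally.tsv",
    "fdr_summary": "fdr_summary.tsv",
    "protein_groups": "protein_groups.tsv",
    "peptide_quant": "peptide_quant.tsv",
    "protein_quant": "protein_quant.tsv",
    "codon_profiles": "codon_profiles.tsv",
    "weighted_totals": "weighted_codon_totals.tsv",
    "codon_group_tests": "codon_group_tests.tsv",
    "peptide_fold_changes": "peptide_fold_changes.tsv",
    "protein_fold_changes": "protein_fold_changes.tsv",
    "enrichment": "codon_enrichment.tsv",
    "heatmap": "codon_heatmap.tsv",
    "regression": "regression_summary.tsv",
    "loglog": "loglog_scatter.tsv",
    "manifest": "manifest.json",
}


@dataclass
class AnalysisOptions:
    """Switches for the statistics stage; defaults match the study."""

    threshold_fold: float = 2.0
    pseudocount: float = 0.5
    significance_gate: bool = False
    gate_alpha: float = 0.05
    grouping: str = "protein_id"
    run_regression: bool = True

    def validate(self) -> None:
        if self.threshold_fold <= 1.0:
            raise ConfigurationError("threshold_fold must exceed 1")
        if not 0.0 < self.gate_alpha < 1.0:
            raise ConfigurationError("gate_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    outdir: Path = Path("codonquant_run")
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        # the top-level seed drives the simulation stream
        self.simulation.seed = self.seed

    def validate(self) -> None:
        self.simulation.validate()
        self.thresholds.validate(self.simulation.n_channels)
        self.analysis.validate()

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "simulation": self.simulation.to_dict(),
            "thresholds": self.thresholds.to_dict(),
            "analysis": self.analysis.to_dict(),
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        sim = SimulationConfig(**d.get("simulation", {}))
        thr = FilterThresholds(**d.get("thresholds", {}))
        ana = AnalysisOptions(**d.get("analysis", {}))
        return cls(outdir=Path(d.get("outdir", "codonquant_run")),
                   seed=int(d.get("seed", 0)),
                   simulation=sim, thresholds=thr, analysis=ana)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# in-memory stage drivers

def process_psms(psms: pd.DataFrame, design: SampleDesign,
                 thresholds: FilterThresholds) -> dict[str, Any]:
    """Filter -> peptide FDR -> protein FDR -> parsimony -> quantify."""
    filtered, tally = filter_psms(psms, thresholds, design)
    if filtered.empty:
        raise ValidationError("no PSMs survive the exclusion rules")

    pep_fdr = apply_fdr(filtered, thresholds.peptide_fdr, unit="peptide")
    # keep decoys above the peptide threshold so the protein-level
    # estimate still has a decoy population
    pep_best = filtered.groupby("peptide")["score"].transform("max")
    at_pep_level = filtered.loc[pep_best >= pep_fdr.threshold]
    prot_fdr = apply_fdr(at_pep_level, thresholds.protein_fdr, unit="protein")
    retained_proteins = set(prot_fdr.retained)

    kept_peptides = set(pep_fdr.retained)
    final = at_pep_level.loc[
        (~at_pep_level["is_decoy"].astype(bool))
        & at_pep_level["peptide"].isin(kept_peptides)].copy()

    # restrict candidate proteins to those surviving protein-level FDR
    pep_to_prots: dict[str, list[str]] = {}
    dropped_no_protein = 0
    keep_rows = []
    for idx, pep, prots in zip(final.index, final["peptide"],
                               final["protein_ids"]):
        cands = [p for p in prots.split(";") if p in retained_proteins]
        if not cands:
            dropped_no_protein += 1
            continue
        keep_rows.append(idx)
        if pep not in pep_to_prots:
            pep_to_prots[pep] = cands
    final = final.loc[keep_rows]
    if final.empty:
        raise ValidationError("no PSMs survive FDR control")
    if dropped_no_protein:
        logger.info("%d PSMs dropped: all candidate proteins failed "
                    "protein-level FDR", dropped_no_protein)

    groups = assemble_parsimony(pep_to_prots)
    assignment = assignment_of(groups)
    peptide_quant = quantify(final, None, design, unit="peptide")
    protein_quant = quantify(final, assignment, design, unit="protein")
    return {
        "filtered_psms": final,
        "tally": tally,
        "peptide_fdr": pep_fdr,
        "protein_fdr": prot_fdr,
        "groups": groups,
        "assignment": assignment,
        "peptide_quant": peptide_quant,
        "protein_quant": protein_quant,
    }


def _significance_gate(peptide_quant: pd.DataFrame, design: SampleDesign,
                       alpha: float) -> pd.Series:
    """BH-adjusted per-peptide group t-test mask (True = significant)."""
    from scipy import stats as sps
    from statsmodels.stats.multitest import multipletests

    ctrl = peptide_quant[list(design.samples_in("control"))].to_numpy(float)
    ko = peptide_quant[list(design.samples_in("ko"))].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(ctrl, ko, axis=1, equal_var=True)
    p = np.where(np.isfinite(p), p, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.Series(q < alpha, index=peptide_quant.index)


def analyze(processed: Mapping[str, Any], design: SampleDesign,
            cds_index: Mapping[str, CodingSequence],
            options: AnalysisOptions) -> dict[str, Any]:
    """Codon mapping plus every statistics table of the analysis stage."""
    options.validate()
    profiles = build_codon_profiles(processed["assignment"], cds_index)

    peptide_quant = processed["peptide_quant"]
    protein_quant = processed["protein_quant"]
    totals = weighted_codon_totals(peptide_quant, profiles)
    group_tests = compare_all_codons(totals, design)

    peptide_fc = fold_changes(peptide_quant, design,
                              options.threshold_fold, options.pseudocount)
    protein_fc = fold_changes(protein_quant, design,
                              options.threshold_fold, options.pseudocount)

    down = peptide_fc.index[peptide_fc["is_down_2x"]]
    if options.significance_gate:
        sig = _significance_gate(peptide_quant, design, options.gate_alpha)
        down = down.intersection(sig.index[sig])
    total_peptides = peptide_fc.index
    enrichment = codon_enrichment(profiles, down, total_peptides)
    heatmap = heatmap_layout(enrichment)

    regression = None
    if options.run_regression:
        regression = regress_fc_on_aaa(peptide_fc, profiles, options.grouping)

    return {
        "profiles": profiles,
        "weighted_totals": totals,
        "group_tests": group_tests,
        "peptide_fc": peptide_fc,
        "protein_fc": protein_fc,
        "down_peptides": list(down),
        "enrichment": enrichment,
        "heatmap": heatmap,
        "regression": regression,
        "loglog": loglog_table(protein_fc, options.threshold_fold),
    }


def run_stages_in_memory(config: PipelineConfig) -> dict[str, Any]:
    """Full simulate->process->analyze run with no file I/O."""
    config.validate()
    cds_list, design, psms, truth = simulate_dataset(config.simulation)
    processed = process_psms(psms, design, config.thresholds)
    cds_index = {c.id: c for c in cds_list}
    analyzed = analyze(processed, design, cds_index, config.analysis)
    return {"cds_list": cds_list, "design": design, "psms": psms,
            "truth": truth, **processed, **analyzed}


# ---------------------------------------------------------------------------
# file-based stages

def _stage_log(stage: str, t0: float, **counts) -> None:
    extra = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage %-9s %6.2fs  %s", stage, time.perf_counter() - t0, extra)


def stage_simulate(config: PipelineConfig) -> dict[str, int]:
    t0 = time.perf_counter()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    cds_list, design, psms, truth = simulate_dataset(config.simulation)
    cqio.write_cds_fasta(cds_list, out / FILES["cds_fasta"])
    cqio.write_protein_fasta(cds_list, out / FILES["protein_fasta"])
    cqio.write_psm_table(psms, out / FILES["psms"])
    cqio.write_design(design, out / FILES["design"])
    cqio.write_table(truth, out / FILES["truth"])
    config.to_yaml(out / FILES["config_echo"])
    counts = {"proteins": len(cds_list), "psms": len(psms)}
    _stage_log("simulate", t0, **counts)
    return counts


def stage_process(config: PipelineConfig) -> dict[str, int]:
    t0 = time.perf_counter()
    out = config.outdir
    psms_path = out / FILES["psms"]
    design_path = out / FILES["design"]
    for p in (psms_path, design_path):
        if not p.exists():
            raise ValidationError(f"process stage: missing input {p}")
    psms = cqio.read_psm_table(psms_path)
    design = cqio.read_design(design_path)
    res = process_psms(psms, design, config.thresholds)

    cqio.write_psm_table(res["filtered_psms"], out / FILES["filtered_psms"])
    tally_df = pd.DataFrame(sorted(res["tally"].items()),
                            columns=["rule", "count"])
    cqio.write_table(tally_df, out / FILES["exclusion_tally"])
    fdr_rows = []
    for r in (res["peptide_fdr"], res["protein_fdr"]):
        fdr_rows.append({"unit": r.unit, "threshold": r.threshold,
                         "estimated_fdr": r.estimated_fdr,
                         "n_targets": r.n_targets, "n_decoys": r.n_decoys,
                         "n_retained": len(r.retained),
                         "reliable": int(r.reliable)})
    cqio.write_table(pd.DataFrame(fdr_rows), out / FILES["fdr_summary"])
    groups_df = pd.DataFrame(
        [(g.representative_protein_id, len(g.member_peptides),
          ";".join(g.member_peptides)) for g in res["groups"]],
        columns=["representative_protein_id", "n_peptides", "member_peptides"])
    cqio.write_table(groups_df, out / FILES["protein_groups"])
    cqio.write_table(res["peptide_quant"], out / FILES["peptide_quant"],
                     index=True)
    cqio.write_table(res["protein_quant"], out / FILES["protein_quant"],
                     index=True)
    counts = {"retained_psms": len(res["filtered_psms"]),
              "peptides": len(res["peptide_quant"]),
              "protein_groups": len(res["groups"])}
    _stage_log("process", t0, **counts)
    return counts


def _read_processed(out: Path, design: SampleDesign) -> dict[str, Any]:
    groups_df = cqio.read_table(out / FILES["protein_groups"])
    assignment: dict[str, str] = {}
    for rep, members in zip(groups_df["representative_protein_id"],
                            groups_df["member_peptides"]):
        for pep in str(members).split(";"):
            assignment[pep] = rep
    peptide_quant = cqio.read_table(out / FILES["peptide_quant"]).set_index(
        "peptide")
    protein_quant = cqio.read_table(out / FILES["protein_quant"]).set_index(
        "protein")
    return {"assignment": assignment, "peptide_quant": peptide_quant,
            "protein_quant": protein_quant}


def stage_analyze(config: PipelineConfig) -> dict[str, int]:
    t0 = time.perf_counter()
    out = config.outdir
    cds_path = out / FILES["cds_fasta"]
    if not cds_path.exists():
        raise ValidationError(f"analyze stage: missing CDS FASTA {cds_path}")
    for key in ("design", "protein_groups", "peptide_quant", "protein_quant"):
        if not (out / FILES[key]).exists():
            raise ValidationError(
                f"analyze stage: missing input {out / FILES[key]}")
    design = cqio.read_design(out / FILES["design"])
    cds_index = cqio.read_cds_fasta(cds_path)
    processed = _read_processed(out, design)
    res = analyze(processed, design, cds_index, config.analysis)

    cqio.write_table(res["profiles"], out / FILES["codon_profiles"])
    totals = res["weighted_totals"].copy()
    totals.index.name = "sample_id"
    cqio.write_table(totals, out / FILES["weighted_totals"], index=True)
    cqio.write_table(res["group_tests"], out / FILES["codon_group_tests"])
    cqio.write_table(res["peptide_fc"], out / FILES["peptide_fold_changes"],
                     index=True)
    cqio.write_table(res["protein_fc"], out / FILES["protein_fold_changes"],
                     index=True)
    cqio.write_table(res["enrichment"], out / FILES["enrichment"])
    heat = res["heatmap"].reset_index()
    cqio.write_table(heat, out / FILES["heatmap"])
    if res["regression"] is not None:
        cqio.write_table(pd.DataFrame([res["regression"].__dict__]),
                         out / FILES["regression"])
    cqio.write_table(res["loglog"], out / FILES["loglog"], index=True)
    counts = {"profiled_peptides": len(res["profiles"]),
              "down_peptides": len(res["down_peptides"])}
    _stage_log("analyze", t0, **counts)
    return counts


def write_manifest(config: PipelineConfig,
                   stage_counts: Mapping[str, Mapping[str, int]]) -> None:
    import statsmodels

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {k: dict(v) for k, v in stage_counts.items()},
        "versions": {
            "codonquant": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "python": ".".join(map(str, sys.version_info[:3])),
        },
    }
    with open(config.outdir / FILES["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("codonquant")
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(config: PipelineConfig, mode: str = "run-all") -> dict:
    """Execute the requested stages; raises CodonQuantError naming the stage.

    Modes: ``simulate`` (fixtures + truth only), ``process``, ``analyze``,
    ``run-all``.
    """
    config.validate()
    stage_counts: dict[str, dict[str, int]] = {}
    plan = {"simulate": ["simulate"],
            "process": ["process"],
            "analyze": ["analyze"],
            "run-all": ["simulate", "process", "analyze"]}.get(mode)
    if plan is None:
        raise ConfigurationError(f"unknown mode {mode!r}")
    stage_fn = {"simulate": stage_simulate, "process": stage_process,
                "analyze": stage_analyze}
    for stage in plan:
        try:
            stage_counts[stage] = stage_fn[stage](config)
        except CodonQuantError as exc:
            raise type(exc)(f"[stage {stage}] {exc}") from exc
    write_manifest(config, stage_counts)
    return stage_counts


# ---------------------------------------------------------------------------
# validation

def validate_inputs(cds_fasta: str | Path | None = None,
                    protein_fasta: str | Path | None = None,
                    psms: str | Path | None = None,
                    design: str | Path | None = None,
                    ) -> list[tuple[str, str]]:
    """Check input files for consistency; returns (level, message) findings.

    Levels are ``"fatal"`` or ``"warning"``; an empty list means all
    supplied inputs are consistent.
    """
    findings: list[tuple[str, str]] = []
    cds_index: dict[str, CodingSequence] = {}
    if cds_fasta is not None:
        try:
            cds_index = cqio.read_cds_fasta(cds_fasta)
        except (CodonQuantError, OSError) as exc:
            findings.append(("fatal", f"CDS FASTA: {exc}"))
    if protein_fasta is not None:
        try:
            proteins = cqio.read_fasta(protein_fasta)
        except (CodonQuantError, OSError) as exc:
            findings.append(("fatal", f"protein FASTA: {exc}"))
        else:
            for pid, aa in proteins.items():
                cds = cds_index.get(pid)
                if cds is None:
                    if cds_index:
                        findings.append(
                            ("warning", f"protein {pid} has no CDS record"))
                elif cds.aa_seq != aa:
                    findings.append(
                        ("fatal", f"protein {pid} does not match its CDS "
                                  f"translation"))
    design_obj = None
    if design is not None:
        try:
            design_obj = cqio.read_design(design)
        except (CodonQuantError, OSError) as exc:
            findings.append(("fatal", f"design table: {exc}"))
    if psms is not None:
        try:
            table = cqio.read_psm_table(psms)
        except (CodonQuantError, OSError) as exc:
            findings.append(("fatal", f"PSM table: {exc}"))
        else:
            n_sn = len(cqio.sn_columns(table))
            if design_obj is not None and n_sn != design_obj.n_channels:
                findings.append(
                    ("fatal", f"PSM table has {n_sn} reporter columns but "
                              f"design has {design_obj.n_channels} channels"))
            if (table["peptide"].str.len() == 0).any():
                findings.append(("fatal", "PSM table contains empty peptides"))
    return findings
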