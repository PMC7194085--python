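"""End-to-end orchestration: curate -> (recode|translate) -> infer ->
diagnose -> posterior predictive -> marginal likelihood -> consensus,
plus the per-gene GGI screen, with provenance (config hash + seeds) on
every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import alphabet as ab
from . import marglik as ml
from . import mcmc, ppred
from .msa_io import (concatenate, filter_genes, filter_low_occupancy_columns,
                     read_gene_table, translate, write_alignment)
from .phylo_model import load_paml_matrix
from .recode import build_degeneracy_table, degen_recode
from .simdata import make_attraction_scenario, simulate_alignment
from .tree import CV1, NDCH, NDCH2, write_newick

log = logging.getLogger("comphet")

ANALYSIS_MODES = ("nucleotide", "degenerate", "amino_acid")


@dataclass
class PipelineConfig:
    """Validated configuration for one full run."""

    output_dir: str
    analysis_mode: str = "nucleotide"
    model_mode: str = CV1
    n_comp_vectors: int = 2            # NDCH only
    replicates: int = 2
    n_iterations: int = 10000
    sample_interval: int = 10
    burnin_fraction: float = 0.25
    seed: int = 0
    min_occupancy: float = 0.5
    min_gene_length: int = 200
    required_groups: dict = field(default_factory=dict)
    ppred_draws: int = 100
    named_splits: dict = field(default_factory=dict)  # name -> list of taxa
    manifest: dict | None = None       # gene -> path; None => scenario
    scenario: dict = field(default_factory=dict)      # attraction preset args
    empirical_matrix: str | None = None  # PAML file/name for amino-acid mode
    genetic_code: int = 1
    prior: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.analysis_mode not in ANALYSIS_MODES:
            raise ValueError(f"analysis_mode must be one of {ANALYSIS_MODES}")
        if self.model_mode not in (CV1, NDCH, NDCH2):
            raise ValueError("model_mode must be cv1, ndch or ndch2")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (convergence needs "
                             "paired runs)")
        if self.manifest is not None:
            missing = [p for p in self.manifest.values()
                       if not Path(p).exists()]
            if missing:
                raise ValueError(f"manifest paths not resolvable: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and persists) the run report.

    Convergence failure is flagged in the report but does not abort; any
    other stage failure raises :class:`StageError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.digest()
    report: dict = {"config_hash": tag, "seed": config.seed, "stages": {},
                    "files": {}}
    t_start = time.time()

    def record(name: str, path: Path):
        report["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t": round(time.time() - t_start, 2)}

    # ---- input -----------------------------------------------------------
    stage("input")
    try:
        if config.manifest is not None:
            table = read_gene_table(config.manifest,
                                    alphabet=ab.NUCLEOTIDE,
                                    codon_structure=True)
            scenario_meta = {}
        else:
            scenario_args = dict(config.scenario)
            if config.analysis_mode in ("degenerate", "amino_acid"):
                scenario_args.setdefault("mode", "codon")
            scenario = make_attraction_scenario(seed=config.seed,
                                                **scenario_args)
            table = simulate_alignment(scenario)
            for name, aln in table.genes:
                aln.codon_structure = aln.n_columns % 3 == 0
            scenario_meta = {
                "true_split": sorted(scenario.meta.get("true_split", [])),
                "attraction_split": sorted(
                    scenario.meta.get("attraction_split", [])),
            }
            report["scenario"] = scenario_meta
    except Exception as exc:
        raise StageError("input", exc) from exc

    # ---- curate ----------------------------------------------------------
    stage("curate")
    try:
        table = filter_genes(table, min_len_bp=config.min_gene_length,
                             required_groups=config.required_groups)
        report["stages"]["curate"]["genes_kept"] = len(table.genes)
        report["stages"]["curate"]["missing_fraction"] = table.missing_fraction()
        concat = concatenate(table)
        concat = filter_low_occupancy_columns(concat, config.min_occupancy)
        path = outdir / f"concatenated.{tag}.fasta"
        write_alignment(concat, path)
        record("concatenated", path)
    except Exception as exc:
        raise StageError("curate", exc) from exc

    # ---- transform (recode / translate) ---------------------------------
    stage("transform")
    try:
        if config.analysis_mode == "degenerate":
            data = degen_recode(concat,
                                build_degeneracy_table(config.genetic_code))
        elif config.analysis_mode == "amino_acid":
            data = translate(concat, config.genetic_code)
        else:
            data = concat
        path = outdir / f"analysis_matrix.{tag}.fasta"
        write_alignment(data, path)
        record("analysis_matrix", path)
    except Exception as exc:
        raise StageError("transform", exc) from exc

    # ---- infer -----------------------------------------------------------
    stage("infer")
    try:
        fixed_R = None
        if config.analysis_mode == "amino_acid":
            name = config.empirical_matrix or "lg"
            fixed_R, _ = load_paml_matrix(name)
        spec = mcmc.ModelSpec(comp_mode=config.model_mode,
                              n_comp_vectors=config.n_comp_vectors,
                              fixed_R=fixed_R)
        prior = mcmc.PriorConfig(**config.prior)
        traces = []
        for rep in range(config.replicates):
            trace = mcmc.run_chain(data, spec, prior,
                                   n_iterations=config.n_iterations,
                                   sample_interval=config.sample_interval,
                                   seed=config.seed + rep)
            path = outdir / f"trace.{tag}.rep{rep}.jsonl"
            trace.save(path)
            record(f"trace_rep{rep}", path)
            traces.append(trace)
            log.info("replicate %d acceptance: %s", rep,
                     trace.acceptance_rates())
    except Exception as exc:
        raise StageError("infer", exc) from exc

    # ---- diagnose --------------------------------------------------------
    stage("diagnose")
    try:
        sd_value = mcmc.asdsf(traces[0], traces[1], config.burnin_fraction)
        margliks = []
        for rep, trace in enumerate(traces):
            try:
                res = ml.estimate_marginal_likelihood(
                    trace, burnin_fraction=config.burnin_fraction,
                    seed=config.seed + rep)
                margliks.append(res.log_marginal)
            except ValueError as exc:
                log.warning("marginal likelihood rep %d failed: %s", rep, exc)
        conv = mcmc.ConvergenceReport(
            asdsf=sd_value, marginal_likelihoods=margliks,
            acceptance_rates=traces[0].acceptance_rates())
        passed, reasons = mcmc.check_convergence(conv)
        report["convergence"] = {
            "asdsf": sd_value, "marginal_likelihoods": margliks,
            "passed": passed, "reasons": reasons,
        }
        if not passed:
            log.warning("convergence flagged: %s", reasons)
    except Exception as exc:
        raise StageError("diagnose", exc) from exc

    # ---- consensus + named splits ---------------------------------------
    stage("consensus")
    try:
        cons, support = mcmc.majority_rule_consensus(
            traces, burnin_fraction=config.burnin_fraction)
        path = outdir / f"consensus.{tag}.nwk"
        write_newick(cons, path, support=support)
        record("consensus", path)
        pooled = []
        for t in traces:
            pooled.extend(t.post_burnin(config.burnin_fraction))
        freqs = mcmc.split_frequencies(pooled)
        taxa = sorted(traces[0].taxa)
        ref, full = taxa[0], frozenset(taxa)
        named = {}
        for name, members in config.named_splits.items():
            side = frozenset(members)
            if ref in side:
                side = full - side
            named[name] = freqs.get(side, 0.0)
        report["named_split_support"] = named
    except Exception as exc:
        raise StageError("consensus", exc) from exc

    # ---- posterior predictive -------------------------------------------
    stage("ppred")
    try:
        x2 = ppred.posterior_predictive_pvalue(
            traces[0], data, n_draws=min(
                config.ppred_draws,
                len(traces[0].post_burnin(config.burnin_fraction))),
            seed=config.seed, burnin_fraction=config.burnin_fraction)
        report["ppred"] = {
            "observed_x2": x2.observed, "p_value": x2.p_value,
            "n_draws": x2.n_draws, "model_fits": x2.model_fits,
        }
    except Exception as exc:
        raise StageError("ppred", exc) from exc

    report["elapsed_s"] = round(time.time() - t_start, 2)
    report_path = outdir / f"report.{tag}.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
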