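"""End-to-end screening workflow: bin -> correct -> predict -> QC.

A :class:`RunConfig` describes one analysis run declaratively (inputs,
corrections and their order, prediction methods and chromosomes,
thresholds, seeds); :func:`run_workflow` executes it and emits a
deterministic JSON report with an embedded manifest.  Chi-squared
variation reduction may follow GC correction or run on uncorrected data,
but never precede a GC step — that ordering is rejected before any
compute.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .binning import bin_bam_sample, compute_gc_table
from .controlgroup import ControlGroup
from .correction import chi_correct, gc_correct
from .errors import ConfigError, NiptScreenError
from .prediction import (
    calculate_ncv_score,
    calculate_z_score,
    perform_regression,
    prepare_ncv,
)
from .qc import diagnose_control_group, match_control_group
from .samples import BinnedSample, GCBinTable
from .simulate import (
    SimulationParams,
    simulate_binned_sample,
    simulate_control_group,
    simulate_gc_table,
)

VALID_CORRECTIONS = ("gc", "chi")
VALID_METHODS = ("z", "ncv", "rbz")


@dataclass
class RunConfig:
    # inputs (either real files or a simulation block)
    sample_path: str | None = None
    control_group_path: str | None = None
    gc_table_path: str | None = None
    fasta_path: str | None = None
    simulate: dict | None = None
    # binning
    bin_size: int = 50_000
    separate_strands: bool = False
    min_mapq: int = 0
    exclude_duplicates: bool = False
    # corrections, applied in list order
    corrections: list[str] = field(default_factory=list)
    gc_method: str = "bin"
    chi_cutoff: float = 3.5
    include_XY: bool = False
    # prediction
    methods: list[str] = field(default_factory=lambda: ["z"])
    chromosomes: list[str] = field(
        default_factory=lambda: ["13", "18", "21"])
    z_bound: float = 3.0
    shapiro_alpha: float = 0.05
    ncv_max_denominators: int = 9
    rbz_n_models: int = 4
    rbz_n_predictors: int = 4
    train_fraction: float = 0.6
    # quality control
    match_qc: bool = False
    match_mode: str = "report"
    match_n: int | None = None
    diagnose: bool = False
    # misc
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.chromosomes = [str(c) for c in self.chromosomes]
        for c in self.corrections:
            if c not in VALID_CORRECTIONS:
                raise ConfigError(f"unknown correction {c!r}")
        if "chi" in self.corrections and "gc" in self.corrections:
            if self.corrections.index("chi") < self.corrections.index("gc"):
                raise ConfigError(
                    "invalid correction order: chi-squared variation "
                    "reduction applies to uncorrected or GC-corrected "
                    "counts, so it can never precede a GC step")
        for m in self.methods:
            if m not in VALID_METHODS:
                raise ConfigError(f"unknown prediction method {m!r}")
        if self.simulate is None and self.sample_path is None:
            raise ConfigError("config needs sample_path or a simulate block")
        if "gc" in self.corrections and self.simulate is None \
                and self.gc_table_path is None and self.fasta_path is None:
            raise ConfigError(
                "GC correction requires gc_table_path or fasta_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = dict(config.simulate)
        n_controls = int(sim.pop("n_controls", 25))
        sample_overrides = sim.pop("sample_params", {})
        base = SimulationParams(seed=config.seed, **sim)
        gc_table = simulate_gc_table(base.n_bins_per_chromosome,
                                     bin_size=base.bin_size,
                                     seed=config.seed)
        group = simulate_control_group(n_controls, base, gc_table)
        sample_params = dataclasses.replace(
            base, seed=config.seed + 1, **{
                k: (tuple(v) if k == "trisomy" and v is not None else v)
                for k, v in sample_overrides.items()})
        sample = simulate_binned_sample(sample_params, gc_table,
                                        sample_id="test_sample")
        return sample, group, gc_table

    path = Path(config.sample_path)
    if path.suffix == ".bam":
        sample = bin_bam_sample(
            path, bin_size=config.bin_size,
            separate_strands=config.separate_strands,
            min_mapq=config.min_mapq,
            exclude_duplicates=config.exclude_duplicates)
    else:
        sample = BinnedSample.load(path)
    if config.control_group_path is None:
        raise ConfigError("control_group_path is required")
    group = ControlGroup.load(config.control_group_path)
    gc_table = None
    if config.gc_table_path is not None:
        gc_table = GCBinTable.load(config.gc_table_path)
    elif config.fasta_path is not None:
        gc_table = compute_gc_table(config.fasta_path,
                                    bin_size=config.bin_size)
    return sample, group, gc_table


def run_workflow(config: RunConfig) -> dict:
    """Execute a configured run and return (and optionally write) the report.

    Partial results accumulated before a failure are still written,
    together with an error manifest, before the error propagates.
    """
    report: dict = {
        "manifest": {
            "package_version": __version__,
            "seed": config.seed,
            "thresholds": {
                "z_bound": config.z_bound,
                "chi_cutoff": config.chi_cutoff,
                "shapiro_alpha": config.shapiro_alpha,
            },
            "corrections": list(config.corrections),
            "methods": list(config.methods),
            "chromosomes": list(config.chromosomes),
            "inputs": {
                "sample_path": config.sample_path,
                "control_group_path": config.control_group_path,
                "gc_table_path": config.gc_table_path,
                "fasta_path": config.fasta_path,
                "simulated": config.simulate is not None,
            },
        },
    }
    try:
        sample, group, gc_table = _load_inputs(config)
        report["binning"] = {
            "sample_id": sample.sample_id,
            "bin_size": sample.bin_size,
            "strands": list(sample.strands),
            "total_autosomal_reads": sample.total_autosomal_reads(),
            "n_controls": len(group),
        }

        corrections_block = []
        for step in config.corrections:
            if step == "gc":
                if gc_table is None:
                    raise ConfigError("GC correction requested without a "
                                      "GC table or FASTA")
                sample = gc_correct(sample, gc_table,
                                    method=config.gc_method,
                                    include_XY=config.include_XY)
                group = gc_correct(group, gc_table,
                                   method=config.gc_method,
                                   include_XY=config.include_XY)
                corrections_block.append({"step": "gc",
                                          "method": config.gc_method})
            else:
                sample, group, chi_report = chi_correct(
                    sample, group, cutoff_sd=config.chi_cutoff,
                    include_XY=config.include_XY)
                corrections_block.append({
                    "step": "chi",
                    "cutoff": config.chi_cutoff,
                    "n_flagged_bins": len(chi_report.flagged),
                    "degrees_of_freedom": chi_report.degrees_of_freedom,
                })
        report["corrections"] = corrections_block
        report["correction_status"] = list(
            sample.autosomal_correction_status)

        predictions: dict = {}
        for chrom in config.chromosomes:
            predictions[chrom] = {}
            if "z" in config.methods:
                predictions[chrom]["z"] = calculate_z_score(
                    sample, group, chrom).to_dict()
            if "ncv" in config.methods:
                template = prepare_ncv(
                    group, chrom,
                    max_denominators=config.ncv_max_denominators,
                    seed=config.seed)
                predictions[chrom]["ncv"] = calculate_ncv_score(
                    sample, template).to_dict()
            if "rbz" in config.methods:
                predictions[chrom]["rbz"] = perform_regression(
                    sample, group, chrom,
                    n_models=config.rbz_n_models,
                    n_predictors=config.rbz_n_predictors,
                    train_fraction=config.train_fraction,
                    seed=config.seed).to_dict()
        report["predictions"] = predictions

        if config.match_qc:
            result = match_control_group(
                sample, group, mode=config.match_mode,
                n_of_samples=config.match_n)
            if config.match_mode == "report":
                report["match_qc"] = result.to_dict()
            else:
                report["match_qc"] = {"subset_ids": result.sample_ids}
        if config.diagnose:
            report["diagnostics"] = diagnose_control_group(group).to_dict()
    except NiptScreenError as exc:
        report["error"] = {
            "type": type(exc).__name__,
            "message": str(exc),
        }
        _write_report(report, config)
        raise
    _write_report(report, config)
    return report


def _write_report(report: dict, config: RunConfig) -> None:
    if config.out_dir is None:
        return
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, allow_nan=True,
                   default=float) + "\n")
    (out_dir / "report.txt").write_text(render_text_report(report))


def render_text_report(report: dict) -> str:
    """Human-readable rendering of the JSON report."""
    lines = ["== screening report =="]
    if "binning" in report:
        b = report["binning"]
        lines.append(f"sample {b['sample_id']}  "
                     f"({b['total_autosomal_reads']:.0f} autosomal reads, "
                     f"{b['n_controls']} controls)")
    if "correction_status" in report:
        lines.append("corrections: "
                     + " -> ".join(report["correction_status"]))
    for chrom, methods in report.get("predictions", {}).items():
        for method, res in methods.items():
            if method == "z":
                s = res["control_group_statistics"]
                lines.append(
                    f"chr{chrom} Z-score: {res['z_score']:.3f}  "
                    f"(mean {s['mean']:.6e}, SD {s['SD']:.6e}, "
                    f"Shapiro_P {s['Shapiro_P_value']:.3f})")
            elif method == "ncv":
                lines.append(
                    f"chr{chrom} NCV: {res['ncv_score']:.3f}  "
                    f"denominators {','.join(res['denominators'])}")
            else:
                rbzs = ", ".join(f"{m['rbz']:.3f}" for m in res["models"])
                lines.append(f"chr{chrom} RBZ models: {rbzs}")
    if "match_qc" in report and "match_score" in report.get("match_qc", {}):
        m = report["match_qc"]
        lines.append(
            f"Match QC score {m['match_score']:.3e}  "
            f"(group {m['group_match_mean']:.3e} "
            f"± {m['group_match_sd']:.3e}; flagged: {m['flagged']})")
    if "diagnostics" in report:
        d = report["diagnostics"]
        lines.append(f"diagnostics: {len(d['abnormal'])} aberrant scores; "
                     f"removal candidates: "
                     f"{', '.join(d['removal_candidates']) or 'none'}")
    if "error" in report:
        lines.append(f"ERROR [{report['error']['type']}]: "
                     f"{report['error']['message']}")
    return "\n".join(lines) + "\n"
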