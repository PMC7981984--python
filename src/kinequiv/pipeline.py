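"""End-to-end workflow: nested models -> TFA -> steady states -> ensembles -> DI.

One call runs, per nesting level: TFA construction (physiology + optional
directionality preset), representative steady-state selection (sampling + PCA
on the first level, band-MILP transfer from the previous level afterwards),
saturation-sampled kinetic ensembles (stratified from the previous level so
shared parameters are bit-identical), control-coefficient computation, and
the cross-level deviation reports.  Every artifact is written with the seed
and a config hash; a completed stage whose outputs already exist is skipped
on re-run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import deviation as dev
from .kinetics import assign_mechanisms, stratified_resample
from .mca import (
    KineticEnsemble,
    build_ensemble,
    ensemble_from_samples,
    make_stability_check,
    reduce_system,
)
from .model_io import (
    NestedMapping,
    StoichiometricModel,
    apply_directionality_preset,
    build_nested_mapping,
    load_model,
)
from .sampling import (
    SteadyState,
    assemble_steady_state,
    sample_concentration_space,
    sample_flux_space,
    select_representative,
)
from .synthetic import ToyFamilySpec, generate_nested_toys
from .thermo import ThermoParams, build_tfa_problem, classify_bidirectional, run_tva
from .transfer import TransferReport, transfer_steady_state


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    model_paths: list[str] = field(default_factory=list)
    physiology_path: str | None = None
    synthetic: dict | None = None  # ToyFamilySpec fields; used if no model paths
    preset: str = "none"
    relaxation: float = 0.01
    n_flux_samples: int = 10000
    n_kinetic: int = 200
    max_tries: int = 10
    seed: int = 1
    variance_coverage: float = 0.9
    gamma_exclusion: float = 0.01
    min_net_flux: float = 1e-4
    warmup: int = 1000
    thin: int = 10
    do_tva: bool = False
    target_flux: str | None = None  # ranking target; default: first lumped reaction
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class LevelResult:
    model: StoichiometricModel
    state: SteadyState
    ensemble: KineticEnsemble
    transfer_flux: TransferReport | None = None
    transfer_conc: TransferReport | None = None
    retained_fraction: float | None = None  # stratified retention from previous level
    bidirectional: set[str] | None = None


@dataclass
class PipelineResult:
    config: RunConfig
    models: list[StoichiometricModel]
    mappings: list[NestedMapping]
    levels: list[LevelResult]
    di_reports: list[dev.DIReport]  # one per consecutive pair
    rankings: list[pd.DataFrame]  # pairwise top-controller comparisons
    subsystem_reports: list[dev.SubsystemDeviationReport]
    run_dir: Path | None = None


class _StageLog:
    """JSON-lines structured log with per-stage timing."""

    def __init__(self, path: Path | None):
        self.path = path
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)

    def event(self, stage: str, **fields) -> None:
        if self.path is None:
            return
        rec = {"t": time.time(), "stage": stage, **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _load_family(
    config: RunConfig,
) -> tuple[list[StoichiometricModel], list[NestedMapping], pd.DataFrame | None]:
    if config.model_paths:
        models = [load_model(p) for p in config.model_paths]
        mappings = [
            build_nested_mapping(models[i], models[i + 1])
            for i in range(len(models) - 1)
        ]
        physiology = (
            pd.read_csv(config.physiology_path, sep="\t")
            if config.physiology_path
            else None
        )
        return models, mappings, physiology
    spec = ToyFamilySpec(**(config.synthetic or {}))
    return generate_nested_toys(spec)


def run_pipeline(config: RunConfig) -> PipelineResult:
    run_dir = None
    if config.outdir is not None:
        run_dir = Path(config.outdir)
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "config.json").write_text(
            json.dumps(
                {"hash": config.config_hash(), **asdict(config)},
                indent=2,
                sort_keys=True,
            )
        )
    log = _StageLog(run_dir / "log.jsonl" if run_dir else None)

    models, mappings, physiology = _load_family(config)
    if config.preset != "none":
        out = []
        for m in models:
            clamped, warnings = apply_directionality_preset(m, config.preset)
            for w in warnings:
                log.event("preset", warning=w)
            out.append(clamped)
        models = out
    log.event("load", models=[m.name for m in models])

    params = ThermoParams(
        gamma_exclusion=config.gamma_exclusion, min_net_flux=config.min_net_flux
    )
    levels: list[LevelResult] = []
    prev_state: SteadyState | None = None
    prev_ensemble: KineticEnsemble | None = None
    for li, model in enumerate(models):
        t0 = time.time()
        problem = build_tfa_problem(model, params, physiology)
        bidir = None
        if config.do_tva:
            tva = run_tva(problem)
            bidir = classify_bidirectional(tva)
            if run_dir:
                _write(run_dir / f"{model.name}_tva.json", tva.to_json())
        transfer_flux = transfer_conc = None
        if li == 0:
            problem.fix_directionality()
            pool = sample_flux_space(
                problem,
                n=config.n_flux_samples,
                seed=config.seed,
                warmup=config.warmup,
                thin=config.thin,
            )
            _, flux_row = select_representative(pool, config.variance_coverage)
            nf = flux_row.copy()
            nf.index = [i.removeprefix("NF_") for i in nf.index]
            cpool = sample_concentration_space(
                problem,
                fixed_flux=nf,
                n=config.n_flux_samples,
                seed=config.seed + 1,
                warmup=config.warmup,
                thin=config.thin,
            )
            _, conc_row = select_representative(cpool, config.variance_coverage)
            state = assemble_steady_state(
                problem, nf, conc_row, provenance={"method": "pca", "seed": config.seed}
            )
        else:
            state, transfer_flux, transfer_conc = transfer_steady_state(
                problem,
                mappings[li - 1],
                prev_state,
                n=config.n_flux_samples,
                seed=config.seed + 10 * li,
                relaxation=config.relaxation,
                variance_coverage=config.variance_coverage,
                warmup=config.warmup,
                thin=config.thin,
            )
        log.event("steady_state", model=model.name, seconds=time.time() - t0)

        t0 = time.time()
        specs = assign_mechanisms(model)
        reduced = reduce_system(model)
        retained_fraction = None
        if li == 0 or prev_ensemble is None:
            ensemble = build_ensemble(
                model,
                state,
                specs,
                n_stable=config.n_kinetic,
                seed=config.seed + 100 * li,
                reduced=reduced,
            )
        else:
            check = make_stability_check(specs, state, model, reduced)
            strat = stratified_resample(
                prev_ensemble.stable_samples,
                mappings[li - 1],
                specs,
                model,
                seed=config.seed + 100 * li,
                stability_check=check,
                max_tries=config.max_tries,
            )
            retained_fraction = strat.retained_fraction
            ensemble = ensemble_from_samples(strat.samples, model, state, specs, reduced)
        log.event(
            "ensemble",
            model=model.name,
            sampled=ensemble.n_sampled,
            stable=ensemble.n_stable,
            retained_fraction=retained_fraction,
            seconds=time.time() - t0,
        )
        levels.append(
            LevelResult(
                model=model,
                state=state,
                ensemble=ensemble,
                transfer_flux=transfer_flux,
                transfer_conc=transfer_conc,
                retained_fraction=retained_fraction,
                bidirectional=bidir,
            )
        )
        if run_dir:
            _write(run_dir / f"{model.name}_state.json", state.to_json())
            if transfer_flux is not None:
                transfer_flux.to_tsv(run_dir / f"{model.name}_transfer_flux.tsv")
                transfer_conc.to_tsv(run_dir / f"{model.name}_transfer_conc.tsv")
        prev_state, prev_ensemble = state, ensemble

    di_reports, rankings, subsystem_reports = [], [], []
    for li in range(1, len(levels)):
        small, large = levels[li - 1], levels[li]
        mapping = mappings[li - 1]
        shared = dev.shared_enzyme_set(mapping, large.model)
        report = dev.deviation_index(large.ensemble, shared)
        if len(report.di) >= 4:
            report = dev.percentile_classes(report)
        di_reports.append(report)
        target = config.target_flux or next(
            (r.id for r in small.model.reactions if r.is_lumped), None
        )
        if target is not None:
            rankings.append(
                dev.pairwise_top_controllers(
                    small.ensemble, large.ensemble, mapping, target
                )
            )
        subsystem_reports.append(
            dev.subsystem_abs_deviation(
                small.ensemble, large.ensemble, mapping, small.model
            )
        )
        if run_dir:
            name = f"{small.model.name}_vs_{large.model.name}"
            report.to_tsv(run_dir / f"{name}_di.tsv")
            _write(run_dir / f"{name}_di.json", report.to_json())
            subsystem_reports[-1].to_tsv(run_dir / f"{name}_subsystem_dev.tsv")
            if rankings:
                rankings[-1].to_csv(run_dir / f"{name}_top_controllers.tsv", sep="\t", index=False)
    log.event("reports", pairs=len(di_reports))
    return PipelineResult(
        config=config,
        models=models,
        mappings=mappings,
        levels=levels,
        di_reports=di_reports,
        rankings=rankings,
        subsystem_reports=subsystem_reports,
        run_dir=run_dir,
    )


def _write(path: Path, text: str) -> None:
    """Idempotent write: skip when the file already holds identical content."""
    if path.exists() and path.read_text() == text:
        return
    path.write_text(text)
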