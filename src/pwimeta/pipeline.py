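"""End-to-end orchestration: trials -> profiles -> study effects -> meta.

The full analysis over a batch of studies mirrors the nine-analysis
layout of a PWI distributional meta-analysis: the pooled interference
effect in each of the five quintiles (by participant), plus the pooled
Fisher-z slope-effect correlation for the slowest and fastest delta
segments, by participant and by item.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from pwimeta import core_data, delta, meta, simulate, study

logger = logging.getLogger(__name__)

QUANTITIES = ("quintile_effects", "correlation_slowest", "correlation_fastest")


@dataclass(frozen=True)
class PipelineConfig:
    """What to analyze and how.

    Either ``input_paths`` (canonical trial tables, one or more studies)
    or ``n_simulated_studies`` (generate that many synthetic studies from
    ``sim_config``) must be given.
    """

    input_paths: tuple[str, ...] = ()
    n_simulated_studies: int = 0
    sim_config: simulate.SimulationConfig | None = None
    unit_kinds: tuple[str, ...] = ("participant", "item")
    quantities: tuple[str, ...] = QUANTITIES
    spec_ms: meta.MetaModelSpec = field(default_factory=meta.MetaModelSpec)
    spec_z: meta.MetaModelSpec = field(default_factory=meta.MetaModelSpec.for_correlations)
    min_per_condition: int = 5
    rt_window: tuple[float, float] | None = None
    k: int = 5
    out_dir: str = "pwimeta_out"
    seed: int = 0
    keep_going: bool = False
    sampler: meta.SamplerSettings | None = None

    def __post_init__(self) -> None:
        if not self.unit_kinds or not self.quantities:
            raise ValueError("select at least one unit kind and one quantity")
        unknown = set(self.quantities) - set(QUANTITIES)
        if unknown:
            raise ValueError(f"unknown quantities: {sorted(unknown)}")
        if not self.input_paths and self.n_simulated_studies < 1:
            raise ValueError("provide input_paths or n_simulated_studies >= 1")


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, digests, counts."""

    config: dict
    seed: int
    started: str
    finished: str = ""
    complete: bool = False
    input_digests: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    analyses: list = field(default_factory=list)
    version: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_studies(config: PipelineConfig) -> dict[str, core_data.TrialTable]:
    studies: dict[str, core_data.TrialTable] = {}
    if config.input_paths:
        for p in config.input_paths:
            table = core_data.read_trials(p)
            studies.update(core_data.split_by_study(table))
    else:
        import numpy as np

        base = config.sim_config or simulate.SimulationConfig()
        seeds = np.random.SeedSequence(config.seed).generate_state(config.n_simulated_studies) % (2**31)
        for i, s in enumerate(seeds):
            sid = f"study{i + 1:02d}"
            cfg = simulate.SimulationConfig(
                n_participants=base.n_participants,
                n_items=base.n_items,
                params_related=base.params_related,
                params_unrelated=base.params_unrelated,
                sd_participant=base.sd_participant,
                sd_item=base.sd_item,
                sd_residual=base.sd_residual,
                seed=int(s),
                study_id=sid,
            )
            studies[sid] = simulate.simulate_experiment(cfg)
    return studies


def _study_effects(
    table: core_data.TrialTable,
    study_id: str,
    config: PipelineConfig,
    manifest: RunManifest,
) -> list[study.StudyEffect]:
    if table.has_correct:
        table = core_data.filter_correct(table)
    if config.rt_window is not None:
        table = core_data.trim_rt(table, *config.rt_window)
    effects: list[study.StudyEffect] = []
    tables: dict[str, core_data.TrialTable] = {}
    for unit_kind in set(config.unit_kinds) | ({"participant"} if "quintile_effects" in config.quantities else set()):
        kept, report = core_data.exclude_sparse_units(table, unit_kind, config.min_per_condition)
        tables[unit_kind] = kept
        manifest.exclusions.setdefault(study_id, {})[unit_kind] = len(report)
    if "quintile_effects" in config.quantities:
        effects.extend(study.quintile_effects(tables["participant"], study_id=study_id, k=config.k))
    for unit_kind in config.unit_kinds:
        profiles = delta.unit_profiles(tables[unit_kind], unit_kind=unit_kind, k=config.k)
        for quantity in config.quantities:
            if not quantity.startswith("correlation_"):
                continue
            segment = quantity.removeprefix("correlation_")
            result = study.slope_effect_correlation(profiles, segment)
            eff = study.correlation_effect(result, study_id, segment)
            effects.append(
                study.StudyEffect(
                    study_id=eff.study_id,
                    quantity=f"{eff.quantity}_{unit_kind}s",
                    y=eff.y,
                    se=eff.se,
                    n_units=eff.n_units,
                )
            )
    manifest.row_counts[study_id] = len(table)
    return effects


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run filtering, profiling, per-study effects and one meta-analysis
    per (quantity, unit kind) over all studies; write everything under
    ``config.out_dir`` and return the manifest.

    Per-study failures abort the run (naming the stage and study) unless
    ``keep_going`` is set, in which case the study is skipped and logged.
    """
    from pwimeta import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: str(v) for k, v in vars(config).items()},
        seed=config.seed,
        started=datetime.datetime.now().isoformat(),
        version=__version__,
    )
    for p in config.input_paths:
        manifest.input_digests[p] = _digest(Path(p))

    studies = _load_studies(config)
    all_effects: list[study.StudyEffect] = []
    for study_id, table in studies.items():
        try:
            all_effects.extend(_study_effects(table, study_id, config, manifest))
        except Exception as exc:
            if config.keep_going:
                logger.warning("skipping study %s: %s", study_id, exc)
                continue
            manifest.finished = datetime.datetime.now().isoformat()
            manifest.write(out / "manifest.json")
            raise RuntimeError(f"pipeline failed at study {study_id!r}: {exc}") from exc

    effects_path = out / "study_effects.csv"
    study.write_effects(all_effects, effects_path)

    sampler = config.sampler or meta.SamplerSettings(seed=config.seed)
    summaries: list[meta.PosteriorSummary] = []
    labels: list[str] = []
    quantities = sorted({e.quantity for e in all_effects})
    for quantity in quantities:
        rows = [e for e in all_effects if e.quantity == quantity]
        spec = config.spec_ms if quantity.startswith("quintile") else config.spec_z
        summaries.append(meta.fit_random_effects(rows, spec, sampler))
        labels.append(quantity)
    summary_path = out / "meta_summaries.csv"
    meta.summaries_frame(summaries, labels).to_csv(summary_path, index=False)

    manifest.analyses = labels
    for path in (effects_path, summary_path):
        manifest.output_digests[path.name] = _digest(path)
    manifest.finished = datetime.datetime.now().isoformat()
    manifest.complete = True
    manifest.write(out / "manifest.json")
    return manifest


def run_simulation_study(
    config: simulate.SimulationConfig | None = None,
    n_replications: int = 100,
    rt_window: tuple[float, float] | None = simulate.DEFAULT_RT_WINDOW,
    out_dir: str | Path | None = None,
) -> simulate.Table5Result:
    """The no-inhibition simulation study: replicate the four slope-effect
    correlations and optionally write the replication table and report."""
    result = simulate.replicate_table5(config, n_replications, rt_window)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if result.replications is not None:
            result.replications.to_csv(out / "table5_replications.csv", index=False)
        report = {
            **result.as_dict(),
            "mean_effect_ms": result.mean_effect,
            "se_mean_effect_ms": result.se_mean_effect,
            "near_zero_effect": result.near_zero_effect,
            "se_slowest_participants": result.se_slowest_participants,
            "se_fastest_participants": result.se_fastest_participants,
            "se_slowest_items": result.se_slowest_items,
            "se_fastest_items": result.se_fastest_items,
            "n_replications": result.n_replications,
            "n_discarded": result.n_discarded,
            "seed": result.seed,
            "rt_window": list(rt_window) if rt_window else None,
        }
        (out / "table5_report.json").write_text(json.dumps(report, indent=2))
    return result
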