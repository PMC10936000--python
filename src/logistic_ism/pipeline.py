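"""End-to-end orchestration: code -> screen -> fit -> ISM -> report.

A :class:`PipelineConfig` points at respondent data + codebook (or a
synthetic scenario), an expert adjacency matrix, and output settings.
:func:`run_pipeline` executes every stage, writes all artifacts to the
output directory, and returns a :class:`PipelineReport` that serializes
deterministically under a fixed seed (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, ism, logistic, screening, survey, synthetic

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class ConfigurationError(ValueError):
    """The pipeline configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class PipelineConfig:
    """Where the pipeline reads inputs and writes artifacts.

    Either ``data_path`` (+ optional ``codebook_path``) or ``scenario_n``
    (simulate under the default synthetic scenario) must be given.  The
    adjacency is read from ``adjacency_path`` or defaults to the published
    expert matrix; ``factor_map`` maps adjacency labels to analysis
    variable names.
    """

    out_dir: str | Path
    data_path: str | Path | None = None
    codebook_path: str | Path | None = None
    adjacency_path: str | Path | None = None
    scenario_n: int | None = None
    alpha: float = 0.05
    outcome_threshold: float | None = None
    seed: int = 0
    factor_map: dict[str, str] = field(
        default_factory=lambda: dict(datasets.FACTOR_VARIABLES)
    )

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.data_path is None and self.scenario_n is None:
            raise ConfigurationError("either data_path or scenario_n is required")

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "data_path": str(self.data_path) if self.data_path else None,
            "codebook_path": str(self.codebook_path) if self.codebook_path else None,
            "adjacency_path": str(self.adjacency_path) if self.adjacency_path else None,
            "scenario_n": self.scenario_n,
            "alpha": self.alpha,
            "outcome_threshold": self.outcome_threshold,
            "seed": self.seed,
            "factor_map": dict(self.factor_map),
        }

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass(frozen=True)
class PipelineReport:
    """All stage outputs plus provenance; serializes deterministically."""

    sample: dict
    screening_report: screening.ScreeningReport
    effects: logistic.EffectTable | None
    gof: logistic.GofResult | None
    factor_sets: ism.FactorSets | None
    partition: ism.LevelPartition | None
    hierarchy: ism.HierarchyGraph | None
    skips: dict[str, str]
    provenance: dict

    def to_dict(self) -> dict:
        d: dict = {
            "sample": self.sample,
            "screening": json.loads(self.screening_report.to_json()),
            "skips": self.skips,
            "provenance": self.provenance,
        }
        d["effects"] = (
            json.loads(self.effects.to_json()) if self.effects is not None else None
        )
        d["goodness_of_fit"] = (
            {
                "statistic": self.gof.statistic,
                "df": self.gof.df,
                "p_value": self.gof.p_value,
                "groups": self.gof.groups,
            }
            if self.gof is not None
            else None
        )
        if self.factor_sets is not None:
            d["factor_sets"] = {
                lab: {
                    "reachable": sorted(self.factor_sets.reachable[lab]),
                    "antecedent": sorted(self.factor_sets.antecedent[lab]),
                    "common": sorted(self.factor_sets.common[lab]),
                }
                for lab in self.factor_sets.labels
            }
        else:
            d["factor_sets"] = None
        d["levels"] = (
            [sorted(level) for level in self.partition.levels]
            if self.partition is not None
            else None
        )
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _load_inputs(
    config: PipelineConfig,
) -> tuple[survey.RawDataset, survey.Codebook]:
    if config.data_path is not None:
        raw = survey.RawDataset.from_csv(config.data_path)
        codebook = (
            survey.Codebook.from_file(config.codebook_path)
            if config.codebook_path
            else datasets.default_codebook()
        )
    else:
        scenario = synthetic.default_scenario(n=config.scenario_n, seed=config.seed)
        raw = synthetic.simulate_responses(scenario)
        codebook = scenario.codebook
    if config.outcome_threshold is not None:
        codebook = survey.Codebook(
            outcome_name=codebook.outcome_name,
            variables=codebook.variables,
            outcome_threshold=config.outcome_threshold,
        )
    return raw, codebook


def _load_adjacency(config: PipelineConfig) -> tuple[list[str], np.ndarray]:
    if config.adjacency_path is not None:
        return ism.load_adjacency_csv(config.adjacency_path)
    return datasets.expert_adjacency()


def sample_characteristics(coded: survey.CodedDataset) -> dict:
    """Per-variable level counts and percentages, plus outcome split."""
    out: dict = {
        "n": coded.n,
        "n_high": coded.n_high,
        "n_low": coded.n_low,
        "low_rate_pct": survey.low_effectiveness_rate(coded) if coded.n else None,
        "n_dropped": coded.n_dropped,
        "variables": {},
    }
    for spec in coded.codebook.variables:
        col = coded.predictors[spec.name]
        out["variables"][spec.name] = {
            level: {
                "n": int((col == level).sum()),
                "pct": round(100.0 * (col == level).mean(), 1) if coded.n else 0.0,
            }
            for level in spec.levels
        }
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages and write artifacts under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    skips: dict[str, str] = {}

    logger.info("stage: load/simulate")
    raw, codebook = _load_inputs(config)
    adj_labels, adj_entries = _load_adjacency(config)
    unknown = [lab for lab in adj_labels if lab not in config.factor_map]
    if unknown:
        raise ConfigurationError(
            f"adjacency labels {unknown} missing from factor_map"
        )

    logger.info("stage: code")
    coded = survey.code_dataset(raw, codebook)
    sample = sample_characteristics(coded)

    logger.info("stage: screen")
    screen = screening.screen_variables(coded, alpha=config.alpha)
    tables = {
        r.variable: survey.crosstab(coded, r.variable)
        for r in screen.results
        if r.error is None
    }
    (out_dir / "screening_table.txt").write_text(
        screening.render_screening_table(screen, tables)
    )

    effects = None
    gof = None
    fsets = None
    partition = None
    hierarchy = None

    binary_selected = [
        v for v in screen.selected if coded.codebook[v].is_binary_coded
    ]
    dropped_multilevel = [v for v in screen.selected if v not in binary_selected]
    if dropped_multilevel:
        skips["multilevel_predictors"] = (
            f"excluded from regression (not binary-coded): {dropped_multilevel}"
        )
    if not binary_selected:
        skips["logistic"] = "no variables passed the chi-square screen"
        skips["ism"] = "no fitted effects to structure"
    else:
        logger.info("stage: fit (%d predictors)", len(binary_selected))
        design = logistic.build_design(coded, binary_selected)
        fit = logistic.fit_logistic(design, coded.outcome)
        effects = logistic.effect_table(fit)
        try:
            gof = logistic.goodness_of_fit(fit)
        except ValueError as exc:  # too few distinct fitted probabilities
            skips["goodness_of_fit"] = str(exc)
        (out_dir / "effect_table.txt").write_text(
            logistic.render_effect_table(effects)
        )

        significant = logistic.select_significant(effects, alpha=config.alpha)
        variable_to_label = {v: s for s, v in config.factor_map.items()}
        mapped = [
            (variable_to_label[v], v) for v in significant if v in variable_to_label
        ]
        unmapped = [v for v in significant if v not in variable_to_label]
        if unmapped:
            skips["ism_unmapped"] = (
                f"significant predictors without a factor label: {unmapped}"
            )
        logger.info("ISM factor mapping: %s", mapped)
        keep_labels = [lab for lab in adj_labels if lab in {s for s, _ in mapped}]
        excluded = [lab for lab in adj_labels if lab not in keep_labels]
        if excluded:
            skips["ism_excluded_factors"] = (
                f"adjacency factors not significant in the model: {excluded}"
            )
        if not keep_labels:
            skips["ism"] = "no significant predictor maps to an adjacency factor"
        else:
            logger.info("stage: ism (%d factors)", len(keep_labels))
            keep_idx = [adj_labels.index(lab) for lab in keep_labels]
            sub = adj_entries[np.ix_(keep_idx, keep_idx)]
            R = ism.validate_adjacency(sub)
            M = ism.reachability_closure(R)
            fsets = ism.factor_sets(M, keep_labels)
            partition = ism.partition_levels(M, keep_labels)
            system = ism.FactorSystem(
                labels=tuple(keep_labels),
                names={lab: config.factor_map[lab] for lab in keep_labels},
            )
            hierarchy = ism.build_hierarchy(R, partition, system)
            (out_dir / "hierarchy.dot").write_text(ism.export_graph(hierarchy))

    provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
    }
    report = PipelineReport(
        sample=sample,
        screening_report=screen,
        effects=effects,
        gof=gof,
        factor_sets=fsets,
        partition=partition,
        hierarchy=hierarchy,
        skips=skips,
        provenance=provenance,
    )
    (out_dir / "report.json").write_text(report.to_json())
    for name, text in render_tables(report).items():
        (out_dir / name).write_text(text)
    return report


def simulate_command(
    n: int, seed: int, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a default-scenario survey CSV plus its generating-truth JSON."""
    if n <= 0:
        raise ConfigurationError(f"n must be positive, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = synthetic.default_scenario(n=n, seed=seed)
    raw = synthetic.simulate_responses(scenario)
    data_path = out_dir / "survey.csv"
    truth_path = out_dir / "truth.json"
    raw.to_csv(data_path)
    truth = synthetic.true_parameters(scenario)
    truth_path.write_text(
        json.dumps(
            {
                "intercept": truth.intercept,
                "coefficients": truth.coefficients,
                "odds_ratios": truth.odds_ratios,
                "n": n,
                "seed": seed,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return data_path, truth_path


def render_tables(report: PipelineReport) -> dict[str, str]:
    """Plain-text renderings of the sample/effects/factor-set tables."""
    docs: dict[str, str] = {}

    lines = [f"Sample characteristics (N = {report.sample['n']})", ""]
    lines.append(
        f"High effectiveness: {report.sample['n_high']}   "
        f"Low effectiveness: {report.sample['n_low']}   "
        f"Low rate: {report.sample['low_rate_pct']:.1f}%"
        if report.sample["low_rate_pct"] is not None
        else "empty sample"
    )
    for var, levels in report.sample["variables"].items():
        for i, (level, cell) in enumerate(levels.items()):
            head = var if i == 0 else ""
            lines.append(f"{head:<28}{level:<26}{cell['n']:>7} ({cell['pct']:.1f})")
    docs["sample_table.txt"] = "\n".join(lines) + "\n"

    if report.factor_sets is not None:
        fs = report.factor_sets
        lines = [f"{'Factor':<8}{'R(Si)':<34}{'T(Si)':<34}"]
        for lab in fs.labels:
            reach = ", ".join(sorted(fs.reachable[lab]))
            common = ", ".join(sorted(fs.common[lab]))
            lines.append(f"{lab:<8}{reach:<34}{common:<34}")
        docs["factor_sets_table.txt"] = "\n".join(lines) + "\n"
    elif "ism" in report.skips:
        docs["factor_sets_table.txt"] = f"(skipped: {report.skips['ism']})\n"

    if report.partition is not None:
        names = {1: "surface", 2: "middle"}
        lines = []
        for i, level in enumerate(report.partition.levels, start=1):
            tag = (
                "bottom"
                if i == report.partition.n_levels and i > 1
                else names.get(i, f"level {i}")
            )
            lines.append(f"Level {i} ({tag}): {', '.join(sorted(level))}")
        docs["levels.txt"] = "\n".join(lines) + "\n"
    return docs
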