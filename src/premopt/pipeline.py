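"""End-to-end orchestration: data -> descriptives -> per-stratum fit -> priorities.

The pipeline mirrors the two-stage analysis: each stratum (departmental area)
is processed fully independently — listwise completion on the variables
entering the regression, a proportional-odds fit, baselines taken as the item
means of the same complete-case population, and one priority table across the
requested target gains.  Everything is deterministic given the configuration
seed, so report files are byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codebook import SATISFACTION_ITEM, default_codebook
from .errors import ConfigurationError
from .ordinal_model import OrdinalFit, fit_collapsed_proportional_odds
from .optimizer import PriorityTable, build_priority_table
from .survey_data import DescriptiveTable, SurveyDataset, listwise_complete, load_survey, summarize_by_stratum
from .synthetic_data import SimScenario, default_scenario, generate_survey

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; exactly one data source must be set."""

    input_path: str | Path | None = None
    scenario: SimScenario | str | None = None  # a SimScenario or a default-scenario area name
    stratum_column: str = "stratum"
    items: tuple[str, ...] | None = None  # default: codebook experience items in the data
    outcome: str = SATISFACTION_ITEM
    targets: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    cap: float = 15.0
    metric: str = "expected_score"
    seed: int = 0
    delimiter: str = ","
    output_dir: str | Path | None = None
    report_format: str = "csv"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ConfigurationError("exactly one of input_path / scenario must be given")
        targets = list(self.targets)
        if sorted(targets) != targets or any(t < 0 for t in targets):
            raise ConfigurationError("targets must be nonnegative and ascending")

    def resolved_scenario(self) -> SimScenario | None:
        if self.scenario is None:
            return None
        if isinstance(self.scenario, str):
            return default_scenario(self.scenario, seed=self.seed)
        return self.scenario

    def echo(self) -> dict:
        scenario = self.resolved_scenario()
        return {
            "input_path": None if self.input_path is None else str(self.input_path),
            "scenario": None
            if scenario is None
            else {
                "seed": scenario.seed,
                "strata": [
                    {
                        "label": s.label,
                        "n": s.n,
                        "item_corr": s.item_corr,
                        "dropout_rate": s.dropout_rate,
                    }
                    for s in scenario.strata
                ],
            },
            "stratum_column": self.stratum_column,
            "outcome": self.outcome,
            "targets": list(self.targets),
            "cap": self.cap,
            "metric": self.metric,
            "seed": self.seed,
            "missing_data_policy": "listwise deletion on outcome + predictors, per stratum",
            "baseline_policy": "item means over the regression's complete-case records",
            "eligible_policy": "items with positive fitted coefficients",
        }


@dataclass
class ReportBundle:
    """All report sections of one run."""

    descriptives: DescriptiveTable
    fits: dict[str, OrdinalFit]
    baselines: dict[str, dict[str, float]]
    priorities: dict[str, PriorityTable]
    metadata: dict = field(default_factory=dict)

    @property
    def strata(self) -> list[str]:
        return list(self.fits)

    def counts_frame(self) -> pd.DataFrame:
        """Selected-item counts per stratum and target (infeasible flagged)."""
        if not self.priorities:
            return pd.DataFrame(index=pd.Index([], name="stratum"))
        return pd.concat([pt.counts_frame() for pt in self.priorities.values()])

    def to_dict(self) -> dict:
        def frame_records(df: pd.DataFrame) -> list[dict]:
            clean = df.replace({np.nan: None})
            return clean.to_dict(orient="records")

        return {
            "descriptives": {
                "rows": frame_records(self.descriptives.rows),
                "columns": list(self.descriptives.rows.columns),
                "satisfaction_summary": frame_records(self.descriptives.satisfaction_summary),
                "satisfaction_columns": list(self.descriptives.satisfaction_summary.columns),
            },
            "fits": {s: f.to_dict() for s, f in self.fits.items()},
            "baselines": self.baselines,
            "priorities": {s: p.to_dict() for s, p in self.priorities.items()},
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReportBundle":
        def records_frame(records: list[dict], columns: list[str]) -> pd.DataFrame:
            df = pd.DataFrame(records, columns=columns)
            for col in df.columns:
                converted = pd.to_numeric(df[col], errors="coerce")
                if converted.notna().sum() == df[col].notna().sum():
                    df[col] = converted
            return df

        desc = DescriptiveTable(
            rows=records_frame(d["descriptives"]["rows"], d["descriptives"]["columns"]),
            satisfaction_summary=records_frame(
                d["descriptives"]["satisfaction_summary"], d["descriptives"]["satisfaction_columns"]
            ),
        )
        return cls(
            descriptives=desc,
            fits={s: OrdinalFit.from_dict(f) for s, f in d["fits"].items()},
            baselines={s: dict(b) for s, b in d["baselines"].items()},
            priorities={s: PriorityTable.from_dict(p) for s, p in d["priorities"].items()},
            metadata=d.get("metadata", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReportBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _versions() -> dict[str, str]:
    import scipy

    return {
        "premopt": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and (optionally) write the report files."""
    stage = "load"
    try:
        codebook = default_codebook()
        scenario = config.resolved_scenario()
        if scenario is not None:
            logger.info("stage=load simulating scenario (seed=%d)", scenario.seed)
            data = generate_survey(scenario, codebook)
        else:
            logger.info("stage=load reading %s", config.input_path)
            data = load_survey(
                config.input_path,
                codebook,
                delimiter=config.delimiter,
                stratum_column=config.stratum_column,
            )

        stage = "descriptives"
        descriptives = summarize_by_stratum(data)

        items = config.items
        if items is None:
            items = tuple(i for i in codebook.experience_ids if i in data.frame.columns)

        fits: dict[str, OrdinalFit] = {}
        baselines: dict[str, dict[str, float]] = {}
        priorities: dict[str, PriorityTable] = {}
        for label in data.strata:
            stage = f"fit[{label}]"
            subset = data.for_stratum(label)
            complete = listwise_complete(subset, [config.outcome, *items])
            logger.info("stage=%s n_complete=%d", stage, complete.n)
            fit = fit_collapsed_proportional_odds(complete, config.outcome, items, stratum=label)
            fits[label] = fit

            stage = f"baselines[{label}]"
            means = complete.frame[list(items)].mean()
            baselines[label] = {i: float(means[i]) for i in items}

            stage = f"priorities[{label}]"
            priorities[label] = build_priority_table(
                fit,
                [baselines[label][i] for i in items],
                targets=config.targets,
                cap=config.cap,
                metric=config.metric,
                stratum=label,
            )

        bundle = ReportBundle(
            descriptives=descriptives,
            fits=fits,
            baselines=baselines,
            priorities=priorities,
            metadata={"config": config.echo(), "versions": _versions()},
        )
        if config.output_dir is not None:
            stage = "render"
            render_report(bundle, config.output_dir, config.report_format)
        return bundle
    except Exception:
        logger.exception("pipeline failed at stage %s", stage)
        raise


def render_report(bundle: ReportBundle, output_dir: str | Path, format: str = "csv") -> list[Path]:
    """Write the report sections; bit-stable for identical bundles.

    ``format`` selects csv (one file per section), json (single bundle file) or
    markdown (single human-readable report).  Partial outputs are removed if a
    write fails.
    """
    if format not in ("csv", "json", "markdown"):
        raise ConfigurationError(f"unknown report format {format!r}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if format == "json":
            path = out / "report.json"
            bundle.to_json(path)
            written.append(path)
        elif format == "csv":
            path = out / "descriptives.csv"
            bundle.descriptives.to_csv(path)
            written.append(path)
            path = out / "satisfaction_summary.csv"
            bundle.descriptives.satisfaction_summary.to_csv(path, index=False, float_format="%.6g")
            written.append(path)
            for label, fit in bundle.fits.items():
                path = out / f"fit_{label}.csv"
                fit.to_frame().to_csv(path, index=False, float_format="%.6g")
                written.append(path)
                path = out / f"fit_{label}.json"
                fit.to_json(path)
                written.append(path)
            for label, pt in bundle.priorities.items():
                path = out / f"priority_{label}.csv"
                pt.to_csv(path)
                written.append(path)
            path = out / "counts.csv"
            bundle.counts_frame().to_csv(path)
            written.append(path)
            path = out / "metadata.json"
            path.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True) + "\n")
            written.append(path)
        else:  # markdown
            lines = ["# Satisfaction improvement report", ""]
            lines += ["## Overall satisfaction per stratum", ""]
            lines.append(bundle.descriptives.satisfaction_summary.to_string(index=False))
            lines.append("")
            for label, fit in bundle.fits.items():
                lines += [f"## Regression — {label}", "", fit.to_frame().to_string(index=False), ""]
            lines += ["## Required items per target", ""]
            lines.append(bundle.counts_frame().to_string())
            lines.append("")
            for label, pt in bundle.priorities.items():
                lines += [f"## Priority table — {label}", "", pt.to_markdown()]
            path = out / "report.md"
            path.write_text("\n".join(lines))
            written.append(path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return written
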