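"""End-to-end pipeline: simulate/read -> classify -> thresholds -> consolidate -> report.

Runs the derivation stages in order on one cohort and writes all artifacts
to an output directory, together with a run-metadata file (package version,
config hash, seed) so identical configurations produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .consolidate import consolidate_cohort
from .detailed import ClassificationPolicy, DEFAULT_POLICY, classify_cohort_detailed
from .interventions import tabulate_categories
from .io import CohortSchema, read_cohort, write_cohort, write_results
from .report import change_report, crosstab, flow_table
from .simulate import GeneratorParams, generate_cohort, self_report_post_sensitivity, truth_confusion
from .thresholds import ThresholdMethod, ThresholdResult, estimate_all_thresholds

logger = logging.getLogger("menoderive")


@dataclass(slots=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a cohort file) or ``simulate`` (generator
    parameters) provides the cohort. ``threshold_method`` picks which of the
    three estimated thresholds drives consolidation.
    """

    output_dir: str | Path = "menoderive_out"
    input_path: Optional[str | Path] = None
    simulate: Optional[GeneratorParams] = None
    schema: Optional[CohortSchema] = None
    policy: ClassificationPolicy = field(default_factory=ClassificationPolicy)
    cut_point: float = 0.90
    threshold_method: ThresholdMethod = ThresholdMethod.REFERENCE
    reclassify_unknown: bool = True

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj
        blob = json.dumps(encode(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _threshold_frame(result: ThresholdResult) -> pd.DataFrame:
    return pd.DataFrame(
        result.cumulative_table, columns=["age", "numerator", "denominator", "proportion"]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full derivation and write artifacts; returns a summary dict.

    Raises on a configuration whose selected threshold is not attained (the
    consolidation stage refuses), after writing the threshold tables so the
    failure can be inspected.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if (config.input_path is None) == (config.simulate is None):
        raise ValueError("provide exactly one of input_path or simulate")

    synthetic = None
    if config.simulate is not None:
        logger.info("simulating cohort: n=%d seed=%d", config.simulate.n, config.simulate.seed)
        synthetic = generate_cohort(config.simulate)
        records = synthetic.records
        write_cohort(records, out / "cohort.csv", config.schema)
        synthetic.truth.to_csv(out / "truth.csv", index=False)
    else:
        logger.info("reading cohort from %s", config.input_path)
        records, validation = read_cohort(config.input_path, config.schema)
        pd.DataFrame(
            [(f.participant_id, f.code, f.message) for f in validation.flags],
            columns=["participant_id", "flag", "message"],
        ).to_csv(out / "validation.csv", index=False)

    interventions = tabulate_categories(records)
    pd.DataFrame(
        [(c.value, cnt, prop) for c, (cnt, prop) in interventions.items()],
        columns=["category", "count", "proportion"],
    ).to_csv(out / "interventions.csv", index=False)

    results = classify_cohort_detailed(records, config.policy)
    thresholds = estimate_all_thresholds(records, results, cut_point=config.cut_point)
    for method, tr in thresholds.items():
        _threshold_frame(tr).to_csv(out / f"threshold_{method.value}.csv", index=False)

    chosen = thresholds[config.threshold_method]
    results = consolidate_cohort(results, records, chosen, config.reclassify_unknown)
    write_results(records, results, out / "results.csv", config.schema)

    self_reported = [r.menopause for r in records]
    crosstab(self_reported, [r.detailed for r in results]).counts.to_csv(out / "crosstab_detailed.csv")
    crosstab(self_reported, [r.consolidated for r in results]).counts.to_csv(
        out / "crosstab_consolidated.csv"
    )
    flow_table(
        self_reported, [r.detailed for r in results], [r.consolidated for r in results]
    ).to_csv(out / "flow.csv", index=False)
    changes = change_report(self_reported, results)
    changes.to_csv(out / "changes.csv", index=False)

    summary = {
        "n": len(records),
        "thresholds": {m.value: t.threshold_age for m, t in thresholds.items()},
        "threshold_method": config.threshold_method.value,
        "reclassify_unknown": config.reclassify_unknown,
    }
    if synthetic is not None:
        comparison = truth_confusion(synthetic, results)
        summary["post_sensitivity"] = comparison.post_sensitivity
        summary["self_report_post_sensitivity"] = self_report_post_sensitivity(synthetic)
        comparison.table.to_csv(out / "truth_confusion.csv")

    metadata = {
        "package": "menoderive",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": None if config.simulate is None else config.simulate.seed,
        "summary": summary,
    }
    with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    return summary
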