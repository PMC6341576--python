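"""End-to-end reproducible run: config in, report bundle out.

A :class:`RunConfig` names the inputs (bundle directory or a simulation
block, code list, pattern file), the window parameters, sample sizes and
seeds; :func:`run_pipeline` executes simulate (optional) -> cohort ->
ascertain -> validate -> epistats, writes every table plus a run log
recording all parameters, and re-derives the step counts from the written
classifications as an internal consistency check.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from .ascertain import StepCounts
from .codelists import default_codelists, load_codelist
from .model import DEFAULT_PPV_SAMPLE, DEFAULT_REVIEW_SIZES, SCLCPhenotype
from .synth import SimConfig, generate_bundle, read_bundle, write_bundle
from .textmine import default_patterns, load_patterns

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: str
    bundle_dir: str | None = None
    simulate: dict | None = None  # SimConfig fields; used if bundle_dir unset
    codes_path: str | None = None
    patterns_path: str | None = None
    study_start: date = date(2000, 1, 1)
    study_end: date = date(2014, 12, 31)
    cross_code_days: int = 90
    text_lo: int = -30
    text_hi: int = 90
    backdate_lookback: int = 90
    review_sizes: dict = field(default_factory=lambda: dict(DEFAULT_REVIEW_SIZES))
    ppv_sample: tuple[int, int] = DEFAULT_PPV_SAMPLE
    confirmation_rates: dict | None = None
    review_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bundle_dir is None and self.simulate is None:
            raise ValueError("RunConfig needs bundle_dir or a simulate block")
        if isinstance(self.study_start, str):
            self.study_start = date.fromisoformat(self.study_start)
        if isinstance(self.study_end, str):
            self.study_end = date.fromisoformat(self.study_end)
        self.ppv_sample = tuple(self.ppv_sample)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig):
    """Execute the full pipeline; returns the fitted results object."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        if config.bundle_dir is not None:
            bundle = read_bundle(config.bundle_dir)
        else:
            sim = dict(config.simulate or {})
            sim.setdefault("seed", config.seed)
            for key in ("study_start", "study_end"):
                if isinstance(sim.get(key), str):
                    sim[key] = date.fromisoformat(sim[key])
            bundle = generate_bundle(SimConfig(**sim))
            write_bundle(bundle, out_dir / "bundle")
    except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
        raise PipelineError("simulate/load", str(exc)) from exc

    try:
        codelists = (load_codelist(config.codes_path)
                     if config.codes_path else default_codelists())
        patterns = (load_patterns(config.patterns_path)
                    if config.patterns_path else default_patterns())
    except Exception as exc:
        raise PipelineError("configuration", str(exc)) from exc

    model = SCLCPhenotype(
        bundle, codelists, patterns, config.study_start, config.study_end,
        config.cross_code_days, config.text_lo, config.text_hi,
        config.backdate_lookback)
    try:
        results = model.fit(
            review_sizes=config.review_sizes, ppv_sample=config.ppv_sample,
            confirmation_rates=config.confirmation_rates,
            review_error_rate=config.review_error_rate, seed=config.seed)
    except Exception as exc:
        raise PipelineError("ascertain/validate", str(exc)) from exc

    results.save(out_dir)
    _consistency_check(out_dir)

    log = {
        "parameters": _jsonable(dataclasses.asdict(config)),
        "stages": {
            "cohort": {"eligible": len(results.followups),
                       "person_years": results.person_years},
            "ascertain": results.step_counts.to_dict(),
            "validate": results.validation_report(),
        },
    }
    (out_dir / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True, default=str))
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, date):
        return obj.isoformat()
    return obj


def _consistency_check(out_dir: Path) -> None:
    """Every count in step_counts.json must be re-derivable from
    classifications.csv."""
    cls = pd.read_csv(out_dir / "classifications.csv")
    written = json.loads((out_dir / "step_counts.json").read_text())
    rederived = StepCounts.from_classifications(cls).to_dict()
    for key, value in rederived.items():
        if key in ("confirmation_rates", "expected_cases_total",
                   "expected_cases_final", "text_both_term"):
            continue
        if written.get(key) != value:
            raise PipelineError(
                "consistency",
                f"step_counts.json {key}={written.get(key)} but "
                f"classifications.csv yields {value}")
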