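"""End-to-end experiment: synthesize a matched cohort, evaluate plan
quality on the averaged/exhale/inhale geometries, robustness bandwidths,
the 4D dynamic (interplay) dose and NTCP, and emit the paired comparison
report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortRanges, generate_matched_cohort
from .dose import DoseEngine, Scenario, SpotKernel
from .dvh import IndexSpec, constraint_report, standard_index_panel
from .interplay import accumulate_dynamic_dose
from .machine import RepaintRules, TimingParams
from .ntcp import DEFAULT_ENDPOINTS, ntcp_from_dose
from .phantom import PhantomConfig
from .robustness import bandwidth_table, make_scenarios, scenario_index_table
from .stats import compare_cohort
from . import io as pio

log = logging.getLogger(__name__)

NOMINAL_CONTEXTS = ("averaged", "exhale", "inhale")


@dataclass
class ExperimentConfig:
    n_pairs: int = 10
    seed: int = 7
    n_fractions: int = 25
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    ranges: CohortRanges = field(default_factory=CohortRanges)
    kernel: SpotKernel = field(default_factory=SpotKernel)
    timing: TimingParams = field(default_factory=TimingParams)
    repaint: RepaintRules = field(default_factory=RepaintRules)
    shift_mm: float = 3.0
    range_pct: float = 3.0
    robustness_phases: tuple[str, ...] = ("averaged", "exhale", "inhale")
    spot_spacing_mm: float = 6.5
    layer_spacing_mm: float = 6.0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key, sub in (
            ("phantom", PhantomConfig),
            ("ranges", CohortRanges),
            ("kernel", SpotKernel),
            ("timing", TimingParams),
            ("repaint", RepaintRules),
        ):
            if key in d and isinstance(d[key], dict):
                sd = d[key]
                for k in list(sd):
                    if isinstance(sd[k], list):
                        sd[k] = tuple(sd[k])
                d[key] = sub(**sd)
        if "robustness_phases" in d:
            d["robustness_phases"] = tuple(d["robustness_phases"])
        return cls(**d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # where results land does not change them
        s = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(s.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    metrics: pd.DataFrame  # long: context, index, group, pair, value
    comparison: pd.DataFrame
    constraints: pd.DataFrame
    ntcp: pd.DataFrame
    failures: list


def _patient_metrics(case, pair_label: str, cfg: ExperimentConfig) -> tuple:
    """All evaluation contexts for one patient; returns (rows, extras)."""
    panel = standard_index_panel()
    eng = DoseEngine(case.phantom, cfg.kernel)
    rows = []

    # ROI covering every structure in the panel keeps dose evaluation cheap.
    roi = np.zeros(case.phantom.grid_shape, dtype=bool)
    for spec in panel:
        roi |= case.phantom.mask(spec.structure)

    nominal_dose = {}
    for phase in NOMINAL_CONTEXTS:
        dose = eng.compute_dose(case.plan, Scenario(phase=phase), motion=case.motion)
        nominal_dose[phase] = dose
        for spec in panel:
            rows.append(
                dict(
                    context=f"nominal:{phase}",
                    index=spec.label,
                    group=case.beam_config.group_label,
                    pair=pair_label,
                    value=spec.evaluate(dose, case.phantom),
                )
            )

    for phase in cfg.robustness_phases:
        scen = make_scenarios(cfg.shift_mm, cfg.range_pct, phase=phase)
        table = scenario_index_table(
            case.plan, case.phantom, scen, panel, motion=case.motion, engine=eng
        )
        for index, width in bandwidth_table(table).items():
            rows.append(
                dict(
                    context=f"bandwidth:{phase}",
                    index=index,
                    group=case.beam_config.group_label,
                    pair=pair_label,
                    value=width,
                )
            )

    interplay = accumulate_dynamic_dose(
        case.plan,
        case.phantom,
        case.motion,
        rules=cfg.repaint,
        timing=cfg.timing,
        n_fractions=cfg.n_fractions,
        seed=cfg.seed,
        case_index=int(pair_label) * 2 + (case.beam_config.group_label == "R-L"),
        engine=eng,
    )
    for spec in panel:
        rows.append(
            dict(
                context="interplay",
                index=spec.label,
                group=case.beam_config.group_label,
                pair=pair_label,
                value=spec.evaluate(interplay.dose, case.phantom),
            )
        )

    constraints = constraint_report(nominal_dose["averaged"], case.phantom)
    constraints.insert(0, "patient", case.id)
    ntcp = ntcp_from_dose(nominal_dose["averaged"], case.phantom)
    ntcp_rows = [
        dict(
            patient=case.id,
            group=case.beam_config.group_label,
            pair=pair_label,
            endpoint=k,
            eud_gy=v["eud_gy"],
            ntcp=v["ntcp"],
        )
        for k, v in ntcp.items()
    ]
    return rows, constraints, ntcp_rows


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full comparison experiment; failures are recorded per patient
    and leave gaps in the report rather than aborting the cohort."""
    cohort = generate_matched_cohort(
        n_pairs=config.n_pairs,
        seed=config.seed,
        ranges=config.ranges,
        phantom_config=config.phantom,
        kernel=config.kernel,
        spot_spacing_mm=config.spot_spacing_mm,
        layer_spacing_mm=config.layer_spacing_mm,
        n_fractions=config.n_fractions,
    )
    metric_rows, constraint_frames, ntcp_rows, failures = [], [], [], []
    for p, pair in enumerate(cohort):
        for case in pair:
            try:
                rows, constraints, nrows = _patient_metrics(case, str(p), config)
                metric_rows.extend(rows)
                constraint_frames.append(constraints)
                ntcp_rows.extend(nrows)
            except Exception as exc:  # gap, not abort
                log.exception("patient %s failed", case.id)
                failures.append((case.id, repr(exc)))
    metrics = pd.DataFrame(metric_rows)
    comparison = compare_cohort(metrics) if len(metrics) else pd.DataFrame()
    ntcp = pd.DataFrame(ntcp_rows)
    if len(ntcp):
        ntcp_long = ntcp.rename(columns={"endpoint": "index", "ntcp": "value"})
        ntcp_long["context"] = "ntcp"
        comparison = pd.concat(
            [comparison, compare_cohort(ntcp_long)], ignore_index=True
        )
    constraints = (
        pd.concat(constraint_frames, ignore_index=True)
        if constraint_frames
        else pd.DataFrame()
    )
    report = ExperimentReport(
        config=config,
        metrics=metrics,
        comparison=comparison,
        constraints=constraints,
        ntcp=ntcp,
        failures=failures,
    )
    if config.output_dir:
        _write_report(report)
    return report


def _write_report(report: ExperimentReport) -> None:
    out = Path(report.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in (
        ("metrics.csv", report.metrics),
        ("comparison.csv", report.comparison),
        ("constraints.csv", report.constraints),
        ("ntcp.csv", report.ntcp),
    ):
        path = out / name
        df.to_csv(path, index=False)
        files[name] = pio.sha256_of(path)
    manifest = {
        "config_hash": report.config.config_hash(),
        "config": report.config.to_dict(),
        "files": files,
        "failures": report.failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
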