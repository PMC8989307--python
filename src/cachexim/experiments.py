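"""Built-in scenario suites reproducing the study's schedule comparisons.

Every suite is a named list of scenarios sharing parameters and differing
only in schedule (and, where relevant, host age or morphine comedication),
scored against a reference regimen — conventionally 24 mg/kg daily, the
most lean-sparing standard schedule.  Suites are deterministic: re-running
one produces identical score tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .coupled import HostTrajectory, Scenario, run
from .efficacy import score_table
from .schedules import (
    Schedule,
    make_cycle,
    make_daily,
    make_every_other_day,
    make_metronomic,
    make_weekly_pattern,
)
from .tissue import TumourParams

__all__ = [
    "ExperimentSuite",
    "run_suite",
    "table2_suite",
    "table3_suite",
    "metronomic_suite",
    "aging_suite",
    "morphine_suite",
    "mtd_suite",
    "BUILTIN_SUITES",
]

#: Label of the standard reference regimen.
REFERENCE_LABEL = "daily:24"


@dataclass
class ExperimentSuite:
    name: str
    scenarios: list[Scenario]
    reference: str = REFERENCE_LABEL

    def __post_init__(self) -> None:
        labels = [s.schedule.label for s in self.scenarios]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate scenario labels in suite {self.name!r}")
        if self.reference not in labels:
            raise ValueError(
                f"reference {self.reference!r} missing from suite {self.name!r}"
            )


def _scenario(schedule: Schedule, **kwargs) -> Scenario:
    kwargs.setdefault("tp", TumourParams())
    return Scenario(schedule=schedule, **kwargs)


def _weekly_standard_schedules() -> list[Schedule]:
    """The ten equal-dose schedules delivering 168-175 mg/kg per week."""
    return [
        make_daily(24),
        make_cycle(6, 1, 28),
        make_cycle(6, 1, 29),
        make_cycle(5, 2, 34),
        make_cycle(5, 2, 35),
        make_cycle(4, 3, 42),
        make_cycle(4, 3, 43),
        make_cycle(3, 4, 56),
        make_cycle(3, 4, 57),
        make_cycle(3, 4, 58),
    ]


def table2_suite() -> ExperimentSuite:
    """Weekly dose-equivalent cycle schedules (168-175 mg/kg/week)."""
    return ExperimentSuite(
        name="table2",
        scenarios=[_scenario(s) for s in _weekly_standard_schedules()],
    )


def table3_suite() -> ExperimentSuite:
    """Weekly on/off patterns at 168-175 mg/kg/week, incl. every-other-day."""
    five_patterns = [(5, 2), (4, 1, 1, 1), (3, 1, 2, 1), (2, 1, 3, 1), (1, 1, 4, 1)]
    four_patterns = [
        (4, 3), (3, 2, 1, 1), (2, 2, 2, 1), (1, 2, 3, 1), (1, 1, 1, 1, 1, 1, 1),
    ]
    schedules = [make_daily(24)]
    for dose in (34, 35):
        schedules += [make_weekly_pattern(p, dose) for p in five_patterns]
    for dose in (42, 43):
        schedules += [make_weekly_pattern(p, dose) for p in four_patterns]
    schedules += [make_every_other_day(48), make_every_other_day(50)]
    return ExperimentSuite(name="table3", scenarios=[_scenario(s) for s in schedules])


def metronomic_suite() -> ExperimentSuite:
    """1-6 equal doses per day at 168 mg/kg/week, plus the two standards."""
    schedules = [make_metronomic(k, 168.0) for k in range(2, 7)]
    schedules += [make_daily(24), make_cycle(5, 2, 35)]
    return ExperimentSuite(name="metronomic", scenarios=[_scenario(s) for s in schedules])


def _aging_schedules() -> list[Schedule]:
    return [
        make_daily(24),
        make_cycle(5, 2, 35),
        make_cycle(4, 3, 42),
        make_cycle(3, 4, 56),
        make_cycle(2, 5, 84),
        make_cycle(1, 6, 168),
        make_every_other_day(48),
        make_metronomic(3, 168.0),
    ]


def aging_suite() -> ExperimentSuite:
    """Young and aged hosts under 168 mg/kg/week regimens."""
    scenarios = []
    for s in _aging_schedules():
        scenarios.append(_scenario(s, aged=False))
        aged_label = replace(s, label=f"aged/{s.label}")
        scenarios.append(_scenario(aged_label, aged=True))
    return ExperimentSuite(name="aging", scenarios=scenarios)


def morphine_suite() -> ExperimentSuite:
    """Each 168 mg/kg/week regimen with and without morphine comedication."""
    scenarios = []
    for s in _aging_schedules():
        scenarios.append(_scenario(s, morphine=False))
        m_label = replace(s, label=f"morphine/{s.label}")
        scenarios.append(_scenario(m_label, morphine=True))
    return ExperimentSuite(name="morphine", scenarios=scenarios)


def mtd_suite() -> ExperimentSuite:
    """Maximum-tolerated-dose concentration of the 168 mg/kg weekly total.

    The four-week cumulative dose (672 mg/kg) is delivered weekly
    (4 x 168), biweekly (2 x 336), or monthly (1 x 672), alongside the two
    standard regimens.
    """
    schedules = [
        make_cycle(1, 6, 168, label="mtd-weekly:168"),
        make_cycle(1, 13, 336, label="mtd-biweekly:336"),
        make_cycle(1, 27, 672, label="mtd-monthly:672"),
        make_daily(24),
        make_cycle(5, 2, 35),
    ]
    return ExperimentSuite(name="mtd", scenarios=[_scenario(s) for s in schedules])


BUILTIN_SUITES = {
    "table2": table2_suite,
    "table3": table3_suite,
    "metronomic": metronomic_suite,
    "aging": aging_suite,
    "morphine": morphine_suite,
    "mtd": mtd_suite,
}


def run_suite(
    suite: ExperimentSuite,
    outdir: str | Path | None = None,
    window: tuple[float, float] = (0.0, 56.0),
) -> tuple[pd.DataFrame, dict[str, HostTrajectory]]:
    """Simulate every scenario and score it against the suite reference.

    Returns the score table and the trajectories; with ``outdir`` set,
    writes one trajectory CSV per scenario, a ``scores.csv`` table, and a
    JSON sidecar recording each scenario's full parameterisation.
    """
    trajectories = {s.schedule.label: run(s) for s in suite.scenarios}
    table = score_table(trajectories, suite.reference, window=window)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {}
        for scenario in suite.scenarios:
            label = scenario.schedule.label
            safe = label.replace("/", "_").replace(":", "_")
            trajectories[label].to_csv(outdir / f"trajectory_{safe}.csv")
            meta[label] = scenario.metadata()
        table.to_csv(outdir / "scores.csv", index=False)
        (outdir / "suite.json").write_text(
            json.dumps({"suite": suite.name, "reference": suite.reference,
                        "window": window, "scenarios": meta}, indent=2, default=str)
        )
    return table, trajectories
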