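"""Cohort simulation and strategy comparison.

For each synthetic patient a simulation anatomy is generated and a plan
library built; for each fraction a daily anatomy is sampled and delivered
under the three adaptation strategies (library selection with couch shift,
conventional couch shift, and full re-plan). Every fraction is evaluated
against the clinical criteria on the *daily* ground-truth structures and
recorded. Summaries mirror a clinical report: per-strategy per-protocol
and acceptable rates, library selection frequencies, and median [IQR] of
each DVH metric. Paired comparisons use Shapiro–Wilk to choose between the
paired t-test and the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .anatomy import (
    AnatomyParams,
    VariationModel,
    generate_simulation_anatomy,
    sample_fraction_scenario,
)
from .dose_engine import (
    DoseModelParams,
    Prescription,
    STRATEGIES,
    daily_target,
    deliver_strategy,
)
from .dvh import CriteriaSet, default_criteria, evaluate_plan, metric_d
from .library_builder import MarginSpec, ShiftGrid, build_plan_library

__all__ = [
    "CohortConfig",
    "FractionRecord",
    "run_cohort",
    "records_to_frame",
    "summarize",
    "compare_strategies",
]

logger = logging.getLogger(__name__)

#: extra (non-criterion) metrics recorded per fraction, as in a clinical report
_EXTRA_METRICS = (
    ("intestine", "1cm3"),
    ("intestine", "mean"),
    ("colon", "1cm3"),
    ("colon", "mean"),
    ("bladder", "mean"),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study design: 10 patients × 5 fractions by default (50 fractions)."""

    n_patients: int = 10
    n_fractions: int = 5
    anatomy: AnatomyParams = field(default_factory=AnatomyParams)
    variation: VariationModel = field(default_factory=VariationModel)
    shift_grid: ShiftGrid = field(default_factory=ShiftGrid)
    margin: MarginSpec = field(default_factory=MarginSpec)
    prescription: Prescription = field(default_factory=Prescription)
    dose_params: DoseModelParams = field(default_factory=DoseModelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_fractions <= 0:
            raise ValueError("cohort counts must be positive")


@dataclass
class FractionRecord:
    """Per-(patient, fraction, strategy) outcome."""

    patient: int
    fraction: int
    strategy: str
    selected_ap_cm: float | None
    selected_si_cm: float | None
    out_of_library: bool | None
    gas_event: bool
    bladder_volume_ratio: float
    plan_class: str
    metrics: dict[str, float]


def _fraction_seeds(seed: int, n_patients: int, n_fractions: int) -> np.ndarray:
    """Deterministic per-(patient, fraction) seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients * n_fractions + n_patients)
    return np.array(
        [int(c.generate_state(1)[0] % (2**31)) for c in children]
    ).reshape(-1)


def run_cohort(
    config: CohortConfig | None = None, criteria: CriteriaSet | None = None
) -> list[FractionRecord]:
    """Run the full in-silico study; deterministic given the config seed."""
    config = config or CohortConfig()
    criteria = criteria or default_criteria()
    seeds = _fraction_seeds(config.seed, config.n_patients, config.n_fractions)
    patient_seeds = seeds[: config.n_patients]
    frac_seeds = seeds[config.n_patients :].reshape(
        config.n_patients, config.n_fractions
    )

    records: list[FractionRecord] = []
    for p in range(config.n_patients):
        sim = generate_simulation_anatomy(config.anatomy, seed=int(patient_seeds[p]))
        library = build_plan_library(
            sim,
            config.shift_grid,
            config.margin,
            config.prescription,
            config.dose_params,
        )
        sim_bladder_vol = sim["bladder"].volume_cm3
        for f in range(config.n_fractions):
            scenario = sample_fraction_scenario(
                sim, config.variation, seed=int(frac_seeds[p, f])
            )
            daily = scenario.daily
            ratio = daily["bladder"].volume_cm3 / sim_bladder_vol
            ctv, ptv = daily_target(daily, config.margin)
            eval_structures = {name: daily[name] for name in daily.names()}
            eval_structures["ctv"] = ctv
            eval_structures["ptv"] = ptv

            for strategy in STRATEGIES:
                dose, selection = deliver_strategy(
                    strategy, library, scenario, sim, config.dose_params
                )
                try:
                    evaluation, values = evaluate_plan(dose, eval_structures, criteria)
                except ValueError as exc:
                    raise RuntimeError(
                        f"patient {p} fraction {f} strategy {strategy}: {exc}"
                    ) from exc
                for struct, which in _EXTRA_METRICS:
                    values[f"{struct}_d{which}"] = metric_d(
                        dose, eval_structures[struct], which
                    )
                records.append(
                    FractionRecord(
                        patient=p,
                        fraction=f,
                        strategy=strategy,
                        selected_ap_cm=(
                            selection.shift.ap_cm if selection is not None else None
                        ),
                        selected_si_cm=(
                            selection.shift.si_cm if selection is not None else None
                        ),
                        out_of_library=(
                            selection.out_of_library if selection is not None else None
                        ),
                        gas_event=scenario.gas_event,
                        bladder_volume_ratio=ratio,
                        plan_class=evaluation.overall,
                        metrics=values,
                    )
                )
            logger.info(
                "patient %d fraction %d done (volume ratio %.2f)", p, f, ratio
            )
    return records


def records_to_frame(records: list[FractionRecord]) -> pd.DataFrame:
    """Flatten records into a tidy DataFrame, one row per record."""
    rows = []
    for r in records:
        row = {
            "patient": r.patient,
            "fraction": r.fraction,
            "strategy": r.strategy,
            "selected_ap_cm": r.selected_ap_cm,
            "selected_si_cm": r.selected_si_cm,
            "out_of_library": r.out_of_library,
            "gas_event": r.gas_event,
            "bladder_volume_ratio": r.bladder_volume_ratio,
            "plan_class": r.plan_class,
        }
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(records: list[FractionRecord]) -> dict[str, pd.DataFrame]:
    """Per-strategy rate table, selection frequencies, and metric median [IQR]."""
    if not records:
        raise ValueError("no records to summarize")
    df = records_to_frame(records)

    rates = (
        df.groupby("strategy")["plan_class"]
        .agg(
            per_protocol_pct=lambda s: 100.0 * (s == "per_protocol").mean(),
            acceptable_pct=lambda s: 100.0 * (s != "unacceptable").mean(),
            n="size",
        )
        .reset_index()
    )

    lorp = df[df["strategy"] == "lorp_atp"]
    sel = (
        lorp.groupby(["selected_ap_cm", "selected_si_cm"])
        .size()
        .rename("n")
        .reset_index()
    )
    sel["frequency_pct"] = 100.0 * sel["n"] / sel["n"].sum()
    sel = sel.sort_values("frequency_pct", ascending=False).reset_index(drop=True)

    metric_cols = [
        c
        for c in df.columns
        if c
        not in (
            "patient",
            "fraction",
            "strategy",
            "selected_ap_cm",
            "selected_si_cm",
            "out_of_library",
            "gas_event",
            "plan_class",
        )
    ]
    q = (
        df.groupby("strategy")[metric_cols]
        .quantile([0.25, 0.5, 0.75])
        .unstack(level=-1)
    )
    q.columns = [f"{m}_q{int(p * 100)}" for m, p in q.columns]
    metrics = q.reset_index()

    return {"rates": rates, "selection_frequencies": sel, "metrics": metrics}


def compare_strategies(
    records: list[FractionRecord],
    metric: str,
    strategies: tuple[str, str] = ("lorp_atp", "catp"),
    alpha: float = 0.05,
) -> dict:
    """Paired comparison of one metric between two strategies.

    Pairs fractions across strategies; a Shapiro–Wilk test on the paired
    differences selects the paired t-test (normal) or Wilcoxon signed-rank
    (otherwise). All-tied pairs short-circuit to p = 1 (no difference).
    Fewer than 5 pairs: the test is skipped with a warning.
    """
    df = records_to_frame(records)
    wide = df.pivot_table(
        index=["patient", "fraction"], columns="strategy", values=metric
    )
    a, b = strategies
    paired = wide[[a, b]].dropna()
    x, y = paired[a].to_numpy(), paired[b].to_numpy()
    n = len(paired)

    report = {
        "metric": metric,
        "strategies": list(strategies),
        "n_pairs": n,
        "median_iqr": {
            s: [
                float(np.median(v)),
                float(np.percentile(v, 25)),
                float(np.percentile(v, 75)),
            ]
            for s, v in ((a, x), (b, y))
        },
    }
    if n < 5:
        warnings.warn(f"only {n} pairs for '{metric}'; comparison skipped")
        report.update(test=None, p_value=None, significant=None)
        return report

    diff = x - y
    if np.allclose(diff, 0.0):
        report.update(
            test="none (identical samples)", statistic=0.0, p_value=1.0,
            normal_differences=None, significant=False,
        )
        return report

    # Shapiro-Wilk is undefined for constant input; a constant nonzero
    # difference is decidedly non-normal -> signed-rank branch
    if np.ptp(diff) == 0:
        normal = False
    else:
        normal = bool(stats.shapiro(diff).pvalue > alpha)
    if normal:
        res = stats.ttest_rel(x, y)
        test = "paired_t"
    else:
        res = stats.wilcoxon(x, y, zero_method="wilcox")
        test = "wilcoxon_signed_rank"
    report.update(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normal_differences=normal,
        significant=bool(res.pvalue < alpha),
    )
    return report
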