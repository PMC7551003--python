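"""End-to-end orchestration: bin -> score -> regress/weight -> compare.

Two analyses share the scoring machinery:

* the *extract comparison* pools all black/red whole-extract records into one
  (IF bin x experiment type) frequency table, scores it once, and runs the
  per-function non-inferiority battery on the scored records;
* the *ginsenoside activity* analysis scores each benefit category's
  single-ginsenoside records separately (the weights are defined per
  function), derives the component weights, and evaluates the Q statistic
  against each variant's composition.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .activity import (
    ProfileComparison,
    UndefinedWeightsError,
    compare_profiles,
    compute_activity_profile,
    compute_component_weights,
)
from .noninferiority import run_function_battery
from .records import (
    FUNCTIONS,
    GINSENOSIDES,
    BinSpec,
    CompositionRecord,
    EmptyStratumError,
    StudyRecord,
    load_weighted_amounts,
    tabulate_frequencies,
)
from .scaling import ScalingConfig, ScoreTable, assign_scores, solve_scoring

__all__ = [
    "extract_comparison",
    "ginsenoside_activity",
    "reference_totals",
]


def extract_comparison(
    records: Sequence[StudyRecord],
    spec: BinSpec | None = None,
    scaling: ScalingConfig | None = None,
    gamma: float = 0.8,
    alpha: float = 0.05,
    missing_if: str = "lowest",
) -> tuple[ScoreTable, pd.DataFrame]:
    """Score the pooled black/red extract corpus and run the test battery."""
    spec = spec or BinSpec()
    extracts = [r for r in records if r.subject in ("black", "red")]
    freq = tabulate_frequencies(extracts, spec, missing_if=missing_if)
    table = solve_scoring(freq, scaling)
    scored = assign_scores(extracts, table, spec, missing_if=missing_if)
    battery = run_function_battery(scored, gamma=gamma, alpha=alpha)
    return table, battery


def ginsenoside_activity(
    records: Sequence[StudyRecord],
    composition: Iterable[CompositionRecord],
    spec: BinSpec | None = None,
    scaling: ScalingConfig | None = None,
    denominator_scope: str = "function",
    normalize: bool = False,
    missing_if: str = "lowest",
) -> tuple[pd.DataFrame, dict[str, ProfileComparison], pd.DataFrame]:
    """Per-function component weights and black-vs-red Q profiles.

    Returns the long activity table (function, variant, compound incl. a
    Total row, weighted_mg_per_g), the per-function comparison objects, and a
    long weights table.  Benefit categories with no scoreable
    single-ginsenoside literature (empty stratum or zero score mass) are
    skipped rather than fatal — they are simply absent from the outputs.
    """
    spec = spec or BinSpec()
    composition = list(composition)
    singles = [r for r in records if r.subject in GINSENOSIDES]
    activity_rows: list[dict] = []
    weight_rows: list[dict] = []
    comparisons: dict[str, ProfileComparison] = {}
    for function in FUNCTIONS:
        stratum = [r for r in singles if r.function == function]
        try:
            freq = tabulate_frequencies(stratum, spec, missing_if=missing_if)
        except EmptyStratumError:
            continue
        table = solve_scoring(freq, scaling)
        scored = assign_scores(stratum, table, spec, missing_if=missing_if)
        try:
            weights = compute_component_weights(
                scored, function, denominator_scope=denominator_scope, normalize=normalize
            )
        except UndefinedWeightsError:
            continue
        for g in GINSENOSIDES:
            if weights.weights[g] > 0:
                weight_rows.append(
                    {
                        "function": function,
                        "compound": g,
                        "weight": weights.weights[g],
                        "numerator": weights.numerators[g],
                        "denominator": weights.denominator,
                    }
                )
        profiles = {
            variant: compute_activity_profile(weights, composition, variant)
            for variant in ("black", "red")
        }
        comparisons[function] = compare_profiles(profiles["black"], profiles["red"])
        for variant, profile in profiles.items():
            for g in GINSENOSIDES:
                if g in profile.contributions:
                    activity_rows.append(
                        {
                            "function": function,
                            "variant": variant,
                            "compound": g,
                            "weighted_mg_per_g": profile.contributions[g],
                        }
                    )
            activity_rows.append(
                {
                    "function": function,
                    "variant": variant,
                    "compound": "Total",
                    "weighted_mg_per_g": profile.total,
                }
            )
    return pd.DataFrame(activity_rows), comparisons, pd.DataFrame(weight_rows)


def reference_totals() -> pd.DataFrame:
    """Recompute per-(function, variant) totals from the packaged
    published weighted-amount cells, next to the printed totals.

    The computed totals sum the per-compound cells exactly; tiny differences
    from the printed totals reflect the printed table's rounding.
    """
    amounts = load_weighted_amounts()
    cells = amounts[amounts["compound"] != "Total"]
    printed = amounts[amounts["compound"] == "Total"]
    computed = (
        cells.groupby(["function", "variant"], sort=False)["weighted_mg_per_g"]
        .sum()
        .rename("computed_total")
        .reset_index()
    )
    printed = printed.rename(columns={"weighted_mg_per_g": "printed_total"})[
        ["function", "variant", "printed_total"]
    ]
    return computed.merge(printed, on=["function", "variant"], how="left")
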