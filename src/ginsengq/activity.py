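"""Literature-derived component weights and the Q activity statistic.

For one benefit category *fun*, each ginsenoside g receives a weight

    w_g = sum_{i: compound g, function fun} s_i b_i  /  sum_i s_i ,

where the numerator runs over the scored single-ginsenoside articles studying
g for that benefit and the denominator is the score sum over the denominator
scope (by default, all scored articles of that benefit category).  The
variant-level activity statistic is then the composition-weighted sum

    Q(fun, type) = sum_g w_g * M_g^type ,

with M_g^type the mean mg/g amount of g in the variant.  Q summarizes how
much literature-supported activity a variant's composition carries for one
benefit, enabling a descriptive black-vs-red comparison.

Note the weights are not normalized: a compound studied with many bioassays
can carry w_g > 1, so the "weighted amounts" w_g * M_g may exceed the raw
mg/g means.  An opt-in sum-to-one normalization is provided, and the raw
numerator/denominator provenance is kept on the result so either convention
is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import GINSENOSIDES, CompositionRecord, StudyRecord, composition_to_amounts

__all__ = [
    "UndefinedWeightsError",
    "WeightVector",
    "QProfile",
    "ProfileComparison",
    "compute_component_weights",
    "compute_activity_profile",
    "compare_profiles",
]

_TOTAL_TOL = 1e-9


class UndefinedWeightsError(ValueError):
    """The denominator score sum is zero; weights are undefined."""


@dataclass(frozen=True)
class WeightVector:
    """Per-compound literature weights for one benefit category."""

    function: str
    weights: Mapping[str, float]
    numerators: Mapping[str, float]
    denominator: float
    normalized: bool = False

    def __post_init__(self):
        for g, w in self.weights.items():
            if g not in GINSENOSIDES:
                raise ValueError(f"unknown compound {g!r}")
            if w < 0:
                raise ValueError("weights must be nonnegative")


@dataclass(frozen=True)
class QProfile:
    """Per-compound weighted amounts w_g * M_g and their total for one variant."""

    function: str
    variant: str
    contributions: Mapping[str, float]
    total: float
    missing_composition: tuple[str, ...] = ()

    def __post_init__(self):
        if abs(self.total - sum(self.contributions.values())) > _TOTAL_TOL:
            raise ValueError("total must equal the sum of per-compound entries")


@dataclass(frozen=True)
class ProfileComparison:
    """Side-by-side black/red weighted amounts for one benefit category."""

    function: str
    table: pd.DataFrame = field(repr=False)
    total_black: float
    total_red: float
    ratio: float
    dominant_black: str | None
    dominant_red: str | None


def compute_component_weights(
    records: Sequence[StudyRecord],
    function: str,
    denominator_scope: str = "function",
    normalize: bool = False,
) -> WeightVector:
    """Eq-style literature weights from scored single-ginsenoside records.

    ``denominator_scope`` chooses which scored articles the denominator score
    sum runs over: ``"function"`` (default; all single-ginsenoside articles of
    the given benefit category) or ``"global"`` (all scored single-ginsenoside
    records passed in).  Compounds with no qualifying article get weight 0.
    ``normalize=True`` rescales the weights to sum to one.
    """
    if denominator_scope not in ("function", "global"):
        raise ValueError(f"unknown denominator_scope {denominator_scope!r}")
    singles = [r for r in records if r.subject in GINSENOSIDES]
    for r in singles:
        if r.score is None:
            raise ValueError(f"record {r.record_id!r} has no score assigned")
    if denominator_scope == "function":
        scope = [r for r in singles if r.function == function]
    else:
        scope = singles
    denominator = sum(r.score for r in scope)
    if denominator <= 0:
        raise UndefinedWeightsError(
            f"zero score mass in denominator scope for {function!r}"
        )
    numerators = {g: 0.0 for g in GINSENOSIDES}
    for r in singles:
        if r.function == function:
            numerators[r.subject] += r.score * r.n_bioassays
    weights = {g: num / denominator for g, num in numerators.items()}
    if normalize:
        total = sum(weights.values())
        if total > 0:
            weights = {g: w / total for g, w in weights.items()}
    return WeightVector(
        function=function,
        weights=weights,
        numerators=numerators,
        denominator=denominator,
        normalized=normalize,
    )


def compute_activity_profile(
    weights: WeightVector,
    composition: Iterable[CompositionRecord] | Mapping[str, float],
    variant: str,
) -> QProfile:
    """Q(fun, type) = sum_g w_g * M_g for one variant's composition.

    Compounds with positive weight but no composition entry contribute 0 and
    are flagged in ``missing_composition`` (they appear as "-" cells in
    published comparison tables); zero-weight compounds are simply absent.
    """
    if isinstance(composition, Mapping):
        amounts = dict(composition)
    else:
        amounts = composition_to_amounts(composition, variant)
    contributions: dict[str, float] = {}
    missing: list[str] = []
    for g in GINSENOSIDES:
        w = weights.weights.get(g, 0.0)
        if w == 0.0:
            continue
        if g in amounts:
            contributions[g] = w * amounts[g]
        else:
            missing.append(g)
    return QProfile(
        function=weights.function,
        variant=variant,
        contributions=contributions,
        total=sum(contributions.values()),
        missing_composition=tuple(missing),
    )


def compare_profiles(profile_black: QProfile, profile_red: QProfile) -> ProfileComparison:
    """Side-by-side comparison of the two variants' weighted amounts."""
    if profile_black.function != profile_red.function:
        raise ValueError(
            f"function mismatch: {profile_black.function!r} vs {profile_red.function!r}"
        )
    compounds = [
        g for g in GINSENOSIDES
        if g in profile_black.contributions or g in profile_red.contributions
    ]
    table = pd.DataFrame(
        {
            "black": [profile_black.contributions.get(g) for g in compounds],
            "red": [profile_red.contributions.get(g) for g in compounds],
        },
        index=pd.Index(compounds, name="compound"),
    )
    ratio = (
        profile_black.total / profile_red.total if profile_red.total > 0 else float("nan")
    )

    def dominant(profile: QProfile) -> str | None:
        if not profile.contributions:
            return None
        return max(profile.contributions, key=profile.contributions.get)

    return ProfileComparison(
        function=profile_black.function,
        table=table,
        total_black=profile_black.total,
        total_red=profile_red.total,
        ratio=ratio,
        dominant_black=dominant(profile_black),
        dominant_red=dominant(profile_red),
    )
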