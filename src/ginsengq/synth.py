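"""Seeded synthetic literature corpora and composition tables.

The generator emulates the statistical structure the pipeline assumes: each
stratum (subject, benefit category) contributes a fixed number of records;
each record falls into an (IF bin, experiment type) cell drawn from a
configurable probability grid, with its continuous IF uniform within the bin;
bioassay counts are Poisson with a per-subject mean.  Composition sources are
drawn from a zero-truncated normal whose location is calibrated so the
post-truncation mean equals the configured mean (a plain truncation would
bias small-mean/large-SD compounds upward by several tenths of a mg/g).

Defaults encode the study conditions the method targets: black vs red extract
bioassay means 8 and 10 (the gamma = 0.8 non-inferiority boundary), five IF
bins with edges (1, 2, 4, 8), cell mass concentrated in low-IF in-vitro work,
and published mg/g composition summaries for the per-variant compound means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .records import (
    DEFAULT_BIN_EDGES,
    EXPERIMENT_TYPES,
    FUNCTIONS,
    BinSpec,
    CompositionRecord,
    StudyRecord,
    load_composition_summary,
    summarize_composition,
)

__all__ = [
    "CorpusConfig",
    "default_cell_probs",
    "default_strata",
    "generate_corpus",
    "generate_composition_samples",
    "generate_compositions",
]

#: Default per-subject Poisson means for bioassay counts: black at the
#: gamma = 0.8 margin of red.
DEFAULT_BIOASSAY_MEANS = {"black": 8.0, "red": 10.0}


def default_cell_probs(n_bins: int = 5) -> np.ndarray:
    """Outer-product cell probabilities over (IF bin x experiment type).

    Low-IF in-vitro studies dominate real corpora of this kind; mass decays
    with IF bin (0.30, 0.30, 0.20, 0.15, 0.05) and with the evidence level
    (0.50 in vitro, 0.35 in vivo, 0.15 human).
    """
    if_mass = np.array([0.30, 0.30, 0.20, 0.15, 0.05][:n_bins])
    if_mass = if_mass / if_mass.sum()
    type_mass = np.array([0.50, 0.35, 0.15])
    return np.outer(if_mass, type_mass)


def default_strata(n_black: int = 20, n_red: int = 20) -> dict[tuple[str, str], int]:
    """One black and one red extract stratum per benefit category."""
    strata: dict[tuple[str, str], int] = {}
    for function in FUNCTIONS:
        strata[("black", function)] = n_black
        strata[("red", function)] = n_red
    return strata


def _default_composition_params() -> dict[tuple[str, str], tuple[float, float, int]]:
    return {
        (c.variant, c.compound): (c.mean_amount, 0.0 if c.sd is None else c.sd, c.n_sources)
        for c in load_composition_summary()
    }


@dataclass(frozen=True)
class CorpusConfig:
    """Everything the generator needs, plus the master seed.

    ``strata`` maps (subject, function) to the exact number of records to
    emit.  ``cell_probs`` is the I x 3 probability grid over (IF bin,
    experiment type).  ``bioassay_means`` gives per-subject Poisson means,
    with ``default_bioassay_mean`` as the fallback for unlisted subjects.
    ``composition`` maps (variant, compound) to (mean mg/g, SD, n_sources).
    """

    strata: Mapping[tuple[str, str], int] = field(default_factory=default_strata)
    cell_probs: np.ndarray = field(default_factory=default_cell_probs)
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    top_if: float = 16.0
    bioassay_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOASSAY_MEANS)
    )
    default_bioassay_mean: float = 9.0
    composition: Mapping[tuple[str, str], tuple[float, float, int]] = field(
        default_factory=_default_composition_params
    )
    seed: int = 0

    def __post_init__(self):
        probs = np.asarray(self.cell_probs, dtype=float)
        spec = BinSpec(self.bin_edges)
        if probs.shape != (spec.n_bins, len(EXPERIMENT_TYPES)):
            raise ValueError(
                f"cell_probs must be {spec.n_bins} x {len(EXPERIMENT_TYPES)}, "
                f"got {probs.shape}"
            )
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-8):
            raise ValueError("cell_probs must be nonnegative and sum to 1")
        if any(m < 0 for m in self.bioassay_means.values()) or self.default_bioassay_mean < 0:
            raise ValueError("Poisson means must be nonnegative")
        if self.top_if <= self.bin_edges[-1]:
            raise ValueError("top_if must exceed the last bin edge")
        object.__setattr__(self, "cell_probs", probs)

    @property
    def bin_spec(self) -> BinSpec:
        return BinSpec(self.bin_edges)


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_corpus(config: CorpusConfig) -> list[StudyRecord]:
    """Draw a corpus with exactly the configured record count per stratum.

    Deterministic given the seed; the corpus and composition streams are
    fanned out from the master seed independently, so corpora are unaffected
    by whether compositions are also drawn.
    """
    rng, _ = _streams(config.seed, 2)
    flat_probs = config.cell_probs.ravel()
    n_cells = flat_probs.size
    lows = np.array([0.0] + list(config.bin_edges))
    highs = np.array(list(config.bin_edges) + [config.top_if])

    records: list[StudyRecord] = []
    counter = 0
    for (subject, function), n_records in sorted(config.strata.items()):
        if function not in FUNCTIONS:
            raise ValueError(f"unknown function {function!r} in strata")
        mean_b = config.bioassay_means.get(subject, config.default_bioassay_mean)
        cells = rng.choice(n_cells, size=n_records, p=flat_probs)
        i_bin, j_type = np.unravel_index(cells, config.cell_probs.shape)
        ifs = rng.uniform(lows[i_bin], highs[i_bin])
        counts = rng.poisson(mean_b, size=n_records)
        for k in range(n_records):
            counter += 1
            records.append(
                StudyRecord(
                    record_id=f"SYN{counter:05d}",
                    subject=subject,
                    function=function,
                    experiment_type=EXPERIMENT_TYPES[j_type[k]],
                    n_bioassays=int(counts[k]),
                    impact_factor=float(ifs[k]),
                )
            )
    return records


def _calibrated_truncnorm(mean: float, sd: float):
    """Zero-truncated normal whose post-truncation mean equals ``mean``.

    Solves for the location parameter by root finding; the returned frozen
    distribution has support [0, inf).
    """

    def trunc_mean(loc):
        a = (0.0 - loc) / sd
        return stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd)

    lo, hi = mean - 10 * sd, mean + sd
    loc = optimize.brentq(lambda m: trunc_mean(m) - mean, lo, hi, xtol=1e-10)
    return stats.truncnorm(a=(0.0 - loc) / sd, b=np.inf, loc=loc, scale=sd)


def generate_composition_samples(
    config: CorpusConfig,
    n_sources: Mapping[tuple[str, str], int] | int | None = None,
) -> list[tuple[str, str, float]]:
    """Per-source (variant, compound, mg/g) draws for every configured pair.

    ``n_sources`` overrides the configured per-pair source counts (an int
    applies to all pairs).  SD 0 yields constant draws at the mean; all
    outputs are nonnegative by construction.
    """
    _, rng = _streams(config.seed, 2)
    samples: list[tuple[str, str, float]] = []
    for (variant, compound), (mean, sd, n_cfg) in sorted(config.composition.items()):
        if mean < 0 or sd < 0 or n_cfg < 1:
            raise ValueError(f"invalid composition parameters for {(variant, compound)}")
        if isinstance(n_sources, int):
            n = n_sources
        elif n_sources is not None:
            n = n_sources.get((variant, compound), n_cfg)
        else:
            n = n_cfg
        if sd == 0.0 or mean == 0.0:
            draws = np.full(n, mean)
        else:
            dist = _calibrated_truncnorm(mean, sd)
            draws = dist.rvs(size=n, random_state=rng)
        samples.extend((variant, compound, float(x)) for x in draws)
    return samples


def generate_compositions(
    config: CorpusConfig,
    n_sources: Mapping[tuple[str, str], int] | int | None = None,
) -> list[CompositionRecord]:
    """Draw per-source amounts and summarize them into composition records."""
    return summarize_composition(generate_composition_samples(config, n_sources))
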