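"""Permutation null models for trait-based community assembly.

Two models, one per trait class:

* **FTS null** (establishment traits): the observed statistic is the
  hypervolume volume of a stage's (LA, SLA, LDMC) records; each of the
  ``n_sims`` simulations resamples the same number of whole individual
  trait triplets from the pooled records of all stages (triplets kept
  intact, preserving inter-trait correlation) and rebuilds the hypervolume
  under the shared standardization.
* **MFD null** (regenerative traits): the observed statistic is a plot's
  mean pairwise Gower distance; each simulation draws the plot's richness
  S species without replacement from the pooled species list (richness-only
  sampling — abundance plays no role in the null).

Both models are compared through the permutation effect size

    P  = (#{sim < obs} + 0.5 #{sim = obs}) / n_sims,
    ES = 2 (P - 0.5)  in [-1, 1],

with ES <= -threshold read as trait convergence (environmental filtering
for establishment traits, dispersal limitation for regenerative traits),
ES >= +threshold as divergence (competition / limiting similarity, or
environmental heterogeneity), and |ES| < threshold as stochastic/neutral
assembly. The plain proportion over n_sims (no +1 correction) lets ES
reach exactly +/-1. The default significance threshold |ES| >= 0.95
corresponds to a two-sided permutation test at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_rng, child_seed
from .data import CommunityMatrix, DistanceMatrix, LeafRecordSet, TraitTable
from .distance import gower_distance, mfd
from .errors import DegenerateInputError, ValidationError
from .hypervolume import (
    HypervolumeSettings,
    build_hypervolume,
    fit_standardization,
)

logger = logging.getLogger("traitassembly")

DEFAULT_ES_THRESHOLD = 0.95

_INTERPRETATION = {
    ("establishment", "convergent"): "environmental filtering",
    ("regenerative", "convergent"): "dispersal limitation",
    ("establishment", "divergent"): "competition / limiting similarity (or environmental heterogeneity)",
    ("regenerative", "divergent"): "competition / limiting similarity (or environmental heterogeneity)",
    ("establishment", "neutral"): "stochastic/neutral",
    ("regenerative", "neutral"): "stochastic/neutral",
}


def effect_size(observed: float, simulated) -> tuple[float, float]:
    """Tie-corrected permutation P and effect size ES = 2(P - 0.5).

    Ties are counted with exact floating-point equality: the statistics
    are deterministic functions of the resample, so equal values are
    genuinely tied realizations.
    """
    sims = np.asarray(simulated, float)
    if sims.size == 0:
        raise ValidationError("empty simulated distribution")
    if not np.isfinite(sims).all() or not np.isfinite(observed):
        raise ValidationError("non-finite statistic in effect size")
    below = (sims < observed).sum()
    ties = (sims == observed).sum()
    p = (below + 0.5 * ties) / sims.size
    return float(p), float(2.0 * (p - 0.5))


@dataclass
class NullModelResult:
    """Observed statistic vs its null distribution for one unit."""

    statistic_name: str  # "FTS_volume" or "MFD"
    trait_class: str     # "establishment" or "regenerative"
    unit: str            # stage label or plot id
    stage: int
    observed: float
    simulated: np.ndarray
    n_sims: int
    P: float
    ES: float
    seed: int
    threshold: float = DEFAULT_ES_THRESHOLD

    @property
    def direction(self) -> str:
        if self.ES <= -self.threshold:
            return "convergent"
        if self.ES >= self.threshold:
            return "divergent"
        return "neutral"

    @property
    def interpretation(self) -> str:
        return _INTERPRETATION[(self.trait_class, self.direction)]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "statistic": self.statistic_name,
                    "trait_class": self.trait_class,
                    "unit": self.unit,
                    "stage": self.stage,
                    "observed": self.observed,
                    "null_mean": float(self.simulated.mean()),
                    "null_sd": float(self.simulated.std(ddof=1)) if self.n_sims > 1 else np.nan,
                    "n_sims": self.n_sims,
                    "P": self.P,
                    "ES": self.ES,
                    "interpretation": self.interpretation,
                }
            ]
        )


class FTSNullModel:
    """Null model for a stage's establishment-trait functional trait space.

    Parameters
    ----------
    leaf
        Pooled individual leaf records across all stages; the pool the
        null resamples and the reference set of the shared z-scoring.
    stage
        The stage whose observed hypervolume volume is tested.
    settings
        Hypervolume settings shared by the observed and every simulated
        volume (identical Monte Carlo effort keeps the rank comparison
        fair). Defaults to 2000 MC samples per estimate — volume *ranks*
        need far fewer samples than absolute volumes.
    replace
        Resample triplets with replacement. Default (None) resamples
        without replacement whenever the pool is large enough, preserving
        the observed individuals' multiplicities; the fallback to
        with-replacement is logged.
    """

    statistic_name = "FTS_volume"
    trait_class = "establishment"

    def __init__(
        self,
        leaf: LeafRecordSet,
        stage: int,
        settings: HypervolumeSettings | None = None,
        replace: bool | None = None,
    ) -> None:
        self.leaf = leaf
        self.stage = int(stage)
        self.settings = settings or HypervolumeSettings(n_samples=2000)
        self.replace = replace
        self.standardization = fit_standardization(leaf)
        self._pool = self.standardization.transform(leaf.triplets())
        self._obs_points = self.standardization.transform(leaf.for_stage(self.stage))
        if len(self._obs_points) < self._pool.shape[1] + 1:
            raise DegenerateInputError(
                f"stage {stage} has {len(self._obs_points)} records; "
                f"need at least {self._pool.shape[1] + 1}"
            )

    def fit(self, n_sims: int = 999, seed: int = 0) -> NullModelResult:
        n_s = len(self._obs_points)
        pool_n = len(self._pool)
        replace = self.replace
        if replace is None:
            replace = pool_n < n_s
            if replace:
                logger.info("pool (%d) smaller than stage sample (%d): "
                            "resampling with replacement", pool_n, n_s)
        elif not replace and pool_n < n_s:
            raise ValidationError(
                f"pool of {pool_n} records cannot supply {n_s} without replacement"
            )

        observed = build_hypervolume(
            self._obs_points, self.settings, seed=child_seed(seed, "obs")
        ).volume
        rng = child_rng(seed, "fts-null", self.stage)
        sims = np.empty(n_sims)
        for k in range(n_sims):
            idx = rng.choice(pool_n, size=n_s, replace=replace)
            sims[k] = build_hypervolume(
                self._pool[idx], self.settings, seed=child_seed(seed, "sim", k)
            ).volume
        p, es = effect_size(observed, sims)
        return NullModelResult(
            statistic_name=self.statistic_name, trait_class=self.trait_class,
            unit=f"stage{self.stage}", stage=self.stage, observed=observed,
            simulated=sims, n_sims=n_sims, P=p, ES=es, seed=seed,
        )


class MFDNullModel:
    """Null model for a plot's regenerative-trait mean pairwise distance.

    The species pool is every species observed in the community matrix
    (all stages); the Gower matrix over that pool may be passed
    pre-computed and is otherwise derived from ``traits``.
    """

    statistic_name = "MFD"
    trait_class = "regenerative"

    def __init__(
        self,
        community: CommunityMatrix,
        traits: TraitTable | None,
        plot_id: str,
        distances: DistanceMatrix | None = None,
    ) -> None:
        if distances is None:
            if traits is None:
                raise ValidationError("provide either a trait table or a distance matrix")
            distances = gower_distance(traits)
        self.community = community
        self.distances = distances
        self.plot_id = plot_id
        self.stage = community.stage_of(plot_id)
        self.pool = [s for s in community.species if s in set(distances.labels)]
        missing = set(community.species) - set(distances.labels)
        if missing:
            raise ValidationError(f"species without trait distances: {sorted(missing)[:5]}")
        self._species = community.species_in_plot(plot_id)
        if len(self._species) < 2:
            raise DegenerateInputError(f"plot {plot_id} has a single species")
        if len(self._species) > len(self.pool):
            raise ValidationError("plot richness exceeds species pool size")

    def fit(self, n_sims: int = 999, seed: int = 0) -> NullModelResult:
        S = len(self._species)
        observed = mfd(self._species, self.distances, "presence", plot_id=self.plot_id).mfd
        rng = child_rng(seed, "mfd-null", self.plot_id)
        pool = np.array(self.pool)
        sims = np.empty(n_sims)
        for k in range(n_sims):
            draw = rng.choice(pool, size=S, replace=False)
            sims[k] = mfd(list(draw), self.distances, "presence").mfd
        p, es = effect_size(observed, sims)
        return NullModelResult(
            statistic_name=self.statistic_name, trait_class=self.trait_class,
            unit=self.plot_id, stage=self.stage, observed=observed,
            simulated=sims, n_sims=n_sims, P=p, ES=es, seed=seed,
        )


def summarize_null_results(
    results: list[NullModelResult],
    threshold: float = DEFAULT_ES_THRESHOLD,
) -> pd.DataFrame:
    """Stage x trait-class ES table with assembly-process labels.

    Plot-level results (MFD nulls) are aggregated to their stage by the
    mean ES across plots; the label is re-derived from the aggregate.
    Emits one row per (stage, trait class): observed/simulated means, ES
    and interpretation — the layout of a stage-by-trait-class ES table.
    """
    if not results:
        raise ValidationError("no null-model results to summarize")
    rows = []
    frame = pd.concat([r.summary() for r in results], ignore_index=True)
    for (stage, tclass), grp in frame.groupby(["stage", "trait_class"]):
        es = float(grp["ES"].mean())
        if es <= -threshold:
            direction = "convergent"
        elif es >= threshold:
            direction = "divergent"
        else:
            direction = "neutral"
        rows.append(
            {
                "stage": int(stage),
                "trait_class": tclass,
                "statistic": grp["statistic"].iloc[0],
                "n_units": len(grp),
                "observed_mean": float(grp["observed"].mean()),
                "ES": es,
                "direction": direction,
                "interpretation": _INTERPRETATION[(tclass, direction)],
            }
        )
    out = pd.DataFrame(rows).sort_values(["trait_class", "stage"]).reset_index(drop=True)
    return out


def es_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot the summary to the compact trait-class x stage ES layout."""
    wide = summary.pivot(index="trait_class", columns="stage", values="ES")
    wide.index = [f"ES_{c}_traits" for c in wide.index]
    wide.columns = [f"stage{int(s)}" for s in wide.columns]
    return wide.reset_index(names="statistic")
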