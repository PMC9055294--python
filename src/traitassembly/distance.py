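"""Mixed-type Gower distances, mean pairwise functional distance (MFD),
per-trait functional diversity, and tree-based trait imputation.

Gower's coefficient scales each trait difference by the trait's observed
range, so continuous and ordinal traits combine on a common [0, 1] scale.
Ordinal traits (longevity classes, months) are compared on their integer
codes. Missing cells are handled by pairwise deletion with weight
renormalization: a pair's distance averages only the traits observed in
both species.

MFD is the mean Gower distance over all unordered species pairs present in
a plot — presence-weighted by default, abundance-weighted optionally with
weights p_i p_j on each pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .data import CommunityMatrix, DistanceMatrix, TraitTable
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger("traitassembly")


@dataclass
class GowerSpec:
    """Per-trait scaling specification for the Gower distance.

    ``ranges`` are the denominators of the per-trait differences. They are
    computed on a declared reference set (by default the pooled species set
    of all stages, so distances are commensurable across stages). Traits
    with zero range carry no information and are dropped with a warning.
    """

    kinds: dict[str, str]
    ranges: dict[str, float]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weights:
            self.weights = {t: 1.0 for t in self.kinds}
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("Gower weights must be non-negative")
        if sum(self.weights.values()) == 0:
            raise ValidationError("all Gower weights are zero")
        degenerate = [t for t, r in self.ranges.items() if not r > 0]
        if len(degenerate) == len(self.ranges):
            # every trait constant: all species identical on these traits,
            # so all distances are 0 (range 1 makes the deltas vanish)
            logger.warning("all traits have zero range; distances are all zero")
            self.ranges = {t: 1.0 for t in self.ranges}
            return
        for t in degenerate:
            logger.warning("trait %s has zero range; dropped from Gower distance", t)
            self.kinds.pop(t, None)
            self.ranges.pop(t, None)
            self.weights.pop(t, None)

    @classmethod
    def from_table(cls, table: TraitTable, weights: dict[str, float] | None = None) -> "GowerSpec":
        kinds = table.kinds()
        ranges = {}
        for t in table.values.columns:
            col = table.values[t].dropna()
            ranges[t] = float(col.max() - col.min()) if len(col) else 0.0
        return cls(kinds=kinds, ranges=ranges, weights=weights or {})


def gower_distance(traits: TraitTable, spec: GowerSpec | None = None) -> DistanceMatrix:
    """Gower distance matrix over the species of ``traits``.

    d(i,j) = sum_t w_t |x_it - x_jt| / range_t / sum_t w_t, the sums running
    over traits observed in both species. A pair sharing no observed trait
    is an error (the distance would be undefined).
    """
    if len(traits.species) < 2:
        raise DegenerateInputError("Gower distance needs at least two species")
    spec = spec or GowerSpec.from_table(traits)
    cols = [t for t in traits.values.columns if t in spec.kinds]
    X = traits.values[cols].to_numpy(float)
    w = np.array([spec.weights[t] for t in cols])
    rng_ = np.array([spec.ranges[t] for t in cols])
    obs = ~np.isnan(X)

    n = X.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for k in range(len(cols)):
        x = X[:, k]
        m = obs[:, k]
        pair_obs = np.outer(m, m)
        delta = np.abs(np.subtract.outer(x, x)) / rng_[k]
        delta = np.where(pair_obs, np.nan_to_num(delta), 0.0)
        num += w[k] * delta
        den += w[k] * pair_obs

    bad = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))
    if len(bad):
        i, j = bad[0]
        raise ValidationError(
            f"species pair ({traits.species[i]}, {traits.species[j]}) shares no observed trait"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den == 0, 1.0, den), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(traits.species), d)


@dataclass
class MFDValue:
    plot_id: str
    mfd: float
    weighting: str


def mfd(
    species: list[str],
    distances: DistanceMatrix,
    weighting: str = "presence",
    abundances: dict[str, float] | None = None,
    plot_id: str = "",
) -> MFDValue:
    """Mean pairwise functional distance of one community.

    ``presence`` mode averages d(i,j) over unordered distinct pairs;
    ``abundance`` mode weights each pair by p_i p_j. Undefined (error) for
    fewer than two species.
    """
    if len(set(species)) < 2:
        raise DegenerateInputError(f"MFD undefined for single-species plot {plot_id!r}")
    sub = distances.sub(list(species))
    n = len(species)
    iu = np.triu_indices(n, k=1)
    if weighting == "presence":
        value = float(sub.d[iu].mean())
    elif weighting == "abundance":
        if abundances is None:
            raise ValidationError("abundance weighting requires abundances")
        p = np.array([abundances[s] for s in species], float)
        p = p / p.sum()
        wts = np.outer(p, p)[iu]
        value = float((sub.d[iu] * wts).sum() / wts.sum())
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    return MFDValue(plot_id=plot_id, mfd=value, weighting=weighting)


def mfd_table(
    community: CommunityMatrix,
    distances: DistanceMatrix,
    weighting: str = "presence",
) -> pd.DataFrame:
    """Per-plot MFD over all plots of a community matrix."""
    rows = []
    for plot in community.plots:
        sp = community.species_in_plot(plot)
        ab = community.abundance.loc[plot, sp].to_dict()
        val = mfd(sp, distances, weighting=weighting, abundances=ab, plot_id=plot)
        rows.append({"plot_id": plot, "stage": community.stage_of(plot),
                     "mfd": val.mfd, "weighting": weighting})
    return pd.DataFrame(rows)


def fd_per_trait(
    traits: TraitTable,
    community: CommunityMatrix,
    weighting: str = "presence",
) -> pd.DataFrame:
    """Per-plot functional diversity of each trait separately.

    FD of one trait is the mean pairwise single-trait Gower distance
    (|Δx| / pooled range) between the species of a plot.
    """
    out = []
    for trait in traits.values.columns:
        single = TraitTable(traits.values[[trait]], {trait: traits.schema[trait]})
        dm = gower_distance(single)
        for plot in community.plots:
            sp = [s for s in community.species_in_plot(plot) if s in dm.labels]
            ab = community.abundance.loc[plot, sp].to_dict()
            val = mfd(sp, dm, weighting=weighting, abundances=ab, plot_id=plot)
            out.append({"plot_id": plot, "stage": community.stage_of(plot),
                        "trait": trait, "fd": val.mfd})
    return pd.DataFrame(out)


def impute_traits(
    traits: TraitTable,
    seed: int = 0,
    min_samples_leaf: int = 5,
) -> TraitTable:
    """Fill missing trait cells with recursive-partitioning regression trees.

    One tree per target trait, the remaining traits as predictors (trees
    route missing predictor values through the split learned at training
    time). Strictly positive continuous targets are fitted on the log
    scale (their errors are multiplicative) and back-transformed; ordinal
    predictions are rounded to the nearest valid class. Deterministic
    given ``seed``.
    """
    df = traits.values.copy()
    frac = df.isna().mean()
    if (frac >= 0.5).any():
        bad = list(frac.index[frac >= 0.5])
        raise ValidationError(f"traits missing >= 50%: {bad}")
    if (frac == 1.0).any():
        raise ValidationError("trait with all values missing")
    if not df.isna().any().any():
        return TraitTable(df, dict(traits.schema))

    for trait in df.columns:
        target_missing = traits.values[trait].isna()
        if not target_missing.any():
            continue
        predictors = [c for c in df.columns if c != trait]
        X = traits.values[predictors].to_numpy(float)
        y = traits.values[trait].to_numpy(float)
        fit_rows = ~np.isnan(y)
        kind, domain = traits.schema[trait]
        log_target = kind == "continuous" and np.nanmin(y) > 0
        if log_target:
            y = np.log(y)
        tree = DecisionTreeRegressor(min_samples_leaf=min_samples_leaf, random_state=seed)
        tree.fit(X[fit_rows], y[fit_rows])
        pred = tree.predict(X[target_missing.to_numpy()])
        if log_target:
            pred = np.exp(pred)
        if kind == "ordinal" and domain is not None:
            pred = np.clip(np.round(pred), domain[0], domain[1])
        df.loc[target_missing, trait] = pred
    return TraitTable(df, dict(traits.schema))
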