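"""Synthetic successional chronosequence generator.

Emulates a four-stage post-mining chronosequence (three plots per stage)
with known ground truth: a regional species pool with correlated leaf
traits and mixed regenerative traits, stage communities assembled under a
declared regime per trait class (``neutral``, ``filtering``,
``limiting_similarity``), individual leaf records following the abundance
>= 5 / six-individuals sampling rule, a soil gradient in which available
Cr and Cu decline with stage, and missing regenerative-trait cells
injected completely at random (default rate 14.3%).

Regimes invert the inference logic the analysis applies downstream:
``filtering`` admits species with probability proportional to a Gaussian
kernel around a stage optimum on the focal trait (trait convergence);
``limiting_similarity`` greedily rejects candidates within an exclusion
radius in Gower space (trait over-dispersion); ``neutral`` samples the
pool uniformly. The regime actually used is recorded in ``truth`` so
recovery tests can compare the analysis output against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import logser

from ._seeds import child_rng
from .data import (
    CommunityMatrix,
    LeafRecordSet,
    REGENERATIVE_SCHEMA,
    SoilTable,
    TraitTable,
)
from .distance import GowerSpec, gower_distance
from .errors import DegenerateInputError, ValidationError

_ESTABLISHMENT_SCHEMA = {
    "la": ("continuous", None),
    "sla": ("continuous", None),
    "ldmc": ("continuous", None),
}

#: Latent trait scales: (log-/logit-scale mean, scale) per establishment axis.
_LEAF_LATENT = {
    "la": (np.log(800.0), 1.0),      # mm^2, log-normal
    "sla": (np.log(15000.0), 0.45),  # mm^2/g, log-normal
    "ldmc": (logit(0.30), 0.6),      # fraction, logit-normal
}

#: Stage-mean soil profiles. Available Cr/Cu decline with stage; moisture,
#: ORP and TN peak by stage 3; the C:N ratio rises from stage 1 to 3.
_SOIL_STAGE_MEANS = {
    "total_cr": (180.0, 175.0, 170.0, 165.0),
    "total_cd": (12.0, 11.5, 11.0, 11.0),
    "total_cu": (900.0, 850.0, 643.75, 700.0),
    "total_ni": (55.0, 54.0, 52.0, 52.0),
    "total_pb": (950.0, 930.0, 900.0, 880.0),
    "total_zn": (1400.0, 1350.0, 1300.0, 1280.0),
    "total_sn": (900.0, 880.0, 800.0, 643.333),
    "avail_cr": (0.415, 0.26, 0.16, 0.10),
    "avail_cd": (0.85, 0.75, 0.65, 0.60),
    "avail_cu": (44.405, 30.0, 20.0, 14.0),
    "avail_pb": (6.0, 5.2, 4.6, 4.2),
    "ph": (6.5, 6.6, 6.8, 6.9),
    "ec": (150.0, 142.0, 133.0, 130.0),
    "orp": (210.0, 235.0, 292.333, 270.0),
    "moisture": (12.0, 18.0, 28.222, 24.0),
    "temperature": (15.0, 15.0, 14.5, 14.5),
    "tn": (0.4, 0.7, 1.6, 1.2),
    "tc": (4.0, 9.0, 28.0, 20.0),
    "tp": (0.5, 0.6, 0.7, 0.7),
    "tk": (12.0, 12.0, 13.0, 13.0),
}


def _default_est_regimes() -> dict[int, str]:
    return {1: "filtering", 2: "filtering", 3: "filtering", 4: "neutral"}


def _default_reg_regimes() -> dict[int, str]:
    return {1: "filtering", 2: "limiting_similarity",
            3: "filtering", 4: "limiting_similarity"}


def _default_filter_strength() -> dict[int, float]:
    # establishment-filter sigma per stage: strong early, weak later
    return {1: 0.20, 2: 0.35, 3: 0.60, 4: 0.85}


def _default_filter_optimum() -> dict[int, float]:
    # focal-trait optimum (standardized scale) drifts along succession
    return {1: -1.2, 2: -0.4, 3: 0.4, 4: 1.0}


@dataclass
class AssemblyConfig:
    """Parameters of the synthetic chronosequence.

    Defaults emulate the four-stage study design: 4 stages x 3 plots,
    stage richness 12/13/17/19, ~14.3% missing regenerative cells, and
    assembly regimes that move from strong establishment filtering toward
    neutrality while regenerative traits alternate between convergence and
    over-dispersion.
    """

    n_stages: int = 4
    plots_per_stage: int = 3
    pool_size: int = 40
    richness_by_stage: tuple[int, ...] = (12, 13, 17, 19)
    regime_establishment: str | dict[int, str] = field(default_factory=_default_est_regimes)
    regime_regenerative: str | dict[int, str] = field(default_factory=_default_reg_regimes)
    filter_strength: float | dict[int, float] = field(default_factory=_default_filter_strength)
    filter_optimum: float | dict[int, float] = field(default_factory=_default_filter_optimum)
    regen_filter_strength: float = 0.06
    exclusion_radius: float | dict[int, float] = field(
        default_factory=lambda: {1: 0.06, 2: 0.11, 3: 0.06, 4: 0.07})
    focal_trait: str = "sla"
    trait_correlation: float = 0.5
    logseries_p: float = 0.95
    occupancy_by_stage: tuple[float, ...] = (0.60, 0.70, 0.80, 0.85)
    noise_cv: float = 0.18
    soil_cv: float = 0.10
    missing_rate: float = 0.143
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.richness_by_stage) != self.n_stages:
            raise ValidationError("richness_by_stage length must equal n_stages")
        if any(r > self.pool_size for r in self.richness_by_stage):
            raise ValidationError("stage richness cannot exceed pool size")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must lie in [0, 1)")
        radii = (self.exclusion_radius.values()
                 if isinstance(self.exclusion_radius, dict) else [self.exclusion_radius])
        if any(not (0 <= r < 1) for r in radii):
            raise ValidationError("exclusion_radius must lie in [0, 1)")
        strengths = (self.filter_strength.values()
                     if isinstance(self.filter_strength, dict) else [self.filter_strength])
        if any(not s > 0 for s in strengths):
            raise ValidationError("filter_strength must be positive")


def _per_stage(value, stage: int, default):
    if isinstance(value, dict):
        return value.get(stage, default)
    return value


@dataclass
class SyntheticDataset:
    """A generated dataset plus the ground truth that produced it."""

    community: CommunityMatrix
    leaf: LeafRecordSet
    traits: TraitTable
    soil: SoilTable
    truth: dict
    traits_complete: TraitTable


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------

def make_species_pool(config: AssemblyConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the regional species pool with latent trait values.

    Establishment traits are correlated on their transformed scales
    (log LA, log SLA, logit LDMC) with SLA--LDMC negatively coupled;
    regenerative traits are drawn on the declared ordinal/continuous
    domains. ``z_focal`` is the standardized focal establishment trait the
    filtering regime acts on.
    """
    rng = rng if rng is not None else child_rng(config.seed, "pool")
    n = config.pool_size
    r = config.trait_correlation
    corr = np.array([[1.0, r, -r], [r, 1.0, -r], [-r, -r, 1.0]])
    z = rng.multivariate_normal(np.zeros(3), corr, size=n, method="cholesky")
    la = np.exp(_LEAF_LATENT["la"][0] + _LEAF_LATENT["la"][1] * z[:, 0])
    sla = np.exp(_LEAF_LATENT["sla"][0] + _LEAF_LATENT["sla"][1] * z[:, 1])
    ldmc = expit(_LEAF_LATENT["ldmc"][0] + _LEAF_LATENT["ldmc"][1] * z[:, 2])

    # regenerative traits share a latent life-history "pace" factor u:
    # slow/persistent species carry heavier seeds, longer life spans and
    # longer reproductive periods — the cross-trait structure that makes
    # trait imputation from covarying traits meaningful
    u = rng.standard_normal(n)
    seed_mass = np.exp(np.log(2.0) + 1.5 * (0.7 * u + 0.714 * rng.standard_normal(n)))
    lat_longev = 0.9 * u + 0.436 * rng.standard_normal(n)
    # thresholds chosen so marginal class frequencies are (.25, .15, .35, .25)
    from scipy.stats import norm

    cuts = norm.ppf([0.25, 0.40, 0.75])
    longevity = 1 + (lat_longev[:, None] > cuts[None, :]).sum(axis=1)
    flowering = np.clip(np.round(5.0 + 2.5 * (0.6 * u + 0.8 * rng.standard_normal(n))), 1, 12)
    fruiting = np.clip(np.round(flowering + rng.normal(-1.0, 1.2, n)), 1, 12)
    # first flowering month tracks the pace factor too (slow species start
    # late). The clonal code 0 is tied to the perennial-clonal longevity
    # class (the two codings are coupled by definition); ~3% of the
    # remaining species flower year-round (code 13).
    fmf = np.clip(np.round(4.0 + 2.0 * (0.7 * u + 0.714 * rng.standard_normal(n))), 1, 12)
    special = rng.random(n)
    fmf = np.where(longevity == 4, 0.0, np.where(special > 0.97, 13.0, fmf))

    focal_idx = {"la": 0, "sla": 1, "ldmc": 2}[config.focal_trait]
    pool = pd.DataFrame(
        {
            "la": la, "sla": sla, "ldmc": ldmc,
            "seed_mass": seed_mass, "longevity": longevity.astype(float),
            "flowering_period": flowering, "fruiting_period": fruiting,
            "fmf": fmf.astype(float),
            "z_focal": z[:, focal_idx],
        },
        index=[f"sp{i:02d}" for i in range(1, n + 1)],
    )
    pool.index.name = "species"
    return pool


def pool_trait_table(pool: pd.DataFrame) -> TraitTable:
    """Regenerative TraitTable view of a species pool."""
    return TraitTable(pool[list(REGENERATIVE_SCHEMA)].copy(), dict(REGENERATIVE_SCHEMA))


def _establishment_table(pool: pd.DataFrame) -> TraitTable:
    return TraitTable(pool[["la", "sla", "ldmc"]].copy(), dict(_ESTABLISHMENT_SCHEMA))


# ---------------------------------------------------------------------------
# stage assembly
# ---------------------------------------------------------------------------

def select_stage_species(
    pool: pd.DataFrame,
    stage: int,
    config: AssemblyConfig,
    rng: np.random.Generator,
    regen_dm: np.ndarray | None = None,
    est_dm: np.ndarray | None = None,
) -> list[str]:
    """Choose the stage species set under the declared regimes.

    Admission is greedy-sequential: candidate log-weights come from the
    establishment regime (Gaussian filter on the focal trait, or flat),
    multiplied under regenerative filtering by a Gaussian kernel on Gower
    distance to a focal species; limiting-similarity regimes veto any
    candidate within the exclusion radius of an admitted species.
    """
    k = config.richness_by_stage[stage - 1]
    n = len(pool)
    reg_est = _per_stage(config.regime_establishment, stage, "neutral")
    reg_reg = _per_stage(config.regime_regenerative, stage, "neutral")

    logw = np.zeros(n)
    if reg_est == "filtering":
        sigma = _per_stage(config.filter_strength, stage, 0.25)
        zopt = _per_stage(config.filter_optimum, stage, 0.0)
        logw = -((pool["z_focal"].to_numpy() - zopt) ** 2) / (2.0 * sigma**2)
    if reg_reg == "filtering":
        if regen_dm is None:
            regen_dm = gower_distance(pool_trait_table(pool)).d
        focal = int(np.argmax(logw + rng.gumbel(size=n)))  # weight-biased focal draw
        logw = logw - regen_dm[focal] ** 2 / (2.0 * config.regen_filter_strength**2)

    constraints: list[np.ndarray] = []
    if reg_est == "limiting_similarity":
        if est_dm is None:
            est_dm = gower_distance(_establishment_table(pool)).d
        constraints.append(est_dm)
    if reg_reg == "limiting_similarity":
        if regen_dm is None:
            regen_dm = gower_distance(pool_trait_table(pool)).d
        constraints.append(regen_dm)

    radius = _per_stage(config.exclusion_radius, stage, 0.10)
    for _attempt in range(30):
        admitted = _greedy_admission(n, k, logw, constraints, radius, rng)
        if admitted is not None:
            return [pool.index[i] for i in admitted]
    raise DegenerateInputError(
        f"limiting similarity cannot reach richness {k} at stage {stage}; "
        f"reduce exclusion_radius (currently {radius})"
    )


def _greedy_admission(
    n: int,
    k: int,
    logw: np.ndarray,
    constraints: list[np.ndarray],
    radius: float,
    rng: np.random.Generator,
) -> list[int] | None:
    """One sequential-admission attempt; None if it dead-ends before k.

    Under limiting similarity, feasible candidates are additionally
    weighted by their distance to the nearest admitted species (soft
    farthest-first), which both packs the pool efficiently and sharpens
    the over-dispersion signal the regime is meant to create.
    """
    admitted: list[int] = []
    available = np.ones(n, dtype=bool)
    while len(admitted) < k:
        feasible = available.copy()
        for dm in constraints:
            for a in admitted:
                feasible &= dm[a] >= radius
        idx = np.where(feasible)[0]
        if len(idx) == 0:
            return None
        lw = logw[idx].copy()
        if constraints and admitted:
            mind = np.minimum.reduce([dm[np.ix_(admitted, idx)].min(axis=0)
                                      for dm in constraints])
            lw = lw + 2.0 * np.log(mind + 1e-9)
        lw -= lw.max()
        p = np.exp(lw)
        choice = int(idx[rng.choice(len(idx), p=p / p.sum())])
        admitted.append(choice)
        available[choice] = False
    return admitted


def assemble_stage(
    pool: pd.DataFrame,
    stage: int,
    config: AssemblyConfig,
    rng: np.random.Generator,
    regen_dm: np.ndarray | None = None,
    est_dm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble one stage: plots x stage-species abundance counts.

    Species occupancy per plot is Bernoulli with a stage-specific
    probability (rising along succession, so Whittaker turnover falls);
    abundances are log-series draws. Every species occupies >= 1 plot,
    every plot holds >= 2 species, and at least two species per plot reach
    the abundance-5 leaf-sampling threshold.
    """
    species = select_stage_species(pool, stage, config, rng, regen_dm, est_dm)
    n_plots, S = config.plots_per_stage, len(species)
    occ = config.occupancy_by_stage[stage - 1]

    membership = rng.random((n_plots, S)) < occ
    for j in range(S):  # every stage species present somewhere
        if not membership[:, j].any():
            membership[rng.integers(n_plots), j] = True
    for i in range(n_plots):  # every plot holds at least two species
        while membership[i].sum() < 2:
            membership[i, rng.integers(S)] = True

    counts = logser.rvs(config.logseries_p, size=(n_plots, S), random_state=rng)
    abundance = np.where(membership, counts, 0)
    for i in range(n_plots):  # leaf sampling needs >= 2 abundant species
        present = np.where(membership[i])[0]
        order = present[np.argsort(abundance[i, present])[::-1]]
        for j in order[:2]:
            abundance[i, j] = max(abundance[i, j], 5)

    plot_ids = [f"s{stage}p{r}" for r in range(1, n_plots + 1)]
    return pd.DataFrame(abundance, index=plot_ids, columns=species)


def assemble_community(pool: pd.DataFrame, config: AssemblyConfig) -> CommunityMatrix:
    """Assemble all stages into one validated community matrix."""
    regen_dm = gower_distance(pool_trait_table(pool)).d
    est_dm = gower_distance(_establishment_table(pool)).d
    blocks = []
    for stage in range(1, config.n_stages + 1):
        rng = child_rng(config.seed, "stage", stage)
        blocks.append(assemble_stage(pool, stage, config, rng, regen_dm, est_dm))
    ab = pd.concat(blocks).fillna(0).astype(int)
    ab = ab[sorted(ab.columns)]
    meta = pd.DataFrame(
        {
            "stage": [int(p[1]) for p in ab.index],
            "replicate": [p.split("p")[1] for p in ab.index],
        },
        index=ab.index,
    )
    meta.index.name = "plot_id"
    return CommunityMatrix(ab, meta)


# ---------------------------------------------------------------------------
# leaf records, soil, missingness
# ---------------------------------------------------------------------------

def emit_leaf_records(
    community: CommunityMatrix,
    pool: pd.DataFrame,
    config: AssemblyConfig,
    rng: np.random.Generator | None = None,
) -> LeafRecordSet:
    """Six individual leaf records per (plot, species) with abundance >= 5.

    Individual values scatter log-normally (logit-normally for LDMC)
    around the species' latent values with coefficient ``noise_cv``;
    ``noise_cv = 0`` reproduces the latent values exactly.
    """
    rng = rng if rng is not None else child_rng(config.seed, "leaf")
    rows = []
    for plot in community.plots:
        stage = community.stage_of(plot)
        for sp in community.species_in_plot(plot):
            if community.abundance.loc[plot, sp] < 5:
                continue
            base = pool.loc[sp]
            eps = rng.standard_normal((6, 3))
            for i in range(6):
                rows.append(
                    {
                        "stage": stage,
                        "plot_id": plot,
                        "species": sp,
                        "la": base["la"] * np.exp(config.noise_cv * eps[i, 0]),
                        "sla": base["sla"] * np.exp(config.noise_cv * eps[i, 1]),
                        "ldmc": float(expit(logit(base["ldmc"]) + config.noise_cv * eps[i, 2])),
                    }
                )
    return LeafRecordSet(pd.DataFrame(rows))


def emit_soil(
    config: AssemblyConfig,
    rng: np.random.Generator | None = None,
) -> SoilTable:
    """Plot-level soil table following the stage-mean profiles.

    All properties get multiplicative log-normal plot noise of coefficient
    ``soil_cv`` (zero noise reproduces the exactly monotone stage means);
    the C:N ratio is computed from the noisy TC and TN.
    """
    rng = rng if rng is not None else child_rng(config.seed, "soil")
    rows = {}
    for stage in range(1, config.n_stages + 1):
        for rep in range(1, config.plots_per_stage + 1):
            plot = f"s{stage}p{rep}"
            vals = {}
            for prop, means in _SOIL_STAGE_MEANS.items():
                mean = means[stage - 1]
                vals[prop] = mean * float(np.exp(config.soil_cv * rng.standard_normal()))
            vals["cn_ratio"] = vals["tc"] / vals["tn"]
            rows[plot] = vals
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "plot_id"
    return SoilTable(df)


def inject_missingness(
    traits: TraitTable,
    rate: float,
    rng: np.random.Generator | int = 0,
) -> TraitTable:
    """Blank trait cells completely at random at the given rate.

    The number of missing cells is round-half-up(rate * n_cells); patterns
    that would blank a species' entire row are redrawn.
    """
    if not (0 <= rate < 1):
        raise ValidationError("missing rate must lie in [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    df = traits.values.copy()
    n_rows, n_cols = df.shape
    n_cells = n_rows * n_cols
    n_missing = int(np.floor(rate * n_cells + 0.5))
    if n_missing == 0:
        return TraitTable(df, dict(traits.schema))
    for _ in range(1000):
        flat = rng.choice(n_cells, size=n_missing, replace=False)
        mask = np.zeros(n_cells, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(n_rows, n_cols)
        if not mask.all(axis=1).any():
            break
    else:
        raise ValidationError("could not draw a missingness pattern keeping every row partly observed")
    out = df.mask(mask)
    return TraitTable(out, dict(traits.schema))


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: AssemblyConfig | None = None) -> SyntheticDataset:
    """Generate a complete chronosequence dataset with recorded truth."""
    config = config or AssemblyConfig()
    pool = make_species_pool(config)
    community = assemble_community(pool, config)
    leaf = emit_leaf_records(community, pool, config)
    leaf.check_against(community)
    soil = emit_soil(config)

    used = sorted(set(community.species))
    complete = TraitTable(pool.loc[used, list(REGENERATIVE_SCHEMA)].copy(),
                          dict(REGENERATIVE_SCHEMA))
    traits = inject_missingness(complete, config.missing_rate,
                                child_rng(config.seed, "missing"))

    truth = asdict(config)
    truth["species_abundance_distribution"] = (
        "log-series (stand-in; the field study's true SAD is unknown)"
    )
    truth["n_leaf_records"] = len(leaf)
    return SyntheticDataset(
        community=community, leaf=leaf, traits=traits, soil=soil,
        truth=truth, traits_complete=complete,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write community.csv, leaf.csv, traits.csv, soil.csv and truth.json."""
    from . import data as io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_community(ds.community, out / "community.csv")
    io.write_leaf(ds.leaf, out / "leaf.csv")
    io.write_traits(ds.traits, out / "traits.csv")
    io.write_soil(ds.soil, out / "soil.csv")
    (out / "truth.json").write_text(json.dumps(ds.truth, indent=2, default=str))
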