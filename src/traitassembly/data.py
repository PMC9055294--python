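"""In-memory containers for community, trait and soil tables, plus CSV I/O.

The containers are thin, validated wrappers around pandas objects and form
the shared vocabulary of the pipeline:

* :class:`CommunityMatrix` — plots x species abundance counts with plot
  metadata (successional stage 1-4, replicate).
* :class:`LeafRecordSet` — individual-level establishment (leaf) traits:
  leaf area LA (mm^2), specific leaf area SLA (mm^2/g) and leaf dry matter
  content LDMC (dry/fresh mass, a fraction in (0, 1)).
* :class:`TraitTable` — species-level regenerative traits (seed mass,
  longevity class, flowering/fruiting period lengths, first month of
  flowering), mixed continuous/ordinal, missing cells permitted.
* :class:`SoilTable` — plot/site-level soil properties (metal
  concentrations, pH, EC, ORP, moisture, nutrients).
* :class:`DistanceMatrix` — labelled symmetric dissimilarity matrix.

Validation is total: every malformed table raises a typed error from
:mod:`traitassembly.errors`; missing values are ``NaN`` in memory and empty
cells on disk, never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger("traitassembly")

#: Establishment (leaf) trait columns, in canonical order.
ESTABLISHMENT_TRAITS = ("la", "sla", "ldmc")

#: Regenerative trait schema: name -> (kind, valid integer domain or None).
REGENERATIVE_SCHEMA: dict[str, tuple[str, tuple[int, int] | None]] = {
    "seed_mass": ("continuous", None),          # g per 1000 seeds
    "longevity": ("ordinal", (1, 4)),           # life-span classes
    "flowering_period": ("ordinal", (1, 12)),   # months
    "fruiting_period": ("ordinal", (1, 12)),    # months
    "fmf": ("ordinal", (0, 13)),                # first month of flowering
}

REGENERATIVE_TRAITS = tuple(REGENERATIVE_SCHEMA)

#: Declared soil-property vocabulary. Concentrations are mg/kg, ORP mV,
#: moisture %, EC uS/cm; nutrient totals are g/kg.
SOIL_PROPERTIES = (
    "total_cr", "total_cd", "total_cu", "total_ni", "total_pb", "total_zn",
    "total_sn", "avail_cr", "avail_cd", "avail_cu", "avail_pb",
    "ph", "ec", "orp", "moisture", "temperature",
    "tn", "tc", "tp", "tk", "cn_ratio",
)

_NONNEGATIVE_SOIL = {p for p in SOIL_PROPERTIES if p not in ("orp", "temperature")}

VALID_STAGES = (1, 2, 3, 4)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Plots x species abundance counts plus plot metadata.

    ``abundance`` is indexed by plot_id with one integer column per species;
    ``meta`` is indexed by plot_id with columns ``stage`` and ``replicate``.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        ab, meta = self.abundance, self.meta
        if not ab.index.equals(meta.index):
            raise ValidationError("abundance and metadata plot ids differ")
        if ab.index.duplicated().any():
            raise ValidationError("duplicate plot ids")
        if ab.columns.duplicated().any():
            raise ValidationError("duplicate species identifiers")
        vals = ab.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            bad = ab.index[np.where(~(np.nan_to_num(vals, nan=-1) >= 0))[0]]
            raise ValidationError(f"negative or missing abundance in plots {list(bad)[:5]}")
        if (vals.sum(axis=1) == 0).any():
            empty = list(ab.index[vals.sum(axis=1) == 0])
            raise ValidationError(f"plots with no species present: {empty}")
        bad_stage = ~meta["stage"].isin(VALID_STAGES)
        if bad_stage.any():
            rows = meta.loc[bad_stage]
            raise ValidationError(
                "stage outside {1,2,3,4} for plots "
                + ", ".join(f"{p} (stage={s})" for p, s in rows["stage"].items())
            )
        self.abundance = ab.astype(int)
        self.meta = meta.copy()
        self.meta["stage"] = self.meta["stage"].astype(int)

    # -- convenience ------------------------------------------------------
    @property
    def plots(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    def stage_of(self, plot_id: str) -> int:
        return int(self.meta.loc[plot_id, "stage"])

    def plots_in_stage(self, stage: int) -> list[str]:
        return list(self.meta.index[self.meta["stage"] == stage])

    def species_in_plot(self, plot_id: str) -> list[str]:
        row = self.abundance.loc[plot_id]
        return list(row.index[row > 0])

    def species_in_stage(self, stage: int) -> list[str]:
        sub = self.abundance.loc[self.plots_in_stage(stage)]
        return list(sub.columns[(sub > 0).any(axis=0)])

    @property
    def stages(self) -> list[int]:
        return sorted(self.meta["stage"].unique())

    def richness(self) -> pd.Series:
        """Per-plot species richness S."""
        return (self.abundance > 0).sum(axis=1).rename("richness")


@dataclass
class LeafRecordSet:
    """Individual-level leaf-trait records (one row per sampled individual)."""

    records: pd.DataFrame  # columns: stage, plot_id, species, la, sla, ldmc

    def __post_init__(self) -> None:
        df = self.records
        required = ["stage", "plot_id", "species", *ESTABLISHMENT_TRAITS]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"leaf records missing columns {missing}")
        df = df[required].reset_index(drop=True)
        if not df["stage"].isin(VALID_STAGES).all():
            raise ValidationError("leaf record with stage outside {1,2,3,4}")
        for col in ("la", "sla"):
            bad = ~(df[col] > 0) | ~np.isfinite(df[col])
            if bad.any():
                raise ValidationError(f"{col} must be positive; bad rows {list(df.index[bad])[:5]}")
        bad = ~((df["ldmc"] > 0) & (df["ldmc"] < 1))
        if bad.any():
            raise ValidationError(
                f"ldmc must lie in (0,1) (dry/fresh fraction); bad rows {list(df.index[bad])[:5]}"
            )
        df["stage"] = df["stage"].astype(int)
        self.records = df

    def check_against(self, community: CommunityMatrix) -> None:
        unknown = set(self.records["plot_id"]) - set(community.plots)
        if unknown:
            raise ValidationError(f"leaf records reference unknown plots {sorted(unknown)}")

    def for_stage(self, stage: int) -> np.ndarray:
        """(n, 3) array of (LA, SLA, LDMC) for one stage."""
        sub = self.records[self.records["stage"] == stage]
        return sub[list(ESTABLISHMENT_TRAITS)].to_numpy(float)

    def triplets(self) -> np.ndarray:
        """(n, 3) array of all (LA, SLA, LDMC) records, pooled over stages."""
        return self.records[list(ESTABLISHMENT_TRAITS)].to_numpy(float)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TraitTable:
    """Species-level regenerative traits with explicit missing cells."""

    values: pd.DataFrame  # index species, columns REGENERATIVE_TRAITS
    schema: dict[str, tuple[str, tuple[int, int] | None]] = field(
        default_factory=lambda: dict(REGENERATIVE_SCHEMA)
    )

    def __post_init__(self) -> None:
        df = self.values
        unknown = [c for c in df.columns if c not in self.schema]
        if unknown:
            raise SchemaError(f"traits not declared in schema: {unknown}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate species in trait table")
        df = df.astype(float)
        for trait, (kind, domain) in self.schema.items():
            if trait not in df.columns:
                continue
            col = df[trait]
            obs = col.dropna()
            if kind == "continuous":
                if (obs < 0).any():
                    raise ValidationError(f"negative values in continuous trait {trait}")
            elif domain is not None:
                lo, hi = domain
                bad = obs[(obs < lo) | (obs > hi) | (obs != obs.round())]
                if len(bad):
                    raise ValidationError(
                        f"{trait} outside classes {lo}..{hi} for species {list(bad.index)[:5]}"
                    )
        self.values = df

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def missingness(self) -> float:
        """Fraction of missing cells over all species x trait cells."""
        return float(self.values.isna().to_numpy().mean())

    def kinds(self) -> dict[str, str]:
        return {t: self.schema[t][0] for t in self.values.columns}


@dataclass
class SoilTable:
    """Plot/site-level soil properties."""

    values: pd.DataFrame  # index plot_id, columns from SOIL_PROPERTIES

    def __post_init__(self) -> None:
        df = self.values.astype(float)
        unknown = [c for c in df.columns if c not in SOIL_PROPERTIES]
        if unknown:
            raise SchemaError(f"soil properties outside declared vocabulary: {unknown}")
        if not np.isfinite(df.to_numpy()).all():
            raise ValidationError("non-finite soil values")
        for prop in df.columns:
            if prop in _NONNEGATIVE_SOIL and (df[prop] < 0).any():
                raise ValidationError(f"negative concentration in {prop}")
        self.values = df

    @property
    def plots(self) -> list[str]:
        return list(self.values.index)


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValidationError("negative distances")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        self.d = np.clip(d, 0.0, None)

    def sub(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)])

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.d[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_META_COLUMNS = ("plot_id", "stage", "replicate")


def read_community(path: str | Path, delimiter: str = ",") -> CommunityMatrix:
    """Read a plots x species abundance CSV.

    The file must carry ``plot_id`` and ``stage`` columns (``replicate``
    optional); every remaining column is taken as a species.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    for col in ("plot_id", "stage"):
        if col not in df.columns:
            raise SchemaError(f"community file lacks required column '{col}'")
    meta_cols = [c for c in _META_COLUMNS if c in df.columns]
    species = [c for c in df.columns if c not in _META_COLUMNS]
    if not species:
        raise SchemaError("community file has no species columns")
    df = df.set_index("plot_id")
    meta = df[[c for c in meta_cols if c != "plot_id"]].copy()
    if "replicate" not in meta.columns:
        meta["replicate"] = [str(i) for i in range(1, len(meta) + 1)]
    ab = df[species]
    if ab.isna().any().any():
        raise ValidationError("missing abundance cells; abundances must be explicit counts")
    return CommunityMatrix(ab, meta)


def write_community(cm: CommunityMatrix, path: str | Path, delimiter: str = ",") -> None:
    out = pd.concat([cm.meta, cm.abundance], axis=1)
    out.insert(0, "plot_id", out.index)
    out.to_csv(path, sep=delimiter, index=False)


def read_leaf(path: str | Path, delimiter: str = ",", ldmc_percent: bool = False) -> LeafRecordSet:
    """Read individual leaf-trait records; ``ldmc_percent=True`` accepts
    LDMC given as a percentage and converts it to a fraction."""
    df = pd.read_csv(path, delimiter=delimiter)
    if ldmc_percent and "ldmc" in df.columns:
        df["ldmc"] = df["ldmc"] / 100.0
    return LeafRecordSet(df)


def write_leaf(leaf: LeafRecordSet, path: str | Path, delimiter: str = ",") -> None:
    leaf.records.to_csv(path, sep=delimiter, index=False)


def read_traits(
    path: str | Path,
    schema: dict[str, tuple[str, tuple[int, int] | None]] | None = None,
    delimiter: str = ",",
) -> TraitTable:
    """Read the species-level regenerative trait table.

    Empty cells are missing values. Any trait column absent from the
    declared schema is a :class:`SchemaError`.
    """
    schema = dict(REGENERATIVE_SCHEMA) if schema is None else schema
    df = pd.read_csv(path, delimiter=delimiter)
    if "species" not in df.columns:
        raise SchemaError("trait file lacks 'species' column")
    df = df.set_index("species")
    table = TraitTable(df, schema)
    logger.info("read %d species, %d traits, missingness %.3f",
                len(table.species), df.shape[1], table.missingness)
    return table


def write_traits(table: TraitTable, path: str | Path, delimiter: str = ",") -> None:
    out = table.values.copy()
    out.insert(0, "species", out.index)
    out.to_csv(path, sep=delimiter, index=False)


def read_soil(path: str | Path, delimiter: str = ",") -> SoilTable:
    df = pd.read_csv(path, delimiter=delimiter)
    if "plot_id" not in df.columns:
        raise SchemaError("soil file lacks 'plot_id' column")
    return SoilTable(df.set_index("plot_id"))


def write_soil(soil: SoilTable, path: str | Path, delimiter: str = ",") -> None:
    out = soil.values.copy()
    out.insert(0, "plot_id", out.index)
    out.to_csv(path, sep=delimiter, index=False)


def write_result_tables(results: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write one CSV per result family with deterministic column order.

    ``results`` maps a family name (``es_table``, ``mantel``, ``diversity``,
    ``csr`` ...) to a DataFrame; returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(results):
        df = results[name]
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths
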