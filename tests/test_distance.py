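"""Gower distance, MFD, per-trait FD and imputation, against oracles."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from traitassembly.data import CommunityMatrix, REGENERATIVE_SCHEMA, TraitTable
from traitassembly.distance import (
    GowerSpec,
    fd_per_trait,
    gower_distance,
    impute_traits,
    mfd,
    mfd_table,
)
from traitassembly.errors import DegenerateInputError, ValidationError


def _table(values: dict, schema=None) -> TraitTable:
    df = pd.DataFrame(values)
    df.index = [f"s{i}" for i in range(len(df))]
    schema = schema or {
        k: ("continuous", None) if k == "seed_mass" else REGENERATIVE_SCHEMA[k]
        for k in values
    }
    return TraitTable(df, schema)


# ---------------------------------------------------------------------------
# Gower
# ---------------------------------------------------------------------------

def test_gower_identical_rows_zero(small_traits):
    dup = pd.concat([small_traits.values.iloc[[0]]] * 2)
    dup.index = ["a", "b"]
    dm = gower_distance(TraitTable(dup, dict(small_traits.schema)))
    assert dm.d[0, 1] == 0.0


def test_gower_one_trait_at_opposite_ends_of_range():
    # five equally weighted traits; two species differ only in one trait,
    # at the extremes of its pooled range -> d = 1/5
    base = {
        "seed_mass": [1.0, 1.0, 5.0],
        "longevity": [2, 2, 2],
        "flowering_period": [6, 6, 6],
        "fruiting_period": [4, 4, 4],
        "fmf": [0, 13, 5],
    }
    table = _table(base, dict(REGENERATIVE_SCHEMA))
    spec = GowerSpec(
        kinds={k: REGENERATIVE_SCHEMA[k][0] for k in base},
        ranges={"seed_mass": 4.0, "longevity": 3.0, "flowering_period": 11.0,
                "fruiting_period": 11.0, "fmf": 13.0},
    )
    dm = gower_distance(table, spec)
    assert dm.d[0, 1] == pytest.approx(1 / 5, abs=1e-12)


def test_gower_single_trait_closed_form():
    table = _table({"seed_mass": [2.0, 6.0, 10.0]})
    spec = GowerSpec(kinds={"seed_mass": "continuous"}, ranges={"seed_mass": 8.0})
    dm = gower_distance(table, spec)
    assert dm.d[0, 1] == pytest.approx(0.5, abs=1e-12)


def test_gower_pairwise_deletion_renormalizes():
    table = _table({"seed_mass": [1.0, np.nan, 3.0], "longevity": [1, 4, 2]})
    dm = gower_distance(table)
    # s0 vs s1 share only longevity: |1-4|/3 = 1
    assert dm.d[0, 1] == pytest.approx(1.0)


def test_gower_no_shared_trait_errors():
    table = _table({"seed_mass": [1.0, np.nan, 2.0], "longevity": [np.nan, 2, 3]})
    with pytest.raises(ValidationError, match="s0.*s1|s1.*s0"):
        gower_distance(table)


def test_gower_scaling_invariance():
    # jointly rescaling a continuous trait and its declared range is a no-op
    t1 = _table({"seed_mass": [1.0, 3.0, 8.0]})
    t2 = _table({"seed_mass": [10.0, 30.0, 80.0]})
    d1 = gower_distance(t1, GowerSpec({"seed_mass": "continuous"}, {"seed_mass": 7.0}))
    d2 = gower_distance(t2, GowerSpec({"seed_mass": "continuous"}, {"seed_mass": 70.0}))
    np.testing.assert_allclose(d1.d, d2.d, atol=1e-12)


@settings(deadline=None, max_examples=40)
@given(st.integers(min_value=0, max_value=10_000))
def test_gower_matrix_is_valid_distance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    df = pd.DataFrame(
        {
            "seed_mass": rng.lognormal(0, 1, n),
            "longevity": rng.integers(1, 5, n).astype(float),
            "fmf": rng.integers(0, 14, n).astype(float),
        },
        index=[f"s{i}" for i in range(n)],
    )
    # sprinkle missing values but keep one shared trait (longevity)
    mask = rng.random(n) < 0.3
    df.loc[mask, "seed_mass"] = np.nan
    dm = gower_distance(TraitTable(df, {k: REGENERATIVE_SCHEMA[k] for k in df}))
    assert (dm.d >= 0).all() and (dm.d <= 1 + 1e-12).all()
    np.testing.assert_allclose(dm.d, dm.d.T)
    assert np.all(np.diag(dm.d) == 0)


# ---------------------------------------------------------------------------
# MFD / FD
# ---------------------------------------------------------------------------

def test_mfd_two_species_equals_their_distance(small_traits):
    dm = gower_distance(small_traits)
    pair = ["sp1", "sp3"]
    expected = dm.sub(pair).d[0, 1]
    assert mfd(pair, dm).mfd == pytest.approx(expected)
    assert mfd(pair, dm, "abundance", {"sp1": 3, "sp3": 9}).mfd == pytest.approx(expected)


def test_mfd_three_species_average():
    from traitassembly.data import DistanceMatrix

    d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
    dm = DistanceMatrix(["a", "b", "c"], d)
    assert mfd(["a", "b", "c"], dm).mfd == pytest.approx(0.4, abs=1e-12)


def test_mfd_equal_abundances_match_presence(small_traits):
    dm = gower_distance(small_traits)
    sp = ["sp1", "sp2", "sp4"]
    ab = {s: 2 for s in sp}
    assert mfd(sp, dm, "abundance", ab).mfd == pytest.approx(mfd(sp, dm).mfd)


def test_mfd_single_species_undefined(small_traits):
    dm = gower_distance(small_traits)
    with pytest.raises(DegenerateInputError):
        mfd(["sp1"], dm)


@settings(deadline=None, max_examples=30)
@given(st.integers(min_value=0, max_value=10_000))
def test_mfd_matches_pair_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 7))
    raw = rng.random((n, n))
    d = np.triu(raw, 1)
    d = d + d.T
    from traitassembly.data import DistanceMatrix

    labels = [f"s{i}" for i in range(n)]
    dm = DistanceMatrix(labels, d)
    ab = {l: float(rng.integers(1, 9)) for l in labels}
    # brute-force oracle over explicit pairs
    pairs = list(itertools.combinations(range(n), 2))
    oracle_presence = np.mean([d[i, j] for i, j in pairs])
    w = np.array([ab[labels[i]] * ab[labels[j]] for i, j in pairs])
    oracle_ab = np.sum(w * [d[i, j] for i, j in pairs]) / w.sum()
    assert mfd(labels, dm).mfd == pytest.approx(oracle_presence, abs=1e-12)
    assert mfd(labels, dm, "abundance", ab).mfd == pytest.approx(oracle_ab, abs=1e-12)


def _two_plot_community(species_by_plot: dict[str, list[str]], all_species: list[str]):
    ab = pd.DataFrame(0, index=list(species_by_plot), columns=all_species)
    for plot, sp in species_by_plot.items():
        ab.loc[plot, sp] = 3
    meta = pd.DataFrame({"stage": [1] * len(ab), "replicate": ["1"] * len(ab)},
                        index=ab.index)
    return CommunityMatrix(ab, meta)


def test_fd_single_trait_closed_form():
    # seed masses (1, 3) with pooled range 4 -> FD = 2/4 = 0.5
    table = _table({"seed_mass": [1.0, 3.0, 5.0]})
    cm = _two_plot_community({"p1": ["s0", "s1"], "p2": ["s0", "s2"]},
                             ["s0", "s1", "s2"])
    fd = fd_per_trait(table, cm)
    val = fd[(fd["plot_id"] == "p1") & (fd["trait"] == "seed_mass")]["fd"].iloc[0]
    assert val == pytest.approx(0.5, abs=1e-12)


def test_fd_constant_trait_within_plot_is_zero():
    table = _table({"seed_mass": [2.0, 2.0, 6.0]})
    cm = _two_plot_community({"p1": ["s0", "s1"], "p2": ["s1", "s2"]},
                             ["s0", "s1", "s2"])
    fd = fd_per_trait(table, cm)
    assert fd[(fd["plot_id"] == "p1")]["fd"].iloc[0] == pytest.approx(0.0)


def test_fd_duplicate_species_leaves_presence_mode_unchanged():
    t_dup = _table({"seed_mass": [1.0, 3.0, 3.0]})
    cm2 = _two_plot_community({"p1": ["s0", "s1"], "p2": ["s0", "s1"]}, ["s0", "s1", "s2"])
    cm3 = _two_plot_community({"p1": ["s0", "s1", "s2"], "p2": ["s0", "s1"]},
                              ["s0", "s1", "s2"])
    fd2 = fd_per_trait(t_dup, cm2)
    fd3 = fd_per_trait(t_dup, cm3)
    v2 = fd2[fd2["plot_id"] == "p1"]["fd"].iloc[0]
    v3 = fd3[fd3["plot_id"] == "p1"]["fd"].iloc[0]
    # 2 species at distance d vs {d, d, 0}: mean over pairs becomes 2d/3
    assert v3 == pytest.approx(2 * v2 / 3, abs=1e-12)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def test_impute_no_missing_is_identity(small_traits):
    out = impute_traits(small_traits, seed=0)
    pd.testing.assert_frame_equal(out.values, small_traits.values)


def test_impute_degenerate_tree_uses_constant():
    df = pd.DataFrame(
        {
            "seed_mass": [2.0] * 6 + [np.nan],
            "longevity": [3.0] * 7,
            "fmf": [5.0] * 7,
        },
        index=[f"s{i}" for i in range(7)],
    )
    table = TraitTable(df, {k: REGENERATIVE_SCHEMA[k] for k in df})
    out = impute_traits(table, seed=0)
    assert out.values.loc["s6", "seed_mass"] == pytest.approx(2.0)


def test_impute_ordinal_rounded_to_valid_class(dataset):
    out = impute_traits(dataset.traits, seed=1)
    assert not out.values.isna().any().any()
    assert out.values["longevity"].isin([1, 2, 3, 4]).all()
    assert out.values["fmf"].between(0, 13).all()


def test_impute_recovers_truth_better_than_noise():
    # MCAR at 14.3% on a pool large enough to estimate per-trait RMSE:
    # imputation must beat the trivial error level (the trait's own SD),
    # with skewed continuous traits judged on their log scale
    from traitassembly.simulate import AssemblyConfig, inject_missingness, make_species_pool, pool_trait_table

    cfg = AssemblyConfig(pool_size=1000, richness_by_stage=(12, 13, 17, 19), seed=5)
    truth_table = pool_trait_table(make_species_pool(cfg))
    truth = truth_table.values
    missing = inject_missingness(truth_table, 0.143, np.random.default_rng(1))
    out = impute_traits(missing, seed=2)
    for trait in truth.columns:
        mask = missing.values[trait].isna()
        imputed, actual = out.values.loc[mask, trait], truth.loc[mask, trait]
        ref = truth[trait]
        if truth_table.schema[trait][0] == "continuous":
            imputed, actual, ref = np.log(imputed), np.log(actual), np.log(ref)
        rmse = float(np.sqrt(((imputed - actual) ** 2).mean()))
        assert rmse < float(ref.std(ddof=1)), trait


def test_impute_rejects_overly_missing_trait():
    df = pd.DataFrame(
        {"seed_mass": [1.0, np.nan, np.nan, np.nan], "longevity": [1.0, 2, 3, 4]},
        index=list("abcd"),
    )
    table = TraitTable(df, {k: REGENERATIVE_SCHEMA[k] for k in df})
    with pytest.raises(ValidationError, match="50%"):
        impute_traits(table, seed=0)


# ---------------------------------------------------------------------------
# independent R oracle (cluster::daisy + picante::mpd)
# ---------------------------------------------------------------------------

def test_gower_and_mfd_match_r_reference(tmp_path):
    df = pd.DataFrame(
        {
            "seed_mass": [1.0, 3.0, 2.0, np.nan],
            "longevity": [1.0, 4.0, 2.0, 3.0],
            "fmf": [0.0, 13.0, 5.0, 7.0],
        },
        index=list("abcd"),
    )
    table = TraitTable(df, {k: REGENERATIVE_SCHEMA[k] for k in df})
    dm = gower_distance(table)
    ours_mfd = mfd(list("abc"), dm).mfd

    script = tmp_path / "oracle.R"
    script.write_text(textwrap.dedent("""
        suppressMessages({library(cluster); library(picante)})
        tr <- data.frame(row.names=c("a","b","c","d"),
                         seed_mass=c(1,3,2,NA), longevity=c(1,4,2,3),
                         fmf=c(0,13,5,7))
        d <- as.matrix(daisy(tr, metric="gower"))
        comm <- matrix(c(1,1,1,0), nrow=1,
                       dimnames=list("p1", c("a","b","c","d")))
        cat(d[lower.tri(d)], "\\n")
        cat(mpd(comm, d), "\\n")
    """))
    res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         timeout=120)
    assert res.returncode == 0, res.stderr
    lines = res.stdout.strip().splitlines()
    r_tri = np.array([float(x) for x in lines[0].split()])
    r_mfd = float(lines[1])
    # R's lower.tri is column-major: (i, j) for j < i, ordered by column
    ours_tri = np.array([dm.d[i, j] for j in range(4) for i in range(j + 1, 4)])
    np.testing.assert_allclose(ours_tri, r_tri, atol=1e-6)
    assert ours_mfd == pytest.approx(r_mfd, abs=1e-6)


def test_mfd_table_covers_all_plots(dataset):
    dm = gower_distance(impute_traits(dataset.traits, seed=0))
    table = mfd_table(dataset.community, dm)
    assert set(table["plot_id"]) == set(dataset.community.plots)
    assert table["mfd"].between(0, 1).all()
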