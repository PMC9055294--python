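"""Soil/strategy dissimilarities, Mantel tests and beta regression."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from traitassembly.association import (
    BetaRegression,
    adjust_pvalues,
    mantel,
    mantel_table,
    significant_properties,
    soil_dissimilarity,
    strategy_dissimilarity,
)
from traitassembly.data import DistanceMatrix, SoilTable
from traitassembly.errors import DegenerateInputError, ValidationError


def _soil(values, prop="avail_cr"):
    df = pd.DataFrame({prop: values}, index=[f"p{i}" for i in range(len(values))])
    return SoilTable(df)


# ---------------------------------------------------------------------------
# dissimilarities
# ---------------------------------------------------------------------------

def test_soil_dissimilarity_log_difference():
    dm = soil_dissimilarity(_soil([1.0, 10.0, 10.0]), "avail_cr")
    assert dm.d[0, 1] == pytest.approx(np.log(10), abs=1e-12)
    assert dm.d[1, 2] == 0.0


def test_soil_dissimilarity_zero_offset_and_negative_error():
    dm = soil_dissimilarity(_soil([0.0, 1.0, 3.0]), "avail_cr")
    # offset c = smallest positive value = 1
    assert dm.d[0, 1] == pytest.approx(np.log(2) - np.log(1), abs=1e-12)
    with pytest.raises(ValidationError, match="negative"):
        soil_dissimilarity(SoilTable(pd.DataFrame({"orp": [-5.0, 2.0]},
                                                  index=["a", "b"])), "orp")


def test_soil_dissimilarity_permutation_consistency():
    soil = _soil([1.0, 2.0, 7.0])
    dm = soil_dissimilarity(soil, "avail_cr")
    perm = ["p2", "p0", "p1"]
    sub = dm.sub(perm)
    assert sub.d[0, 1] == dm.d[2, 0]


def test_strategy_dissimilarity_closed_forms():
    scores = pd.DataFrame(
        {"plot_id": ["a", "b", "c", "d"],
         "C": [100.0, 0.0, 60.0, 20.0], "S": [0.0, 100.0, 20.0, 60.0],
         "R": [0.0, 0.0, 20.0, 20.0]}
    )
    dm = strategy_dissimilarity(scores)
    assert dm.d[0, 1] == pytest.approx(np.sqrt(2), abs=1e-12)
    assert dm.d[2, 3] == pytest.approx(np.sqrt(0.32), abs=1e-12)
    assert dm.d[0, 0] == 0.0


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _random_dm(rng, n):
    m = rng.random((n, n))
    m = np.triu(m, 1)
    return DistanceMatrix([f"p{i}" for i in range(n)], m + m.T)


def test_mantel_perfect_linear_relation(rng):
    dm1 = _random_dm(rng, 6)
    dm2 = DistanceMatrix(dm1.labels, 2.0 * dm1.d)
    res = mantel(dm1, dm2, n_perm=99, seed=1)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    assert res.p <= 0.05


def test_mantel_r_symmetric_in_arguments(rng):
    dm1, dm2 = _random_dm(rng, 7), _random_dm(rng, 7)
    assert mantel(dm1, dm2, 49, seed=0).r == pytest.approx(
        mantel(dm2, dm1, 49, seed=0).r, abs=1e-12)


def test_mantel_exhaustive_matches_brute_force_oracle(rng):
    dm1, dm2 = _random_dm(rng, 4), _random_dm(rng, 4)
    res = mantel(dm1, dm2, exhaustive=True)
    tri = np.tril_indices(4, k=-1)

    def pearson(a, b):
        return np.corrcoef(a, b)[0, 1]

    r_obs = pearson(dm1.d[tri], dm2.d[tri])
    hits = 0
    for perm in itertools.permutations(range(4)):
        permuted = dm2.d[np.ix_(perm, perm)]
        if pearson(dm1.d[tri], permuted[tri]) >= r_obs - 1e-12:
            hits += 1
    assert res.r == pytest.approx(r_obs, abs=1e-12)
    assert res.p == pytest.approx(hits / 24, abs=1e-12)
    assert res.n_perm == 24


def test_mantel_rejects_degenerate_input():
    dm = DistanceMatrix([f"p{i}" for i in range(4)], np.zeros((4, 4)))
    other = _random_dm(np.random.default_rng(0), 4)
    with pytest.raises(DegenerateInputError):
        mantel(dm, other, 9)
    with pytest.raises(ValidationError, match="labels"):
        mantel(other, _random_dm(np.random.default_rng(1), 5), 9)


def test_mantel_matches_r_vegan(tmp_path, rng):
    dm1, dm2 = _random_dm(rng, 8), _random_dm(rng, 8)
    np.savetxt(tmp_path / "m1.csv", dm1.d, delimiter=",")
    np.savetxt(tmp_path / "m2.csv", dm2.d, delimiter=",")
    script = tmp_path / "mantel.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(vegan))
        m1 <- as.matrix(read.csv("{tmp_path}/m1.csv", header=FALSE))
        m2 <- as.matrix(read.csv("{tmp_path}/m2.csv", header=FALSE))
        res <- mantel(as.dist(m1), as.dist(m2), permutations=999)
        cat(res$statistic, "\\n")
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         timeout=120)
    assert out.returncode == 0, out.stderr
    r_vegan = float(out.stdout.strip().split()[-1])
    ours = mantel(dm1, dm2, n_perm=99, seed=0)
    assert ours.r == pytest.approx(r_vegan, abs=1e-6)


# ---------------------------------------------------------------------------
# p adjustment and the screening gate
# ---------------------------------------------------------------------------

def test_adjust_pvalues_rules():
    assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)
    np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    assert adjust_pvalues([0.01] * 8, "bonferroni")[0] == pytest.approx(0.08)
    with pytest.raises(ValidationError):
        adjust_pvalues([])
    with pytest.raises(ValidationError):
        adjust_pvalues([0.0, 0.5])


def test_adjusted_p_never_smaller(rng):
    p = rng.uniform(0.001, 1.0, 10)
    adj = adjust_pvalues(p)
    assert (adj >= p - 1e-12).all()


def test_significance_gate_branches():
    table = pd.DataFrame({"property": ["a", "b"], "r": [0.5, 0.1],
                          "p": [0.001, 0.4], "p_adjusted": [0.01, 0.8]})
    assert significant_properties(table) == ["a"]
    table["p_adjusted"] = [0.2, 0.8]
    assert significant_properties(table) == []


def test_mantel_table_shape(dataset):
    from traitassembly.csr import plot_mean_strategy, score_leaf_records

    plot_scores = plot_mean_strategy(score_leaf_records(dataset.leaf))
    out = mantel_table(dataset.soil, plot_scores, properties=["avail_cr", "ph"],
                       n_perm=99, seed=0)
    assert list(out["property"]) == ["avail_cr", "ph"]
    assert ((out["p"] > 0) & (out["p"] <= 1)).all()
    assert (out["p_adjusted"] >= out["p"] - 1e-12).all()


# ---------------------------------------------------------------------------
# beta regression
# ---------------------------------------------------------------------------

def _simulate_beta(rng, n=100, b0=-1.0, b1=2.0, phi=30.0):
    x = rng.uniform(-1, 1, n)
    mu = 1 / (1 + np.exp(-(b0 + b1 * x)))
    y = rng.beta(mu * phi, (1 - mu) * phi)
    return y, x


def test_beta_regression_recovers_parameters(rng):
    y, x = _simulate_beta(rng)
    fit = BetaRegression(y, x).fit()
    assert fit.converged
    assert abs(fit.params[0] - (-1.0)) < 3 * fit.bse[0]
    assert abs(fit.params[1] - 2.0) < 3 * fit.bse[1]
    assert fit.phi > 0
    mu_hat = fit.fitted_mean(x)
    assert ((mu_hat > 0) & (mu_hat < 1)).all()


def test_beta_regression_loglik_beats_start(rng):
    y, x = _simulate_beta(rng, n=60)
    model = BetaRegression(y, x)
    from statsmodels.othermod.betareg import BetaModel

    X = np.column_stack([np.ones_like(x), x])
    raw = BetaModel(model.y, X, exog_precision=np.ones((len(y), 1)))
    start = model._start_params()
    fit = model.fit()
    assert fit.llf >= raw.loglike(start) - 1e-8


def test_beta_regression_boundary_compression(rng):
    y, x = _simulate_beta(rng, n=40)
    y[0], y[1] = 0.0, 1.0
    model = BetaRegression(y, x)
    assert model.boundary_compressed
    assert ((model.y > 0) & (model.y < 1)).all()
    fit = model.fit()
    assert fit.boundary_compressed and fit.converged


def test_beta_regression_degenerate_design(rng):
    y, _ = _simulate_beta(rng, n=20)
    with pytest.raises(DegenerateInputError, match="constant"):
        BetaRegression(y, np.full(20, 2.0), covariate="ph")
    with pytest.raises(ValidationError):
        BetaRegression(y[:3], np.arange(3.0))
    with pytest.raises(ValidationError):
        BetaRegression(np.linspace(-0.1, 0.5, 20), np.arange(20.0))


def test_beta_regression_summary_layout(rng):
    y, x = _simulate_beta(rng, n=50)
    fit = BetaRegression(y, x, response="S", covariate="avail_cr").fit()
    table = fit.summary()
    assert list(table["term"]) == ["intercept", "avail_cr", "phi"]
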