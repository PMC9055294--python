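"""Soil-strategy association: Mantel tests and beta regression.

Per soil property, plots are compared through an a-priori dissimilarity
matrix (absolute difference of log-transformed values), the community
strategy composition through Euclidean distance between plot-mean
(C, S, R)/100 triplets, and the two matrices are correlated with a Mantel
permutation test (one-sided "greater" by default, identity permutation
counted in both numerator and denominator: p = (r + 1)/(n_perm + 1)).
p-values across properties are adjusted (Benjamini-Hochberg default) and
only properties passing the adjusted threshold proceed to beta
regressions of the individual strategy proportions on the (log) property.

Note the permutation-p convention here differs deliberately from the
null-model effect size: the ES uses the plain proportion over
simulations (so it can reach exactly +/-1), while Mantel p uses the
standard (r+1)/(n+1) form and can never be 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel
from statsmodels.stats.multitest import multipletests

from ._seeds import child_rng, child_seed
from .data import DistanceMatrix, SoilTable
from .errors import ConvergenceError, DegenerateInputError, ValidationError

logger = logging.getLogger("traitassembly")


# ---------------------------------------------------------------------------
# dissimilarity matrices
# ---------------------------------------------------------------------------

def soil_dissimilarity(soil: SoilTable, prop: str, log: bool = True) -> DistanceMatrix:
    """Per-property plot dissimilarity d(i,j) = |log(x_i + c) - log(x_j + c)|.

    The offset c is 0 unless zeros are present, in which case it is the
    smallest positive value of the property. Negative values are an error
    (the log transform is undefined there).
    """
    if prop not in soil.values.columns:
        raise ValidationError(f"soil property {prop!r} not present")
    x = soil.values[prop].to_numpy(float)
    if log:
        if (x < 0).any():
            raise ValidationError(f"negative values in {prop}; log-dissimilarity undefined")
        c = 0.0
        if (x == 0).any():
            positive = x[x > 0]
            if len(positive) == 0:
                raise DegenerateInputError(f"{prop} is identically zero")
            c = float(positive.min())
        x = np.log(x + c)
    d = np.abs(np.subtract.outer(x, x))
    return DistanceMatrix(soil.plots, d)


def strategy_dissimilarity(plot_scores: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between plots' (C, S, R)/100 compositions.

    ``plot_scores`` must carry columns plot_id, C, S, R (percentages).
    """
    for col in ("plot_id", "C", "S", "R"):
        if col not in plot_scores.columns:
            raise ValidationError(f"plot scores lack column {col!r}")
    if plot_scores[["C", "S", "R"]].isna().any().any():
        raise ValidationError("missing plot strategy scores")
    comp = plot_scores[["C", "S", "R"]].to_numpy(float) / 100.0
    diff = comp[:, None, :] - comp[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(list(plot_scores["plot_id"]), d)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    property: str
    r: float
    p: float
    n_perm: int
    alternative: str
    p_adjusted: float | None = None


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
    exhaustive: bool = False,
    property_name: str = "",
) -> MantelResult:
    """Mantel correlation between two labelled distance matrices.

    r is the Pearson correlation of the lower-triangle entries; p comes
    from random row/column permutations of the second matrix —
    p = (#{r* >= r} + 1)/(n_perm + 1) for ``greater`` (|r*| >= |r| for
    ``two-sided``). With ``exhaustive=True`` all n! permutations are
    enumerated and p is the exact proportion (identity included).
    """
    if dm1.labels != dm2.labels:
        raise ValidationError("distance matrices have different labels")
    n = len(dm1.labels)
    if n < 4:
        raise ValidationError("Mantel test needs at least 4 labels")
    tri = np.tril_indices(n, k=-1)
    v1 = dm1.d[tri]
    if v1.std() == 0 or dm2.d[tri].std() == 0:
        raise DegenerateInputError("zero-variance distance triangle; r undefined")
    v1 = (v1 - v1.mean()) / v1.std()

    def corr(mat: np.ndarray) -> float:
        v2 = mat[tri]
        v2 = (v2 - v2.mean()) / v2.std()
        return float((v1 * v2).mean())

    r_obs = corr(dm2.d)

    def bigger(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        if alternative == "two-sided":
            return abs(r_perm) >= abs(r_obs) - 1e-12
        raise ValidationError(f"unknown alternative {alternative!r}")

    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        hits = sum(bigger(corr(dm2.d[np.ix_(p, p)])) for p in perms)
        p_val = hits / math.factorial(n)
        n_used = math.factorial(n)
    else:
        rng = child_rng(seed, "mantel", property_name)
        hits = 0
        for _ in range(n_perm):
            p = rng.permutation(n)
            if bigger(corr(dm2.d[np.ix_(p, p)])):
                hits += 1
        p_val = (hits + 1) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(property=property_name, r=r_obs, p=float(p_val),
                        n_perm=n_used, alternative=alternative)


def adjust_pvalues(p_list, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: Benjamini-Hochberg (default), Holm, or
    Bonferroni, with monotonicity enforced by the step procedure."""
    p = np.asarray(p_list, float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    key = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValidationError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def mantel_table(
    soil: SoilTable,
    plot_scores: pd.DataFrame,
    properties: list[str] | None = None,
    n_perm: int = 9999,
    seed: int = 0,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Per-property Mantel tests against strategy composition, adjusted.

    The soil table is aligned to the plots present in ``plot_scores``.
    """
    strat = strategy_dissimilarity(plot_scores)
    soil_aligned = SoilTable(soil.values.loc[strat.labels])
    properties = properties or list(soil.values.columns)
    results = []
    for prop in properties:
        dm = soil_dissimilarity(soil_aligned, prop)
        results.append(mantel(dm, strat, n_perm=n_perm,
                              seed=child_seed(seed, "mantel", prop),
                              property_name=prop))
    adj = adjust_pvalues([r.p for r in results], method=adjust)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return pd.DataFrame(
        [
            {"property": r.property, "r": r.r, "p": r.p,
             "p_adjusted": r.p_adjusted, "n_perm": r.n_perm}
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# beta regression
# ---------------------------------------------------------------------------

@dataclass
class BetaRegressionFit:
    """Estimates of a logit-link beta regression with constant precision."""

    response: str
    covariate: str
    params: np.ndarray        # (intercept, slope) on the link scale
    bse: np.ndarray
    pvalues: np.ndarray       # Wald, mean submodel
    phi: float
    converged: bool
    llf: float
    n: int
    boundary_compressed: bool

    @property
    def slope(self) -> float:
        return float(self.params[1])

    def fitted_mean(self, x) -> np.ndarray:
        eta = self.params[0] + self.params[1] * np.asarray(x, float)
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["intercept", self.covariate, "phi"],
                "estimate": [*self.params, self.phi],
                "se": [*self.bse, np.nan],
                "p": [*self.pvalues, np.nan],
            }
        )


class BetaRegression:
    """Beta regression of a proportion on one covariate.

    Mean model logistic(b0 + b1 x) with constant precision phi, fitted by
    maximum likelihood (quasi-Newton from a least-squares-on-logit
    start). Responses on the boundary {0, 1} are compressed by the
    standard (y (n-1) + 0.5)/n shrinkage, which is logged and flagged.
    """

    def __init__(self, y, x, response: str = "y", covariate: str = "x") -> None:
        y = np.asarray(y, float)
        x = np.asarray(x, float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValidationError("y and x must be 1-D arrays of equal length")
        if len(y) < 5:
            raise ValidationError("beta regression needs at least 5 observations")
        if ((y < 0) | (y > 1)).any():
            raise ValidationError("responses must lie in [0, 1]")
        if np.ptp(x) == 0:
            raise DegenerateInputError(
                f"covariate {covariate!r} is constant; the slope is unidentifiable"
            )
        self.boundary_compressed = bool(((y == 0) | (y == 1)).any())
        if self.boundary_compressed:
            n = len(y)
            y = (y * (n - 1) + 0.5) / n
            logger.info("boundary responses compressed with (y(n-1)+0.5)/n")
        self.y, self.x = y, x
        self.response, self.covariate = response, covariate

    def _start_params(self) -> np.ndarray:
        z = np.log(self.y / (1 - self.y))
        X = np.column_stack([np.ones_like(self.x), self.x])
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ beta
        var = max(resid.var(), 1e-6)
        mu = 1 / (1 + np.exp(-(X @ beta)))
        # moment-style precision start: Var(y) ~ mu(1-mu)/(1+phi) on link scale
        phi0 = max(float(np.mean(mu * (1 - mu)) / var * 4.0), 1.0)
        return np.array([beta[0], beta[1], np.log(phi0)])

    def fit(self, maxiter: int = 200) -> BetaRegressionFit:
        X = np.column_stack([np.ones_like(self.x), self.x])
        model = BetaModel(self.y, X, exog_precision=np.ones((len(self.y), 1)))
        start = self._start_params()
        res = model.fit(start_params=start, method="bfgs", maxiter=maxiter, disp=False)
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged:
            res = model.fit(start_params=start, method="nm", maxiter=2000, disp=False)
            converged = bool(res.mle_retvals.get("converged", False))
        fit = BetaRegressionFit(
            response=self.response,
            covariate=self.covariate,
            params=np.asarray(res.params[:2], float),
            bse=np.asarray(res.bse[:2], float),
            pvalues=np.asarray(res.pvalues[:2], float),
            phi=float(np.exp(res.params[2])),
            converged=converged,
            llf=float(res.llf),
            n=len(self.y),
            boundary_compressed=self.boundary_compressed,
        )
        if not converged:
            raise ConvergenceError(
                f"beta regression of {self.response} on {self.covariate} did not "
                f"converge (llf={fit.llf:.3f}); inspect the data or rescale x"
            )
        return fit


def significant_properties(table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """The logic gate between Mantel screening and beta regression: only
    properties with adjusted p < alpha proceed."""
    return list(table.loc[table["p_adjusted"] < alpha, "property"])
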