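"""Taxonomic diversity: richness, Shannon H' and Whittaker beta turnover."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CommunityMatrix
from .errors import DegenerateInputError, ValidationError


def shannon(abundances, base: float | None = None) -> float:
    """Shannon-Wiener index H' = -sum p_i ln p_i (natural log by default)."""
    a = np.asarray(abundances, float)
    if (a < 0).any() or not np.isfinite(a).all():
        raise ValidationError("abundances must be finite and non-negative")
    total = a.sum()
    if total == 0:
        raise DegenerateInputError("Shannon index undefined for an empty community")
    p = a[a > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def whittaker_beta(plot_species_sets: list[set] | list[list], variant: str = "ratio_minus_one") -> float:
    """Whittaker beta diversity across the plots of one stage.

    beta_w = gamma / alpha-bar - 1 by default (0 for identical plots);
    ``variant="ratio"`` gives the plain gamma / alpha-bar form.
    """
    sets = [set(s) for s in plot_species_sets]
    if len(sets) < 2:
        raise DegenerateInputError("Whittaker beta needs at least two plots")
    if any(len(s) == 0 for s in sets):
        raise ValidationError("empty plot in Whittaker beta")
    gamma = len(set().union(*sets))
    alpha = float(np.mean([len(s) for s in sets]))
    ratio = gamma / alpha
    if variant == "ratio_minus_one":
        return ratio - 1.0
    if variant == "ratio":
        return ratio
    raise ValidationError(f"unknown Whittaker variant {variant!r}")


def diversity_table(community: CommunityMatrix, base: float | None = None) -> pd.DataFrame:
    """Per-plot richness and H' with the plot's stage attached."""
    rows = []
    for plot in community.plots:
        a = community.abundance.loc[plot].to_numpy()
        rows.append(
            {
                "plot_id": plot,
                "stage": community.stage_of(plot),
                "richness": int((a > 0).sum()),
                "shannon": shannon(a, base=base),
            }
        )
    return pd.DataFrame(rows)


def stage_summary(community: CommunityMatrix, base: float | None = None,
                  beta_variant: str = "ratio_minus_one") -> pd.DataFrame:
    """Stage-level mean +/- SE of richness and H', plus Whittaker beta."""
    per_plot = diversity_table(community, base=base)
    rows = []
    for stage, grp in per_plot.groupby("stage"):
        sets = [set(community.species_in_plot(p)) for p in grp["plot_id"]]
        n = len(grp)
        rows.append(
            {
                "stage": stage,
                "n_plots": n,
                "richness_mean": grp["richness"].mean(),
                "richness_se": grp["richness"].std(ddof=1) / np.sqrt(n),
                "shannon_mean": grp["shannon"].mean(),
                "shannon_se": grp["shannon"].std(ddof=1) / np.sqrt(n),
                "whittaker_beta": whittaker_beta(sets, variant=beta_variant),
            }
        )
    return pd.DataFrame(rows)
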