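"""Grime C-S-R strategy scores from the three establishment leaf traits.

Each individual (or species mean) is placed on the 100% C+S+R simplex
from LA, SLA and LDMC via a calibration file: monotone transforms per
trait (square root for leaf size, log for SLA, logit for LDMC), z-scoring
against the calibration's reference distribution, a linear map to raw
C/S/R components, then clip-negatives-to-zero and renormalize to 100.

The bundled default calibration is synthetic (constructed for this
package, direction-level only — see the file header); any calibration
with the same YAML layout can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit

from .data import LeafRecordSet
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger("traitassembly")

_COMPONENTS = ("C", "S", "R")


@dataclass
class CSRCalibration:
    """Transform + mapping coefficients loaded from a calibration file."""

    name: str
    transforms: dict[str, dict]
    economy: dict[str, float]
    mapping: dict[str, dict[str, float]]
    z_clip: float

    @classmethod
    def from_file(cls, path: str | Path) -> "CSRCalibration":
        raw = yaml.safe_load(Path(path).read_text())
        return cls._from_dict(raw)

    @classmethod
    def default(cls) -> "CSRCalibration":
        ref = resources.files("traitassembly") / "calibrations" / "csr_global_synthetic.yml"
        return cls._from_dict(yaml.safe_load(ref.read_text()))

    @classmethod
    def _from_dict(cls, raw: dict) -> "CSRCalibration":
        try:
            return cls(
                name=raw["name"],
                transforms=raw["transforms"],
                economy=raw["axes"]["economy"],
                mapping=raw["mapping"],
                z_clip=float(raw["domain"]["z_clip"]),
            )
        except KeyError as exc:
            raise ValidationError(f"calibration file missing key {exc}") from exc

    def to_file(self, path: str | Path) -> None:
        payload = {
            "version": 1,
            "name": self.name,
            "transforms": self.transforms,
            "axes": {"economy": self.economy},
            "mapping": self.mapping,
            "domain": {"z_clip": self.z_clip},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    # -- evaluation -------------------------------------------------------
    def _z(self, trait: str, x: np.ndarray) -> np.ndarray:
        spec = self.transforms[trait]
        kind = spec["type"]
        if kind == "sqrt":
            t = np.sqrt(x)
        elif kind == "log":
            t = np.log(x)
        elif kind == "logit":
            t = logit(x)
        else:
            raise ValidationError(f"unknown transform {kind!r} for {trait}")
        return (t - spec["center"]) / spec["scale"]


def csr_score(
    la,
    sla,
    ldmc,
    calibration: CSRCalibration | None = None,
) -> pd.DataFrame:
    """C/S/R percentages for each (LA, SLA, LDMC) input.

    Returns a DataFrame with columns C, S, R summing to exactly 100 and an
    ``out_of_domain`` flag for inputs whose transformed values had to be
    clamped to the calibration's stated domain.
    """
    cal = calibration or CSRCalibration.default()
    la = np.atleast_1d(np.asarray(la, float))
    sla = np.atleast_1d(np.asarray(sla, float))
    ldmc = np.atleast_1d(np.asarray(ldmc, float))
    if not ((la > 0).all() and (sla > 0).all()):
        raise ValidationError("LA and SLA must be positive")
    if not ((ldmc > 0) & (ldmc < 1)).all():
        raise ValidationError("LDMC must lie in (0,1); convert percentages first")

    z = {t: cal._z(t, x) for t, x in (("la", la), ("sla", sla), ("ldmc", ldmc))}
    clipped = np.zeros(len(la), dtype=bool)
    for t in z:
        out = np.abs(z[t]) > cal.z_clip
        if out.any():
            logger.warning("%d %s values outside calibration domain; clamped", out.sum(), t)
            clipped |= out
            z[t] = np.clip(z[t], -cal.z_clip, cal.z_clip)

    e = sum(cal.economy[t] * z[t] for t in cal.economy)
    raw = {}
    for comp in _COMPONENTS:
        m = cal.mapping[comp]
        raw[comp] = (m["intercept"] + m["size"] * z["la"]
                     + m["economy"] * e + m["abs_economy"] * np.abs(e))
    return _close_simplex(raw, clipped)


def _close_simplex(raw: dict[str, np.ndarray], flagged: np.ndarray) -> pd.DataFrame:
    """Clip negative raw components to zero and renormalize to sum 100."""
    arr = np.column_stack([np.clip(raw[c], 0.0, None) for c in _COMPONENTS])
    total = arr.sum(axis=1)
    degenerate = total <= 0
    if degenerate.any():  # all components clipped away: no direction left
        arr[degenerate] = 1.0
        total = arr.sum(axis=1)
        flagged = flagged | degenerate
    scores = 100.0 * arr / total[:, None]
    out = pd.DataFrame(scores, columns=list(_COMPONENTS))
    out["out_of_domain"] = flagged
    return out


def score_leaf_records(
    leaf: LeafRecordSet,
    calibration: CSRCalibration | None = None,
) -> pd.DataFrame:
    """Per-individual CSR scores with stage/plot/species metadata attached."""
    df = leaf.records
    scores = csr_score(df["la"], df["sla"], df["ldmc"], calibration)
    return pd.concat(
        [df[["stage", "plot_id", "species"]].reset_index(drop=True), scores], axis=1
    )


def stage_mean_strategy(
    scores: pd.DataFrame,
    weights: pd.Series | dict | None = None,
    by: str = "stage",
) -> pd.DataFrame:
    """Mean (C, S, R) per stage (or per plot), renormalized to 100.

    Unweighted arithmetic mean by default; ``weights`` (e.g. relative
    abundances keyed like the group units) enables a weighted mean.
    """
    if scores.empty:
        raise DegenerateInputError("no CSR scores to average")
    rows = []
    for key, grp in scores.groupby(by):
        if weights is None:
            w = np.ones(len(grp))
        else:
            w = np.asarray([weights[k] for k in grp.index], float)
        w = w / w.sum()
        mean = {c: float((grp[c] * w).sum()) for c in _COMPONENTS}
        total = sum(mean.values())
        rows.append({by: key, **{c: 100.0 * mean[c] / total for c in _COMPONENTS}})
    return pd.DataFrame(rows)


def plot_mean_strategy(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-plot mean CSR composition (unweighted over individuals)."""
    return stage_mean_strategy(scores, by="plot_id")


def ternary_coordinates(scores: pd.DataFrame) -> pd.DataFrame:
    """2-D ternary projection: C at the top vertex, S bottom-left, R
    bottom-right: x = (2R + C) / (2 total), y = sqrt(3)/2 * C / total."""
    total = scores[list(_COMPONENTS)].sum(axis=1)
    x = 0.5 * (2 * scores["R"] + scores["C"]) / total
    y = (np.sqrt(3) / 2.0) * scores["C"] / total
    return pd.DataFrame({"x": x, "y": y})
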