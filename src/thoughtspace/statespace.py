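"""Locating brain maps in a gradient-based neural state space.

The state space is spanned by k macroscale connectivity gradients (k=5 in
the analyses this package supports): each parcel of a cortical atlas has a
value on every gradient.  Any parcel-resolved brain map can then be located
in the space by computing its Spearman rank correlation with each gradient;
the resulting k correlations act as coordinates in [-1, 1].
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "YEO7_NETWORKS",
    "GradientSet",
    "StateSpaceProjection",
    "compute_coordinates",
    "coordinates_table",
    "group_average_location",
    "network_summary",
]

#: Canonical 7-network cortical parcellation labels.
YEO7_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)


class StateSpaceError(ValueError):
    """Raised for invalid state-space inputs (overlap, constant maps...)."""


@dataclasses.dataclass
class GradientSet:
    """Reference gradient values over parcels, with 7-network labels.

    Parameters
    ----------
    values : DataFrame, shape (n_parcels, k)
        Gradient values; index holds parcel ids, columns are gradient names
        ordered by the connectivity variance they explain (descending).
    networks : Series
        One of the seven network labels per parcel, aligned with ``values``.
    provenance : str
        Free-text origin of the maps (deposit id, simulator seed, ...).
    """

    values: pd.DataFrame
    networks: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise StateSpaceError("gradient values contain missing entries")
        if self.values.shape[1] < 1:
            raise StateSpaceError("need at least one gradient")
        self.networks = self.networks.reindex(self.values.index)
        if self.networks.isna().any():
            missing = self.networks.index[self.networks.isna()][:5].tolist()
            raise StateSpaceError(f"network labels missing for parcels {missing}")

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def parcel_ids(self) -> pd.Index:
        return self.values.index

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out["network"] = self.networks
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "GradientSet":
        if "network" not in frame.columns:
            raise StateSpaceError("expected a 'network' column")
        values = frame.drop(columns="network").astype(float)
        return cls(values=values, networks=frame["network"], provenance=provenance)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="parcel_id")

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "GradientSet":
        frame = pd.read_csv(path, sep="\t", index_col="parcel_id")
        return cls.from_frame(frame, provenance=provenance or str(path))


def _align(map_values: pd.Series, gradients: GradientSet) -> tuple[np.ndarray, np.ndarray]:
    """Align a map with the gradients by parcel id, pairwise-complete."""
    shared = map_values.dropna().index.intersection(gradients.parcel_ids)
    if len(shared) < 3:
        raise StateSpaceError(
            f"only {len(shared)} shared parcels between map and gradients; need >= 3"
        )
    return map_values.loc[shared].to_numpy(float), gradients.values.loc[shared].to_numpy(float)


def compute_coordinates(map_values: pd.Series, gradients: GradientSet) -> pd.Series:
    """Spearman-correlate one brain map with every gradient.

    Parcel alignment is by id (never by positional order); ties receive
    average ranks.  Returns one rho per gradient, indexed by gradient name.
    """
    x, g = _align(map_values, gradients)
    if np.ptp(x) == 0:
        raise StateSpaceError("map is constant over shared parcels; rho undefined")
    rx = stats.rankdata(x)
    rg = np.apply_along_axis(stats.rankdata, 0, g)
    rx = rx - rx.mean()
    rg = rg - rg.mean(axis=0)
    denom = np.sqrt((rx**2).sum() * (rg**2).sum(axis=0))
    rho = rg.T @ rx / denom
    return pd.Series(rho, index=gradients.values.columns, name=map_values.name)


class StateSpaceProjection(BaseEstimator, TransformerMixin):
    """Transformer mapping parcel maps to gradient-space coordinates.

    ``fit`` stores the gradient basis; ``transform`` takes a DataFrame of
    maps (rows = parcels, columns = one map each) and returns their
    coordinates (rows = maps, columns = gradients).  Composes with sklearn
    pipelines operating on parcel-indexed frames.
    """

    def fit(self, gradients: GradientSet, y=None) -> "StateSpaceProjection":
        if not isinstance(gradients, GradientSet):
            raise TypeError("fit expects a GradientSet")
        self.gradients_ = gradients
        self.n_features_in_ = len(gradients.parcel_ids)
        return self

    def transform(self, maps: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "gradients_"):
            raise RuntimeError("StateSpaceProjection is not fitted")
        rows = {name: compute_coordinates(col, self.gradients_) for name, col in maps.items()}
        return pd.DataFrame(rows).T


def coordinates_table(
    maps: Mapping[str, pd.DataFrame] | pd.DataFrame, gradients: GradientSet
) -> pd.DataFrame:
    """Tidy coordinates for a cohort of maps.

    ``maps`` is either a DataFrame with MultiIndex columns
    (condition, subject) or a mapping condition -> (parcels x subjects)
    frame.  Returns tidy rows (subject, condition, dimension, rho).
    """
    if isinstance(maps, pd.DataFrame):
        items = {cond: maps[cond] for cond in maps.columns.get_level_values(0).unique()}
    else:
        items = dict(maps)
    records = []
    for condition, frame in items.items():
        for subject, col in frame.items():
            rho = compute_coordinates(col, gradients)
            for dim, value in rho.items():
                records.append(
                    {"subject": subject, "condition": condition, "dimension": dim, "rho": value}
                )
    return pd.DataFrame.from_records(records)


def group_average_location(
    coords: pd.DataFrame, condition: str, confidence: float = 0.95
) -> pd.DataFrame:
    """Mean coordinate per dimension with normal-theory CIs across subjects.

    ``coords`` is the tidy table from :func:`coordinates_table`.  With a
    single subject the mean is that subject's coordinates and the CI columns
    are NaN (flagged undefined).
    """
    sub = coords[coords["condition"] == condition]
    if sub.empty:
        known = sorted(coords["condition"].unique().tolist())
        raise KeyError(f"unknown condition {condition!r}; have {known}")
    rows = []
    for dim, grp in sub.groupby("dimension", sort=False):
        vals = grp["rho"].to_numpy(float)
        n = len(vals)
        mean = vals.mean()
        if n > 1:
            se = vals.std(ddof=1) / np.sqrt(n)
            zcrit = stats.norm.ppf(0.5 + confidence / 2)
            lo, hi = mean - zcrit * se, mean + zcrit * se
        else:
            lo = hi = np.nan
        rows.append({"dimension": dim, "mean": mean, "ci_low": lo, "ci_high": hi, "n": n})
    return pd.DataFrame(rows).set_index("dimension")


def network_summary(
    values: pd.Series, gradients: GradientSet, standardize: bool = False
) -> pd.Series:
    """Average a parcel map (or one gradient) within each of the 7 networks.

    When ``standardize`` is set the 7 network means are z-scored across
    networks (population sd), matching radar-plot style summaries where maps
    on different scales are compared.  Networks with no parcels are reported
    as NaN (missing), never as zero.
    """
    aligned = values.reindex(gradients.parcel_ids)
    means = aligned.groupby(gradients.networks).mean()
    means = means.reindex([n for n in YEO7_NETWORKS if n in set(gradients.networks)] or means.index)
    # keep any non-canonical labels too, appended in sorted order
    extra = [n for n in means.index if n not in YEO7_NETWORKS]
    means = means.reindex([n for n in YEO7_NETWORKS if n in means.index] + sorted(extra))
    if standardize:
        sd = means.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise StateSpaceError("network means are constant; standardized summary undefined")
        means = (means - means.mean()) / sd
    means.name = getattr(values, "name", None)
    return means
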