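"""Extreme agers and e-ageotypes.

A subject is an *extreme ager* when any model's z-scored age gap exceeds
2 in absolute value. Extreme agers are clustered by k-means (default
k=13) after setting sub-threshold gap entries to zero, each cluster is
labelled by the model with the largest mean z-gap within it, and subjects
extreme in at least 5 models are overridden to the multi-organ label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

MULTI_ORGAN_LABEL = "multi-organ"


@dataclass
class AgeotypeConfig:
    z_threshold: float = 2.0
    k_clusters: int = 13
    multi_organ_min: int = 5
    seed: int = 0
    n_restarts: int = 10
    #: False (default): zero entries with |z| below the threshold before
    #: clustering. True: the alternative reading that zeroes the extremes
    #: instead (destroys the clustering signal; kept only for comparison).
    truncate_extremes: bool = False

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")


def flag_extreme_agers(
    zgaps_wide: pd.DataFrame, config: AgeotypeConfig | None = None
) -> pd.DataFrame:
    """Per-model extreme flags (+1 old / -1 young / 0) and the any-model flag.

    ``zgaps_wide`` is subjects x models of z-scored gaps (no missing
    entries allowed).
    """
    config = config or AgeotypeConfig()
    if zgaps_wide.isna().any().any():
        bad = list(zgaps_wide.columns[zgaps_wide.isna().any()])
        raise ValueError(f"missing z-gap values in model columns {bad}")
    z = zgaps_wide.to_numpy(dtype=float)
    flags = np.where(z > config.z_threshold, 1, np.where(z < -config.z_threshold, -1, 0))
    out = pd.DataFrame(flags, index=zgaps_wide.index, columns=zgaps_wide.columns)
    out["is_extreme_ager"] = (flags != 0).any(axis=1)
    return out


def truncate_gaps(zgaps_wide: pd.DataFrame, config: AgeotypeConfig) -> pd.DataFrame:
    z = zgaps_wide.to_numpy(dtype=float).copy()
    if config.truncate_extremes:
        z[np.abs(z) >= config.z_threshold] = 0.0
    else:
        z[np.abs(z) < config.z_threshold] = 0.0
    return pd.DataFrame(z, index=zgaps_wide.index, columns=zgaps_wide.columns)


def cluster_ageotypes(
    zgaps_wide: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    config: AgeotypeConfig | None = None,
) -> pd.DataFrame:
    """Cluster extreme agers and label each subject's e-ageotype.

    Returns a DataFrame indexed like ``zgaps_wide`` with columns
    ``is_extreme_ager``, ``cluster`` (nullable int; non-extreme subjects
    have no cluster), ``label`` (organ name, "multi-organ", an
    "<organ> (youth)" tag for purely negative outliers, or None) and
    ``n_extreme_models``.
    """
    config = config or AgeotypeConfig()
    if flags is None:
        flags = flag_extreme_agers(zgaps_wide, config)
    model_cols = list(zgaps_wide.columns)
    extreme = flags["is_extreme_ager"].to_numpy()
    n_extreme = int(extreme.sum())
    if n_extreme < config.k_clusters:
        raise ValueError(
            f"{n_extreme} extreme agers but k={config.k_clusters}; use a smaller k"
        )
    trunc = truncate_gaps(zgaps_wide.loc[extreme], config)
    km = KMeans(
        n_clusters=config.k_clusters,
        n_init=config.n_restarts,
        random_state=config.seed,
    ).fit(trunc.to_numpy())

    # cluster label = model with largest mean z within the cluster
    cluster_labels = {}
    for c in range(config.k_clusters):
        members = trunc.to_numpy()[km.labels_ == c]
        cluster_labels[c] = model_cols[int(members.mean(axis=0).argmax())]

    out = pd.DataFrame(index=zgaps_wide.index)
    out["is_extreme_ager"] = extreme
    cluster = np.full(len(out), -1)
    cluster[extreme] = km.labels_
    out["cluster"] = pd.array([c if c >= 0 else None for c in cluster], dtype="Int64")
    flag_mat = flags[model_cols].to_numpy()
    out["n_extreme_models"] = (flag_mat != 0).sum(axis=1)

    labels: list = []
    z = zgaps_wide.to_numpy(dtype=float)
    for i in range(len(out)):
        if not extreme[i]:
            labels.append(None)
            continue
        if out["n_extreme_models"].iloc[i] >= config.multi_organ_min:
            labels.append(MULTI_ORGAN_LABEL)  # manual override after clustering
        elif (flag_mat[i] <= 0).all():
            # purely negative outlier: tag the dominant youthful organ
            labels.append(f"{model_cols[int(np.abs(z[i]).argmax())]} (youth)")
        else:
            labels.append(cluster_labels[int(out['cluster'].iloc[i])])
    out["label"] = labels
    return out
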