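"""Product-profile fingerprinting: normalization, DP aggregation, clustering.

Per-sample intensities are normalized to the most abundant compound in that
sample, so that clustering compares product fingerprints rather than overall
activity.  Samples within a (substrate, time) stratum are clustered by
complete-linkage hierarchical clustering on Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .composition import CompositionError, parse_name
from .identify import SampleProfile


@dataclass
class NormalizedProfile:
    enzyme: str
    substrate: str
    time_min: float
    values: dict[str, float] = field(default_factory=dict)
    all_zero: bool = False

    @property
    def key(self):
        return (self.enzyme, self.substrate, self.time_min)


def normalize(profile: SampleProfile) -> NormalizedProfile:
    """Divide every intensity by the sample maximum.

    An all-zero profile is passed through unchanged and flagged rather than
    divided.  Negative intensities are rejected.
    """
    vals = profile.intensities
    if any(v < 0 for v in vals.values()):
        raise CompositionError("negative intensity in profile")
    peak = max(vals.values(), default=0.0)
    if peak == 0.0:
        return NormalizedProfile(*profile.key, dict(vals), all_zero=True)
    return NormalizedProfile(*profile.key, {k: v / peak for k, v in vals.items()})


def aggregate_by_dp(profile: NormalizedProfile, split_acetyl: bool = True) -> dict:
    """Sum normalized intensities per degree of polymerization.

    With ``split_acetyl`` each DP is divided into a non-acetylated bin
    (dp, False) and an acetylated bin (dp, True); isomers of one composition
    are summed.  Keys must parse as compound labels.
    """
    out: dict = {}
    for label, value in profile.values.items():
        try:
            comp, _ = parse_name(label)
        except CompositionError as exc:
            raise CompositionError(f"unparseable profile key {label!r}") from exc
        key = (comp.dp, comp.n_acetyl >= 1) if split_acetyl else (comp.dp, False)
        out[key] = out.get(key, 0.0) + value
    return out


@dataclass
class ProfileMatrix:
    """Rectangular samples x compounds matrix of normalized values."""

    frame: pd.DataFrame  # index: sample labels; columns: compounds/bins

    @classmethod
    def from_profiles(cls, profiles: list[NormalizedProfile], columns=None) -> "ProfileMatrix":
        rows = {f"{p.enzyme}|{p.substrate}|{p.time_min:g}": p.values for p in profiles}
        frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
        if columns is not None:
            frame = frame.reindex(columns=list(columns), fill_value=0.0)
        # Lexicographic row order makes downstream tie-breaking reproducible.
        return cls(frame.sort_index())


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]  # sample labels in dendrogram order


def cluster_samples(matrix: ProfileMatrix) -> ClusterResult:
    """Complete-linkage hierarchical clustering on Euclidean distances.

    Requires at least two rows of equal length (the matrix is rectangular by
    construction).  Rows are pre-sorted lexicographically so the dendrogram
    leaf order is deterministic under distance ties.
    """
    frame = matrix.frame
    if frame.shape[0] < 2:
        raise CompositionError("clustering needs at least 2 samples")
    if frame.isna().any().any():
        raise CompositionError("profile matrix contains missing values")
    linkage = hierarchy.linkage(pdist(frame.to_numpy(), metric="euclidean"), method="complete")
    order = hierarchy.leaves_list(linkage)
    return ClusterResult(linkage, [frame.index[i] for i in order])


def export_heatmap_table(matrix: ProfileMatrix, clustering: ClusterResult) -> pd.DataFrame:
    """Rows reordered by dendrogram leaf order; values untransformed."""
    return matrix.frame.loc[clustering.leaf_order]


def cluster_strata(
    profiles: list[NormalizedProfile], cross_strata: bool = False
) -> dict[tuple, tuple[ProfileMatrix, ClusterResult | None]]:
    """Cluster samples within each (substrate, time) stratum.

    With ``cross_strata`` a single clustering over all samples is returned
    under the key ("all", "all").  Strata with a single sample get a matrix
    but no clustering.
    """
    if cross_strata:
        matrix = ProfileMatrix.from_profiles(profiles)
        return {("all", "all"): (matrix, cluster_samples(matrix))}
    strata: dict[tuple, list[NormalizedProfile]] = {}
    for p in profiles:
        strata.setdefault((p.substrate, p.time_min), []).append(p)
    out = {}
    for key, group in sorted(strata.items()):
        matrix = ProfileMatrix.from_profiles(group)
        result = cluster_samples(matrix) if matrix.frame.shape[0] >= 2 else None
        out[key] = (matrix, result)
    return out


def linkage_table(result: ClusterResult) -> pd.DataFrame:
    """Linkage matrix as a tidy merge-step table."""
    z = result.linkage
    return pd.DataFrame(
        {
            "step": np.arange(1, z.shape[0] + 1),
            "member_a": z[:, 0].astype(int),
            "member_b": z[:, 1].astype(int),
            "height": z[:, 2],
            "cluster_size": z[:, 3].astype(int),
        }
    )
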