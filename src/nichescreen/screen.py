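"""Screen-level analysis: percent change, Blom scores, clustering, hit rules.

Per compound the six phenotypic parameters are averaged over replicate
wells and expressed as the percentage change (drug - control) / control
against the plate's control-well mean.  Each parameter column is then
normalized to rank-based normal scores (Blom's method,
Phi^-1((r - 3/8) / (n + 1/4)), average ranks for ties) and compounds are
hierarchically clustered with Euclidean distance and centroid linkage.
Flat clusters are classified by the screen's selection rules on the raw
percent changes:

* excluded   — pan-cytotoxic: >80% inhibition of total CSCs, colony count
               and total colony cells simultaneously;
* anti_CSC   — substantial CSC inhibition without colony-parameter
               increase and |mean CAF change| < 15%;
* anti_CAF   — substantial CAF inhibition, not pan-cytotoxic;
* neutral    — otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import norm, rankdata

from .imaging import WellPhenotype

__all__ = [
    "DegenerateControlError",
    "percent_change",
    "summarize_screen",
    "blom_normalize",
    "normalize_matrix",
    "ClusterTree",
    "cluster_compounds",
    "cut_clusters",
    "HitRules",
    "HitSelection",
    "select_hits",
    "tree_to_newick",
]

PARAMETERS = list(WellPhenotype.PARAMETERS)


class DegenerateControlError(ValueError):
    """Control mean of a parameter is zero: percent change undefined."""


def percent_change(drug_mean: float, control_mean: float,
                   parameter: str = "", well: str = "") -> float:
    """(drug - control) / control, as a signed fraction."""
    if control_mean == 0:
        where = f" for parameter '{parameter}'" if parameter else ""
        at = f" (well {well})" if well else ""
        raise DegenerateControlError(f"control mean is zero{where}{at}")
    return (drug_mean - control_mean) / control_mean


def summarize_screen(
    phenotypes: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Replicate means and percent change vs the plate control mean.

    ``phenotypes`` holds one row per well with the six parameter columns;
    ``annotation`` maps wells to compounds and roles.  Controls are averaged
    over all control wells.  Returns compounds x parameters of percent
    change (fractions).
    """
    merged = annotation.merge(phenotypes, on="well", validate="one_to_one")
    controls = merged[merged["role"] == "control"]
    if controls.empty:
        raise ValueError("no control wells in the annotation")
    treated = merged[merged["role"] != "control"]
    dup = treated.groupby("compound")["replicate"].apply(lambda s: s.duplicated().any())
    if dup.any():
        raise ValueError(f"duplicated replicates for compounds: {list(dup[dup].index)}")
    control_mean = controls[PARAMETERS].mean()
    comp_mean = treated.groupby("compound")[PARAMETERS].mean()
    out = pd.DataFrame(index=comp_mean.index, columns=PARAMETERS, dtype=float)
    for p in PARAMETERS:
        for comp, value in comp_mean[p].items():
            out.loc[comp, p] = percent_change(value, control_mean[p], parameter=p)
    return out


def blom_normalize(column) -> np.ndarray:
    """Blom normal scores: Phi^-1((r - 3/8) / (n + 1/4)), average-rank ties."""
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty 1-D column")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in column")
    r = rankdata(x, method="average")
    return norm.ppf((r - 0.375) / (x.size + 0.25))


def normalize_matrix(pct: pd.DataFrame) -> pd.DataFrame:
    """Blom-normalize each parameter column of a percent-change matrix."""
    out = pct.copy()
    for col in out.columns:
        out[col] = blom_normalize(out[col].to_numpy())
    return out


@dataclass
class ClusterTree:
    """Centroid-linkage merge history plus the compound labels."""

    linkage: np.ndarray  # scipy linkage matrix (n-1 x 4)
    labels: list[str]
    has_inversions: bool = False

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_compounds(matrix: pd.DataFrame) -> ClusterTree:
    """Agglomerative clustering, Euclidean distance and centroid linkage.

    Heights are Euclidean distances between cluster centroids.  Centroid
    linkage can produce inversions (a merge lower than an earlier one);
    these are retained and flagged, not reordered.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 compounds to cluster")
    X = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("missing values in the normalized matrix")
    Z = hierarchy.linkage(X, method="centroid")
    inversions = bool(np.any(np.diff(Z[:, 2]) < -1e-12))
    return ClusterTree(Z, list(matrix.index), has_inversions=inversions)


def cut_clusters(
    tree: ClusterTree,
    n_clusters: int | None = None,
    height: float | None = None,
) -> pd.Series:
    """Flat cluster assignment.

    Default cut: below the largest *relative* jump between consecutive merge
    heights, which isolates groups of near-identical profiles (the natural
    cut when replicate noise is small against between-compound differences).
    A fixed cluster count or explicit cut height overrides it.
    """
    Z = tree.linkage
    if height is not None:
        assign = hierarchy.fcluster(Z, t=height, criterion="distance")
    elif n_clusters is not None:
        assign = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        h = np.sort(Z[:, 2])
        hmax = h[-1]
        if hmax <= 0:
            assign = np.ones(tree.n_leaves, dtype=int)
        else:
            eps = 1e-9 * hmax
            levels = np.concatenate([[0.0], h])
            ratios = (levels[1:] + eps) / (levels[:-1] + eps)
            k = int(np.argmax(ratios))  # cut between levels[k] and levels[k+1]
            t = 0.5 * (levels[k] + levels[k + 1])
            assign = hierarchy.fcluster(Z, t=t, criterion="distance")
    return pd.Series(assign, index=tree.labels, name="cluster")


@dataclass(frozen=True)
class HitRules:
    """Thresholds of the selection rules (fractions of control).

    ``pan_tox_inhibition``: clusters inhibiting total CSCs, colony count and
    total colony cells each by more than this are excluded as nonselective.
    ``max_caf_change``: anti-CSC clusters must keep |mean CAF change| below
    this.  ``min_effect`` is the minimum mean inhibition counted as a real
    effect rather than replicate noise (the assay protocol names no magnitude).
    """

    pan_tox_inhibition: float = 0.80
    max_caf_change: float = 0.15
    min_effect: float = 0.20


@dataclass
class HitSelection:
    """Classification of one flat cluster with the triggering rule."""

    cluster: int
    compounds: list[str]
    classification: str  # anti_CAF | anti_CSC | excluded | neutral
    rule: str
    mean_change: dict[str, float] = field(default_factory=dict)


def _classify(mean: pd.Series, rules: HitRules) -> tuple[str, str]:
    csc = mean["total_cscs"]
    colony = mean["colony_count"]
    ccells = mean["total_colony_cells"]
    density = mean["colony_density"]
    caf = mean["total_cafs"]
    thr = -rules.pan_tox_inhibition
    if csc <= thr and colony <= thr and ccells <= thr:
        return "excluded", (
            f"pan-cytotoxic: total CSCs, colony and total colony cells all "
            f"inhibited > {rules.pan_tox_inhibition:.0%}"
        )
    anti_csc = (
        csc <= -rules.min_effect
        and colony < rules.min_effect
        and ccells < rules.min_effect
        and density < rules.min_effect
        and abs(caf) < rules.max_caf_change
    )
    if anti_csc:
        return "anti_CSC", (
            f"total CSCs inhibited >= {rules.min_effect:.0%}, colony parameters "
            f"not increased, |mean CAF change| < {rules.max_caf_change:.0%}"
        )
    if caf <= -rules.min_effect:
        return "anti_CAF", (
            f"total CAFs inhibited >= {rules.min_effect:.0%} and not pan-cytotoxic"
        )
    return "neutral", "no rule triggered"


def select_hits(
    tree: ClusterTree,
    pct: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
    rules: HitRules | None = None,
) -> list[HitSelection]:
    """Classify flat clusters on their mean raw percent changes.

    The >80% / <15% rules speak in percentages of control, so they are
    evaluated on raw percent change, not on the Blom scores used for
    clustering.
    """
    rules = rules or HitRules()
    assign = cut_clusters(tree, n_clusters=n_clusters, height=height)
    results: list[HitSelection] = []
    for cl in sorted(assign.unique()):
        members = list(assign.index[assign == cl])
        if not members:
            raise ValueError(f"empty cluster {cl}")
        mean = pct.loc[members, PARAMETERS].mean()
        label, rule = _classify(mean, rules)
        results.append(
            HitSelection(
                cluster=int(cl),
                compounds=members,
                classification=label,
                rule=rule,
                mean_change={p: float(mean[p]) for p in PARAMETERS},
            )
        )
    return results


def hits_to_frame(hits: list[HitSelection]) -> pd.DataFrame:
    rows = []
    for h in hits:
        for comp in h.compounds:
            rows.append({
                "compound": comp, "cluster": h.cluster,
                "classification": h.classification, "rule": h.rule,
                **{f"mean_{k}": v for k, v in h.mean_change.items()},
            })
    return pd.DataFrame(rows)


def tree_to_newick(tree: ClusterTree) -> str:
    """Serialize the dendrogram as newick with branch lengths.

    Branch lengths are parent height minus child height, clipped at 0 for
    centroid-linkage inversions.
    """
    root = hierarchy.to_tree(tree.linkage)

    def rec(node) -> str:
        if node.is_leaf():
            return str(tree.labels[node.id]).replace(" ", "_")
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            length = max(0.0, node.dist - (0.0 if child.is_leaf() else child.dist))
            parts.append(f"{rec(child)}:{length:.6g}")
        return f"({','.join(parts)})"

    return rec(root) + ";"
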