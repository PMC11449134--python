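"""Similarity clustering of band-power dynamics across tasks and DMN subsystems.

Ten variables are tracked: {theta, gamma} x {MW, AUT} x {dorsomedial,
lateral} (eight task/node combinations) plus the overall theta and overall
gamma dynamics (means over the four variables of the band).  Observations
concatenate the 29-bin time courses of both task stages across subjects, so
n_subjects complete subjects yield n_subjects x 2 x 29 observations per
variable.  Distance is 1 - Pearson correlation, agglomeration is complete
linkage, and cluster reliability is the plain bootstrap probability: the
fraction of row-resampled replicate trees containing a cluster with identical
leaf membership.  (The approximately-unbiased correction of multiscale
bootstrap is deliberately not implemented.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import ValidationError

logger = logging.getLogger(__name__)

VARIABLE_ORDER = [
    "theta_MW_dorsomedial", "theta_MW_lateral",
    "theta_AUT_dorsomedial", "theta_AUT_lateral",
    "gamma_MW_dorsomedial", "gamma_MW_lateral",
    "gamma_AUT_dorsomedial", "gamma_AUT_lateral",
    "theta_overall", "gamma_overall",
]


@dataclass
class VariableMatrix:
    """Observations x variables matrix with its (subject, stage, bin) index."""

    values: np.ndarray
    var_names: list[str]
    obs_index: pd.DataFrame
    dropped_subjects: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]


@dataclass
class Dendrogram:
    """Complete-linkage merge tree; ``bp`` holds one bootstrap probability per
    internal node (ordered as the linkage rows), or None before resampling."""

    Z: np.ndarray
    labels: list[str]
    bp: np.ndarray | None = None

    def clusters(self) -> list[frozenset]:
        """Leaf-label membership of every internal node, in linkage order."""
        n = len(self.labels)
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for row_i, (a, b, _, _) in enumerate(self.Z):
            merged = members[int(a)] | members[int(b)]
            members[n + row_i] = merged
            out.append(merged)
        return out

    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


def build_variable_matrix(table: pd.DataFrame) -> VariableMatrix:
    """Electrode-averaged observation vectors per variable.

    Only subjects with electrodes in both DMN subsystems contribute; others
    are dropped with a log entry.  Rows are ordered by (subject, stage, bin);
    the two overall variables are means over the four task/node variables of
    their band.
    """
    df = table[(table["network"] == "default")
               & (table["subsystem"].isin(["dorsomedial-DMN", "lateral-DMN"]))
               & (table["task"].isin(["MW", "AUT"]))]
    have_both = df.groupby("subject", observed=True)["subsystem"].nunique()
    keep = sorted(have_both[have_both == 2].index)
    dropped = sorted(set(df["subject"]) - set(keep))
    for s in dropped:
        logger.info("subject %s lacks one DMN subsystem; dropped from clustering", s)
    if not keep:
        raise ValidationError("no subject has electrodes in both DMN subsystems")
    df = df[df["subject"].isin(keep)]

    cell = (df.groupby(["subject", "stage", "bin_index", "band", "task", "subsystem"],
                       observed=True)["pct_change"].mean().reset_index())
    cell["variable"] = (cell["band"] + "_" + cell["task"] + "_"
                        + cell["subsystem"].str.replace("-DMN", "", regex=False))
    wide = cell.pivot_table(index=["subject", "stage", "bin_index"],
                            columns="variable", values="pct_change")
    base_vars = VARIABLE_ORDER[:8]
    missing = [v for v in base_vars if v not in wide.columns]
    if missing or wide[base_vars].isna().any().any():
        raise ValidationError(f"incomplete task/node cells for clustering: {missing}")
    wide = wide.sort_index()
    wide["theta_overall"] = wide[[v for v in base_vars if v.startswith("theta")]].mean(axis=1)
    wide["gamma_overall"] = wide[[v for v in base_vars if v.startswith("gamma")]].mean(axis=1)
    obs_index = wide.index.to_frame(index=False)
    return VariableMatrix(values=wide[VARIABLE_ORDER].to_numpy(),
                          var_names=list(VARIABLE_ORDER),
                          obs_index=obs_index, dropped_subjects=dropped)


def correlation_distance(values: np.ndarray, var_names: list[str] | None = None
                         ) -> np.ndarray:
    """D[i, j] = 1 - Pearson r between variable columns; in [0, 2]."""
    X = np.asarray(values, dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [var_names[i] if var_names else str(i) for i in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant variable(s): {', '.join(bad)}")
    D = 1.0 - np.corrcoef(X, rowvar=False)
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 2.0)


def complete_linkage(D: np.ndarray, labels: list[str]) -> Dendrogram:
    """Farthest-neighbor agglomeration of a symmetric distance matrix."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be square and symmetric")
    Z = linkage(squareform(D, checks=False), method="complete")
    return Dendrogram(Z=Z, labels=list(labels))


def bootstrap_cluster_probability(vm: VariableMatrix, n_boot: int = 10_000,
                                  seed: int = 0) -> Dendrogram:
    """Complete-linkage tree with per-node bootstrap probabilities.

    Observations (rows) are resampled with replacement ``n_boot`` times; each
    internal node's BP is the fraction of replicate trees containing a cluster
    with identical leaf membership.  Degenerate replicates (a variable going
    constant under resampling) are redrawn.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    D = correlation_distance(vm.values, vm.var_names)
    dend = complete_linkage(D, vm.var_names)
    base_clusters = dend.clusters()
    counts = np.zeros(len(base_clusters))
    n = vm.n_obs
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            Db = correlation_distance(vm.values[idx], vm.var_names)
        except ValidationError:
            continue
        rep = complete_linkage(Db, vm.var_names)
        rep_clusters = set(rep.clusters())
        for i, cl in enumerate(base_clusters):
            if cl in rep_clusters:
                counts[i] += 1
        b += 1
    dend.bp = counts / n_boot
    return dend


def cluster_bp(dend: Dendrogram, members: set[str] | frozenset) -> float:
    """Bootstrap probability of the internal node with exactly ``members``;
    0.0 if no such node exists in the tree."""
    if dend.bp is None:
        raise ValidationError("dendrogram carries no bootstrap probabilities")
    target = frozenset(members)
    for i, cl in enumerate(dend.clusters()):
        if cl == target:
            return float(dend.bp[i])
    return 0.0


def smallest_containing_cluster(dend: Dendrogram, members: set[str] | frozenset
                                ) -> tuple[frozenset, float | None]:
    """The lowest internal node whose leaf set contains all ``members``, with
    its bootstrap probability (None if BP was not computed)."""
    target = frozenset(members)
    for i, cl in enumerate(dend.clusters()):
        if target <= cl:
            return cl, (None if dend.bp is None else float(dend.bp[i]))
    raise ValidationError(f"no cluster contains {sorted(target)}")


def to_newick(dend: Dendrogram, digits: int = 4) -> str:
    """Serialize as Newick: bootstrap probability as internal node label,
    height step to the parent as branch length."""
    tree = to_tree(dend.Z)
    bp = dend.bp

    def node_height(node) -> float:
        return 0.0 if node.is_leaf() else float(dend.Z[node.id - len(dend.labels), 2])

    def fmt(node, parent_height: float) -> str:
        bl = parent_height - node_height(node)
        if node.is_leaf():
            return f"{dend.labels[node.id]}:{bl:.{digits}f}"
        inner = ",".join(fmt(ch, node_height(node)) for ch in (node.left, node.right))
        label = "" if bp is None else f"{bp[node.id - len(dend.labels)]:.{digits}f}"
        return f"({inner}){label}:{bl:.{digits}f}"

    root = fmt(tree, node_height(tree))
    return root + ";"
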