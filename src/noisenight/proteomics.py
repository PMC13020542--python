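"""Responder-stratified proteomic workflow on NPX (log2) matrices.

Steps: per-subject pre/post expression change, responder stratification by
noise-induced FMD change (bottom/top n subjects), per-protein Student
t-tests at an unadjusted threshold, z-normalized group-mean clustering with
Euclidean distance, PCA of the change matrix, and score-thresholded
filtering of a protein-interaction edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from sklearn.decomposition import PCA


@dataclass
class NPXMatrix:
    """Proteins x samples NPX values with per-sample annotation.

    ``values``: DataFrame indexed by protein id, columns are sample ids.
    ``annotation``: DataFrame indexed by sample id with columns ``subject``
    and ``timepoint`` ("pre"/"post"), optionally ``fmd_change``.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.annotation.index)
        if missing:
            raise ValueError(f"samples missing annotation: {sorted(missing)[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("NPX values must be finite")

    @property
    def proteins(self) -> list:
        return list(self.values.index)

    def samples_at(self, timepoint: str) -> pd.DataFrame:
        """Values for one timepoint, columns relabelled to subject ids."""
        ann = self.annotation[self.annotation["timepoint"] == timepoint]
        sub = self.values[ann.index]
        sub.columns = ann["subject"].to_list()
        return sub

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path)


@dataclass
class ResponderSplit:
    strong: list
    weak: list
    ranking: pd.Series  # subject -> FMD change used for the split

    def group_of(self, subject) -> str:
        if subject in self.strong:
            return "strong"
        if subject in self.weak:
            return "weak"
        return "unassigned"


@dataclass
class DEResult:
    protein: str
    mean_a: float
    mean_b: float
    difference: float
    p_value: float
    retained: bool


def pairwise_change(npx: NPXMatrix) -> pd.DataFrame:
    """Post-minus-pre NPX change per subject per protein.

    Returns a subjects x proteins DataFrame (one NPX unit of change means a
    doubled concentration).
    """
    pre = npx.samples_at("pre")
    post = npx.samples_at("post")
    unmatched = set(pre.columns) ^ set(post.columns)
    if unmatched:
        raise ValueError(
            f"subjects without matched pre/post samples: {sorted(unmatched)}"
        )
    post = post[pre.columns]
    return (post - pre).T  # subjects x proteins


def split_responders(fmd_changes: pd.Series | dict, n: int = 20) -> ResponderSplit:
    """Partition subjects into the n strongest and n weakest responders.

    Subjects are ranked by FMD change; the ``strong`` set holds the n
    largest values, ``weak`` the n smallest. Ties are broken by subject id
    order (stable sort on the input order).
    """
    ranking = pd.Series(fmd_changes, dtype=float)
    if len(ranking) < 2 * n:
        raise ValueError(f"need at least {2 * n} subjects, got {len(ranking)}")
    order = ranking.sort_values(kind="stable")
    weak = order.index[:n].to_list()
    strong = order.index[-n:].to_list()
    if set(weak) & set(strong):
        raise ValueError("strong and weak sets overlap; reduce n")
    return ResponderSplit(strong=strong, weak=weak, ranking=ranking)


def _ttest_row(a: np.ndarray, b: np.ndarray, paired: bool) -> float:
    if paired:
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            return 1.0 if np.allclose(d.mean(), 0.0) else 0.0
        return float(scipy.stats.ttest_rel(a, b).pvalue)
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        return 1.0 if np.allclose(a.mean(), b.mean()) else 0.0
    return float(scipy.stats.ttest_ind(a, b).pvalue)


def de_ttest(
    changes: pd.DataFrame,
    groups: dict | ResponderSplit | None = None,
    threshold: float = 0.05,
    paired: bool = False,
) -> list[DEResult]:
    """Per-protein Student t-test with an unadjusted p threshold.

    Two modes:

    * unpaired (default): ``groups`` assigns subjects (rows of ``changes``)
      to two groups; each protein's change is compared between them.
    * paired: ``changes`` holds two aligned sample sets -- pass a dict
      ``{"a": frame_a, "b": frame_b}`` with matching columns -- and a paired
      test is run per protein (used for pre-vs-post over all subjects).

    Zero-variance proteins get p = 1.0 when group means are equal and
    p = 0.0 (retained) when they differ.
    """
    results: list[DEResult] = []
    if paired:
        if not (isinstance(changes, dict) and set(changes) == {"a", "b"}):
            raise ValueError("paired mode expects {'a': frame, 'b': frame}")
        fa, fb = changes["a"], changes["b"]
        fb = fb[fa.columns]
        for protein in fa.index:
            a = fa.loc[protein].to_numpy(dtype=float)
            b = fb.loc[protein].to_numpy(dtype=float)
            p = _ttest_row(a, b, paired=True)
            results.append(
                DEResult(protein, float(a.mean()), float(b.mean()),
                         float(a.mean() - b.mean()), p, p < threshold)
            )
        return results

    if isinstance(groups, ResponderSplit):
        group_map = {s: "strong" for s in groups.strong}
        group_map.update({s: "weak" for s in groups.weak})
    else:
        group_map = dict(groups)
    labels = sorted(set(group_map.values()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    ga = [s for s in changes.index if group_map.get(s) == labels[0]]
    gb = [s for s in changes.index if group_map.get(s) == labels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least 2 observations per group")
    A = changes.loc[ga]
    B = changes.loc[gb]
    for protein in changes.columns:
        a = A[protein].to_numpy(dtype=float)
        b = B[protein].to_numpy(dtype=float)
        p = _ttest_row(a, b, paired=False)
        results.append(
            DEResult(protein, float(a.mean()), float(b.mean()),
                     float(a.mean() - b.mean()), p, p < threshold)
        )
    return results


def de_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": r.protein,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "difference": r.difference,
                "p_value": r.p_value,
                "retained": r.retained,
            }
            for r in results
        ]
    )


def zscore_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Z-normalize each row to mean 0 and (population) sd 1.

    Constant rows are left at 0. Idempotent up to floating error.
    """
    arr = frame.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((arr - mean) / sd, index=frame.index, columns=frame.columns)


def zscore_cluster(
    retained_changes: pd.DataFrame,
    split: ResponderSplit | None = None,
    linkage_method: str = "average",
):
    """Group-mean, z-normalized, Euclidean-clustered heat-map table.

    ``retained_changes`` is subjects x retained proteins. If ``split`` is
    given, per-protein means are computed for the strong and weak groups;
    otherwise every column of ``retained_changes`` is treated as a group
    already. Rows (proteins) are z-normalized across groups and clustered
    agglomeratively with Euclidean distance; returns ``(table, leaf_order,
    linkage_matrix)`` where ``table`` rows follow the dendrogram leaf order.
    """
    if split is not None:
        means = pd.DataFrame(
            {
                "strong": retained_changes.loc[split.strong].mean(axis=0),
                "weak": retained_changes.loc[split.weak].mean(axis=0),
            }
        )
    else:
        means = retained_changes.T.copy()
    if means.shape[0] < 2:
        return means, list(means.index), None  # single protein: unclustered
    z = zscore_rows(means)
    Z = sch.linkage(z.to_numpy(), method=linkage_method, metric="euclidean")
    leaves = sch.leaves_list(Z)
    order = [z.index[i] for i in leaves]
    return z.loc[order], order, Z


def pca_scores(changes: pd.DataFrame, n_components: int = 2):
    """Centered PCA of the subjects x proteins change matrix.

    Returns ``(scores, explained_variance_ratio)``; ``scores`` is a
    DataFrame (subjects x components). Rank-degenerate inputs reduce the
    component count with a note in ``scores.attrs``.
    """
    if changes.shape[0] < 2 or changes.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 proteins")
    k = min(n_components, changes.shape[0] - 1, changes.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(changes.to_numpy(dtype=float))
    out = pd.DataFrame(
        scores, index=changes.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    if k < n_components:
        out.attrs["note"] = f"rank limited components to {k}"
    return out, pca.explained_variance_ratio_


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read a (node_a, node_b, score) whitespace/tab-separated edge list."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 3:
        raise ValueError("edge list needs columns: node_a, node_b, score")
    df = df.iloc[:, :3]
    df.columns = ["node_a", "node_b", "score"]
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        bad = int(np.flatnonzero(scores.isna().to_numpy())[0])
        raise ValueError(f"malformed edge row {bad + 1}: non-numeric score")
    df["score"] = scores
    return df


def filter_network(
    edges: pd.DataFrame, node_set, min_score: float = 0.4
) -> nx.Graph:
    """Subgraph of edges with score strictly above ``min_score`` between
    nodes of ``node_set``; connected components are listed in
    ``graph.graph["components"]``."""
    node_set = set(node_set)
    if not {"node_a", "node_b", "score"}.issubset(edges.columns):
        raise ValueError("edges must have columns node_a, node_b, score")
    keep = edges[
        (edges["score"] > min_score)
        & edges["node_a"].isin(node_set)
        & edges["node_b"].isin(node_set)
    ]
    g = nx.Graph()
    g.add_nodes_from(sorted(node_set & (set(edges["node_a"]) | set(edges["node_b"]))))
    for _, row in keep.iterrows():
        g.add_edge(row["node_a"], row["node_b"], score=float(row["score"]))
    g.graph["components"] = [sorted(c) for c in nx.connected_components(g)]
    return g
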