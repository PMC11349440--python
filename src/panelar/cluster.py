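"""Correlation-based dissimilarity and Ward clustering of growth-rate series.

Sites whose growth-rate series co-fluctuate are grouped before model fitting,
so each fitted panel is homogeneous.  Dissimilarity between two locations is
``d = 1 - r`` when the Pearson correlation ``r`` over their shared years is
significantly non-zero (two-sided test), and ``d = 1`` otherwise.  The
agglomeration uses Ward's minimum-variance criterion via the Lance-Williams
recurrence applied to the raw dissimilarities (the ``ward.D`` convention of
R's ``hclust``), with a deterministic smallest-label tie rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ClusteringError(ValueError):
    pass


@dataclass
class Dendrogram:
    """Agglomeration record: n-1 merges over n leaves.

    ``merges[i] = (a, b)`` joins clusters ``a`` and ``b`` at ``heights[i]``;
    ids 0..n-1 are leaves, id n+i is the cluster created by merge ``i``
    (scipy linkage numbering).
    """

    merges: list
    heights: list
    labels: list
    variant: str = "ward.D"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, height: float) -> np.ndarray:
        """Flat cluster labels after performing all merges with height <= cut."""
        n = self.n_leaves
        parent = list(range(2 * n - 1))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for (a, b), h, newid in zip(self.merges, self.heights, range(n, 2 * n - 1)):
            if h <= height:
                parent[find(a)] = newid
                parent[find(b)] = newid
        roots = {}
        out = np.empty(n, dtype=int)
        for leaf in range(n):
            r = find(leaf)
            out[leaf] = roots.setdefault(r, len(roots))
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "labels": list(map(str, self.labels)),
            "merges": [list(map(int, m)) for m in self.merges],
            "heights": [float(h) for h in self.heights],
            "variant": self.variant,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "Dendrogram":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            merges=[tuple(m) for m in payload["merges"]],
            heights=payload["heights"],
            labels=payload["labels"],
            variant=payload.get("variant", "ward.D"),
        )


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    labels: list
    alpha: float = 0.05

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ClusteringError("dissimilarity matrix must be square")
        if not np.allclose(d, d.T):
            raise ClusteringError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ClusteringError("dissimilarity diagonal must be zero")
        if d.min() < 0 or d.max() > 2 + 1e-12:
            raise ClusteringError("dissimilarities must lie in [0, 2]")
        self.values = d


def pairwise_dissimilarity(panel, alpha: float = 0.05) -> DissimilarityMatrix:
    """d = 1 - r on overlapping years; non-significant correlations give d = 1.

    ``panel`` is a mapping location -> (years, growth_rates) as produced by
    :meth:`panelar.preprocess.PanelData.growth_arrays`, or a PanelData.
    Pairs must share at least 3 years.  Constant series have undefined r and
    fall back to d = 1 with a warning.
    """
    if hasattr(panel, "growth_arrays"):
        panel = panel.growth_arrays()
    labels = list(panel)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        yi, xi = panel[labels[i]]
        si = pd.Series(np.asarray(xi, float), index=yi)
        for j in range(i + 1, n):
            yj, xj = panel[labels[j]]
            sj = pd.Series(np.asarray(xj, float), index=yj)
            a, b = si.align(sj, join="inner")
            if len(a) < 3:
                raise ClusteringError(
                    f"locations {labels[i]!r} and {labels[j]!r} share fewer than 3 years"
                )
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"constant series for pair ({labels[i]!r}, {labels[j]!r}); d set to 1",
                    stacklevel=2,
                )
                d[i, j] = d[j, i] = 1.0
                continue
            r, p = stats.pearsonr(a.to_numpy(), b.to_numpy())
            d[i, j] = d[j, i] = (1.0 - r) if p < alpha else 1.0
    return DissimilarityMatrix(d, labels, alpha=alpha)


def ward_cluster(dmat: DissimilarityMatrix) -> Dendrogram:
    """Agglomerate by Ward's criterion (Lance-Williams on raw dissimilarities).

    The Lance-Williams update for Ward's method,

        d(i+j, k) = [(n_i+n_k) d(i,k) + (n_j+n_k) d(j,k) - n_k d(i,j)]
                    / (n_i+n_j+n_k),

    is applied to the supplied d values directly (ward.D convention).  Ties in
    the minimum pairwise distance are broken by the smallest (i, j) cluster-id
    pair, so the result is deterministic.
    """
    d0 = dmat.values
    n = d0.shape[0]
    if n < 2:
        raise ClusteringError("need at least 2 leaves to cluster")
    # active clusters: id -> (size, row index in working matrix)
    d = d0.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    size = {i: 1 for i in range(n)}
    rowid = list(range(n))  # rowid[r] = cluster id stored in row r of d
    active = [True] * n
    merges, heights = [], []
    work = d
    ids = np.array(rowid)
    for step in range(n - 1):
        # find min over active pairs, smallest (id_i, id_j) on ties
        best = None
        rows = [r for r in range(len(ids)) if active[r]]
        for ai in range(len(rows)):
            for aj in range(ai + 1, len(rows)):
                r1, r2 = rows[ai], rows[aj]
                val = work[r1, r2]
                key = (val, min(ids[r1], ids[r2]), max(ids[r1], ids[r2]))
                if best is None or key < best[0]:
                    best = (key, r1, r2)
        _, r1, r2 = best
        id1, id2 = int(ids[r1]), int(ids[r2])
        h = work[r1, r2]
        merges.append((min(id1, id2), max(id1, id2)))
        heights.append(float(h))
        ni, nj = size[id1], size[id2]
        newid = n + step
        # Lance-Williams update into row r1
        for r in range(len(ids)):
            if not active[r] or r in (r1, r2):
                continue
            nk = size[int(ids[r])]
            val = (
                (ni + nk) * work[r1, r]
                + (nj + nk) * work[r2, r]
                - nk * h
            ) / (ni + nj + nk)
            work[r1, r] = work[r, r1] = val
        active[r2] = False
        ids[r1] = newid
        size[newid] = ni + nj
    return Dendrogram(merges=merges, heights=heights, labels=list(dmat.labels))


def cut_rule_height(dend: Dendrogram, resolution: float = 0.1) -> float:
    """Per-dendrogram cut height from the longest-branch heuristic.

    Every cluster (leaf or internal) owns one vertical branch running from
    its formation height to the height at which it next merges; none of these
    lines crosses a merging point.  The rule finds the branch with the
    largest gap between those two heights — the largest separation between
    clusters — and places the cut "just prior to" that branch's merging
    point: the largest multiple of ``resolution`` strictly below it.  Ties go
    to the branch with the lower merging point, then the lower cluster id,
    so the earliest qualifying branch wins and the result is deterministic.
    """
    if dend.n_leaves < 2:
        raise ClusteringError("dendrogram needs at least 2 leaves")
    n = dend.n_leaves
    formation = {i: 0.0 for i in range(n)}
    for newid, h in zip(range(n, 2 * n - 1), dend.heights):
        formation[newid] = h
    best = None  # (-length, merge height, cluster id)
    for (a, b), h in zip(dend.merges, dend.heights):
        for c in (a, b):
            key = (-(h - formation[c]), h, c)
            if best is None or key < best:
                best = key
    top = best[1]
    k = int(np.ceil(round(top / resolution, 9))) - 1
    return round(k * resolution, 10)


def cut(dendrograms: list[Dendrogram], resolution: float = 0.1):
    """Cut every dendrogram at the max of the per-dendrogram rule heights.

    Returns ``(common_height, [assignment arrays])``.
    """
    if not dendrograms:
        raise ClusteringError("need at least one dendrogram")
    common = max(cut_rule_height(d, resolution) for d in dendrograms)
    return common, [d.cut(common) for d in dendrograms]


def assignments_frame(dendrograms, group_names=None, resolution: float = 0.1) -> pd.DataFrame:
    """Tidy location/group/subgroup table from the common-height cut."""
    common, cuts = cut(dendrograms, resolution)
    if group_names is None:
        group_names = [f"group{i + 1}" for i in range(len(dendrograms))]
    rows = []
    for name, dend, labels in zip(group_names, dendrograms, cuts):
        for loc, sub in zip(dend.labels, labels):
            rows.append({"location": loc, "group": name, "subgroup": int(sub)})
    df = pd.DataFrame(rows)
    df.attrs["cut_height"] = common
    return df
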