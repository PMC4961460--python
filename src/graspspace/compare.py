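"""Geometry comparison: Procrustes similarity and hierarchical clustering.

Procrustes analysis aligns the neural state space (reduced to 27 canonical
components) to the 27-DOF joint space by an optimal translation and rotation
(optionally with uniform scaling and reflection) and reports the normalized
residual dissimilarity ``d = min SSD / sum ||reference - column means||^2``:
0 means the two trial clouds match up to a similarity transform, values near
1 mean the target carries none of the reference geometry.

Hierarchical cluster analysis builds an agglomerative average-linkage tree
from a condition distance matrix, with deterministic lowest-leaf-id
tie-breaking, plus a purity measure (fraction of parametric-family objects
sharing a cluster with another object of the same shape) and Newick export.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spaces import ConditionDistanceMatrix


@dataclass
class ProcrustesResult:
    rotation: np.ndarray
    translation: np.ndarray
    scale: float
    dissimilarity: float
    allow_scaling: bool
    allow_reflection: bool
    reference_id: str | None = None
    target_id: str | None = None

    def transform(self, target: np.ndarray) -> np.ndarray:
        """Apply the fitted similarity transform to target rows."""
        return self.scale * np.asarray(target, float) @ self.rotation + self.translation


def procrustes_similarity(
    reference: np.ndarray,
    target: np.ndarray,
    allow_scaling: bool = True,
    allow_reflection: bool = True,
    *,
    reference_id: str | None = None,
    target_id: str | None = None,
) -> ProcrustesResult:
    """Fit ``reference ~ scale * target @ rotation + translation`` by least
    squares and return the normalized dissimilarity.

    Rows of both matrices are matched observations (trials, shared index);
    both must have the same shape.  With fewer rows than ``columns + 1`` the
    fit is rank-deficient and a warning is raised.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("reference and target must have the same number of rows")
    if x.shape[1] != y.shape[1]:
        raise ValueError("reference and target must have the same number of columns")
    if x.shape[0] <= x.shape[1]:
        warnings.warn(
            f"only {x.shape[0]} rows for {x.shape[1]} dimensions: "
            "Procrustes fit is rank deficient",
            stacklevel=2,
        )

    mu_x, mu_y = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mu_x, y - mu_y
    norm_x2 = float((xc**2).sum())
    norm_y2 = float((yc**2).sum())
    if norm_x2 == 0.0:
        raise ValueError("reference has zero variance; dissimilarity undefined")
    if norm_y2 == 0.0:
        # degenerate target: best fit is the reference centroid
        return ProcrustesResult(
            rotation=np.eye(x.shape[1]),
            translation=mu_x,
            scale=0.0 if allow_scaling else 1.0,
            dissimilarity=1.0,
            allow_scaling=allow_scaling,
            allow_reflection=allow_reflection,
            reference_id=reference_id,
            target_id=target_id,
        )

    u, s, vt = np.linalg.svd(yc.T @ xc)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        u = u.copy()
        u[:, -1] *= -1.0
        s = s.copy()
        s[-1] *= -1.0
    rotation = u @ vt
    trace = float(s.sum())

    scale = trace / norm_y2 if allow_scaling else 1.0
    ssd = norm_x2 + scale**2 * norm_y2 - 2.0 * scale * trace
    d = max(ssd, 0.0) / norm_x2
    translation = mu_x - scale * mu_y @ rotation
    return ProcrustesResult(
        rotation=rotation,
        translation=translation,
        scale=scale,
        dissimilarity=float(d),
        allow_scaling=allow_scaling,
        allow_reflection=allow_reflection,
        reference_id=reference_id,
        target_id=target_id,
    )


@dataclass
class Dendrogram:
    """Average-linkage merge tree.

    ``merges`` has one row per agglomeration step: (cluster_a, cluster_b,
    height, new_size), where leaves are numbered 0..n-1 in ``labels`` order
    and the cluster created at step i gets index n + i (scipy linkage
    convention).
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def hca(distance_matrix: ConditionDistanceMatrix | pd.DataFrame | np.ndarray,
        labels: list[str] | None = None) -> Dendrogram:
    """Agglomerative average-linkage clustering of a dissimilarity matrix.

    Ties are broken deterministically by the pair with the lowest smallest
    leaf id (then lowest second id).
    """
    if isinstance(distance_matrix, ConditionDistanceMatrix):
        d = distance_matrix.matrix.to_numpy(dtype=float, copy=True)
        labels = [str(c) for c in distance_matrix.condition_ids]
    elif isinstance(distance_matrix, pd.DataFrame):
        d = distance_matrix.to_numpy(dtype=float, copy=True)
        labels = [str(c) for c in distance_matrix.index]
    else:
        d = np.array(distance_matrix, dtype=float, copy=True)
        if labels is None:
            labels = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any() or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distances must be nonnegative with zero diagonal")

    active: dict[int, dict] = {
        i: {"size": 1, "min_leaf": i} for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (a, b), val in dist.items():
            key = (
                val,
                min(active[a]["min_leaf"], active[b]["min_leaf"]),
                max(active[a]["min_leaf"], active[b]["min_leaf"]),
            )
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        height = dist[(min(a, b), max(a, b))]
        size = active[a]["size"] + active[b]["size"]
        merges[step] = (a, b, height, size)

        new = {
            "size": size,
            "min_leaf": min(active[a]["min_leaf"], active[b]["min_leaf"]),
        }
        for c in list(active):
            if c in (a, b):
                continue
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            dist[(c, next_id)] = (
                active[a]["size"] * da + active[b]["size"] * db
            ) / size
        dist.pop((min(a, b), max(a, b)))
        del active[a], active[b]
        active[next_id] = new
        next_id += 1
    return Dendrogram(merges=merges, labels=list(labels))


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Leaf label -> cluster id for a cut yielding exactly k clusters."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = {}
    for step, (a, b, _h, _s) in enumerate(dendrogram.merges[: n - k]):
        parent[int(a)] = n + step
        parent[int(b)] = n + step

    def root(i: int) -> int:
        while i in parent:
            i = parent[i]
        return i

    roots = {}
    assignment = {}
    for leaf, label in enumerate(dendrogram.labels):
        r = root(leaf)
        roots.setdefault(r, len(roots))
        assignment[label] = roots[r]
    return assignment


def shape_cluster_purity(
    dendrogram: Dendrogram,
    catalog: pd.DataFrame,
    k: int | None = None,
    shapes: tuple[str, ...] = ("ring", "cube", "sphere", "cylinder_h", "cylinder_v", "bar"),
) -> float:
    """Fraction of parametric-family objects whose cluster contains at least
    one other object of the same shape, at a cut into k clusters (default:
    the number of shape families present)."""
    shape_of = dict(zip(catalog["id"].astype(str), catalog["shape"]))
    if k is None:
        k = len({s for s in shape_of.values() if s in shapes})
    assignment = cut_dendrogram(dendrogram, k)
    members: dict[int, list[str]] = {}
    for label, cluster in assignment.items():
        members.setdefault(cluster, []).append(label)

    hits = total = 0
    for label, cluster in assignment.items():
        shape = shape_of.get(label)
        if shape not in shapes:
            continue
        total += 1
        mates = [m for m in members[cluster] if m != label]
        if any(shape_of.get(m) == shape for m in mates):
            hits += 1
    if total == 0:
        raise ValueError("no parametric-family objects among the leaves")
    return hits / total


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick text with branch lengths from merge heights.

    The tree is ultrametric: every leaf sits at depth ``root_height / 2``,
    i.e. a 2-leaf tree merged at height 3 becomes ``(A:1.5,B:1.5);``.
    """
    n = dendrogram.n_leaves
    height = {i: 0.0 for i in range(n)}
    children = {}
    for step, (a, b, h, _s) in enumerate(dendrogram.merges):
        node = n + step
        height[node] = h
        children[node] = (int(a), int(b))

    def render(node: int, parent_height: float) -> str:
        branch = (parent_height - height[node]) / 2.0
        if node < n:
            return f"{dendrogram.labels[node]}:{branch:.10g}"
        a, b = children[node]
        return f"({render(a, height[node])},{render(b, height[node])}):{branch:.10g}"

    root = n + len(dendrogram.merges) - 1
    a, b = children[root]
    return f"({render(a, height[root])},{render(b, height[root])});"


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;:]+:[-0-9.eE+]+")


def parse_newick(text: str) -> Dendrogram:
    """Parse an ultrametric Newick string back into a Dendrogram.

    Round-trips :func:`to_newick`: merge heights are recovered from leaf
    depths (each leaf sits at depth height/2 below its subtree root).
    """
    pos = 0
    text = text.strip()

    def parse_node():
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            kids = [parse_node()]
            while text[pos] == ",":
                pos += 1
                kids.append(parse_node())
            if text[pos] != ")":
                raise ValueError("unbalanced parentheses in Newick string")
            pos += 1
            branch = 0.0
            if pos < len(text) and text[pos] == ":":
                pos += 1
                m = re.match(r"[-0-9.eE+]+", text[pos:])
                branch = float(m.group())
                pos += len(m.group())
            return {"children": kids, "branch": branch}
        m = re.match(r"([^(),;:]+):([-0-9.eE+]+)", text[pos:])
        if m is None:
            raise ValueError(f"cannot parse Newick at position {pos}")
        pos += m.end()
        return {"label": m.group(1), "branch": float(m.group(2))}

    tree = parse_node()
    if pos >= len(text) or text[pos] != ";":
        raise ValueError("Newick string must end with ';'")

    def subtree_height(node) -> float:
        if "label" in node:
            return 0.0
        child = node["children"][0]
        return 2.0 * child["branch"] + subtree_height(child)

    labels: list[str] = []

    def collect_leaves(node):
        if "label" in node:
            labels.append(node["label"])
        else:
            for child in node["children"]:
                collect_leaves(child)

    collect_leaves(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    merges: list[tuple[float, list[int]]] = []

    def build(node) -> int:
        """Return the cluster id of the node, recording merges bottom-up."""
        if "label" in node:
            return index[node["label"]]
        ids = [build(child) for child in node["children"]]
        h = subtree_height(node)
        acc = ids[0]
        for other in ids[1:]:
            merges.append((h, [acc, other]))
            acc = -len(merges)   # placeholder, resolved after sorting
        return acc

    # rebuild with explicit ordering: sort merges by height, smallest first
    build(tree)
    # re-run agglomeration ordering deterministically: replay merges sorted
    merges_sorted = sorted(range(len(merges)), key=lambda i: merges[i][0])
    remap: dict[int, int] = {}
    rows = np.empty((len(merges), 4))
    sizes = {i: 1 for i in range(n)}
    for new_step, old in enumerate(merges_sorted):
        h, (a, b) = merges[old]
        a = remap.get(a, a) if a >= 0 else remap[a]
        b = remap.get(b, b) if b >= 0 else remap[b]
        size = sizes[a] + sizes[b]
        rows[new_step] = (a, b, h, size)
        new_id = n + new_step
        sizes[new_id] = size
        remap[-(old + 1)] = new_id
    return Dendrogram(merges=rows, labels=labels)
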