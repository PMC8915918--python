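"""Structure-based clustering on binary fingerprints.

Pairwise Tanimoto (Jaccard) distance, Ward agglomerative clustering via the
Lance-Williams recurrence, and a fixed-height dendrogram cut.  The default
Ward dialect ("D2") applies the recurrence to squared distances and reports
square-root merge heights — the textbook Ward objective; the unsquared
dialect ("D") applies it to the raw distances.  Merge ties are broken by the
lexicographically smallest member indices so the partition is deterministic
for a fixed input ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import FingerprintMatrix

__all__ = [
    "ClusterAssignment",
    "tanimoto_distance",
    "pairwise_tanimoto",
    "ward_linkage",
    "labels_at_cut",
    "cluster_chemicals",
    "linkage_to_newick",
]


@dataclass
class ClusterAssignment:
    """Flat cluster labels from cutting the dendrogram.

    ``cluster_id`` values are contiguous positive integers numbered by first
    appearance in ``chem_ids`` order.  ``unclustered`` lists chemicals that
    had no fingerprint and therefore no label.
    """

    chem_ids: list[str]
    cluster_id: np.ndarray  # int, parallel to chem_ids
    cut_height: float
    unclustered: list[str]

    def members(self, cid: int) -> list[str]:
        return [c for c, k in zip(self.chem_ids, self.cluster_id) if k == cid]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.chem_ids, (int(k) for k in self.cluster_id)))

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max()) if len(self.cluster_id) else 0


def tanimoto_distance(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """1 − |a ∧ b| / |a ∨ b| for two equal-length binary vectors.

    Two all-zero fingerprints are identical degenerate inputs and get
    distance 0 (the 0/0 case), preserving the identity axiom.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(a, b).sum() / union


def pairwise_tanimoto(bits: np.ndarray) -> np.ndarray:
    """Dense n x n Tanimoto distance matrix for a binary matrix."""
    x = np.asarray(bits, dtype=np.float64)
    inter = x @ x.T
    row = x.sum(axis=1)
    union = row[:, None] + row[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    dist[union == 0] = 0.0  # pairs of all-zero fingerprints
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 1.0)


def ward_linkage(dist: np.ndarray, dialect: str = "D2") -> np.ndarray:
    """Agglomerate a distance matrix under the Ward criterion.

    Returns a scipy-style linkage array ``(n-1, 4)``: merged cluster indices
    (original observations are ``0..n-1``, internal nodes ``n..2n-2``), merge
    height, and merged size.  When several candidate pairs share the minimal
    criterion value the pair with the lexicographically smallest member
    indices is merged, so the tree is deterministic.

    ``dialect="D2"`` runs the Lance-Williams update on squared distances and
    reports square-root heights (the classical Ward objective); ``"D"`` runs
    it on the distances as given.
    """
    if dialect not in ("D", "D2"):
        raise ValueError(f"unknown Ward dialect: {dialect!r}")
    d = np.asarray(dist, dtype=np.float64)
    n = d.shape[0]
    if n == 0:
        raise ValueError("empty distance matrix")
    crit = d**2 if dialect == "D2" else d.copy()
    np.fill_diagonal(crit, np.inf)
    crit[np.tril_indices(n)] = np.inf  # keep upper triangle only

    size = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    # node[slot] = scipy-style id of the cluster currently held in the slot;
    # a merged cluster is stored in the smaller slot, so the slot index is
    # the smallest original member index (the lexicographic tie-break key).
    node = np.arange(n)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        flat = np.argmin(crit)  # row-major => lexicographically smallest tie
        i, j = divmod(flat, n)
        h = crit[i, j]
        height = float(np.sqrt(h)) if dialect == "D2" else float(h)
        Z[step] = (node[i], node[j], height, size[i] + size[j])

        # Lance-Williams Ward update into slot i
        k = active.copy()
        k[i] = k[j] = False
        si, sj, sk = size[i], size[j], size[k]
        # gather symmetric entries from the upper triangle
        idx = np.nonzero(k)[0]
        cki = np.where(idx < i, crit[idx, i], crit[i, idx])
        ckj = np.where(idx < j, crit[idx, j], crit[j, idx])
        tot = si + sj + sk
        new = ((si + sk) * cki + (sj + sk) * ckj - sk * h) / tot
        lo = np.minimum(idx, i)
        hi = np.maximum(idx, i)
        crit[lo, hi] = new

        active[j] = False
        size[i] += size[j]
        node[i] = n + step
        crit[j, :] = np.inf
        crit[:, j] = np.inf
    return Z


def labels_at_cut(Z: np.ndarray, n: int, cut_height: float) -> np.ndarray:
    """Flat labels: connected components after dropping merges above the cut.

    Labels are renumbered 1..k by first appearance in observation order.
    """
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - 1):
        a, b, h = int(Z[step, 0]), int(Z[step, 1]), Z[step, 2]
        if h <= cut_height:
            parent[find(a)] = parent[find(b)] = n + step
    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=np.int64)
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return labels


def cluster_chemicals(
    fps: FingerprintMatrix,
    cut_height: float = 0.7,
    dialect: str = "D2",
    all_chem_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Cluster fingerprinted chemicals and cut the Ward tree at a height.

    The cut height defaults to 0.7 on the Tanimoto-distance Ward tree.
    ``all_chem_ids``, when given, lists the full chemical set so that
    chemicals without fingerprints are reported as ``unclustered``.
    """
    n = len(fps.chem_ids)
    if n == 0:
        raise ValueError("empty fingerprint matrix")
    if cut_height < 0:
        raise ValueError("cut_height must be non-negative")
    zero_rows = [c for c, row in zip(fps.chem_ids, fps.bits) if row.sum() == 0]
    if zero_rows:
        warnings.warn(
            "all-zero fingerprints (mutual distance 0, will co-cluster): "
            + ", ".join(zero_rows),
            stacklevel=2,
        )
    if n == 1:
        labels = np.array([1])
    else:
        dist = pairwise_tanimoto(fps.bits)
        Z = ward_linkage(dist, dialect=dialect)
        labels = labels_at_cut(Z, n, cut_height)
    unclustered = (
        [c for c in all_chem_ids if c not in set(fps.chem_ids)]
        if all_chem_ids is not None
        else []
    )
    return ClusterAssignment(
        chem_ids=list(fps.chem_ids),
        cluster_id=labels,
        cut_height=cut_height,
        unclustered=unclustered,
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render the merge tree as a newick string (branch lengths = heights)."""
    n = len(leaf_names)
    nodes: dict[int, tuple[str, float]] = {i: (leaf_names[i], 0.0) for i in range(n)}
    for step in range(n - 1):
        a, b, h = int(Z[step, 0]), int(Z[step, 1]), float(Z[step, 2])
        (sa, ha), (sb, hb) = nodes.pop(a), nodes.pop(b)
        nodes[n + step] = (
            f"({sa}:{max(h - ha, 0.0):.6g},{sb}:{max(h - hb, 0.0):.6g})",
            h,
        )
    (s, _), = nodes.values()
    return s + ";"
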