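"""mOTU delimitation by objective clustering on uncorrected p-distances.

Barcodes are grouped at a distance threshold by single linkage: the mOTUs
are the connected components of the graph joining every pair at p-distance
<= t (inclusive). Multi-member components are named "ClusterN", singletons
"SingletonN", numbered by decreasing size then smallest member id. A
stability analysis reports, for candidate cluster pairs, the minimum
inter-cluster distance and the lowest evaluated threshold at which they
merge — pairs sharing a database name that never merge are flagged as
putative distinct species hiding under one reference label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from coipipe.seqs import encode, round_half_up

DEFAULT_THRESHOLDS = (0.02, 0.028, 0.033, 0.038, 0.045)


def p_distance(a: str, b: str) -> float:
    """Uncorrected pairwise distance: mismatches / compared sites.

    Sites where either sequence has a non-ACGT symbol are excluded
    (pairwise deletion). Sequences must be equal length (barcodes are
    fixed-length and indel-free by QC); supply pre-aligned sequences
    otherwise.
    """
    if len(a) != len(b):
        raise ValueError(
            f"length mismatch ({len(a)} vs {len(b)}); supply a pairwise alignment"
        )
    ea, eb = encode(a), encode(b)
    valid = np.isin(ea, encode("ACGT")) & np.isin(eb, encode("ACGT"))
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    return float((ea[valid] != eb[valid]).sum() / n)


def percent_identity(a: str, b: str) -> float:
    """(1 - p) x 100, rounded half away from zero to 1 decimal."""
    return round_half_up(100.0 * (1.0 - p_distance(a, b)))


def substitutions_for_identity(identity: float, length: int = 652) -> int | None:
    """Smallest substitution count over ``length`` ungapped sites whose
    percent identity prints as ``identity`` (1 decimal), or None if the
    printed value is unreachable by any integer count."""
    for n in range(length + 1):
        if round_half_up(100.0 * (1.0 - n / length)) == identity:
            return n
    return None


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, fractions in [0, 1]

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "DistanceMatrix":
        ids = sorted(sequences)
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = p_distance(sequences[ids[i]], sequences[ids[j]])
        return cls(ids, d)

    def validate(self) -> None:
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("matrix must be symmetric with zero diagonal")

    def to_phylip(self, path) -> None:
        """Write the square PHYLIP distance matrix."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{name[:30]:<32s}{row}\n")


@dataclass
class MOTUPartition:
    threshold: float
    clusters: list[list[str]]  # member ids, sorted within each cluster
    names: list[str]  # parallel to clusters: ClusterN / SingletonN

    def member_to_name(self) -> dict[str, str]:
        return {m: name for name, members in zip(self.names, self.clusters)
                for m in members}

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(c) for c in self.clusters}

    def to_frame(self) -> pd.DataFrame:
        rows = [(m, name, self.threshold)
                for name, members in zip(self.names, self.clusters) for m in members]
        return pd.DataFrame(rows, columns=["barcode_id", "cluster_name", "threshold"])


def objective_cluster(matrix: DistanceMatrix, threshold: float) -> MOTUPartition:
    """Single-linkage clustering at an inclusive distance cut.

    mOTUs are the connected components of {(i, j): d[i][j] <= threshold};
    the inclusive comparison means a pair at exactly the threshold
    co-clusters.
    """
    matrix.validate()
    n = len(matrix.ids)
    adj = csr_matrix((matrix.d <= threshold) & ~np.eye(n, dtype=bool))
    n_comp, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(matrix.ids[idx])
    comps = sorted((sorted(g) for g in groups.values()),
                   key=lambda g: (-len(g), g[0]))
    names = []
    n_cluster = n_singleton = 0
    for comp in comps:
        if len(comp) > 1:
            n_cluster += 1
            names.append(f"Cluster{n_cluster}")
        else:
            n_singleton += 1
            names.append(f"Singleton{n_singleton}")
    return MOTUPartition(threshold, comps, names)


def _min_inter_distance(matrix: DistanceMatrix, a: list[str], b: list[str]) -> float:
    pos = {name: i for i, name in enumerate(matrix.ids)}
    ia = [pos[x] for x in a]
    ib = [pos[x] for x in b]
    return float(matrix.d[np.ix_(ia, ib)].min())


def stability_analysis(
    matrix: DistanceMatrix,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Characterise how cluster pairs behave across a threshold ladder.

    Clusters at the lowest threshold are paired when they share a taxon
    label (if labels are given) or when they are mutually nearest. For
    each pair the report gives the minimum inter-cluster distance and the
    lowest evaluated threshold at which the two co-cluster (NaN if never);
    same-label pairs that never merge are flagged as putative distinct
    species sharing one database name.
    """
    if len(thresholds) < 2:
        raise ValueError("stability analysis requires at least two thresholds")
    thresholds = tuple(sorted(thresholds))
    base = objective_cluster(matrix, thresholds[0])
    if len(base.clusters) < 2:
        return pd.DataFrame(columns=["cluster_a", "cluster_b", "shared_label",
                                     "min_distance", "merge_threshold",
                                     "same_label_never_merged"])
    partitions = {t: objective_cluster(matrix, t).member_to_name() for t in thresholds}

    pairs: list[tuple[int, int, str | None]] = []
    if labels is not None:
        label_sets = [{labels[m] for m in c if m in labels} for c in base.clusters]
        for i in range(len(base.clusters)):
            for j in range(i + 1, len(base.clusters)):
                shared = label_sets[i] & label_sets[j]
                if shared:
                    pairs.append((i, j, sorted(shared)[0]))
    else:
        k = len(base.clusters)
        nearest = []
        for i in range(k):
            dists = [(_min_inter_distance(matrix, base.clusters[i], base.clusters[j]), j)
                     for j in range(k) if j != i]
            nearest.append(min(dists)[1])
        for i in range(k):
            j = nearest[i]
            if i < j and nearest[j] == i:
                pairs.append((i, j, None))

    rows = []
    for i, j, shared in pairs:
        rep_a, rep_b = base.clusters[i][0], base.clusters[j][0]
        merge_t = next((t for t in thresholds
                        if partitions[t][rep_a] == partitions[t][rep_b]), None)
        dmin = _min_inter_distance(matrix, base.clusters[i], base.clusters[j])
        rows.append((base.names[i], base.names[j], shared, dmin,
                     np.nan if merge_t is None else merge_t,
                     shared is not None and merge_t is None))
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "shared_label",
                                       "min_distance", "merge_threshold",
                                       "same_label_never_merged"])
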