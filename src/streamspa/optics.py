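"""Optics-group assignment from EPU beam shifts.

Movies are grouped by agglomerative (complete-linkage, Euclidean)
clustering of their beam-shift coordinates; each beam-shift cluster is then
split into sub-populations by the shot-location identifier encoded in the
EPU filename, separating the multiple beam-tilt shots taken per hole. The
user may cap the population of each group (split round-robin) and offset
the group numbering to ease dataset combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class OpticsAssignment:
    movie_id: str
    group: int          # 1-based (plus offset), contiguous
    cluster: int        # beam-shift cluster label
    location_id: str


def cluster_beamshifts(records, k: int | None = None,
                       linkage_cutoff: float | None = None) -> np.ndarray:
    """Complete-linkage clustering of (shift_x, shift_y); returns labels.

    With neither ``k`` nor ``linkage_cutoff`` given, the number of clusters
    is chosen automatically at the largest relative gap in the merge
    distances of the dendrogram. Deterministic for fixed input.
    """
    records = list(records)
    if len(records) == 0:
        raise ValueError("no beam-shift records")
    X = np.array([(r.shift_x, r.shift_y) for r in records])
    if len(records) == 1:
        return np.zeros(1, dtype=int)
    Z = linkage(X, method="complete")
    heights = Z[:, 2]
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif linkage_cutoff is not None:
        labels = fcluster(Z, t=linkage_cutoff, criterion="distance")
    else:
        if heights[-1] <= 0:  # all shifts identical
            return np.zeros(len(records), dtype=int)
        # largest relative jump between consecutive merge heights
        lo = np.maximum(heights[:-1], 1e-12 * heights[-1])
        ratios = heights[1:] / lo
        if len(ratios) == 0 or ratios.max() < 3.0:
            labels = np.ones(len(records), dtype=int)
        else:
            split = int(np.argmax(ratios))
            cutoff = 0.5 * (heights[split] + heights[split + 1])
            labels = fcluster(Z, t=cutoff, criterion="distance")
    return np.asarray(labels, dtype=int) - int(labels.min())


def assign_groups(records, labels, max_pop: int | None = None,
                  offset: int = 0) -> list[OpticsAssignment]:
    """Split clusters by location identifier and number the groups.

    Within each beam-shift cluster, movies are partitioned by their
    location_id; any partition larger than ``max_pop`` is split round-robin
    into ceil(n/max_pop) equal-as-possible subgroups. Final groups are
    renumbered contiguously from ``1 + offset`` in (cluster, location_id)
    order; membership is independent of the input record order.
    """
    records = list(records)
    labels = np.asarray(labels)
    if len(records) != len(labels):
        raise ValueError("labels do not match records")
    buckets: dict[tuple[int, str], list[int]] = {}
    for i, (rec, lab) in enumerate(zip(records, labels)):
        buckets.setdefault((int(lab), rec.location_id), []).append(i)
    out: list[OpticsAssignment | None] = [None] * len(records)
    group = offset
    for key in sorted(buckets):
        # movie_id ordering makes the split stable under input permutation
        members = sorted(buckets[key], key=lambda i: records[i].movie_id)
        n_sub = 1 if max_pop is None else max(math.ceil(len(members) / max_pop), 1)
        for m, idx in enumerate(members):
            rec = records[idx]
            out[idx] = OpticsAssignment(
                movie_id=rec.movie_id,
                group=group + 1 + (m % n_sub),
                cluster=key[0],
                location_id=rec.location_id,
            )
        group += n_sub
    return out  # type: ignore[return-value]
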