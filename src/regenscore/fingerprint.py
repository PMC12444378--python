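"""Farm management fingerprints: practice-consistency matrices and clustering.

A fingerprint summarizes how consistently each practice was implemented on
each farm over a multi-year window: cell (farm, practice) is the fraction of
window years *with data* in which the practice was applied on at least one
field (1 = implemented every year).  Presence is binary per year for every
practice — graded area-based scores belong to the scoring module, not here.

Farms are then grouped by agglomerative clustering on their fingerprint rows
(Euclidean distance, average linkage by default), the standard treatment for
continuous profiles in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import RegenError, ScoreError
from .practice_model import FarmHistory, PracticeMap

__all__ = [
    "Fingerprint",
    "ClusterResult",
    "consistency_matrix",
    "cluster_farms",
    "fingerprint_to_csv",
    "fingerprint_from_csv",
    "fingerprint_heatmap_data",
]


@dataclass
class Fingerprint:
    """Farm × practice consistency matrix over a window of years."""

    farms: list[str]
    practices: list[str]
    matrix: np.ndarray  # shape (n_farms, n_practices), values in [0, 1]
    window: tuple[int, int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.farms), len(self.practices)):
            raise ScoreError("fingerprint matrix shape mismatch")
        if self.matrix.size and (
            (self.matrix < 0).any() or (self.matrix > 1).any()
        ):
            raise ScoreError("fingerprint cells must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Practice-by-farm frame (farms as columns, mirroring heatmap layout)."""
        return pd.DataFrame(
            self.matrix.T, index=self.practices, columns=self.farms
        ).rename_axis(index="practice", columns="farm")

    def row(self, farm_id: str) -> np.ndarray:
        return self.matrix[self.farms.index(farm_id)]


@dataclass
class ClusterResult:
    """A flat cut of the farm dendrogram into k clusters."""

    labels: dict[str, int]
    linkage: np.ndarray
    k: int

    def members(self, cluster_id: int) -> list[str]:
        return [f for f, c in self.labels.items() if c == cluster_id]


def consistency_matrix(histories: Sequence[FarmHistory],
                       pmap: PracticeMap,
                       window: tuple[int, int]) -> Fingerprint:
    """Build the farm × practice consistency fingerprint over ``window``.

    For each farm, the denominator is the number of window years with any
    recorded field-season (years without data are excluded, not counted as
    "not implemented").  Farms with no data in the window are dropped with a
    warning.
    """
    first, last = window
    if last < first:
        raise ScoreError(f"invalid window {window}")
    farms, rows = [], []
    for h in sorted(histories, key=lambda h: h.farm_id):
        years = [y for y in h.years if first <= y <= last]
        if not years:
            warnings.warn(
                f"farm {h.farm_id}: no data in window {window}; excluded",
                stacklevel=2,
            )
            continue
        row = []
        for pr in pmap.practices:
            applied = sum(
                1
                for y in years
                if any(pr.id in s.practices for s in h.seasons_in(y))
            )
            row.append(applied / len(years))
        farms.append(h.farm_id)
        rows.append(row)
    if not farms:
        raise ScoreError(f"no farm has data in window {window}")
    return Fingerprint(farms, list(pmap.practice_ids), np.array(rows), window)


def cluster_farms(fp: Fingerprint, k: int,
                  metric: str = "euclidean",
                  method: str = "average") -> ClusterResult:
    """Agglomerative clustering of fingerprint rows, cut into k clusters.

    Farms are processed in sorted-id order, which fixes tie-breaking and makes
    the result deterministic for a given fingerprint.
    """
    n = len(fp.farms)
    if not 1 <= k <= n:
        raise ScoreError(f"k={k} out of range for {n} farms")
    order = np.argsort(fp.farms)
    farms = [fp.farms[i] for i in order]
    rows = fp.matrix[order]
    if n == 1:
        return ClusterResult({farms[0]: 1}, np.empty((0, 4)), 1)
    dist = pdist(rows, metric=metric)
    tree = linkage(dist, method=method)
    flat = fcluster(tree, t=k, criterion="maxclust")
    # relabel clusters 1..k in order of first appearance for stable ids
    seen: dict[int, int] = {}
    labels = {}
    for farm, c in zip(farms, flat):
        labels[farm] = seen.setdefault(int(c), len(seen) + 1)
    return ClusterResult(labels, tree, len(set(labels.values())))


def fingerprint_to_csv(fp: Fingerprint, path: str | Path,
                       header_lines: Sequence[str] = ()) -> None:
    """Write the matrix with practices as rows and farms as columns."""
    if not fp.practices:
        raise RegenError("fingerprint has no practices")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# window: {fp.window[0]}-{fp.window[1]}\n")
        fp.to_frame().to_csv(fh)


def fingerprint_from_csv(path: str | Path) -> Fingerprint:
    window = (0, 0)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# window:"):
                a, b = line.split(":", 1)[1].strip().split("-")
                window = (int(a), int(b))
    df = pd.read_csv(path, comment="#", index_col=0)
    return Fingerprint(
        farms=[str(c) for c in df.columns],
        practices=[str(i) for i in df.index],
        matrix=df.to_numpy().T,
        window=window,
    )


def fingerprint_heatmap_data(fp: Fingerprint) -> pd.DataFrame:
    """Long-format (farm, practice, consistency) triples for plotting."""
    if not fp.practices:
        raise RegenError("fingerprint has no practices")
    recs = [
        (farm, practice, fp.matrix[i, j])
        for i, farm in enumerate(fp.farms)
        for j, practice in enumerate(fp.practices)
    ]
    return pd.DataFrame(recs, columns=["farm", "practice", "consistency"])
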