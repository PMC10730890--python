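"""Spatial cell-cell interaction features.

Cells segmented from a multiplexed tissue image are represented as points
in the plane with a phenotype label.  A radius graph links cells lying
within a fixed neighbor distance (default 4 μm); its connected components
are the *cellular communities*.  Two families of per-patient features are
computed:

* **CP** (cellular phenotype) densities — count of each phenotype per μm²
  of tissue area.
* **CCIS** (cell-cell interaction score) — for every unordered phenotype
  pair (x, y), the sum over communities of ``C * B_xy`` divided by the
  tissue area ``A``, where ``C`` is the community's mean local clustering
  coefficient and ``B_xy`` the number of graph edges joining a cell of
  phenotype x to one of phenotype y (each undirected edge counted once).

Pairwise features are organized by the tissue classes of their members:
pairs with at least one immune or stromal member form the
tumor-microenvironment interaction (TMI) set; epithelial-epithelial pairs
form the tumor-core interaction (TCI) set.  A 27-phenotype palette yields
27 CP + 273 TMI + 105 TCI = 405 features before zero-variance filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .palette import PhenotypePalette

CELL_COLUMNS = ("cell_id", "x_um", "y_um", "phenotype")

#: feature-set tags
CP, TMI, TCI = "CP", "TMI", "TCI"

_CLASS_ORDER = {"immune": 0, "stromal": 1, "epithelial": 2}


class EmptyImageError(ValueError):
    """Raised when an operation requires at least one cell."""


@dataclass
class PatientImage:
    """One patient's segmented cell table plus geometry.

    Parameters
    ----------
    patient_id
        Identifier shared with the clinical and survival tables.
    cells
        Table with columns ``cell_id, x_um, y_um, phenotype``.
    area_um2
        Total tissue area in μm².  When ``None`` the convex hull of the
        cell centroids is used as a fallback.
    neighbor_radius
        Neighbor distance in μm defining graph edges (inclusive).
    """

    patient_id: str
    cells: pd.DataFrame
    area_um2: float | None = None
    neighbor_radius: float = 4.0

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(
                f"cell table of patient {self.patient_id!r} lacks columns {missing}"
            )
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError(f"non-finite coordinates in patient {self.patient_id!r}")
        if self.area_um2 is not None and self.area_um2 <= 0:
            raise ValueError("area_um2 must be positive when provided")
        if self.neighbor_radius <= 0:
            raise ValueError("neighbor_radius must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def area(self) -> float:
        """Tissue area in μm²: the provided value, else the convex hull area."""
        if self.area_um2 is not None:
            return float(self.area_um2)
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(xy) < 3:
            raise ValueError(
                f"patient {self.patient_id!r}: cannot infer area from fewer "
                "than 3 cells; provide area_um2"
            )
        try:
            hull = ConvexHull(xy)
        except QhullError as exc:
            raise ValueError(
                f"patient {self.patient_id!r}: degenerate cell geometry, "
                "provide area_um2"
            ) from exc
        if hull.volume <= 0:
            raise ValueError(f"patient {self.patient_id!r}: zero hull area")
        return float(hull.volume)


@dataclass
class CommunityStats:
    """Per-community clustering coefficient and phenotype-pair edge counts."""

    community_id: int
    clustering_coefficient: float
    pair_counts: dict[tuple[str, str], int]


@dataclass
class FeatureMatrix:
    """Patients × features with per-feature taxonomy metadata.

    ``values`` holds the numeric matrix (patients in rows); ``meta`` has one
    row per feature with columns ``feature, set, category, member_1,
    member_2`` where ``set`` is CP/TMI/TCI.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.meta["feature"]):
            raise ValueError("feature metadata out of sync with value columns")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, feature_set: str) -> pd.DataFrame:
        """Columns belonging to one feature set (CP, TMI or TCI)."""
        names = self.meta.loc[self.meta["set"] == feature_set, "feature"]
        return self.values[list(names)]

    def set_sizes(self) -> dict[str, int]:
        return self.meta["set"].value_counts().to_dict()


def build_neighbor_graph(image: PatientImage) -> nx.Graph:
    """Radius graph on cell centroids with community ids.

    Edges join cells whose Euclidean distance is at most
    ``image.neighbor_radius`` (ties at the radius are edges).  Communities
    are the connected components of the graph, labelled by a ``community``
    node attribute; isolated cells form singleton communities.
    """
    if image.n_cells == 0:
        raise EmptyImageError(f"patient {image.patient_id!r} has no cells")
    ids = image.cells["cell_id"].tolist()
    xy = image.cells[["x_um", "y_um"]].to_numpy(dtype=float)
    g = nx.Graph()
    for cid, pheno in zip(ids, image.cells["phenotype"]):
        g.add_node(cid, phenotype=pheno)
    tree = cKDTree(xy)
    for i, j in tree.query_pairs(r=image.neighbor_radius):
        g.add_edge(ids[i], ids[j])
    for comm_id, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            g.nodes[node]["community"] = comm_id
    return g


def community_stats(
    graph: nx.Graph, clustering: str = "local"
) -> list[CommunityStats]:
    """Clustering coefficient and phenotype-pair edge counts per community.

    ``clustering="local"`` (default) averages the local clustering
    coefficient over the community's nodes, with nodes of degree < 2
    contributing 0; ``"global"`` uses the community transitivity instead.
    """
    if clustering not in ("local", "global"):
        raise ValueError(f"unknown clustering mode {clustering!r}")
    stats: list[CommunityStats] = []
    communities: dict[int, list] = {}
    for node, data in graph.nodes(data=True):
        communities.setdefault(data["community"], []).append(node)
    local_cc = nx.clustering(graph) if clustering == "local" else None
    for comm_id in sorted(communities):
        nodes = communities[comm_id]
        sub = graph.subgraph(nodes)
        if clustering == "local":
            c = float(np.mean([local_cc[n] for n in nodes]))
        else:
            c = float(nx.transitivity(sub)) if sub.number_of_edges() else 0.0
        counts: dict[tuple[str, str], int] = {}
        for u, v in sub.edges():
            pair = tuple(sorted((graph.nodes[u]["phenotype"], graph.nodes[v]["phenotype"])))
            counts[pair] = counts.get(pair, 0) + 1
        stats.append(CommunityStats(comm_id, c, counts))
    return stats


def ccis(
    image: PatientImage,
    palette: PhenotypePalette,
    clustering: str = "local",
) -> dict[tuple[str, str], float]:
    """Cell-cell interaction score for every unordered phenotype pair.

    For each community the phenotype-pair edge counts are weighted by the
    community's clustering coefficient; the weighted counts are summed over
    communities and divided by the tissue area, giving scores in 1/μm².
    Pairs with no supporting edges score 0.
    """
    area = image.area()
    unknown = set(image.cells["phenotype"]) - set(palette.names)
    if unknown:
        raise ValueError(f"phenotypes outside palette: {sorted(unknown)}")
    graph = build_neighbor_graph(image)
    scores = {pair: 0.0 for pair, _ in enumerate_pairs(palette)}
    for cs in community_stats(graph, clustering=clustering):
        if cs.clustering_coefficient == 0.0:
            continue
        for pair, count in cs.pair_counts.items():
            key = _canonical_pair(pair, palette)
            scores[key] += cs.clustering_coefficient * count
    return {pair: val / area for pair, val in scores.items()}


def phenotype_density(
    image: PatientImage, palette: PhenotypePalette
) -> dict[str, float]:
    """Count of each phenotype per μm² of tissue area."""
    area = image.area()
    counts = image.cells["phenotype"].value_counts()
    unknown = set(counts.index) - set(palette.names)
    if unknown:
        raise ValueError(f"phenotypes outside palette: {sorted(unknown)}")
    return {p: float(counts.get(p, 0)) / area for p in palette.names}


def _canonical_pair(
    pair: tuple[str, str], palette: PhenotypePalette
) -> tuple[str, str]:
    x, y = pair
    return (x, y) if palette.index(x) <= palette.index(y) else (y, x)


def pair_category(pair: tuple[str, str], palette: PhenotypePalette) -> str:
    """Tissue-class category of a phenotype pair, e.g. ``"immune-epithelial"``."""
    classes = sorted(
        (palette.class_of[pair[0]], palette.class_of[pair[1]]),
        key=_CLASS_ORDER.__getitem__,
    )
    return f"{classes[0]}-{classes[1]}"


def enumerate_pairs(
    palette: PhenotypePalette,
) -> list[tuple[tuple[str, str], str]]:
    """All unordered phenotype pairs (self-pairs included) with categories.

    A palette of k phenotypes yields k(k+1)/2 pairs; the default
    27-phenotype palette yields 378.
    """
    pairs = []
    for i, x in enumerate(palette.names):
        for y in palette.names[i:]:
            pairs.append(((x, y), pair_category((x, y), palette)))
    return pairs


def ccis_feature_name(pair: tuple[str, str]) -> str:
    return f"ccis|{pair[0]}|{pair[1]}"


def density_feature_name(phenotype: str) -> str:
    return f"density|{phenotype}"


def assemble_features(
    images: Sequence[PatientImage],
    palette: PhenotypePalette,
    clustering: str = "local",
) -> FeatureMatrix:
    """Per-patient CP density and pairwise CCIS features for a cohort.

    Columns are the palette's phenotype densities (set CP) followed by all
    pairwise interaction scores: non-epithelial-involving pairs are tagged
    TMI and epithelial-epithelial pairs TCI.
    """
    if not images:
        raise ValueError("no patient images provided")
    pairs = enumerate_pairs(palette)
    meta_rows = [
        {
            "feature": density_feature_name(p),
            "set": CP,
            "category": "density",
            "member_1": p,
            "member_2": p,
        }
        for p in palette.names
    ]
    for pair, category in pairs:
        meta_rows.append(
            {
                "feature": ccis_feature_name(pair),
                "set": TCI if category == "epithelial-epithelial" else TMI,
                "category": category,
                "member_1": pair[0],
                "member_2": pair[1],
            }
        )
    meta = pd.DataFrame(meta_rows)
    rows = {}
    for image in images:
        dens = phenotype_density(image, palette)
        inter = ccis(image, palette, clustering=clustering)
        row = [dens[p] for p in palette.names]
        row.extend(inter[pair] for pair, _ in pairs)
        rows[image.patient_id] = row
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(meta["feature"])
    )
    values.index.name = "patient_id"
    return FeatureMatrix(values=values, meta=meta)


def drop_zero_features(m: FeatureMatrix) -> FeatureMatrix:
    """Remove features that are identically zero across all patients.

    The names of the removed features are recorded on the returned
    matrix's ``dropped`` attribute.
    """
    zero = (m.values == 0).all(axis=0)
    dropped = list(m.values.columns[zero])
    keep = [c for c in m.values.columns if c not in set(dropped)]
    return FeatureMatrix(
        values=m.values[keep],
        meta=m.meta[m.meta["feature"].isin(keep)].reset_index(drop=True),
        dropped=dropped,
    )
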