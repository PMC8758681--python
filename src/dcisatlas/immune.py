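"""Immune micro-environment states from compartmentalized cell densities.

Multiplex IHC phenotypes each nucleated cell (T-cell, B-cell, regulatory
T-cell, epithelial, other), its proliferative status (Ki67+/-), and its
compartment (epithelium = cytokeratin-positive area; stroma = adjacent
cytokeratin-negative area).  Per region the pipeline computes 18 density
features — {BC, TC, TREG} x {p: Ki67+, np: Ki67-, t: total} x {Epi, Str},
in cells/mm^2, with absent cell populations contributing an explicit 0 —
then:

1. :func:`decile_regularize` maps each feature to integer decile scores
   1..10 across regions, removing scale differences between features.
2. :func:`factorize_densities` decomposes the regions x features score
   matrix by rank-4 non-negative matrix factorization (Frobenius loss,
   multiplicative updates, best of seeded restarts) into meta-markers
   MM1-MM4: W gives each meta-marker's feature composition, H gives each
   region's meta-marker loading.
3. :func:`assign_immune_states` clusters H columns hierarchically
   (Euclidean distance, Ward linkage, cut at k=3) and names the clusters:
   the MM4-dominant cluster is "Excluded" (stromal-restricted
   lymphocytes), the MM2-dominant remainder is "Active" (ubiquitous high
   T-cells), the last is "Suppressed" (low T-cells, elevated B-cells and
   T-regs).

Epithelial (PanCK) counts define the compartments but are not density
features; T-reg counts are kept disjoint from the T-cell feature by
default so the features stay non-redundant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

__all__ = [
    "CellRecord",
    "RegionDensities",
    "MetaMarkerModel",
    "IMMUNE_STATES",
    "FEATURES",
    "compute_density_matrix",
    "densities_frame",
    "decile_regularize",
    "factorize_densities",
    "assign_immune_states",
    "compartment_ratio",
]

PHENOTYPES = ("T-cell", "B-cell", "T-reg", "epithelial", "other")
COMPARTMENTS = ("epithelium", "stroma")
IMMUNE_STATES = ("Active", "Suppressed", "Excluded")

CELL_TYPES = ("BC", "TC", "TREG")
_PHENOTYPE_OF = {"BC": "B-cell", "TC": "T-cell", "TREG": "T-reg"}
_COMP_TAG = {"epithelium": "Epi", "stroma": "Str"}

#: The 18 density features, grouped by cell type, Ki67 state, compartment.
FEATURES = tuple(
    f"{ct}_{state}_{comp}"
    for ct in CELL_TYPES
    for state in ("p", "np", "t")
    for comp in ("Epi", "Str")
)


@dataclass(frozen=True)
class CellRecord:
    """One phenotyped cell from a multiplex IHC region."""

    x: float
    y: float
    phenotype: str
    ki67: str  # positive / negative
    compartment: str  # epithelium / stroma

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.ki67 not in ("positive", "negative"):
            raise ValueError(f"unknown ki67 status {self.ki67!r}")


@dataclass(frozen=True)
class RegionDensities:
    """18 compartmentalized cell densities (cells/mm^2) for one region."""

    region_id: str
    densities: Mapping[str, float]
    area_mm2: Mapping[str, float]
    region_class: str = "main pre-invasive"

    def __post_init__(self) -> None:
        missing = set(FEATURES) - set(self.densities)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")
        if any(v < 0 for v in self.densities.values()):
            raise ValueError("negative density")


@dataclass
class MetaMarkerModel:
    """Rank-4 NMF of the regions x features decile scores."""

    W: pd.DataFrame  # features x meta-markers, columns MM1..MM4
    H: pd.DataFrame  # meta-markers x regions
    loss: float
    seed: int
    n_iter: int
    loss_history: np.ndarray

    @property
    def rank(self) -> int:
        return self.W.shape[1]

    @property
    def meta_markers(self) -> list[str]:
        return list(self.W.columns)


def compute_density_matrix(
    cells_by_region: Mapping[str, Sequence[CellRecord]],
    areas_by_region: Mapping[str, Mapping[str, float]],
    include_tregs_in_tcells: bool = False,
) -> list[RegionDensities]:
    """Compartmentalized densities for each region.

    ``areas_by_region`` maps region -> {"epithelium": mm2, "stroma": mm2};
    both areas must be positive.  Absent populations yield density 0, and
    the total feature is the sum of the Ki67+ and Ki67- features by
    construction.
    """
    out = []
    for region_id, cells in cells_by_region.items():
        areas = areas_by_region[region_id]
        for comp in COMPARTMENTS:
            if comp not in areas or areas[comp] <= 0:
                raise ValueError(
                    f"region {region_id!r}: {comp} area must be positive"
                )
        counts: dict[str, int] = {f: 0 for f in FEATURES}
        for cell in cells:
            for ct in CELL_TYPES:
                match = cell.phenotype == _PHENOTYPE_OF[ct] or (
                    include_tregs_in_tcells and ct == "TC" and cell.phenotype == "T-reg"
                )
                if not match:
                    continue
                state = "p" if cell.ki67 == "positive" else "np"
                tag = _COMP_TAG[cell.compartment]
                counts[f"{ct}_{state}_{tag}"] += 1
                counts[f"{ct}_t_{tag}"] += 1
        densities = {
            f: counts[f] / areas["epithelium" if f.endswith("Epi") else "stroma"]
            for f in FEATURES
        }
        out.append(
            RegionDensities(region_id=region_id, densities=densities, area_mm2=dict(areas))
        )
    return out


def densities_frame(regions: Sequence[RegionDensities]) -> pd.DataFrame:
    """Stack per-region densities into a regions x 18 DataFrame."""
    return pd.DataFrame(
        {r.region_id: [r.densities[f] for f in FEATURES] for r in regions},
        index=list(FEATURES),
    ).T


def decile_regularize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature decile scores 1..10 with average ranks for ties.

    score = ceil(10 * rank / n).  A constant feature maps every region to
    a single decile; with n >= 10 distinct values the scores spread close
    to uniformly over 1..10.
    """
    n = len(matrix)
    if n < 2:
        raise ValueError("decile regularization requires at least 2 regions")
    scores = {}
    for col in matrix.columns:
        ranks = rankdata(matrix[col].to_numpy(), method="average")
        scores[col] = np.ceil(10.0 * ranks / n).astype(int)
    return pd.DataFrame(scores, index=matrix.index)


def _nmf_mu(
    X: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF for 0.5*||X - WH||_F^2; returns W, H, losses."""
    eps = 1e-12
    m, n = X.shape
    scale = math.sqrt(X.mean() / rank) if X.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(m, rank)) * scale
    H = rng.uniform(0.1, 1.0, size=(rank, n)) * scale
    losses = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ H @ H.T + eps)
        loss = 0.5 * float(np.linalg.norm(X - W @ H) ** 2)
        losses.append(loss)
        if prev is not None and abs(prev - loss) <= tol * max(prev, eps):
            break
        prev = loss
    return W, H, np.asarray(losses)


def _canonical_factor_order(W: np.ndarray, features: Sequence[str]) -> list[int]:
    """Order rank-4 factors so meta-marker indices carry their usual meaning.

    NMF factor order is arbitrary, so factors are relabeled by the
    feature groups they load on: MM2 is the factor with the largest
    T-cell weight (the ubiquitous T-cell axis), MM4 the remaining factor
    with the largest stroma-minus-epithelium skew (the exclusion axis),
    MM1 the remaining factor with the largest Ki67+ share (the
    proliferative axis), and MM3 the leftover (B-cell / T-reg axis).
    """
    feats = [str(f) for f in features]
    tc = np.array([f.startswith("TC_") for f in feats])
    stromal = np.array([f.endswith("_Str") for f in feats])
    epi = np.array([f.endswith("_Epi") for f in feats])
    prolif = np.array(["_p_" in f for f in feats])

    available = set(range(W.shape[1]))
    mm2 = max(available, key=lambda j: W[tc, j].sum())
    available.discard(mm2)
    mm4 = max(available, key=lambda j: W[stromal, j].sum() - W[epi, j].sum())
    available.discard(mm4)
    mm1 = max(available, key=lambda j: W[prolif, j].sum())
    available.discard(mm1)
    (mm3,) = available
    return [mm1, mm2, mm3, mm4]


def factorize_densities(
    scores: pd.DataFrame,
    rank: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> MetaMarkerModel:
    """Rank-``rank`` NMF of the regions x features score matrix.

    Runs ``n_restarts`` seeded initializations of multiplicative updates
    and keeps the best final Frobenius loss.  W columns are normalized to
    unit maximum with compensating scaling of H, so meta-marker loadings
    in H are comparable across factors.  Deterministic given ``seed``.
    """
    X = scores.to_numpy(dtype=float).T  # features x regions
    if np.any(X < 0):
        raise ValueError("scores must be non-negative")
    if rank > min(X.shape):
        raise ValueError(f"rank {rank} exceeds min(matrix dimensions) {min(X.shape)}")
    root = np.random.SeedSequence(seed)
    best = None
    for child in root.spawn(n_restarts):
        rng = np.random.default_rng(child)
        W, H, losses = _nmf_mu(X, rank, rng, max_iter, tol)
        if best is None or losses[-1] < best[2][-1]:
            best = (W, H, losses)
    W, H, losses = best
    col_max = W.max(axis=0)
    col_max[col_max == 0] = 1.0
    W = W / col_max
    H = H * col_max[:, None]
    if rank == 4 and any(str(c).startswith("TC_") for c in scores.columns):
        order = _canonical_factor_order(W, list(scores.columns))
        W = W[:, order]
        H = H[order, :]
    names = [f"MM{i + 1}" for i in range(rank)]
    return MetaMarkerModel(
        W=pd.DataFrame(W, index=scores.columns, columns=names),
        H=pd.DataFrame(H, index=names, columns=scores.index),
        loss=float(losses[-1]),
        seed=seed,
        n_iter=len(losses),
        loss_history=losses,
    )


def assign_immune_states(model: MetaMarkerModel, k: int = 3) -> pd.Series:
    """Immune-state label per region from Ward clustering of H columns.

    H columns (regions) are clustered with Euclidean distance and Ward
    linkage, cut at ``k`` = 3.  Naming: the cluster with maximal mean MM4
    is Excluded; of the remainder the cluster with maximal mean MM2 is
    Active; the last is Suppressed.
    """
    if k != len(IMMUNE_STATES):
        raise ValueError(f"k must be {len(IMMUNE_STATES)} (one per immune state)")
    H = model.H
    data = H.to_numpy().T  # regions x meta-markers
    if len(np.unique(data, axis=0)) < k:
        raise ValueError(f"H has fewer than {k} distinct columns")
    Z = hierarchy.linkage(data, method="ward", metric="euclidean")
    clusters = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    cluster_ids = sorted(set(clusters))
    means = {
        c: data[clusters == c].mean(axis=0) for c in cluster_ids
    }
    mm2 = H.index.get_loc("MM2") if "MM2" in H.index else 1
    mm4 = H.index.get_loc("MM4") if "MM4" in H.index else 3
    excluded = max(cluster_ids, key=lambda c: means[c][mm4])
    rest = [c for c in cluster_ids if c != excluded]
    active = max(rest, key=lambda c: means[c][mm2])
    (suppressed,) = [c for c in rest if c != active]
    name_of = {excluded: "Excluded", active: "Active", suppressed: "Suppressed"}
    return pd.Series(
        [name_of[c] for c in clusters], index=H.columns, name="immune_state"
    )


def compartment_ratio(matrix: pd.DataFrame) -> pd.DataFrame:
    """Stroma/epithelium total-density ratio and category per cell type.

    For each region and cell type: ratio = Str_t / Epi_t (``inf`` when the
    epithelial density is 0 but stroma is populated — an unbounded skew).
    The category is ``none`` when both compartments are empty, otherwise
    ``high``/``low`` by comparing the epithelial total density with the
    per-cell-type median of nonzero epithelial densities.
    """
    out = {}
    for ct in CELL_TYPES:
        epi = matrix[f"{ct}_t_Epi"].to_numpy(dtype=float)
        stro = matrix[f"{ct}_t_Str"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(epi > 0, stro / np.where(epi > 0, epi, 1.0),
                             np.where(stro > 0, np.inf, np.nan))
        nonzero = epi[epi > 0]
        cutoff = np.median(nonzero) if nonzero.size else np.nan
        category = np.where(
            (epi == 0) & (stro == 0),
            "none",
            np.where(epi >= cutoff if not np.isnan(cutoff) else False, "high", "low"),
        )
        out[f"{ct}_ratio"] = ratio
        out[f"{ct}_category"] = category
    return pd.DataFrame(out, index=matrix.index)


# ---------------------------------------------------------------------------
# cell-table I/O


def read_cell_table(source) -> tuple[dict[str, list[CellRecord]], pd.DataFrame]:
    """Read a delimited cell table (x, y, phenotype, ki67, compartment, region_id)."""
    df = pd.read_csv(source, sep="\t")
    cells: dict[str, list[CellRecord]] = {}
    for _, r in df.iterrows():
        cells.setdefault(str(r["region_id"]), []).append(
            CellRecord(
                x=float(r["x"]),
                y=float(r["y"]),
                phenotype=str(r["phenotype"]),
                ki67=str(r["ki67"]),
                compartment=str(r["compartment"]),
            )
        )
    return cells, df
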