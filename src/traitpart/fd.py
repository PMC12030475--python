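"""Functional diversity indices: FRic, FEve, FDiv, FDis.

Species are positioned in a low-dimensional trait space, either by
range-normalised Gower dissimilarities embedded with square-root-corrected
principal coordinates (the default, mirroring common distance-based practice
for mixed trait sets), or by z-scored traits in Euclidean geometry.  On that
space:

* FRic — convex-hull volume of the species cloud (abundance-free);
* FEve — regularity of abundance along the minimum spanning tree, in [0, 1];
* FDiv — abundance-weighted divergence from the hull-vertex centroid, in [0, 1];
* FDis — abundance-weighted mean distance to the abundance-weighted centroid.

Degenerate inputs (too few species, collinear points, a point community)
yield explicit ``undefined`` flags rather than fabricated numbers; the single
exception is a true point community, whose FRic is genuinely 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from .data_model import (
    AbundanceMatrix,
    CommonSpeciesFilter,
    PlotDesign,
    TraitTable,
    ValidationError,
)

GEOMETRIES = ("gower-pcoa", "zscore-euclidean")


@dataclass(frozen=True)
class TraitSpace:
    """Species coordinates plus abundance weights for one community."""

    species: list[str]
    coords: np.ndarray          # S x d
    weights: np.ndarray         # S, non-negative, sums to 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.shape[0] != len(self.species):
            raise ValidationError("coordinate rows must match species")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1, got {w.sum()!r}")
        if np.isnan(coords).any():
            raise ValidationError("coordinates contain missing values")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "weights", w)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    @property
    def degenerate(self) -> bool:
        """All species at a single point of trait space."""
        return bool(np.allclose(self.coords, self.coords[0], atol=1e-12))

    def distances(self) -> np.ndarray:
        return squareform(pdist(self.coords)) if self.n_species > 1 else np.zeros((1, 1))


def gower_distance(traits: pd.DataFrame) -> pd.DataFrame:
    """Range-normalised Gower dissimilarity among species (rows).

    Each trait contributes |x_i - x_j| / range; traits with zero range are
    skipped (they cannot distinguish species).  For a single trait this is
    simply the normalised absolute difference.
    """
    X = traits.to_numpy(dtype=float)
    rng = X.max(axis=0) - X.min(axis=0)
    keep = rng > 0
    n = X.shape[0]
    if not keep.any():
        return pd.DataFrame(np.zeros((n, n)), index=traits.index, columns=traits.index)
    Xn = X[:, keep] / rng[keep]
    D = squareform(pdist(Xn, metric="cityblock")) / keep.sum()
    return pd.DataFrame(D, index=traits.index, columns=traits.index)


def _pcoa_embed(D: pd.DataFrame, n_axes: int) -> np.ndarray:
    """Classical PCoA of the square-root-corrected dissimilarity matrix.

    Taking sqrt of a Gower matrix makes it Euclidean-embeddable, removing
    negative eigenvalues up to numerical noise; remaining tiny negative axes
    are dropped.
    """
    if D.shape[0] == 1:
        return np.zeros((1, 1))
    corrected = np.sqrt(D.to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ord_res = pcoa(DistanceMatrix(corrected, ids=[str(i) for i in D.index]),
                       method="eigh", warn_neg_eigval=False)
    eig = ord_res.eigvals.to_numpy()
    coords = ord_res.samples.to_numpy()
    pos = eig > max(1e-10, 1e-8 * abs(eig).max() if len(eig) else 0)
    coords = coords[:, pos]
    if coords.shape[1] == 0:
        coords = np.zeros((D.shape[0], 1))
    return coords[:, :n_axes]


def build_trait_space(
    traits: pd.DataFrame,
    abundances: pd.Series,
    geometry: str = "gower-pcoa",
    standardize: bool = True,
) -> TraitSpace:
    """Place a community's species in trait space.

    ``traits`` is a species x trait matrix with no missing values (species
    with incomplete vectors must be dropped by the caller); ``abundances``
    holds the matching covers.  ``geometry`` selects Gower + corrected PCoA
    (default) or (optionally z-scored) Euclidean coordinates.  The number of
    retained axes is min(S - 1, number of traits).
    """
    if geometry not in GEOMETRIES:
        raise ValidationError(f"unknown geometry {geometry!r}")
    traits = traits.loc[abundances.index]
    if traits.isna().any().any():
        raise ValidationError("trait matrix has missing values")
    w = abundances.to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValidationError("total abundance must be positive")
    w = w / w.sum()
    S, n_traits = traits.shape
    n_axes = max(1, min(S - 1, n_traits))
    if geometry == "gower-pcoa":
        D = gower_distance(traits)
        coords = _pcoa_embed(D, n_axes)
        prov = {"distance": "gower", "embedding": "pcoa-sqrt", "axes": coords.shape[1]}
    else:
        X = traits.to_numpy(dtype=float)
        if standardize:
            sd = X.std(axis=0, ddof=1) if S > 1 else np.ones(n_traits)
            sd = np.where(sd > 0, sd, 1.0)
            X = (X - X.mean(axis=0)) / sd
        coords = X
        prov = {"distance": "euclidean", "embedding": "raw" if not standardize else "zscore",
                "axes": coords.shape[1]}
    return TraitSpace(list(traits.index), coords, w, prov)


def fric(space: TraitSpace) -> tuple[float, str | None]:
    """Convex-hull volume of the species coordinates (abundance-free).

    Returns ``(value, flag)``; the flag names the reason when the volume is
    undefined (fewer points than axes + 1, or affinely dependent points).
    A true point community has volume 0 with no flag.
    """
    if space.degenerate:
        return 0.0, None
    pts = space.coords
    S, d = pts.shape
    used = [j for j in range(d) if np.ptp(pts[:, j]) > 1e-12]
    pts = pts[:, used] if used else pts[:, :1]
    d = pts.shape[1]
    if d == 1:
        return float(np.ptp(pts)), None
    if S < d + 1:
        return np.nan, f"needs at least {d + 1} species for {d} axes, have {S}"
    try:
        return float(ConvexHull(pts).volume), None
    except QhullError:
        return np.nan, "degenerate geometry (affinely dependent points)"


def feve(space: TraitSpace) -> tuple[float, str | None]:
    """Minimum-spanning-tree evenness of abundance in trait space, in [0, 1]."""
    S = space.n_species
    if S < 3:
        return np.nan, f"needs at least 3 species, have {S}"
    if space.degenerate:
        return np.nan, "all species coincide in trait space"
    D = space.distances()
    # shift edge weights by a constant so zero-length edges between coincident
    # species stay in the graph; every spanning tree has S-1 edges, so a
    # uniform shift cannot change which tree is minimal
    graph = csr_matrix(np.triu(D + 1.0, k=1))
    tree = minimum_spanning_tree(graph)
    ii, jj = tree.nonzero()
    w = space.weights
    ew = np.array([D[i, j] / (w[i] + w[j]) for i, j in zip(ii, jj)])
    if ew.sum() <= 0:
        return np.nan, "minimum spanning tree has zero total length"
    pew = ew / ew.sum()
    thresh = 1.0 / (S - 1)
    val = (np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh)
    return float(val), None


def fdiv(space: TraitSpace) -> tuple[float, str | None]:
    """Abundance-weighted divergence from the hull-vertex centroid, in [0, 1]."""
    if space.degenerate:
        return np.nan, "all species coincide in trait space"
    pts = space.coords
    S, d = pts.shape
    used = [j for j in range(d) if np.ptp(pts[:, j]) > 1e-12]
    red = pts[:, used] if used else pts[:, :1]
    if red.shape[1] == 1:
        verts = [int(np.argmin(red[:, 0])), int(np.argmax(red[:, 0]))]
    else:
        if S < red.shape[1] + 1:
            return np.nan, "hull undefined: fewer species than axes + 1"
        try:
            verts = list(ConvexHull(red).vertices)
        except QhullError:
            return np.nan, "hull undefined (degenerate geometry)"
    G = pts[verts].mean(axis=0)
    dG = np.linalg.norm(pts - G, axis=1)
    dbar = dG.mean()
    dev = dG - dbar
    delta_d = float(space.weights @ dev)
    delta_abs = float(space.weights @ np.abs(dev))
    if delta_abs + dbar <= 0:
        return np.nan, "zero spread around the hull centroid"
    return float((delta_d + dbar) / (delta_abs + dbar)), None


def fdis(space: TraitSpace) -> tuple[float, str | None]:
    """Abundance-weighted mean distance to the abundance-weighted centroid."""
    c = space.weights @ space.coords
    dist = np.linalg.norm(space.coords - c, axis=1)
    return float(space.weights @ dist), None


@dataclass(frozen=True)
class FDResult:
    plot_id: str
    fric: float
    feve: float
    fdiv: float
    fdis: float
    species_count: int
    axes_used: int
    flags: dict

    def as_row(self) -> dict:
        return {
            "plot_id": self.plot_id, "FRic": self.fric, "FEve": self.feve,
            "FDiv": self.fdiv, "FDis": self.fdis,
            "species_count": self.species_count, "axes_used": self.axes_used,
            "flags": ";".join(f"{k}:{v}" for k, v in self.flags.items()),
        }


def community_fd(space: TraitSpace, plot_id: str = "") -> FDResult:
    """All four indices for one community, with undefined-value flags."""
    flags: dict[str, str] = {}
    out = {}
    for name, fn in (("FRic", fric), ("FEve", feve), ("FDiv", fdiv), ("FDis", fdis)):
        val, flag = fn(space)
        out[name] = val
        if flag:
            flags[name] = flag
    return FDResult(plot_id, out["FRic"], out["FEve"], out["FDiv"], out["FDis"],
                    space.n_species, space.n_axes, flags)


def plot_trait_matrix(
    traits: TraitTable, plot_id: str, species: list[str]
) -> pd.DataFrame:
    """Species x trait matrix for one plot: plot-specific values where
    measured, pooled averages otherwise; species with incomplete vectors are
    dropped."""
    cols = {}
    for trait in traits.traits:
        spec = traits.specific_values(trait, plot_id)
        pool = traits.pooled_values(trait)
        merged = pool.reindex(species)
        merged.update(spec.reindex(species).dropna())
        cols[trait] = merged
    mat = pd.DataFrame(cols)
    return mat.dropna(axis=0, how="any")


def fd_table(
    design: PlotDesign,
    abundance: AbundanceMatrix,
    traits: TraitTable,
    species_filter: CommonSpeciesFilter | None = None,
    geometry: str = "gower-pcoa",
) -> pd.DataFrame:
    """Per-plot functional diversity table across the whole design."""
    if species_filter is not None:
        abundance = species_filter.apply(abundance)
    rows = []
    for plot_id in design.plot_ids:
        if plot_id not in abundance.matrix.index:
            continue
        present = abundance.present_species(plot_id)
        mat = plot_trait_matrix(traits, plot_id, present)
        if mat.empty:
            raise ValidationError(f"plot {plot_id!r}: no species with complete trait data")
        covers = abundance.matrix.loc[plot_id, mat.index]
        space = build_trait_space(mat, covers, geometry=geometry)
        rows.append(community_fd(space, plot_id).as_row())
    return pd.DataFrame(rows).set_index("plot_id")
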