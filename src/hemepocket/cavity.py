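"""Cavity-shape quantification and comparison of heme-binding pockets.

A pocket's shape is encoded as a bit vector over the integer lattice points
(1 A spacing) inside an 8.5 A sphere centered on the heme iron, after rigid
superposition of each complex onto a common five-atom heme core (FE and the
four pyrrole nitrogens).  A lattice point belongs to the cavity when it lies
farther than the full Van der Waals radius from every protein heavy atom.

Cavity vectors are compared with the Tanimoto score, grouped by hierarchical
(average-linkage) clustering on 1 - Tanimoto, examined by principal component
analysis within clusters, correlated against distortion amplitudes, and
summarized by the barycenter-dispersion statistic

    N_I = |I|,  mu_I = (1/N_I) sum_i v_i,  dbar_I = (1/N_I) sum_i ||v_i - mu_I||.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._kabsch import kabsch
from .curation import HemeSample, StructureModel
from .voxel import VDW_RADIUS

#: Heme core atoms used for pocket superposition, fixed order.
CORE_ATOMS: tuple[str, ...] = ("FE", "NA", "NB", "NC", "ND")

INCLUSION_RADIUS = 8.5  # A, set by the heme size (Fe-to-propionate-O distance)

#: Exclusion radius for protein heavy atoms outside the C/N/O/S channels.
DEFAULT_EXCLUSION_RADIUS = 1.80


@lru_cache(maxsize=8)
def lattice_points(radius: float = INCLUSION_RADIUS) -> np.ndarray:
    """Fixed lexicographic enumeration of integer points with norm <= radius."""
    m = int(np.floor(radius))
    axis = np.arange(-m, m + 1)
    pts = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(pts, axis=1) <= radius
    return pts[keep].astype(float)


@dataclass(frozen=True)
class CavityVector:
    """Bits over the fixed lattice enumeration; 1 = cavity (unoccluded)."""

    bits: np.ndarray  # (n_points,) uint8
    sample_id: str = ""
    radius: float = INCLUSION_RADIUS

    def __len__(self) -> int:
        return len(self.bits)


def reference_core(reference_skeleton: np.ndarray | None = None) -> np.ndarray:
    """(5, 3) coordinates of FE, NA-ND in the reference porphyrin frame."""
    if reference_skeleton is None:
        from .synthetic import reference_porphyrin
        from .nsd import SKELETON_ATOMS

        ref = reference_porphyrin()
        idx = [SKELETON_ATOMS.index(n) for n in CORE_ATOMS]
        return ref[idx]
    return np.asarray(reference_skeleton, dtype=float)[:5]


def superpose_on_core(
    model: StructureModel,
    sample: HemeSample,
    core: np.ndarray | None = None,
) -> StructureModel:
    """Rigidly superpose the whole complex onto a reference heme core.

    The sample's FE, NA, NB, NC, ND are least-squares fitted onto ``core``
    (defaults to the package reference porphyrin) and the fitted transform is
    applied to every atom of the model.  Raises if any core atom is missing.
    """
    missing = [n for n in CORE_ATOMS if n not in sample.skeleton]
    if missing:
        raise ValueError(f"{sample.label}: core atoms missing for superposition: {missing}")
    mobile = np.array([sample.skeleton[n] for n in CORE_ATOMS])
    target = reference_core() if core is None else np.asarray(core, dtype=float)
    if target.shape != (5, 3):
        raise ValueError(f"reference core must be (5, 3), got {target.shape}")
    fit = kabsch(mobile, target)
    return model.transformed(fit.rotation, fit.translation)


def cavity_vector(
    model: StructureModel,
    center: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
    radius: float = INCLUSION_RADIUS,
    sample_id: str = "",
) -> CavityVector:
    """Cavity bit vector from the protein coordinates only.

    ``model`` must already be superposed on the reference core; ``center``
    is the Fe position in that frame (the origin for the reference core).
    A lattice point is cavity (bit 1) iff every protein heavy atom is farther
    away than its full Van der Waals radius.
    """
    pts = lattice_points(radius) + np.asarray(center, dtype=float)
    coords, elements = model.protein_coords()
    bits = np.ones(len(pts), dtype=np.uint8)
    if len(coords):
        radii = np.array([VDW_RADIUS.get(e, DEFAULT_EXCLUSION_RADIUS) for e in elements])
        # process atoms in blocks to bound memory on large proteins
        for start in range(0, len(coords), 512):
            c = coords[start:start + 512]
            r = radii[start:start + 512]
            d2 = ((pts[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
            occluded = (d2 <= (r ** 2)[None, :]).any(axis=1)
            bits[occluded] = 0
    return CavityVector(bits=bits, sample_id=sample_id, radius=radius)


def tanimoto(v: CavityVector | np.ndarray, w: CavityVector | np.ndarray) -> float:
    """|v AND w| / |v OR w|; two all-zero vectors count as identical (1)."""
    a = (v.bits if isinstance(v, CavityVector) else np.asarray(v)).astype(bool)
    b = (w.bits if isinstance(w, CavityVector) else np.asarray(w)).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"cavity vectors differ in length: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return float(np.sum(a & b)) / union


def tanimoto_matrix(vectors: Sequence[CavityVector | np.ndarray]) -> np.ndarray:
    """Dense pairwise Tanimoto similarity matrix."""
    bits = np.stack([(v.bits if isinstance(v, CavityVector) else np.asarray(v)) for v in vectors]).astype(bool)
    inter = (bits[:, None, :] & bits[None, :, :]).sum(axis=2).astype(float)
    union = (bits[:, None, :] | bits[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


def cluster_cavities(vectors: Sequence[CavityVector | np.ndarray], n_clusters: int = 35) -> np.ndarray:
    """Average-linkage hierarchical clustering on 1 - Tanimoto distance.

    Returns integer labels in ``1..n_clusters``; the partition is invariant
    (up to label renaming) under permutation of the input.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    if len(vectors) < n_clusters:
        raise ValueError(f"need at least n_clusters={n_clusters} vectors, got {len(vectors)}")
    dist = 1.0 - tanimoto_matrix(vectors)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=n_clusters, criterion="maxclust")


@dataclass
class PCAResult:
    scores: np.ndarray              # (n, n_components)
    components: np.ndarray          # (n_components, n_points) lattice loadings
    explained_variance_ratio: np.ndarray

    @property
    def pc1(self) -> np.ndarray:
        return self.scores[:, 0]

    def loadings_table(self, radius: float = INCLUSION_RADIUS, component: int = 0) -> pd.DataFrame:
        """Per-lattice-point loadings of one eigenvector (point-cloud export)."""
        pts = lattice_points(radius)
        return pd.DataFrame({
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "loading": self.components[component],
        })


def pca_within_cluster(vectors: Sequence[CavityVector | np.ndarray], n_components: int | None = None) -> PCAResult:
    """Mean-centered PCA of cavity bit vectors (eigenvectors over lattice points).

    Scores have zero mean per component; component signs are fixed so the
    largest-magnitude loading is positive, making the result independent of
    input order.  Raises for fewer than 3 members or zero variance.
    """
    x = np.stack([(v.bits if isinstance(v, CavityVector) else np.asarray(v)) for v in vectors]).astype(float)
    if len(x) < 3:
        raise ValueError(f"PCA needs at least 3 members, got {len(x)}")
    xc = x - x.mean(axis=0)
    total_var = float((xc ** 2).sum())
    if total_var <= 0:
        raise ValueError("cavity vectors are identical; PCA variance is zero")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = n_components or min(len(x) - 1, vt.shape[0])
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    evr = (s ** 2) / total_var
    return PCAResult(scores=scores, components=vt, explained_variance_ratio=evr)


def correlate_pc_with_distortion(
    scores: np.ndarray,
    distortions: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation (with regression slope/intercept) per mode.

    ``scores`` are per-member PC values; ``distortions`` maps mode name to
    the paired amplitudes.  Zero variance in either variable yields NaN and
    ``defined=False`` for that mode.
    """
    from scipy import stats

    scores = np.asarray(scores, dtype=float).ravel()
    if len(scores) < 3:
        raise ValueError("need at least 3 paired samples")
    cols = distortions.columns if isinstance(distortions, pd.DataFrame) else list(distortions)
    rows = []
    for mode in cols:
        vals = np.asarray(distortions[mode], dtype=float).ravel()
        if vals.shape != scores.shape:
            raise ValueError(f"mode {mode!r}: length mismatch with scores")
        if np.std(vals) == 0 or np.std(scores) == 0:
            rows.append({"mode": mode, "r": np.nan, "slope": np.nan, "intercept": np.nan, "defined": False})
            continue
        fit = stats.linregress(scores, vals)
        rows.append({"mode": mode, "r": fit.rvalue, "slope": fit.slope,
                     "intercept": fit.intercept, "defined": True})
    return pd.DataFrame(rows).set_index("mode")


@dataclass(frozen=True)
class DispersionReport:
    """Barycenter statistics of one cavity-shape cluster."""

    cluster_id: int | str
    n: int                       # N_I
    barycenter: np.ndarray       # mu_I
    mean_distance: float         # dbar_I (L2)


def dispersion(vectors: Sequence[CavityVector | np.ndarray], cluster_id: int | str = 0) -> DispersionReport:
    """Mean Euclidean distance of a cluster's members from their barycenter."""
    if len(vectors) == 0:
        raise ValueError("dispersion of an empty cluster is undefined")
    x = np.stack([(v.bits if isinstance(v, CavityVector) else np.asarray(v)) for v in vectors]).astype(float)
    mu = x.mean(axis=0)
    dbar = float(np.mean(np.linalg.norm(x - mu, axis=1)))
    return DispersionReport(cluster_id=cluster_id, n=len(x), barycenter=mu, mean_distance=dbar)


def heme_coverage(model: StructureModel, sample: HemeSample, cutoff: float = 5.0) -> float:
    """Fraction of the 25 skeleton atoms buried in protein (burial fraction).

    A skeleton atom counts as covered when at least one protein heavy atom
    lies within ``cutoff`` angstroms.  Samples below 0.6 coverage indicate a
    pocket split across an asymmetric unit and are excluded from dispersion
    analyses.
    """
    skel = sample.skeleton_array()
    coords, _ = model.protein_coords()
    if len(coords) == 0:
        return 0.0
    d2 = ((skel[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    covered = (d2 <= cutoff * cutoff).any(axis=1)
    return float(np.mean(covered))
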