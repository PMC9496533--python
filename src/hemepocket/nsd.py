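"""Normal-coordinate structural decomposition (NSD) of the Fe-porphyrin skeleton.

The deviation of an observed 25-atom Fe-porphyrin skeleton from a planar
equilibrium geometry is expressed as a linear combination of 12 orthonormal
displacement modes (the low-frequency out-of-plane modes saddling, ruffling,
doming, waving(x), waving(y) and propellering, plus six in-plane modes
including breathing).  The observed skeleton is first rigidly superposed onto
the reference geometry; the residual 75-dimensional displacement is then
projected onto the mode basis, yielding one amplitude in angstroms per mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._kabsch import Superposition, kabsch

#: Canonical names of the 25 skeleton atoms, in the fixed row order used
#: throughout the package: iron, pyrrole nitrogens, meso carbons, then the
#: alpha/beta carbons of pyrroles A-D.
SKELETON_ATOMS: tuple[str, ...] = (
    "FE",
    "NA", "NB", "NC", "ND",
    "CHA", "CHB", "CHC", "CHD",
    "C1A", "C2A", "C3A", "C4A",
    "C1B", "C2B", "C3B", "C4B",
    "C1C", "C2C", "C3C", "C4C",
    "C1D", "C2D", "C3D", "C4D",
)

#: Canonical names of the 12 modes, fixed order.
MODE_NAMES: tuple[str, ...] = (
    "saddling",
    "ruffling",
    "doming",
    "waving_x",
    "waving_y",
    "propellering",
    "breathing",
    "meso_stretch",
    "pyrrole_stretch",
    "quad_stretch_x",
    "quad_stretch_y",
    "pyrrole_shear",
)

#: The four lowest out-of-plane modes for which pocket structure is most
#: predictive; used as default regression targets.
PRIMARY_MODES: tuple[str, ...] = ("saddling", "ruffling", "doming", "waving_y")


@dataclass(frozen=True)
class ModeBasis:
    """Reference skeleton geometry plus 12 orthonormal displacement modes.

    Attributes
    ----------
    reference : (25, 3) float array, centroid at the origin (angstroms).
    modes : (12, 75) float array; each row is a unit-norm displacement of the
        25 atoms flattened in ``SKELETON_ATOMS`` order, mutually orthogonal.
    names : the 12 mode names, a permutation-free copy of ``MODE_NAMES``.
    """

    reference: np.ndarray
    modes: np.ndarray
    names: tuple[str, ...] = field(default=MODE_NAMES)

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        modes = np.asarray(self.modes, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "modes", modes)
        object.__setattr__(self, "names", tuple(self.names))
        validate_mode_basis(self)

    def index(self, name: str) -> int:
        return self.names.index(name)


def validate_mode_basis(basis: ModeBasis, tol: float = 1e-8) -> None:
    """Check cardinality, names, orthonormality and reference centering."""
    if basis.reference.shape != (25, 3):
        raise ValueError(f"reference must be (25, 3), got {basis.reference.shape}")
    if basis.modes.ndim != 2 or basis.modes.shape[1] != 75:
        raise ValueError(f"modes must be (n, 75), got {basis.modes.shape}")
    if basis.modes.shape[0] != 12:
        raise ValueError(f"expected exactly 12 modes, got {basis.modes.shape[0]}")
    if sorted(basis.names) != sorted(MODE_NAMES):
        unknown = set(basis.names) - set(MODE_NAMES)
        raise ValueError(f"mode names do not match the canonical 12 (unexpected: {sorted(unknown)})")
    gram = basis.modes @ basis.modes.T
    dev = np.abs(gram - np.eye(12))
    if dev.max() > tol:
        i, j = np.unravel_index(np.argmax(dev), dev.shape)
        raise ValueError(
            "mode basis is not orthonormal: max Gram deviation "
            f"{dev.max():.3e} at ({basis.names[i]}, {basis.names[j]})"
        )
    centroid = basis.reference.mean(axis=0)
    if np.linalg.norm(centroid) > 1e-6:
        raise ValueError(f"reference centroid must be at the origin, got {centroid}")


@dataclass(frozen=True)
class DistortionVector:
    """Amplitudes in angstroms along the 12 modes, plus the fit residual."""

    amplitudes: Mapping[str, float]
    residual: float = 0.0
    rmsd: float = 0.0

    def as_array(self, names: Sequence[str] = MODE_NAMES) -> np.ndarray:
        return np.array([self.amplitudes[n] for n in names], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.amplitudes[name]


def load_mode_basis(path: str | Path) -> ModeBasis:
    """Load a mode basis from the documented JSON schema.

    Schema: an object with keys ``names`` (12 strings), ``reference``
    (25 rows of 3 floats, angstroms) and ``modes`` (12 rows of 75 floats).
    Orthonormality and naming are validated on load.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    missing = {"names", "reference", "modes"} - set(doc)
    if missing:
        raise ValueError(f"mode-basis file {path} lacks keys: {sorted(missing)}")
    return ModeBasis(
        reference=np.asarray(doc["reference"], dtype=float),
        modes=np.asarray(doc["modes"], dtype=float),
        names=tuple(doc["names"]),
    )


def save_mode_basis(basis: ModeBasis, path: str | Path) -> None:
    """Write a mode basis in the JSON schema read by :func:`load_mode_basis`."""
    doc = {
        "names": list(basis.names),
        "reference": basis.reference.tolist(),
        "modes": basis.modes.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def superpose(observed: np.ndarray, reference: np.ndarray) -> Superposition:
    """Rigid least-squares superposition of an observed skeleton onto a reference.

    Thin wrapper over the Kabsch fit; both arguments are (25, 3) arrays in
    ``SKELETON_ATOMS`` row order.  The returned rotation is always proper.
    """
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if observed.shape != (25, 3) or reference.shape != (25, 3):
        raise ValueError("superpose expects complete (25, 3) skeletons")
    return kabsch(observed, reference)


def decompose(
    observed: np.ndarray,
    basis: ModeBasis,
    bypass_superposition: bool = False,
) -> DistortionVector:
    """Project an observed skeleton onto the mode basis.

    The skeleton is rigidly superposed onto ``basis.reference`` (unless
    ``bypass_superposition`` is set, for skeletons already expressed in the
    reference frame), the 75-dimensional displacement ``aligned - reference``
    is formed, and amplitudes are obtained by least squares on the 12 modes --
    for an orthonormal basis this equals the per-mode dot products.  The
    Euclidean norm of the out-of-basis displacement is reported as
    ``residual``.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (25, 3):
        raise ValueError(f"observed skeleton must be (25, 3), got {observed.shape}")
    if not np.all(np.isfinite(observed)):
        raise ValueError("observed skeleton contains non-finite coordinates")
    if bypass_superposition:
        aligned = observed
        rmsd = float(np.sqrt(np.mean(np.sum((observed - basis.reference) ** 2, axis=1))))
    else:
        fit = superpose(observed, basis.reference)
        aligned = fit.aligned
        rmsd = fit.rmsd
    disp = (aligned - basis.reference).ravel()
    amps = basis.modes @ disp
    residual = float(np.linalg.norm(disp - basis.modes.T @ amps))
    return DistortionVector(
        amplitudes=dict(zip(basis.names, amps.tolist())),
        residual=residual,
        rmsd=rmsd,
    )
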