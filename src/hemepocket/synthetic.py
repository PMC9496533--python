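"""Synthetic heme-protein complexes with known distortion ground truth.

Generates idealized planar Fe-porphyrin skeletons, a symmetry-constructed
12-mode displacement basis, and procedurally built binding pockets whose
wall geometry deterministically encodes the applied mode amplitudes.  Each
sample is emitted as a standard PDB file (heme as HETATM records, pocket as
ATOM records) together with a manifest of true amplitudes, so that every
stage of the curation -> NSD -> voxelization -> regression pipeline can be
exercised and audited without external downloads.

The pocket model: two pseudo-protein sheets above and below the macrocycle
whose local height follows the heme's out-of-plane displacement scaled by a
coupling gain, a peripheral ring enclosing the heme edge, and one proximal
histidine-like ligand coordinating the iron.  Gaussian positional noise of
width ``sigma`` is added to every pocket atom.  Optional disqualifying
features (water axial ligand, missing FE record, low-resolution tag,
duplicated chain sequence) are injected at configurable rates for testing
the curation filters.  None of this emulates real protein folds or
side-chain chemistry; it provides a controlled, fully labelled stand-in for
the curated corpus.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import Atom, StructureModel
from .nsd import MODE_NAMES, SKELETON_ATOMS, ModeBasis

# --- reference geometry ----------------------------------------------------

_N_RADIUS = 2.01        # Fe-N distance, A
_ALPHA_RADIUS = 3.07
_BETA_RADIUS = 4.30
_MESO_RADIUS = 3.42
_ALPHA_ANGLE = 24.0     # degrees off the pyrrole axis
_BETA_ANGLE = 10.5

#: Pyrrole axis angles (degrees) for pyrroles A-D; meso carbons sit between.
_PYRROLE_ANGLES = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}


def _polar(radius: float, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), 0.0])


def reference_porphyrin() -> np.ndarray:
    """Idealized planar fourfold-symmetric 25-atom skeleton, Fe at the origin.

    Rows follow ``SKELETON_ATOMS`` order; all z coordinates are zero, the
    four meso carbons share one radius and the four Fe-N distances are equal.
    """
    pos: dict[str, np.ndarray] = {"FE": np.zeros(3)}
    for p, theta in _PYRROLE_ANGLES.items():
        pos[f"N{p}"] = _polar(_N_RADIUS, theta)
        pos[f"C1{p}"] = _polar(_ALPHA_RADIUS, theta - _ALPHA_ANGLE)
        pos[f"C2{p}"] = _polar(_BETA_RADIUS, theta - _BETA_ANGLE)
        pos[f"C3{p}"] = _polar(_BETA_RADIUS, theta + _BETA_ANGLE)
        pos[f"C4{p}"] = _polar(_ALPHA_RADIUS, theta + _ALPHA_ANGLE)
    for p, theta in _PYRROLE_ANGLES.items():
        pos[f"CH{p}"] = _polar(_MESO_RADIUS, theta + 45.0)
    return np.array([pos[name] for name in SKELETON_ATOMS])


def _atom_metadata() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-atom (phi, r, pyrrole sign) arrays over the canonical order."""
    ref = reference_porphyrin()
    phi = np.arctan2(ref[:, 1], ref[:, 0])
    r = np.linalg.norm(ref[:, :2], axis=1)
    sign = np.zeros(25)
    for i, name in enumerate(SKELETON_ATOMS):
        for p, s in zip("ABCD", (1.0, -1.0, 1.0, -1.0)):
            if name in (f"N{p}", f"C1{p}", f"C2{p}", f"C3{p}", f"C4{p}"):
                sign[i] = s
    return phi, r, sign


def _rigid_body_space(ref: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 75) of rigid translations and rotations."""
    n = len(ref)
    basis = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        basis.append(t.ravel())
    centered = ref - ref.mean(axis=0)
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        basis.append(np.cross(e, centered).ravel())
    q, _ = np.linalg.qr(np.array(basis).T)
    return q.T


def synthetic_mode_basis(reference: np.ndarray | None = None) -> ModeBasis:
    """Symmetry-constructed orthonormal 12-mode basis over the reference.

    Out-of-plane patterns: saddling (whole pyrroles alternating up/down),
    ruffling (meso alternation), doming (ring one way, Fe the other),
    waving x/y (single-node tilts), propellering (within-pyrrole twist,
    same sense in all pyrroles).  In-plane patterns include breathing
    (uniform radial expansion) plus five further radial/tangential patterns.
    All patterns are projected off the rigid-body subspace and Gram-Schmidt
    orthonormalized, so the basis is exactly free of net translation and
    infinitesimal rotation; saddling/ruffling/doming/waving/propellering
    remain purely out-of-plane and breathing purely in-plane.
    """
    ref = reference_porphyrin() if reference is None else np.asarray(reference, dtype=float)
    if np.abs(ref[:, 2]).max() > 1e-9:
        raise ValueError("reference skeleton must be planar (z = 0)")
    phi, r, psign = _atom_metadata()
    rmax = r.max()
    rw = r / rmax
    is_fe = np.array([n == "FE" for n in SKELETON_ATOMS])
    is_meso = np.array([n.startswith("CH") for n in SKELETON_ATOMS])
    is_n = np.array([n in ("NA", "NB", "NC", "ND") for n in SKELETON_ATOMS])
    is_alpha = np.array([n.startswith(("C1", "C4")) for n in SKELETON_ATOMS])

    def oop(z: np.ndarray) -> np.ndarray:
        m = np.zeros((25, 3))
        m[:, 2] = z
        return m.ravel()

    radial = np.zeros((25, 3))
    radial[~is_fe, 0] = np.cos(phi[~is_fe])
    radial[~is_fe, 1] = np.sin(phi[~is_fe])
    tangential = np.zeros((25, 3))
    tangential[~is_fe, 0] = -np.sin(phi[~is_fe])
    tangential[~is_fe, 1] = np.cos(phi[~is_fe])

    def ip(weight: np.ndarray, direction: np.ndarray) -> np.ndarray:
        return (direction * weight[:, None]).ravel()

    raw = {
        "saddling": oop(psign * rw),
        "ruffling": oop(np.sin(2 * phi) * rw ** 2),
        "doming": oop(np.where(is_fe, -1.5, 0.5)),
        # cubic radial weight: a linear weight would be a pure rigid tilt;
        # the surviving non-rigid part changes sign along the radius (wave)
        "waving_x": oop(np.cos(phi) * rw ** 3),
        "waving_y": oop(np.sin(phi) * rw ** 3),
        "propellering": oop(np.sin(4 * phi) * rw ** 2),
        "breathing": ip(np.where(is_fe, 0.0, 1.0), radial),
        "meso_stretch": ip(is_meso.astype(float), radial),
        "pyrrole_stretch": ip((is_n | is_alpha).astype(float), radial),
        "quad_stretch_x": ip(np.cos(2 * phi), radial),
        "quad_stretch_y": ip(np.sin(2 * phi), radial),
        "pyrrole_shear": ip(np.cos(2 * phi), tangential),
    }
    rigid = _rigid_body_space(ref)
    modes = np.zeros((12, 75))
    for k, name in enumerate(MODE_NAMES):
        v = raw[name]
        v = v - rigid.T @ (rigid @ v)
        for prev in modes[:k]:
            v = v - prev * (prev @ v)
        # second orthogonalization pass for numerical tightness
        v = v - rigid.T @ (rigid @ v)
        for prev in modes[:k]:
            v = v - prev * (prev @ v)
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            raise RuntimeError(f"synthetic mode {name!r} is linearly dependent")
        modes[k] = v / norm
    return ModeBasis(reference=ref, modes=modes, names=MODE_NAMES)


def distort_porphyrin(
    reference: np.ndarray,
    amplitudes: Mapping[str, float] | np.ndarray,
    basis: ModeBasis | None = None,
    rng: np.random.Generator | None = None,
    max_translation: float = 10.0,
) -> np.ndarray:
    """Reference + sum of amplitude-scaled modes, optionally rigidly moved.

    ``amplitudes`` is either a mapping of mode name to angstrom amplitude or
    a length-12 array in canonical mode order.  When ``rng`` is given, a
    random proper rotation and a uniform translation are applied afterwards.
    """
    basis = synthetic_mode_basis(reference) if basis is None else basis
    if isinstance(amplitudes, Mapping):
        a = np.array([float(amplitudes.get(n, 0.0)) for n in basis.names])
    else:
        a = np.asarray(amplitudes, dtype=float)
        if a.shape != (12,):
            raise ValueError(f"amplitude array must have length 12, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("amplitudes must be finite")
    coords = np.asarray(reference, dtype=float) + (basis.modes.T @ a).reshape(25, 3)
    if rng is not None:
        rot = _random_rotation(rng)
        trans = rng.uniform(-max_translation, max_translation, size=3)
        coords = coords @ rot.T + trans
    return coords


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# --- generator configuration ----------------------------------------------

#: Modes whose amplitudes are drawn uniformly from [-1, 1] A by default.
DEFAULT_ACTIVE_MODES = ("saddling", "ruffling", "doming", "waving_y")

_AA1 = "ACDEFGHIKLMNPQRSTVWY"
_WALL_RESNAMES = ("ALA", "GLY", "SER", "VAL", "LEU", "THR")
_WALL_CLEARANCE = 2.8  # A, minimum wall standoff from the local heme surface


def _default_ranges() -> dict[str, tuple[float, float]]:
    return {m: ((-1.0, 1.0) if m in DEFAULT_ACTIVE_MODES else (0.0, 0.0)) for m in MODE_NAMES}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``gain`` couples the pocket-wall relief to the heme's out-of-plane
    displacement (wall z-offset = gain x local skeleton z-displacement); at
    the default 6.0 a full +-1 A amplitude moves the walls by roughly
    +-2 A, i.e. about two voxel cells.  ``sigma`` is the isotropic Gaussian
    positional noise on every pocket atom.  Defect fractions are all zero by
    default; they exist to exercise the curation filters.
    """

    n: int = 100
    seed: int = 0
    amplitude_ranges: Mapping[str, tuple[float, float]] = field(default_factory=_default_ranges)
    gain: float = 6.0
    sigma: float = 0.1
    wall_spacing: float = 1.5
    wall_z: float = 3.5
    wall_extent: float = 7.5
    ring_radius: float = 9.2
    het_probs: Mapping[str, float] = field(default_factory=lambda: {"HEM": 0.7, "HEC": 0.3})
    frac_water_ligand: float = 0.0
    frac_missing_fe: float = 0.0
    frac_low_resolution: float = 0.0
    frac_duplicate_seq: float = 0.0
    resolution: float = 1.6
    low_resolution: float = 2.5
    sequence_length: int = 120
    rigid_motions: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name, (lo, hi) in self.amplitude_ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid amplitude range for {name}: ({lo}, {hi})")

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc["amplitude_ranges"] = {k: list(v) for k, v in self.amplitude_ranges.items()}
        doc["het_probs"] = dict(self.het_probs)
        return json.dumps(doc, indent=2)


@dataclass
class LabeledSample:
    """One generated complex plus its ground truth."""

    sample_id: str
    path: Path | None
    amplitudes: dict[str, float]
    het_id: str
    heme_type: str
    sequence: str
    resolution: float
    defects: dict[str, bool]
    model: StructureModel | None = None


# peripheral marker atoms per compound, placed outward of the beta carbons
_PERIPHERALS = {
    "HEM": ("CMA", "CMB", "CMC", "CMD"),
    "HEB": ("CMA", "CMB", "CMC", "CMD"),
    "HEC": ("CMA", "CMB", "CMC", "CMD"),
    "HEA": ("CMA", "CMC", "CMD", "C11"),
    "HEO": ("CMA", "CMB", "CMC", "CMD"),
}
_HEME_TYPE = {"HEM": "b", "HEB": "b", "HEC": "c", "HEA": "a", "HEO": "o"}


def local_wall_displacement(heme_coords: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Out-of-plane displacement of the nearest (in xy) skeleton atom.

    This is the deterministic field the pocket walls follow; exposed so
    tests can verify the geometric encoding independently.
    """
    d2 = ((xy[:, None, :] - heme_coords[None, :, :2]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    return heme_coords[nearest, 2]


def build_pocket(
    heme_coords: np.ndarray,
    amplitudes: Mapping[str, float],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    het_id: str = "HEM",
    water_ligand: bool = False,
    omit_fe: bool = False,
    sequence: str | None = None,
) -> tuple[StructureModel, str]:
    """Assemble one complex (pocket + heme) in the canonical heme frame.

    Returns the in-memory :class:`StructureModel` and the chain sequence.
    Wall sheets sit at ``+-wall_z`` and follow ``gain`` times the local heme
    out-of-plane displacement; a peripheral ring encloses the macrocycle; a
    histidine NE2 coordinates the iron from below.  With ``sigma = 0`` and
    positive gain the wall z-offsets reproduce the displacement field of
    :func:`local_wall_displacement` exactly.
    """
    heme_coords = np.asarray(heme_coords, dtype=float)
    if heme_coords.shape != (25, 3):
        raise ValueError("heme_coords must be (25, 3)")
    elements = np.array(["C", "N", "O", "S"])
    elem_p = np.array([0.62, 0.15, 0.18, 0.05])
    atoms: list[Atom] = []
    res_seq = 1

    def add_protein_atom(pos: np.ndarray, element: str, name: str) -> None:
        nonlocal res_seq
        res_name = _WALL_RESNAMES[(res_seq - 1) % len(_WALL_RESNAMES)]
        atoms.append(Atom(element, name, res_name, res_seq, "A", pos, False))
        if sum(1 for a in atoms if a.res_seq == res_seq and not a.is_het) >= 4:
            res_seq += 1

    # wall sheets following the heme relief
    axis = np.arange(-cfg.wall_extent, cfg.wall_extent + 1e-9, cfg.wall_spacing)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    dz = local_wall_displacement(heme_coords, xy)
    for side in (+1.0, -1.0):
        for (x, y), d in zip(xy, dz):
            z = side * cfg.wall_z + cfg.gain * d
            # never let a wall atom cross within the clearance of the local
            # heme surface; the clamped branch still tracks d with slope 1
            if side > 0:
                z = max(z, d + _WALL_CLEARANCE)
            else:
                z = min(z, d - _WALL_CLEARANCE)
            pos = np.array([x, y, z])
            pos = pos + rng.normal(scale=cfg.sigma, size=3)
            e = str(rng.choice(elements, p=elem_p))
            add_protein_atom(pos, e, f"{e}W")
    # peripheral enclosing ring
    for z0 in (-2.4, 0.0, 2.4):
        for ang in np.linspace(0, 2 * np.pi, 20, endpoint=False):
            pos = np.array([cfg.ring_radius * np.cos(ang), cfg.ring_radius * np.sin(ang), z0])
            pos = pos + rng.normal(scale=cfg.sigma, size=3)
            e = str(rng.choice(elements, p=elem_p))
            add_protein_atom(pos, e, f"{e}R")

    fe = heme_coords[0]
    his_seq = res_seq + 1
    for name, element, offset in (
        ("NE2", "N", np.array([0.0, 0.0, -2.05])),
        ("CE1", "C", np.array([1.15, 0.0, -2.75])),
        ("CD2", "C", np.array([-1.15, 0.0, -2.75])),
    ):
        pos = fe + offset + rng.normal(scale=cfg.sigma, size=3)
        atoms.append(Atom(element, name, "HIS", his_seq, "A", pos, False))

    # heme het group: 25-atom skeleton plus peripheral marker atoms
    het_atoms: list[Atom] = []
    for i, name in enumerate(SKELETON_ATOMS):
        if omit_fe and name == "FE":
            continue
        el = "FE" if name == "FE" else ("N" if name.startswith("N") else "C")
        het_atoms.append(Atom(el, name, het_id, 900, "A", heme_coords[i].copy(), True))
    phi_marker = {"CMA": 0.0, "CMB": 90.0, "CMC": 180.0, "CMD": 270.0, "C11": 45.0}
    for name in _PERIPHERALS[het_id]:
        a = np.deg2rad(phi_marker[name])
        pos = np.array([5.4 * np.cos(a), 5.4 * np.sin(a), 0.0])
        # markers ride along with the mean heme plane but carry no signal
        het_atoms.append(Atom("C", name, het_id, 900, "A", pos, True))
    atoms.extend(het_atoms)

    if water_ligand:
        pos = fe + np.array([0.0, 0.0, 2.5])
        atoms.append(Atom("O", "O", "HOH", 901, "A", pos, True))

    if sequence is None:
        sequence = "".join(rng.choice(list(_AA1), size=cfg.sequence_length))
    model = StructureModel(
        entry_id="SYNTH",
        resolution=cfg.resolution,
        atoms=atoms,
        het_groups=[(het_id, het_atoms)],
        chains={"A": [a.res_name for a in atoms]},
    )
    return model, sequence


def _write_pdb(model: StructureModel, resolution: float, path: Path) -> None:
    """Emit a StructureModel as a PDB file via gemmi."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.entry_id
    st.resolution = resolution
    gm = gemmi.Model("1")
    chain = gemmi.Chain("A")
    current_key = None
    res = None
    for a in model.atoms:
        key = (a.chain_id, a.res_seq, a.res_name)
        if key != current_key:
            if res is not None:
                chain.add_residue(res)
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            res.het_flag = "H" if a.is_het else "A"
            current_key = key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.pos)
        at.occ = 1.0
        at.b_iso = 20.0
        res.add_atom(at)
    if res is not None:
        chain.add_residue(res)
    gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def generate_dataset(
    cfg: GeneratorConfig,
    out_dir: str | Path | None = None,
    basis: ModeBasis | None = None,
) -> tuple[list[LabeledSample], pd.DataFrame]:
    """Generate a labelled corpus; optionally write PDB + FASTA + manifest.

    Deterministic for a given config (identical config and seed reproduce
    identical file bytes).  When ``out_dir`` is None the structures are kept
    in memory only (``sample.model``); otherwise each sample is written to
    ``sample_NNNN.pdb`` and the manifest to ``manifest.csv`` alongside a
    ``corpus.fasta`` of chain sequences and the generator config JSON.
    """
    basis = synthetic_mode_basis() if basis is None else basis
    rng = np.random.default_rng(cfg.seed)
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
    het_ids = list(cfg.het_probs)
    het_p = np.array([cfg.het_probs[h] for h in het_ids], dtype=float)
    het_p = het_p / het_p.sum()

    samples: list[LabeledSample] = []
    rows = []
    sequences: list[str] = []
    for i in range(cfg.n):
        amps = {m: float(rng.uniform(*cfg.amplitude_ranges.get(m, (0.0, 0.0)))) for m in MODE_NAMES}
        het_id = het_ids[int(rng.choice(len(het_ids), p=het_p))]
        defects = {
            "water_ligand": bool(rng.random() < cfg.frac_water_ligand),
            "missing_fe": bool(rng.random() < cfg.frac_missing_fe),
            "low_resolution": bool(rng.random() < cfg.frac_low_resolution),
            "duplicate_seq": bool(rng.random() < cfg.frac_duplicate_seq) and len(sequences) > 0,
        }
        heme = distort_porphyrin(basis.reference, amps, basis=basis)
        sequence = sequences[int(rng.integers(len(sequences)))] if defects["duplicate_seq"] else None
        model, sequence = build_pocket(
            heme, amps, cfg, rng, het_id=het_id,
            water_ligand=defects["water_ligand"],
            omit_fe=defects["missing_fe"],
            sequence=sequence,
        )
        sequences.append(sequence)
        resolution = cfg.low_resolution if defects["low_resolution"] else cfg.resolution
        model.resolution = resolution
        if cfg.rigid_motions:
            rot = _random_rotation(rng)
            trans = rng.uniform(-10.0, 10.0, size=3)
            model = model.transformed(rot, trans)
            model.resolution = resolution
        sid = f"sample_{i:04d}"
        model.entry_id = sid
        path = None
        if out_path is not None:
            path = out_path / f"{sid}.pdb"
            _write_pdb(model, resolution, path)
        sample = LabeledSample(
            sample_id=sid, path=path, amplitudes=amps, het_id=het_id,
            heme_type=_HEME_TYPE[het_id], sequence=sequence, resolution=resolution,
            defects=defects, model=None if out_path is not None else model,
        )
        samples.append(sample)
        row = {"sample_id": sid, "path": path.name if path else "", "het_id": het_id,
               "heme_type": sample.heme_type, "resolution": resolution, "sequence": sequence}
        row.update({m: amps[m] for m in MODE_NAMES})
        row.update({f"defect_{k}": v for k, v in defects.items()})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        with open(out_path / "corpus.fasta", "w") as fh:
            for s in samples:
                fh.write(f">{s.sample_id}\n{s.sequence}\n")
        (out_path / "generator_config.json").write_text(cfg.to_json())
    return samples, manifest
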