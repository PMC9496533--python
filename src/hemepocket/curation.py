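"""Curation of heme sites from macromolecular structure files.

Reads mmCIF/PDB files, identifies heme groups (compound IDs HEM, HEA, HEB,
HEC, HEO), validates the 25-atom Fe-porphyrin skeleton, detects axial
ligands of the iron, applies the study filters (resolution <= 2.0 A, no
non-amino-acid axial ligand, complete skeleton) and reduces sequence
redundancy by greedy pairwise-identity screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .nsd import SKELETON_ATOMS

#: Heme compound IDs recognised during extraction.
HEME_COMPOUND_IDS: tuple[str, ...] = ("HEM", "HEA", "HEB", "HEC", "HEO")

#: Compound ID -> heme type letter.
HEME_TYPE_BY_ID: dict[str, str] = {
    "HEM": "b", "HEB": "b", "HEC": "c", "HEA": "a", "HEO": "o",
}

#: Simplified marker sets of peripheral atoms that must be present for the
#: heme type to be assigned from the compound ID; if any is missing from the
#: deposited group the type is reported as "unknown".  The full substituent
#: chemistry of each compound definition is deliberately not re-derived.
REQUIRED_PERIPHERALS: dict[str, frozenset[str]] = {
    "HEM": frozenset({"CMA", "CMB", "CMC", "CMD"}),
    "HEB": frozenset({"CMA", "CMB", "CMC", "CMD"}),
    "HEC": frozenset({"CMA", "CMB", "CMC", "CMD"}),
    "HEA": frozenset({"CMA", "CMC", "CMD", "C11"}),
    "HEO": frozenset({"CMA", "CMB", "CMC", "CMD"}),
}

#: Standard amino-acid residue names used for the is_amino_acid flag.
AMINO_ACIDS: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split()
)

AXIAL_CUTOFF = 3.1  # A, closed interval: a contact at exactly 3.1 A counts


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    res_name: str
    res_seq: int
    chain_id: str
    pos: np.ndarray  # (3,) angstroms
    is_het: bool


@dataclass
class StructureModel:
    """Parsed contents of one structure file (first model, first altloc)."""

    entry_id: str
    resolution: float | None
    atoms: list[Atom]
    het_groups: list[tuple[str, list[Atom]]]
    chains: dict[str, list[str]]  # chain id -> residue names in order

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_het]

    def protein_coords(self, elements: Iterable[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Coordinates and elements of protein heavy atoms (hydrogens dropped)."""
        sel = [a for a in self.atoms if not a.is_het and a.element != "H"]
        if elements is not None:
            allowed = set(elements)
            sel = [a for a in sel if a.element in allowed]
        if not sel:
            return np.zeros((0, 3)), []
        return np.array([a.pos for a in sel]), [a.element for a in sel]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with ``x -> R x + t`` applied to every atom."""
        def move(a: Atom) -> Atom:
            return Atom(a.element, a.name, a.res_name, a.res_seq, a.chain_id,
                        a.pos @ rotation.T + translation, a.is_het)
        atoms = [move(a) for a in self.atoms]
        hets = [(cid, [move(a) for a in grp]) for cid, grp in self.het_groups]
        return StructureModel(self.entry_id, self.resolution, atoms, hets, dict(self.chains))


@dataclass
class AxialLigand:
    res_name: str
    atom_name: str
    distance: float
    is_amino_acid: bool


@dataclass
class HemeSample:
    """One heme site: skeleton coordinates plus curation metadata."""

    entry_id: str
    het_id: str
    skeleton: dict[str, np.ndarray]      # atom name -> (3,)
    extra_atom_names: frozenset[str]     # non-skeleton atoms of the het group
    resolution: float | None
    chain_id: str = ""
    res_seq: int = 0
    heme_type: str = "unknown"
    axial_ligands: list[AxialLigand] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return all(n in self.skeleton for n in SKELETON_ATOMS)

    def skeleton_array(self) -> np.ndarray:
        """(25, 3) coordinates in canonical ``SKELETON_ATOMS`` order."""
        if not self.complete:
            missing = [n for n in SKELETON_ATOMS if n not in self.skeleton]
            raise ValueError(f"skeleton incomplete, missing {missing}")
        return np.array([self.skeleton[n] for n in SKELETON_ATOMS])

    @property
    def label(self) -> str:
        return f"{self.entry_id}/{self.het_id}/{self.chain_id}{self.res_seq}"


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    Only the first model is used; alternative conformers are reduced to the
    first location.  Resolution is taken from the file header when present.
    Raises a parse error naming the file for unreadable or malformed input.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            fmap = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
            key = fmt.lower().replace("cif", "cif")
            if key not in fmap:
                raise ValueError(f"unknown format {fmt!r}; use 'pdb' or 'mmcif'")
            st = gemmi.read_structure(str(path), format=fmap[key])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise ValueError(f"structure file {path} contains no models")
    model = st[0]

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    atoms: list[Atom] = []
    het_groups: list[tuple[str, list[Atom]]] = []
    chains: dict[str, list[str]] = {}
    for chain in model:
        chains.setdefault(chain.name, [])
        for res in chain:
            is_het = res.het_flag == "H" or res.name in HEME_COMPOUND_IDS or res.name == "HOH"
            chains[chain.name].append(res.name)
            group: list[Atom] = []
            for at in res:
                a = Atom(
                    element=at.element.name.upper(),
                    name=at.name,
                    res_name=res.name,
                    res_seq=res.seqid.num,
                    chain_id=chain.name,
                    pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    is_het=is_het,
                )
                if not np.all(np.isfinite(a.pos)):
                    raise ValueError(f"non-finite coordinates for {at.name} in {path}")
                atoms.append(a)
                group.append(a)
            if res.name in HEME_COMPOUND_IDS:
                het_groups.append((res.name, group))
    return StructureModel(
        entry_id=st.name or path.stem,
        resolution=resolution,
        atoms=atoms,
        het_groups=het_groups,
        chains=chains,
    )


def extract_hemes(model: StructureModel) -> list[HemeSample]:
    """One :class:`HemeSample` per heme-compound het group in the model.

    Samples missing any of the 25 skeleton atoms are returned with
    ``complete == False`` and are excluded by :func:`apply_filters`.
    """
    samples = []
    for comp_id, group in model.het_groups:
        skeleton: dict[str, np.ndarray] = {}
        extra: set[str] = set()
        for a in group:
            if a.name in SKELETON_ATOMS and a.name not in skeleton:
                skeleton[a.name] = a.pos
            elif a.name not in SKELETON_ATOMS:
                extra.add(a.name)
        sample = HemeSample(
            entry_id=model.entry_id,
            het_id=comp_id,
            skeleton=skeleton,
            extra_atom_names=frozenset(extra),
            resolution=model.resolution,
            chain_id=group[0].chain_id if group else "",
            res_seq=group[0].res_seq if group else 0,
        )
        sample.heme_type = assign_heme_type(sample)
        samples.append(sample)
    return samples


def detect_axial_ligands(model: StructureModel, sample: HemeSample) -> HemeSample:
    """Record every non-heme atom within 3.1 A (closed) of the heme iron.

    Each contact is stored with its residue and atom name, distance, and an
    amino-acid flag; waters and other small molecules carry
    ``is_amino_acid=False``.  Requires a complete skeleton.
    """
    if not sample.complete:
        raise ValueError(f"{sample.label}: axial-ligand detection requires a complete skeleton")
    fe = sample.skeleton["FE"]
    own = {(sample.chain_id, sample.res_seq, sample.het_id)}
    ligands: list[AxialLigand] = []
    for a in model.atoms:
        if (a.chain_id, a.res_seq, a.res_name) in own:
            continue
        if a.element == "H":
            continue
        d = float(np.linalg.norm(a.pos - fe))
        if d <= AXIAL_CUTOFF:
            ligands.append(AxialLigand(a.res_name, a.name, d, a.res_name in AMINO_ACIDS))
    sample.axial_ligands = sorted(ligands, key=lambda lig: lig.distance)
    return sample


def assign_heme_type(sample: HemeSample) -> str:
    """Heme type letter from the compound ID, with a completeness check.

    Mapping: HEM/HEB -> b, HEC -> c, HEA -> a, HEO -> o.  When peripheral
    marker atoms required by the compound definition are absent from the
    deposited group, the type is "unknown".
    """
    if sample.het_id not in HEME_TYPE_BY_ID:
        raise ValueError(f"unrecognized heme compound ID {sample.het_id!r}")
    required = REQUIRED_PERIPHERALS[sample.het_id]
    if not required <= sample.extra_atom_names:
        return "unknown"
    if not sample.complete:
        return "unknown"
    return HEME_TYPE_BY_ID[sample.het_id]


@dataclass(frozen=True)
class Rejection:
    sample: HemeSample
    reason: str  # one of: incomplete_skeleton, no_resolution, resolution, axial_ligand


def apply_filters(
    samples: Sequence[HemeSample],
    max_resolution: float = 2.0,
    require_amino_axial: bool = True,
) -> tuple[list[HemeSample], list[Rejection]]:
    """Apply the curation filters; every rejection gets exactly one reason.

    A sample is rejected if its skeleton is incomplete, if the entry has no
    resolution record or resolves worse than ``max_resolution``, or (when
    ``require_amino_axial``) if any axial ligand is not an amino acid.
    Reasons are assigned in that priority order.
    """
    kept: list[HemeSample] = []
    rejected: list[Rejection] = []
    for s in samples:
        if not s.complete:
            rejected.append(Rejection(s, "incomplete_skeleton"))
        elif s.resolution is None:
            rejected.append(Rejection(s, "no_resolution"))
        elif s.resolution > max_resolution:
            rejected.append(Rejection(s, "resolution"))
        elif require_amino_axial and any(not lig.is_amino_acid for lig in s.axial_ligands):
            rejected.append(Rejection(s, "axial_ligand"))
        else:
            kept.append(s)
    return kept, rejected


def curation_table(kept: Sequence[HemeSample], rejected: Sequence[Rejection]) -> pd.DataFrame:
    """Tidy per-sample curation log (CSV-ready)."""
    rows = []
    for s in kept:
        rows.append(_row(s, True, ""))
    for r in rejected:
        rows.append(_row(r.sample, False, r.reason))
    return pd.DataFrame(rows)


def _row(s: HemeSample, kept: bool, reason: str) -> dict:
    return {
        "entry": s.entry_id,
        "het_id": s.het_id,
        "chain": s.chain_id,
        "res_seq": s.res_seq,
        "heme_type": s.heme_type,
        "resolution": s.resolution,
        "n_axial": len(s.axial_ligands),
        "axial": ";".join(f"{lig.res_name}.{lig.atom_name}@{lig.distance:.2f}" for lig in s.axial_ligands),
        "kept": kept,
        "reason": reason,
    }


# ---------------------------------------------------------------------------
# Sequence redundancy


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global pairwise identity in percent: matches / alignment length * 100."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return 100.0
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


def _identity_reaches(seq_a: str, seq_b: str, threshold: float) -> bool:
    """Whether global identity >= threshold, with a cheap edit-distance screen.

    A pair at identity >= t carries at most ``(len_a + len_b) * (1 - t/100)``
    edit operations, so a bounded edit-distance computation can rule most
    pairs out without a full alignment.
    """
    if seq_a == seq_b:
        return True
    k = int(np.ceil((len(seq_a) + len(seq_b)) * (1.0 - threshold / 100.0))) + 1
    try:
        import edlib
    except ImportError:
        edlib = None
    if edlib is not None:
        res = edlib.align(seq_a, seq_b, mode="NW", task="distance", k=k)
        if res["editDistance"] == -1:  # distance exceeds k
            return False
    return pairwise_identity(seq_a, seq_b) >= threshold


def deduplicate_sequences(
    chains: Sequence[tuple[str, str]],
    identity_threshold: float = 99.99,
) -> list[tuple[str, str]]:
    """Greedy scan in input order; drop chains near-identical to a kept one.

    ``chains`` is a list of ``(chain_id, sequence)``.  A chain is dropped when
    its global identity to any already-kept chain reaches the threshold (in
    percent).  Deterministic given input order; idempotent.
    """
    kept: list[tuple[str, str]] = []
    for cid, seq in chains:
        if not seq:
            raise ValueError(f"chain {cid!r} has an empty sequence")
        if any(_identity_reaches(seq, kseq, identity_threshold) for _, kseq in kept):
            continue
        kept.append((cid, seq))
    return kept


@dataclass
class SequenceCluster:
    representative: str            # chain id of the founding (longest) member
    members: list[str]             # chain ids, representative first
    threshold: float               # percent identity


def cluster_sequences(
    chains: Sequence[tuple[str, str]],
    identity_threshold: float = 90.0,
) -> list[SequenceCluster]:
    """Greedy incremental clustering by descending sequence length.

    A chain joins the first existing cluster whose representative it matches
    at >= threshold percent identity, otherwise it founds a new cluster.
    The partition is deterministic given the input (length ties keep input
    order).
    """
    for cid, seq in chains:
        if not seq:
            raise ValueError(f"chain {cid!r} has an empty sequence")
    order = sorted(range(len(chains)), key=lambda i: -len(chains[i][1]))
    clusters: list[SequenceCluster] = []
    reps: list[str] = []
    for i in order:
        cid, seq = chains[i]
        placed = False
        for cl, rep_seq in zip(clusters, reps):
            if _identity_reaches(seq, rep_seq, identity_threshold):
                cl.members.append(cid)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(representative=cid, members=[cid], threshold=identity_threshold))
            reps.append(seq)
    return clusters


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Chain ids and sequences from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
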