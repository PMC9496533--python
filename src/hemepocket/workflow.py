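"""End-to-end pipeline: curate -> NSD labels -> voxelize -> training arrays.

Glue for running the whole analysis on a directory of structure files (or an
in-memory synthetic corpus): heme sites are curated with the study filters,
sequence redundancy is removed, distortion labels are computed by NSD, and
binding pockets are voxelized into the CNN input arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curation import (
    HemeSample,
    StructureModel,
    apply_filters,
    deduplicate_sequences,
    detect_axial_ligands,
    extract_hemes,
    read_structure,
)
from .nsd import MODE_NAMES, ModeBasis, decompose
from .synthetic import LabeledSample, synthetic_mode_basis
from .voxel import collapse_channels, compute_frame, voxelize


@dataclass
class CuratedDataset:
    """Aligned arrays for regression plus the per-sample bookkeeping."""

    grids: np.ndarray            # (n, channels, L, L, L) float32
    labels: pd.DataFrame         # NSD amplitudes per mode + heme_type + sample_id
    models: list[StructureModel]
    samples: list[HemeSample]
    rejections: pd.DataFrame

    def amplitude(self, mode: str) -> np.ndarray:
        return self.labels[mode].to_numpy(dtype=np.float32)


def _load_models(source: Sequence[LabeledSample] | str | Path) -> list[tuple[str, StructureModel, str | None]]:
    """(sample_id, model, sequence) triples from files or in-memory samples."""
    out = []
    if isinstance(source, (str, Path)):
        root = Path(source)
        manifest = None
        mpath = root / "manifest.csv"
        if mpath.exists():
            manifest = pd.read_csv(mpath).set_index("sample_id")
        for path in sorted(root.glob("*.pdb")) + sorted(root.glob("*.cif")):
            model = read_structure(path)
            sid = path.stem
            seq = None
            if manifest is not None and sid in manifest.index:
                seq = str(manifest.loc[sid, "sequence"])
            out.append((sid, model, seq))
    else:
        for s in source:
            model = s.model if s.model is not None else read_structure(s.path)
            out.append((s.sample_id, model, s.sequence))
    return out


def curate_corpus(
    source: Sequence[LabeledSample] | str | Path,
    edge: int = 17,
    channels: int = 4,
    basis: ModeBasis | None = None,
    max_resolution: float = 2.0,
    dedup_threshold: float = 99.99,
) -> CuratedDataset:
    """Run curation, NSD labelling and voxelization over a corpus.

    Sequence redundancy is removed greedily at ``dedup_threshold`` percent
    identity (set to None to skip).  Labels are the NSD amplitudes computed
    from the deposited coordinates, not any generator metadata.
    """
    basis = synthetic_mode_basis() if basis is None else basis
    triples = _load_models(source)

    kept_entries: list[tuple[str, StructureModel, HemeSample]] = []
    reject_rows: list[dict] = []
    all_samples: list[tuple[str, StructureModel, HemeSample]] = []
    for sid, model, _seq in triples:
        hemes = extract_hemes(model)
        for sample in hemes:
            if sample.complete:
                detect_axial_ligands(model, sample)
            all_samples.append((sid, model, sample))
    kept, rejected = apply_filters([s for _, _, s in all_samples], max_resolution=max_resolution)
    kept_ids = {id(s) for s in kept}
    reasons = {id(r.sample): r.reason for r in rejected}
    for sid, model, sample in all_samples:
        if id(sample) in kept_ids:
            kept_entries.append((sid, model, sample))
        else:
            reject_rows.append({"sample_id": sid, "het_id": sample.het_id,
                                "reason": reasons[id(sample)]})

    if dedup_threshold is not None:
        seq_by_sid = {sid: seq for sid, _m, seq in triples if seq}
        chains = [(sid, seq_by_sid[sid]) for sid, _m, _s in kept_entries if sid in seq_by_sid]
        kept_chain_ids = {cid for cid, _ in deduplicate_sequences(chains, dedup_threshold)}
        before = kept_entries
        kept_entries = [e for e in before if e[0] not in seq_by_sid or e[0] in kept_chain_ids]
        for sid, _m, sample in before:
            if sid in seq_by_sid and sid not in kept_chain_ids:
                reject_rows.append({"sample_id": sid, "het_id": sample.het_id,
                                    "reason": "duplicate_sequence"})

    grids, rows, models, samples = [], [], [], []
    for sid, model, sample in kept_entries:
        skel = sample.skeleton_array()
        dist = decompose(skel, basis)
        frame = compute_frame(sample.skeleton)
        grid = voxelize(model, frame, edge)
        if channels == 1:
            grid = collapse_channels(grid)
        grids.append(grid.data)
        row = {"sample_id": sid, "het_id": sample.het_id, "heme_type": sample.heme_type,
               "residual": dist.residual}
        row.update({m: dist.amplitudes[m] for m in MODE_NAMES})
        rows.append(row)
        models.append(model)
        samples.append(sample)
    x = np.stack(grids).astype(np.float32) if grids else np.zeros((0, channels, edge, edge, edge), np.float32)
    return CuratedDataset(
        grids=x,
        labels=pd.DataFrame(rows),
        models=models,
        samples=samples,
        rejections=pd.DataFrame(reject_rows, columns=["sample_id", "het_id", "reason"]),
    )


def save_grids(path: str | Path, dataset: CuratedDataset) -> None:
    """Store voxel grids + labels in a chunked HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("grids", data=dataset.grids, chunks=(1,) + dataset.grids.shape[1:],
                          compression="gzip")
        for col in dataset.labels.columns:
            vals = dataset.labels[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            fh.create_dataset(f"labels/{col}", data=vals)


def load_grids(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    import h5py

    with h5py.File(path, "r") as fh:
        grids = fh["grids"][...]
        cols = {}
        for key in fh["labels"]:
            vals = fh[f"labels/{key}"][...]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            cols[key] = vals
    return grids, pd.DataFrame(cols)
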