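"""Shared fixtures: reference geometry, mode basis, and a small synthetic corpus."""

from __future__ import annotations

import numpy as np
import pytest

from hemepocket.nsd import ModeBasis
from hemepocket.synthetic import (
    GeneratorConfig,
    generate_dataset,
    reference_porphyrin,
    synthetic_mode_basis,
)


@pytest.fixture(scope="session")
def reference() -> np.ndarray:
    return reference_porphyrin()


@pytest.fixture(scope="session")
def basis(reference) -> ModeBasis:
    return synthetic_mode_basis(reference)


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """A 24-sample corpus with injected curation defects, written as PDB files."""
    out = tmp_path_factory.mktemp("corpus")
    cfg = GeneratorConfig(
        n=24,
        seed=42,
        frac_water_ligand=0.25,
        frac_missing_fe=0.15,
        frac_low_resolution=0.2,
        frac_duplicate_seq=0.25,
    )
    samples, manifest = generate_dataset(cfg, out)
    return out


@pytest.fixture(scope="session")
def clean_corpus():
    """A defect-free in-memory corpus of 20 samples (models kept in memory)."""
    cfg = GeneratorConfig(n=20, seed=7)
    samples, manifest = generate_dataset(cfg, None)
    return samples, manifest
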