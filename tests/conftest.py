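"""Shared fixtures: bundled defensin sequences and tiny generated files."""
from __future__ import annotations

import numpy as np
import pytest

from csabminer import datasets


@pytest.fixture(scope="session")
def lsamp1_mature() -> str:
    return datasets.LSAMP1_MATURE


@pytest.fixture(scope="session")
def lsamp2_mature() -> str:
    return datasets.LSAMP2_MATURE


@pytest.fixture(scope="session")
def lsamp1_precursor() -> str:
    return datasets.LSAMP1_PRECURSOR


@pytest.fixture(scope="session")
def lsamp2_precursor() -> str:
    return datasets.LSAMP2_PRECURSOR


@pytest.fixture
def write_fasta(tmp_path):
    """Factory writing a FASTA file from id→sequence pairs; returns the path."""

    def _write(records: dict[str, str], name: str = "in.fasta", width: int = 0):
        path = tmp_path / name
        with path.open("w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n")
                if width:
                    for i in range(0, len(seq), width):
                        fh.write(seq[i:i + width] + "\n")
                else:
                    fh.write(seq + "\n")
        return path

    return _write


def make_pdb_text(residues):
    """Render a minimal PDB from (resname, resnum, {atom: (x, y, z)}) triples."""
    lines = []
    serial = 1
    for resname, resnum, atoms in residues:
        for atom_name, (x, y, z) in atoms.items():
            element = atom_name[0]
            lines.append(
                f"ATOM  {serial:5d}  {atom_name:<3s}{resname:>4s} A{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_pdb(tmp_path):
    """Factory writing a minimal PDB file; returns the path."""

    def _write(residues, name: str = "model.pdb", extra_header: str = ""):
        path = tmp_path / name
        path.write_text(extra_header + make_pdb_text(residues))
        return path

    return _write


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
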