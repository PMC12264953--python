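"""Plain-text chemistry file I/O shared by the CLI.

SMILES files: one record per line, whitespace-separated optional name
column, ``#`` comments ignored. SDF: V2000 via RDKit, first record used as
the reference bioactive conformer.
"""

from __future__ import annotations

from pathlib import Path

from rdkit import Chem

from .scaffoldfinder import Decoration

__all__ = [
    "read_smiles_file",
    "write_smiles_file",
    "read_decorations",
    "read_reference_sdf",
    "write_sdf",
]


def read_smiles_file(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split()[0])
    return out


def write_smiles_file(path: str | Path, records: list[str], header: str | None = None) -> None:
    lines = ([f"# {header}"] if header else []) + list(records)
    Path(path).write_text("\n".join(lines) + "\n")


def read_decorations(path: str | Path) -> list[Decoration]:
    """One decoration SMILES per line; dummy written as ``[*]`` or ``*``."""
    return [Decoration.from_smiles(s) for s in read_smiles_file(path)]


def read_reference_sdf(path: str | Path) -> Chem.Mol:
    """First record of an SDF, with its 3D coordinates."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for mol in supplier:
        if mol is not None:
            if mol.GetNumConformers() == 0:
                raise ValueError(f"SDF record in {path} carries no conformer")
            return mol
    raise ValueError(f"no parseable record in {path}")


def write_sdf(path: str | Path, mols: list[Chem.Mol]) -> None:
    writer = Chem.SDWriter(str(path))
    for mol in mols:
        writer.write(mol)
    writer.close()
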