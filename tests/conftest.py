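"""Shared fixtures: hand-built PDB texts and tiny ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from disorderbench.containers import EnsembleStructure


def format_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int, xyz
) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:^4s} {resname:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{name[0]:>2s}"
    )


def make_pdb_text(
    models: list[list[tuple[str, int, str, str, tuple]]],
    seqres: list[str] | None = None,
    remark465: list[tuple[str, str, int]] | None = None,
    chain_for_seqres: str = "A",
    endmdl: bool = True,
) -> str:
    """Assemble PDB text from per-model atom tuples
    (chain, resnum, resname, atom_name, xyz)."""
    lines: list[str] = []
    if remark465:
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465   M RES C SSSEQI")
        for resname, chain, num in remark465:
            lines.append(f"REMARK 465     {resname:>3s} {chain} {num:5d}")
    if seqres:
        for i in range(0, len(seqres), 13):
            block = seqres[i:i + 13]
            lines.append(
                f"SEQRES {i // 13 + 1:3d} {chain_for_seqres} {len(seqres):4d} "
                " " + " ".join(f"{r:>3s}" for r in block)
            )
    multi = len(models) > 1
    for mi, atoms in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        for serial, (chain, resnum, resname, aname, xyz) in enumerate(atoms, start=1):
            lines.append(format_atom_line(serial, aname, resname, chain, resnum, xyz))
        if multi and endmdl:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def backbone_atoms(
    chain: str, resnum: int, resname: str, origin: tuple[float, float, float]
) -> list[tuple]:
    """N, CA, C atoms of one residue near the given origin (arbitrary but
    fixed internal geometry)."""
    ox, oy, oz = origin
    return [
        (chain, resnum, resname, "N", (ox, oy, oz)),
        (chain, resnum, resname, "CA", (ox + 1.2, oy + 0.8, oz)),
        (chain, resnum, resname, "C", (ox + 2.4, oy, oz + 0.5)),
    ]


def ca_only_ensemble(ca_sets: np.ndarray, chain: str = "A") -> EnsembleStructure:
    """EnsembleStructure from CA coordinates only, shape (K, L, 3); the N
    and C slots are copied from CA (distance-matrix operations use CA)."""
    ca_sets = np.asarray(ca_sets, dtype=float)
    K, L, _ = ca_sets.shape
    coords = np.repeat(ca_sets[:, :, None, :], 3, axis=2)
    residues = [(chain, i + 1, "ALA") for i in range(L)]
    return EnsembleStructure("ca-only", residues, coords)


@pytest.fixture
def rigid_ensemble() -> EnsembleStructure:
    """Three identical conformers of a 12-residue ideal backbone."""
    from disorderbench.synthetic_data import build_backbone

    L = 12
    xyz = build_backbone(np.full(L, -65.0), np.full(L, -40.0))
    coords = np.repeat(xyz[None], 3, axis=0)
    residues = [("A", i + 1, "ALA") for i in range(L)]
    return EnsembleStructure("rigid", residues, coords)
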