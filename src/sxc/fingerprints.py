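"""Optional real-molecule mode: SMILES to folded layered-atom-environment
fingerprints (Morgan radius 2, 2048 bits) with bit -> atom-set maps.

Requires RDKit (``pip install sxc[chem]``); everything else in the package
works without it.  Folding collisions merge atom sets and are logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["smiles_to_fingerprints", "read_smiles_file"]


def _require_rdkit():
    try:
        from rdkit import Chem
        from rdkit.Chem import AllChem
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "real-molecule mode requires RDKit; install with 'pip install sxc[chem]'"
        ) from exc
    return Chem, AllChem


def smiles_to_fingerprints(
    smiles: list[str], n_bits: int = 2048, radius: int = 2
) -> tuple[np.ndarray, list[dict[int, frozenset[int]]]]:
    """Fingerprint matrix plus per-compound bit -> atom-set maps.

    Each set bit maps to the union of atoms of every environment hashed to
    it (the central atom and all atoms within the environment radius).
    """
    Chem, AllChem = _require_rdkit()
    fps = np.zeros((len(smiles), n_bits), dtype=np.int8)
    atom_maps: list[dict[int, frozenset[int]]] = []
    for row, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES at line {row + 1}: {smi!r}")
        bit_info: dict[int, list[tuple[int, int]]] = {}
        AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits, bitInfo=bit_info)
        amap: dict[int, set[int]] = {}
        for bit, environments in bit_info.items():
            fps[row, bit] = 1
            atoms: set[int] = set()
            for center, env_radius in environments:
                if env_radius == 0:
                    atoms.add(center)
                    continue
                env = Chem.FindAtomEnvironmentOfRadiusN(mol, env_radius, center)
                atoms.add(center)
                for bond_idx in env:
                    bond = mol.GetBondWithIdx(bond_idx)
                    atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            if len(environments) > 1:
                logger.info("SMILES %d: bit %d folds %d environments; atom sets merged",
                            row, bit, len(environments))
            amap.setdefault(bit, set()).update(atoms)
        atom_maps.append({b: frozenset(a) for b, a in amap.items()})
    return fps, atom_maps


def read_smiles_file(path: str | Path) -> list[str]:
    """One SMILES per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.strip().startswith("#")]
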