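"""Molecule/role topology: mapping atoms to molecules and analysis roles.

XYZ carries no atom names, so roles (headgroup oxygens, ordered tail
carbons, peptide alpha-carbons) are declared in a small structured spec
rather than inferred.  The spec is a list of molecule blocks, each
consuming a run of consecutive atom indices::

    molecules:
      - species: amphiphile      # amphiphile | peptide | water | ion
        count: 790               # identical copies
        atoms: 12                # atoms per copy
        roles:                   # intra-molecule 0-based offsets
          o1: 0
          o2: 1
          tail_carbons: [2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
      - species: peptide
        count: 1
        atoms: 16
        roles:
          calpha: [0, 1, ..., 15]   # ordered by residue number

Blocks may also pin an explicit ``start`` index; every atom of the
trajectory must be claimed exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import TopologyError

SPECIES = ("amphiphile", "peptide", "water", "ion")


@dataclass
class Molecule:
    molecule_id: int
    species: str
    atoms: np.ndarray  # global atom indices


@dataclass
class MoleculeMap:
    """Partition of the atom roster into molecules with role tags.

    ``headgroup_o1``/``headgroup_o2`` are per-amphiphile global atom
    indices of the two carboxyl oxygens; ``tail_carbons`` is a
    ``(n_amphiphiles, n_tail)`` index array ordered from the carboxyl
    carbon outward; ``peptide_calphas`` is ordered by residue number.
    """

    molecules: list[Molecule]
    headgroup_o1: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    headgroup_o2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    tail_carbons: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=int))
    peptide_calphas: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def amphiphile_ids(self) -> np.ndarray:
        return np.array([m.molecule_id for m in self.molecules if m.species == "amphiphile"], dtype=int)

    @property
    def n_amphiphiles(self) -> int:
        return len(self.headgroup_o1)

    @property
    def has_peptide(self) -> bool:
        return len(self.peptide_calphas) >= 2

    @property
    def n_peptide_residues(self) -> int:
        return len(self.peptide_calphas)

    @property
    def amphiphile_atoms(self) -> np.ndarray:
        """Global indices of every amphiphile atom, in molecule order."""
        idx = [m.atoms for m in self.molecules if m.species == "amphiphile"]
        return np.concatenate(idx) if idx else np.empty(0, dtype=int)

    def atoms_by_species(self, species: str) -> np.ndarray:
        idx = [m.atoms for m in self.molecules if m.species == species]
        return np.concatenate(idx) if idx else np.empty(0, dtype=int)

    @property
    def amphiphile_atom_matrix(self) -> np.ndarray:
        """(n_amphiphiles, atoms_per_monomer) index matrix; requires identical monomers."""
        mols = [m.atoms for m in self.molecules if m.species == "amphiphile"]
        sizes = {len(a) for a in mols}
        if len(sizes) != 1:
            raise TopologyError("amphiphiles are not identical; no rectangular atom matrix")
        return np.stack(mols)


def load_topology_spec(path) -> dict:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "molecules" not in spec:
        raise TopologyError(f"{path}: topology spec must be a mapping with a 'molecules' list")
    return spec


def write_topology_spec(spec: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec, sort_keys=False))


def topology_spec_from_map(mmap: MoleculeMap) -> dict:
    """Inverse of :func:`build_molecule_map` for maps with contiguous molecules."""
    blocks = []
    amph_seen = 0
    for mol in mmap.molecules:
        base = int(mol.atoms[0])
        per = len(mol.atoms)
        roles = {}
        if mol.species == "amphiphile":
            roles = {
                "o1": int(mmap.headgroup_o1[amph_seen] - base),
                "o2": int(mmap.headgroup_o2[amph_seen] - base),
                "tail_carbons": (mmap.tail_carbons[amph_seen] - base).tolist(),
            }
            amph_seen += 1
        elif mol.species == "peptide":
            roles = {"calpha": (np.asarray(mmap.peptide_calphas) - base).tolist()}
        if (
            blocks
            and blocks[-1]["species"] == mol.species
            and blocks[-1]["atoms"] == per
            and blocks[-1].get("roles", {}) == roles
            and blocks[-1]["start"] + blocks[-1]["count"] * per == base
        ):
            blocks[-1]["count"] += 1
        else:
            block = {"species": mol.species, "count": 1, "atoms": per, "start": base}
            if roles:
                block["roles"] = roles
            blocks.append(block)
    return {"molecules": blocks}


def build_molecule_map(trajectory, topology_spec) -> MoleculeMap:
    """Materialize a :class:`MoleculeMap` from a declarative spec.

    ``topology_spec`` is a dict (schema above) or a path to a YAML file.
    Raises :class:`TopologyError` if any atom is claimed twice or left
    unclaimed.
    """
    if not isinstance(topology_spec, dict):
        topology_spec = load_topology_spec(topology_spec)

    n_atoms = trajectory.n_atoms
    claimed = np.zeros(n_atoms, dtype=bool)
    molecules: list[Molecule] = []
    o1, o2, tails, calphas = [], [], [], []
    cursor = 0
    problems: list[str] = []

    for bi, block in enumerate(topology_spec["molecules"]):
        species = block.get("species")
        if species not in SPECIES:
            raise TopologyError(f"block {bi}: unknown species {species!r}")
        count = int(block.get("count", 1))
        per = int(block["atoms"])
        if count < 0 or per <= 0:
            raise TopologyError(f"block {bi}: count/atoms must be positive")
        start = int(block.get("start", cursor))
        roles = block.get("roles", {}) or {}

        for c in range(count):
            base = start + c * per
            idx = np.arange(base, base + per)
            if idx[-1] >= n_atoms:
                problems.append(f"block {bi}: atoms {base}..{base + per - 1} exceed roster ({n_atoms})")
                break
            if claimed[idx].any():
                problems.append(f"block {bi}: atom(s) starting at {base} claimed twice")
                break
            claimed[idx] = True
            molecules.append(Molecule(len(molecules), species, idx))
            if species == "amphiphile":
                if "o1" not in roles or "o2" not in roles or "tail_carbons" not in roles:
                    raise TopologyError(f"block {bi}: amphiphile block needs o1, o2 and tail_carbons roles")
                o1.append(base + int(roles["o1"]))
                o2.append(base + int(roles["o2"]))
                tails.append(base + np.asarray(roles["tail_carbons"], dtype=int))
            elif species == "peptide":
                if "calpha" not in roles:
                    raise TopologyError(f"block {bi}: peptide block needs a calpha role list")
                calphas.extend(base + np.asarray(roles["calpha"], dtype=int))
        cursor = start + count * per

    unclaimed = int(n_atoms - claimed.sum())
    if unclaimed:
        problems.append(f"{unclaimed} atom(s) unclaimed by the topology spec")
    if problems:
        raise TopologyError("; ".join(problems))

    tail_matrix = np.stack(tails) if tails else np.empty((0, 0), dtype=int)
    return MoleculeMap(
        molecules=molecules,
        headgroup_o1=np.asarray(o1, dtype=int),
        headgroup_o2=np.asarray(o2, dtype=int),
        tail_carbons=tail_matrix,
        peptide_calphas=np.asarray(calphas, dtype=int),
    )
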