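"""Synthetic assemblies with analytic ground truth.

Every stage of the pipeline is testable without any deposited structure:

* :func:`make_ring` — n pseudo-chromophores equally spaced on a circle,
  mimicking the bilins of an (αβ)₃ trimer ring seen down the cylinder axis.
  Each pseudo-chromophore is a short collinear run of atoms (reusing the
  configured conjugated-atom names) so that the principal-axis dipole
  assignment reproduces the intended direction exactly; chord distances
  2·R·sin(kπ/n) are recorded analytically in the manifest.

* :func:`make_stacked_rings` — rings stacked along z at a fixed spacing,
  mimicking trimer stacking within a core cylinder (each ring is labelled as
  its own cylinder so inter-ring edges register as bridging pairs).

* :func:`make_helical_rod` / :func:`perturb_assembly` — a multi-unit rod of
  Cα helices, with planted per-unit rigid motions. The manifest stores each
  unit's exact anchored RMSD, computed directly from the planted coordinates
  (for a pure translation this is simply |t|), independent of any fitting
  code.

* :func:`sample_isotropic_pair` — one seeded draw of the freely-rotating
  donor/acceptor orientation scenario whose κ² average is 2/3.

Generators are deterministic: the same seed and parameters reproduce the
fixture and manifest bit-for-bit. No attempt is made to mimic real bilin
chemistry, B-factors, or occupancies.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .chromophores import ChromophoreID
from .errors import ConfigError, DataError
from .structure_io import (
    Atom,
    AssemblyMap,
    Chain,
    ChainAssignment,
    Residue,
    StructureModel,
    write_assembly_map,
    write_structure,
)

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits

#: atom names given to the 5-atom collinear pseudo-chromophore
PSEUDO_ATOM_NAMES = ("C4A", "CHB", "C1B", "C2B", "C3B")
PSEUDO_ATOM_SPACING = 1.0  # Å between consecutive atoms of the run


@dataclass
class SyntheticAssembly:
    model: StructureModel
    assembly_map: AssemblyMap
    manifest: dict
    seed: int

    def write(self, basepath: str | Path, fmt: str = "pdb") -> dict[str, Path]:
        """Write structure + manifest TSV + assembly-map config next to ``basepath``."""
        base = Path(basepath)
        suffix = ".pdb" if fmt == "pdb" else ".cif"
        paths = {
            "structure": base.with_suffix(suffix),
            "manifest": base.with_suffix(".manifest.tsv"),
            "map": base.with_suffix(".map.cfg"),
        }
        write_structure(self.model, paths["structure"], fmt=fmt)
        write_assembly_map(self.assembly_map, paths["map"])
        self._write_manifest(paths["manifest"])
        return paths

    def _write_manifest(self, path: Path) -> None:
        lines = [f"# seed = {self.seed}"]
        if "chromophores" in self.manifest:
            lines.append("id\tcx\tcy\tcz\tdx\tdy\tdz")
            for entry in self.manifest["chromophores"]:
                c, d = entry["centroid"], entry["dipole"]
                lines.append(
                    f"{entry['id']}\t{c[0]:.6f}\t{c[1]:.6f}\t{c[2]:.6f}"
                    f"\t{d[0]:.6f}\t{d[1]:.6f}\t{d[2]:.6f}"
                )
        if "unit_rmsd" in self.manifest:
            lines.append("unit\trmsd_angstrom")
            for unit, rmsd in self.manifest["unit_rmsd"].items():
                lines.append(f"{unit}\t{rmsd:.6f}")
        path.write_text("\n".join(lines) + "\n")


def _chain_id(i: int) -> str:
    if i >= len(_CHAIN_ALPHABET):
        raise ConfigError(f"fixture too large: no single-character chain ID left for index {i}")
    return _CHAIN_ALPHABET[i]


def _pseudo_residue(centroid: np.ndarray, direction: np.ndarray, seqnum: int) -> Residue:
    """Collinear 5-atom run centered on ``centroid`` pointing along ``direction``."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    atoms = []
    for k, name in enumerate(PSEUDO_ATOM_NAMES):
        pos = centroid + (k - (len(PSEUDO_ATOM_NAMES) - 1) / 2) * PSEUDO_ATOM_SPACING * direction
        atoms.append(Atom(name=name, element=name[0], coords=pos))
    return Residue(name="CYC", seqnum=seqnum, hetero=True, atoms=atoms)


def _ring_dipole(mode: str, angle: float) -> np.ndarray:
    if mode == "tangent":
        return np.array([-np.sin(angle), np.cos(angle), 0.0])
    if mode == "radial":
        return np.array([np.cos(angle), np.sin(angle), 0.0])
    if mode == "axial":
        return np.array([0.0, 0.0, 1.0])
    raise ConfigError(f"unknown dipole_mode {mode!r}; use tangent, radial or axial")


def make_ring(
    n: int,
    radius: float,
    dipole_mode: str = "tangent",
    seed: int = 0,
    *,
    z: float = 0.0,
    cylinder: str = "A",
    ring_index: int = 1,
    chain_offset: int = 0,
) -> SyntheticAssembly:
    """``n`` pseudo-chromophores equally spaced on a circle of given radius (Å).

    The manifest lists exact centroids, dipoles, and the analytic chord
    distance matrix d(i, j) = 2·radius·sin(|i−j|·π/n).
    """
    if n < 2:
        raise ConfigError("ring needs n >= 2 chromophores")
    if radius <= 0:
        raise ConfigError("radius must be positive")
    chains: list[Chain] = []
    assignments: dict[str, ChainAssignment] = {}
    entries = []
    for i in range(n):
        angle = 2 * np.pi * i / n
        centroid = np.array([radius * np.cos(angle), radius * np.sin(angle), z])
        direction = _ring_dipole(dipole_mode, angle)
        cid_str = _chain_id(chain_offset + i)
        seqnum = 1
        chains.append(
            Chain(chain_id=cid_str, residues=[_pseudo_residue(centroid, direction, seqnum)])
        )
        assignments[cid_str] = ChainAssignment(
            cylinder=cylinder, unit_index=ring_index, subunit_role="ApcA", monomer_index=i + 1
        )
        entries.append(
            {
                "id": str(
                    ChromophoreID(cylinder, ring_index, "a", str(i + 1), seqnum,
                                  attach_uncertain=True)
                ),
                "centroid": centroid,
                "dipole": direction,
            }
        )
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = 2 * radius * abs(np.sin(abs(i - j) * np.pi / n))
    amap = AssemblyMap(
        chain_assignments=assignments,
        ligand_codes=frozenset({"CYC"}),
        conjugated_atom_names=PSEUDO_ATOM_NAMES,
        dipole_sign_reference=(PSEUDO_ATOM_NAMES[0], PSEUDO_ATOM_NAMES[-1]),
    )
    model = StructureModel(identifier=f"ring{n}", chains=chains, source_format="pdb")
    manifest = {
        "chromophores": entries,
        "chord_distances": dist,
        "params": {"n": n, "radius": radius, "dipole_mode": dipole_mode},
    }
    return SyntheticAssembly(model=model, assembly_map=amap, manifest=manifest, seed=seed)


def make_stacked_rings(
    n_rings: int,
    spacing: float,
    n: int = 3,
    radius: float = 20.0,
    dipole_mode: str = "tangent",
    seed: int = 0,
) -> SyntheticAssembly:
    """Rings stacked along z with aligned phases; one cylinder label per ring.

    The manifest distance matrix over all n_rings·n chromophores is analytic:
    d((i,p),(j,q))² = chord(i,j)² + ((p−q)·spacing)². A single ring reduces
    exactly to :func:`make_ring`.
    """
    if n_rings < 1:
        raise ConfigError("need n_rings >= 1")
    if spacing <= 0:
        raise ConfigError("spacing must be positive")
    rings = []
    for p in range(n_rings):
        rings.append(
            make_ring(
                n,
                radius,
                dipole_mode,
                seed,
                z=p * spacing,
                cylinder=_chain_id(p),
                ring_index=p + 1,
                chain_offset=p * n,
            )
        )
    chains = [c for ring in rings for c in ring.model.chains]
    assignments = {}
    entries = []
    for ring in rings:
        assignments.update(ring.assembly_map.chain_assignments)
        entries.extend(ring.manifest["chromophores"])
    total = n_rings * n
    dist = np.zeros((total, total))
    chord = rings[0].manifest["chord_distances"]
    for p in range(n_rings):
        for q in range(n_rings):
            for i in range(n):
                for j in range(n):
                    dist[p * n + i, q * n + j] = np.hypot(chord[i, j], (p - q) * spacing)
    amap = AssemblyMap(
        chain_assignments=assignments,
        ligand_codes=frozenset({"CYC"}),
        conjugated_atom_names=PSEUDO_ATOM_NAMES,
        dipole_sign_reference=(PSEUDO_ATOM_NAMES[0], PSEUDO_ATOM_NAMES[-1]),
    )
    model = StructureModel(identifier=f"stack{n_rings}x{n}", chains=chains, source_format="pdb")
    manifest = {
        "chromophores": entries,
        "distances": dist,
        "params": {"n_rings": n_rings, "spacing": spacing, "n": n, "radius": radius},
    }
    return SyntheticAssembly(model=model, assembly_map=amap, manifest=manifest, seed=seed)


# ---------------------------------------------------------------------------
# rods with planted rigid perturbations


def make_helical_rod(
    n_units: int = 4,
    n_residues: int = 30,
    seed: int = 0,
    unit_offset: float = 15.0,
) -> SyntheticAssembly:
    """A rod of ``n_units`` identical Cα helices, one chain per unit.

    Units are laid side by side ``unit_offset`` Å apart along x; the manifest
    maps unit labels ("1", "2", ...) to chain IDs.
    """
    if n_units < 1 or n_residues < 4:
        raise ConfigError("need n_units >= 1 and n_residues >= 4")
    helix = np.array(
        [
            [2.3 * np.cos(np.deg2rad(100.0) * k), 2.3 * np.sin(np.deg2rad(100.0) * k), 1.5 * k]
            for k in range(n_residues)
        ]
    )
    chains = []
    units: dict[str, str] = {}
    assignments = {}
    for u in range(n_units):
        cid = _chain_id(u)
        coords = helix + np.array([u * unit_offset, 0.0, 0.0])
        residues = [
            Residue(name="ALA", seqnum=k + 1, atoms=[Atom("CA", "C", coords[k])])
            for k in range(n_residues)
        ]
        chains.append(Chain(chain_id=cid, residues=residues))
        units[str(u + 1)] = cid
        assignments[cid] = ChainAssignment(cylinder="Rb", unit_index=u + 1, subunit_role="CpcA")
    amap = AssemblyMap(
        chain_assignments=assignments,
        conjugated_atom_names=PSEUDO_ATOM_NAMES,
        dipole_sign_reference=(PSEUDO_ATOM_NAMES[0], PSEUDO_ATOM_NAMES[-1]),
    )
    model = StructureModel(identifier=f"rod{n_units}", chains=chains, source_format="pdb")
    manifest = {"units": units, "params": {"n_units": n_units, "n_residues": n_residues}}
    return SyntheticAssembly(model=model, assembly_map=amap, manifest=manifest, seed=seed)


RigidTransform = tuple[np.ndarray, np.ndarray]  # (3×3 proper rotation, translation Å)


def _check_proper(rot: np.ndarray) -> np.ndarray:
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
        raise DataError("transform rotation is not orthogonal")
    if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-9):
        raise DataError("transform rotation is improper (det != +1)")
    return rot


def perturb_assembly(
    base: SyntheticAssembly,
    unit_transforms: Mapping[str, RigidTransform],
    seed: int = 0,
    anchor: str = "1",
) -> SyntheticAssembly:
    """Apply planted rigid motions per unit and record exact anchored RMSDs.

    Each listed unit's coordinates become R·x + t. The manifest's
    ``unit_rmsd`` holds, for every unit, the RMSD it would show after an
    anchored superposition on ``anchor`` — computed here directly from the
    planted coordinates (the anchored alignment is the exact inverse of the
    anchor's own planted motion), with no fitting code involved. For a pure
    translation of a unit while the anchor stays put, this is simply |t|.
    """
    units: dict[str, str] = base.manifest["units"]
    for label in unit_transforms:
        if label not in units:
            raise DataError(f"unknown unit label {label!r}")
    if anchor not in units:
        raise DataError(f"unknown anchor unit {anchor!r}")

    identity: RigidTransform = (np.eye(3), np.zeros(3))
    transforms = {
        label: (
            _check_proper(unit_transforms[label][0]),
            np.asarray(unit_transforms[label][1], dtype=float),
        )
        if label in unit_transforms
        else identity
        for label in units
    }

    chain_of = {units[label]: label for label in units}
    new_chains = []
    base_coords: dict[str, np.ndarray] = {}
    new_coords: dict[str, np.ndarray] = {}
    for chain in base.model.chains:
        label = chain_of[chain.chain_id]
        rot, trans = transforms[label]
        residues = []
        b_xyz, n_xyz = [], []
        for res in chain.residues:
            atoms = []
            for atom in res.atoms:
                moved = rot @ atom.coords + trans
                atoms.append(Atom(atom.name, atom.element, moved))
                b_xyz.append(atom.coords)
                n_xyz.append(moved)
            residues.append(Residue(res.name, res.seqnum, res.icode, res.hetero, atoms))
        new_chains.append(Chain(chain_id=chain.chain_id, residues=residues))
        base_coords[label] = np.array(b_xyz)
        new_coords[label] = np.array(n_xyz)

    # anchored alignment = exact inverse of the anchor's planted motion
    rot_a, trans_a = transforms[anchor]
    unit_rmsd = {}
    for label in units:
        aligned = (new_coords[label] - trans_a) @ rot_a  # R_aᵀ(y − t_a)
        delta = aligned - base_coords[label]
        unit_rmsd[label] = float(np.sqrt(np.mean(np.sum(delta**2, axis=1))))

    model = StructureModel(
        identifier=base.model.identifier + "_perturbed",
        chains=new_chains,
        source_format=base.model.source_format,
    )
    manifest = dict(base.manifest)
    manifest["unit_rmsd"] = unit_rmsd
    manifest["anchor"] = anchor
    manifest["planted_transforms"] = {
        k: (v[0].copy(), v[1].copy()) for k, v in transforms.items()
    }
    return SyntheticAssembly(
        model=model, assembly_map=base.assembly_map, manifest=manifest, seed=seed
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion draw."""
    from scipy.spatial.transform import Rotation

    q = rng.standard_normal(4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def sample_isotropic_pair(seed: int, r: float = 20.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One draw of the freely-rotating scenario: two isotropic unit dipoles
    and a fixed-length separation vector along z."""
    from .fret_geometry import sample_unit_sphere

    rng = np.random.default_rng(seed)
    mu = sample_unit_sphere(2, rng)
    return mu[0], mu[1], np.array([0.0, 0.0, r])
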