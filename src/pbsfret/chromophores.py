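"""Bilin chromophore extraction, naming, and transition-dipole assignment.

A phycocyanobilin (PCB, PDB ligand code CYC) is an open-chain tetrapyrrole
covalently bound to a conserved cysteine of an α or β phycobiliprotein
subunit. Its lowest-energy transition dipole lies along the long axis of the
conjugated π-system, so we take the dipole direction to be the principal axis
of the configured conjugated atoms, with the sign oriented from the ring-A
side toward the ring-D side by a configurable reference atom pair. The
chromophore "center" used for inter-chromophore distances is the unweighted
centroid of those same conjugated atoms.

Chromophores are named after the field's convention: core cylinder plus
trimer index, subunit type (``a`` for α, ``b`` for β) plus a monomer index or
a role tag (``LCM`` for the ApcE terminal-emitter domain, ``ApcD``,
``ApcF``), and the author number of the attachment cysteine — e.g.
``A3bApcF-82`` or ``C1b3-84``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError
from .structure_io import (
    ALPHA_ROLES,
    AssemblyMap,
    Chain,
    ChainAssignment,
    Residue,
    StructureModel,
)

logger = logging.getLogger(__name__)

#: maximum S–C distance (Å) accepted as a cysteine thioether attachment
ATTACHMENT_CUTOFF = 2.5

#: role → tag rendered in the subunit descriptor (indexed roles use the
#: monomer index instead)
_ROLE_TAGS = {"ApcE": "LCM", "ApcD": "ApcD", "ApcF": "ApcF"}


@dataclass(frozen=True)
class ChromophoreID:
    cylinder: str
    unit_index: int
    subunit: str            # "a" (α) or "b" (β)
    subunit_tag: str        # monomer index ("1".."3") or role tag ("LCM", "ApcD", "ApcF")
    attach_residue: int     # author number of the attachment cysteine
    tentative: bool = False
    attach_uncertain: bool = False  # set when no Cys SG found within cutoff

    def __str__(self) -> str:
        return f"{self.cylinder}{self.unit_index}{self.subunit}{self.subunit_tag}-{self.attach_residue}"

    def __lt__(self, other: "ChromophoreID") -> bool:
        return str(self) < str(other)


@dataclass(frozen=True)
class TransitionDipole:
    direction: np.ndarray   # unit 3-vector
    magnitude: float = 1.0  # relative; couplings are reported relative

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "direction", d / n)
        else:
            object.__setattr__(self, "direction", d)
        if self.magnitude <= 0:
            raise DataError("dipole magnitude must be positive")


@dataclass
class Chromophore:
    id: ChromophoreID
    parent_chain: str
    ligand_code: str
    conjugated_coords: np.ndarray   # (n, 3) Å
    centroid: np.ndarray            # (3,) Å — unweighted mean of conjugated atoms
    dipole: TransitionDipole | None = None
    residue: Residue | None = field(default=None, repr=False)
    incomplete: bool = False

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Chromophore":
        """Return a copy under the rigid motion x → R x + t (dipole rotated)."""
        coords = self.conjugated_coords @ rotation.T + translation
        dip = None
        if self.dipole is not None:
            dip = TransitionDipole(rotation @ self.dipole.direction, self.dipole.magnitude)
        return replace(
            self,
            conjugated_coords=coords,
            centroid=coords.mean(axis=0),
            dipole=dip,
        )


def extract_chromophores(model: StructureModel, amap: AssemblyMap) -> list[Chromophore]:
    """Extract one chromophore per ligand residue whose name is in the map's codes.

    IDs combine the chain's map assignment with the author number of the
    covalently linked cysteine (nearest SG within 2.5 Å of the ligand's
    attachment carbon, or of any ligand atom if no attachment atom is
    configured). Ligands with fewer than 4 configured conjugated atoms are
    flagged incomplete and excluded, with a warning. Chains absent from the
    map are skipped with a logged notice. Dipoles are assigned.
    """
    sg_atoms = _collect_sg_atoms(model)
    chroms: list[Chromophore] = []
    for chain in model.chains:
        assignment = amap.chain_assignments.get(chain.chain_id)
        ligands = [r for r in chain.residues if r.name in amap.ligand_codes]
        if assignment is None:
            if ligands:
                logger.info(
                    "chain %s not in assembly map; skipping %d ligand(s)",
                    chain.chain_id, len(ligands),
                )
            continue
        for res in ligands:
            chrom = _build_chromophore(res, chain, assignment, amap, sg_atoms)
            if chrom.incomplete:
                logger.warning(
                    "ligand %s/%s has %d of %d conjugated atoms (<4); excluded",
                    chain.chain_id, res.label, len(chrom.conjugated_coords),
                    len(amap.conjugated_atom_names),
                )
                continue
            chrom.dipole = assign_dipole(chrom, amap)
            chroms.append(chrom)
    return chroms


def _collect_sg_atoms(model: StructureModel) -> list[tuple[str, int, np.ndarray]]:
    out = []
    for chain in model.chains:
        for res in chain.residues:
            if res.name == "CYS":
                sg = res.get_atom("SG")
                if sg is not None:
                    out.append((chain.chain_id, res.seqnum, sg.coords))
    return out


def _build_chromophore(
    res: Residue,
    chain: Chain,
    assignment: ChainAssignment,
    amap: AssemblyMap,
    sg_atoms: list[tuple[str, int, np.ndarray]],
) -> Chromophore:
    coords = []
    for name in amap.conjugated_atom_names:
        atom = res.get_atom(name)
        if atom is not None:
            coords.append(atom.coords)
    coords = np.array(coords, dtype=float) if coords else np.empty((0, 3))
    incomplete = len(coords) < 4

    attach, uncertain = _find_attachment(res, amap, sg_atoms)
    subunit = "a" if assignment.subunit_role in ALPHA_ROLES else "b"
    tag = _ROLE_TAGS.get(assignment.subunit_role)
    if tag is None:
        tag = str(assignment.monomer_index) if assignment.monomer_index is not None else "?"
    cid = ChromophoreID(
        cylinder=assignment.cylinder,
        unit_index=assignment.unit_index,
        subunit=subunit,
        subunit_tag=tag,
        attach_residue=attach,
        tentative=assignment.tentative,
        attach_uncertain=uncertain,
    )
    centroid = coords.mean(axis=0) if len(coords) else np.full(3, np.nan)
    return Chromophore(
        id=cid,
        parent_chain=chain.chain_id,
        ligand_code=res.name,
        conjugated_coords=coords,
        centroid=centroid,
        residue=res,
        incomplete=incomplete,
    )


def _find_attachment(
    res: Residue, amap: AssemblyMap, sg_atoms: list[tuple[str, int, np.ndarray]]
) -> tuple[int, bool]:
    """Author number of the linked Cys; falls back to the ligand number (flagged)."""
    if amap.attachment_atom:
        anchor = res.get_atom(amap.attachment_atom)
        probe = anchor.coords[None, :] if anchor is not None else res.coords_array()
    else:
        probe = res.coords_array()
    if sg_atoms and len(probe):
        sg_xyz = np.array([xyz for _, _, xyz in sg_atoms])
        d = np.linalg.norm(probe[:, None, :] - sg_xyz[None, :, :], axis=2)
        j = int(np.argmin(d.min(axis=0)))
        if d.min() <= ATTACHMENT_CUTOFF:
            return sg_atoms[j][1], False
    return res.seqnum, True


def assign_dipole(chrom: Chromophore, amap: AssemblyMap) -> TransitionDipole:
    """Principal-axis transition dipole of the conjugated system.

    The direction is the eigenvector of the largest eigenvalue of the 3×3
    covariance of the conjugated coordinates, sign-oriented so that its
    projection onto the vector from the first to the second sign-reference
    atom is positive. Raises if the two largest eigenvalues coincide (the
    long axis would be undefined).
    """
    coords = np.asarray(chrom.conjugated_coords, dtype=float)
    if len(coords) < 4:
        raise DataError(f"{chrom.id}: conjugated system incomplete, cannot assign dipole")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] <= 0 or (evals[2] - evals[1]) / evals[2] < 1e-6:
        raise DataError(f"{chrom.id}: dipole axis undefined (degenerate covariance)")
    direction = evecs[:, 2]

    ref_a, ref_d = amap.dipole_sign_reference
    res = chrom.residue
    if res is not None and res.get_atom(ref_a) is not None and res.get_atom(ref_d) is not None:
        ref_vec = res.get_atom(ref_d).coords - res.get_atom(ref_a).coords
    else:
        # fixture path: reference atoms by position in the configured atom order
        names = [n for n in amap.conjugated_atom_names]
        ia = names.index(ref_a) if ref_a in names else 0
        idx = min(ia, len(coords) - 1)
        jd = names.index(ref_d) if ref_d in names else len(names) - 1
        jdx = min(jd, len(coords) - 1)
        ref_vec = coords[jdx] - coords[idx]
    if float(direction @ ref_vec) < 0:
        direction = -direction
    mag = chrom.dipole.magnitude if chrom.dipole is not None else 1.0
    return TransitionDipole(direction=direction, magnitude=mag)


def environment(
    chrom: Chromophore,
    model: StructureModel,
    cutoff: float,
    include_attachment: bool = False,
) -> list[tuple[str, float]]:
    """Polymer residues with any atom within ``cutoff`` Å of the conjugated system.

    Returns ``(label, min_distance)`` tuples sorted by ascending distance,
    label formatted ``<resname><author number>/<chain>``. The chromophore's
    own attachment cysteine is excluded unless ``include_attachment``.
    """
    if cutoff <= 0:
        raise DataError("cutoff must be positive")
    conj = np.asarray(chrom.conjugated_coords)
    if conj.size == 0:
        return []
    out: list[tuple[str, float]] = []
    for chain in model.chains:
        for res in chain.polymer_residues():
            if (
                not include_attachment
                and res.name == "CYS"
                and res.seqnum == chrom.id.attach_residue
                and chain.chain_id == chrom.parent_chain
            ):
                continue
            xyz = res.coords_array()
            d = float(np.min(np.linalg.norm(conj[:, None, :] - xyz[None, :, :], axis=2)))
            if d <= cutoff:
                out.append((f"{res.name}{res.seqnum}/{chain.chain_id}", d))
    out.sort(key=lambda t: (t[1], t[0]))
    return out
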