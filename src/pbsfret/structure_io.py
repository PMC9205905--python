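"""Reading and writing atomic structures and tabular outputs.

Structures are read with :mod:`gemmi` from PDB or mmCIF and exposed through a
small immutable-ish object model (:class:`StructureModel` / :class:`Chain` /
:class:`Residue` / :class:`Atom`) that keeps *author* residue numbering, drops
waters and hydrogens, and resolves alternate locations to a single conformer
(highest occupancy; ties broken by the alphabetically first alt-loc ID).
Only the first model of multi-model files is used.

The :class:`AssemblyMap` carries the user-supplied correspondence between file
chain IDs and the biological nomenclature (core cylinder, trimer/disk index,
subunit role) plus the ligand/atom conventions used to locate chromophores.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from configparser import ConfigParser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import ConfigError, FormatError, NoAtomsError

logger = logging.getLogger(__name__)

#: subunit roles accepted in an assembly map
ALLOWED_ROLES = (
    "ApcA", "ApcB", "ApcC", "ApcD", "ApcE", "ApcF",
    "CpcA", "CpcB", "CpcC", "CpcD", "CpcG",
)

#: roles that carry an alpha-type (α) bilin; beta-type roles carry β bilins
ALPHA_ROLES = frozenset({"ApcA", "ApcD", "ApcE", "CpcA"})
BETA_ROLES = frozenset({"ApcB", "ApcF", "CpcB"})

#: default conjugated π-system of phycocyanobilin (PDB ligand CYC): the
#: C4A–C1D conjugation path through rings B and C and the methine bridges.
DEFAULT_CONJUGATED_ATOMS = (
    "C4A", "CHB", "C1B", "C2B", "C3B", "C4B", "NB",
    "CHC", "C1C", "C2C", "C3C", "C4C", "NC", "CHD", "C1D",
)

#: ring-A-side atom -> ring-D-side atom; orients the transition-dipole sign
DEFAULT_DIPOLE_SIGN_REFERENCE = ("C4A", "C1D")


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) float, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise FormatError(f"atom {self.name!r}: coordinates must be finite 3-vectors")


@dataclass
class Residue:
    name: str
    seqnum: int  # author residue number, never renumbered
    icode: str = ""
    hetero: bool = False
    atoms: list[Atom] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.name}{self.seqnum}{self.icode}".strip()

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if _is_polymer(r)]

    @property
    def one_letter_sequence(self) -> str:
        return "".join(_one_letter(r.name) for r in self.polymer_residues())

    def hetero_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.hetero and not _is_polymer(r)]


@dataclass
class StructureModel:
    identifier: str
    chains: list[Chain]
    source_format: str  # "pdb" | "mmcif"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in model {self.identifier!r}")

    def atom_count(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"
    return "X"


def _is_polymer(res: Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


# ---------------------------------------------------------------------------
# reading


def read_structure(path: str | Path, format_hint: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alt-locs are resolved to the highest-occupancy conformer (ties to the
    alphabetically first alt-loc ID), waters and hydrogens are dropped, and
    only the first model of a multi-model file is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
    if format_hint is not None and format_hint not in fmt_map:
        raise ConfigError(f"unknown format hint {format_hint!r}; use 'pdb' or 'mmcif'")
    try:
        if format_hint is None:
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path), format=fmt_map[format_hint])
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc

    source_format = format_hint or (
        "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    )
    if len(st) == 0:
        raise NoAtomsError(f"{path.name}: no atoms (file has no models)")
    if len(st) > 1:
        logger.info("%s: %d models present, using the first only", path.name, len(st))
    gmodel = st[0]

    chains: dict[str, Chain] = {}
    for gchain in gmodel:
        chain = chains.setdefault(gchain.name, Chain(chain_id=gchain.name))
        for gres in gchain:
            if gres.is_water():
                continue
            atoms = _resolve_altlocs(gres)
            atoms = [a for a in atoms if a.element.name != "H"]
            if not atoms:
                continue
            chain.residues.append(
                Residue(
                    name=gres.name,
                    seqnum=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    hetero=(gres.het_flag == "H"),
                    atoms=[
                        Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                        for a in atoms
                    ],
                )
            )

    model = StructureModel(
        identifier=st.name or path.stem,
        chains=[c for c in chains.values() if c.residues],
        source_format=source_format,
    )
    if model.atom_count() == 0:
        raise NoAtomsError(f"{path.name}: no atoms")
    return model


def _resolve_altlocs(gres: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per atom name: highest occupancy, ties to first alt-loc ID."""
    best: dict[str, gemmi.Atom] = {}
    for atom in gres:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            continue
        if atom.occ > prev.occ or (atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~")):
            best[atom.name] = atom
    return list(best.values())


# ---------------------------------------------------------------------------
# writing (synthetic fixtures and round-trip support)


def write_structure(model: StructureModel, path: str | Path, fmt: str | None = None) -> None:
    """Write a :class:`StructureModel` to PDB or mmCIF (format from ``fmt`` or suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = gemmi.Structure()
    st.name = model.identifier
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
            gres.het_flag = "H" if res.hetero else "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coords)
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ConfigError(f"unknown output format {fmt!r}")


# ---------------------------------------------------------------------------
# assembly map


@dataclass(frozen=True)
class ChainAssignment:
    cylinder: str           # A, A', B, C, C' or a rod disk label
    unit_index: int         # trimer / disk-monomer index within the cylinder
    subunit_role: str       # one of ALLOWED_ROLES
    monomer_index: int | None = None  # αβ-monomer index within the trimer
    tentative: bool = False


@dataclass
class AssemblyMap:
    chain_assignments: dict[str, ChainAssignment] = field(default_factory=dict)
    ligand_codes: frozenset[str] = frozenset({"CYC"})
    conjugated_atom_names: tuple[str, ...] = DEFAULT_CONJUGATED_ATOMS
    dipole_sign_reference: tuple[str, str] = DEFAULT_DIPOLE_SIGN_REFERENCE
    attachment_atom: str | None = None  # ligand carbon bonded to the Cys SG

    def __post_init__(self) -> None:
        for code in self.ligand_codes:
            if not (len(code) == 3 and code.isalnum()):
                raise ConfigError(f"ligand code {code!r} is not a 3-letter alphanumeric code")
        if not self.conjugated_atom_names:
            raise ConfigError("conjugated_atom_names must be non-empty")
        for name in self.dipole_sign_reference:
            if name not in self.conjugated_atom_names:
                raise ConfigError(
                    f"dipole sign reference atom {name!r} is not a conjugated atom"
                )

    def role_counts(self) -> Counter:
        return Counter(a.subunit_role for a in self.chain_assignments.values())


def load_assembly_map(path: str | Path) -> AssemblyMap:
    """Load an assembly map from an INI-style config.

    Format::

        [ligands]
        codes = CYC
        conjugated_atoms = C4A CHB C1B ... C1D
        dipole_sign_reference = C4A C1D
        attachment_atom = C3A          ; optional

        [chains]                       ; or several [chains.*] sections
        A = A 1 ApcA 1                 ; cylinder unit role [monomer] [tentative]
        B = A 1 ApcB 1

    Unmapped chains in a structure are permitted and ignored downstream.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config: {path}")
    parser = ConfigParser(inline_comment_prefixes=(";", "#"))
    parser.optionxform = str  # chain IDs are case-sensitive
    parser.read(path)

    kwargs: dict = {}
    if parser.has_section("ligands"):
        lig = parser["ligands"]
        if "codes" in lig:
            kwargs["ligand_codes"] = frozenset(lig["codes"].split())
        if "conjugated_atoms" in lig:
            kwargs["conjugated_atom_names"] = tuple(lig["conjugated_atoms"].split())
        if "dipole_sign_reference" in lig:
            ref = tuple(lig["dipole_sign_reference"].split())
            if len(ref) != 2:
                raise ConfigError("dipole_sign_reference needs exactly two atom names")
            kwargs["dipole_sign_reference"] = ref
        if "attachment_atom" in lig:
            kwargs["attachment_atom"] = lig["attachment_atom"].strip()

    assignments: dict[str, ChainAssignment] = {}
    for section in parser.sections():
        if not (section == "chains" or section.startswith("chains.")):
            continue
        for chain_id, value in parser[section].items():
            if chain_id in assignments:
                raise ConfigError(f"chain {chain_id!r} assigned more than once")
            assignments[chain_id] = _parse_assignment(chain_id, value)

    return AssemblyMap(chain_assignments=assignments, **kwargs)


def _parse_assignment(chain_id: str, value: str) -> ChainAssignment:
    tokens = value.split()
    if len(tokens) < 3:
        raise ConfigError(
            f"chain {chain_id!r}: expected 'cylinder unit role [monomer] [tentative]', got {value!r}"
        )
    cylinder, unit_s, role = tokens[0], tokens[1], tokens[2]
    if role not in ALLOWED_ROLES:
        raise ConfigError(
            f"chain {chain_id!r}: unknown subunit role {role!r}; allowed: {', '.join(ALLOWED_ROLES)}"
        )
    try:
        unit_index = int(unit_s)
    except ValueError as exc:
        raise ConfigError(f"chain {chain_id!r}: unit index {unit_s!r} is not an integer") from exc
    monomer_index: int | None = None
    tentative = False
    for tok in tokens[3:]:
        if tok.lower() == "tentative":
            tentative = True
        else:
            try:
                monomer_index = int(tok)
            except ValueError as exc:
                raise ConfigError(f"chain {chain_id!r}: unexpected token {tok!r}") from exc
    # ApcD identification is tentative in the deposited core model
    if role == "ApcD":
        tentative = True
    return ChainAssignment(cylinder, unit_index, role, monomer_index, tentative)


def write_assembly_map(amap: AssemblyMap, path: str | Path) -> None:
    """Write an :class:`AssemblyMap` in the format read by :func:`load_assembly_map`."""
    lines = ["[ligands]"]
    lines.append("codes = " + " ".join(sorted(amap.ligand_codes)))
    lines.append("conjugated_atoms = " + " ".join(amap.conjugated_atom_names))
    lines.append("dipole_sign_reference = " + " ".join(amap.dipole_sign_reference))
    if amap.attachment_atom:
        lines.append("attachment_atom = " + amap.attachment_atom)
    lines.append("")
    lines.append("[chains]")
    for chain_id, a in amap.chain_assignments.items():
        parts = [a.cylinder, str(a.unit_index), a.subunit_role]
        if a.monomer_index is not None:
            parts.append(str(a.monomer_index))
        if a.tentative and a.subunit_role != "ApcD":
            parts.append("tentative")
        lines.append(f"{chain_id} = {' '.join(parts)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tabular output


PAIR_TABLE_COLUMNS = (
    "donor_id", "acceptor_id", "r_angstrom", "cos_theta_T", "cos_theta_D",
    "cos_theta_A", "kappa_sq", "v_rel", "weight",
)


def write_pair_table(pairs: Sequence, path: str | Path) -> None:
    """Write donor/acceptor geometry rows as TSV.

    Rows are sorted by descending weight; ties broken by donor then acceptor
    ID so output is reproducible. Floats use 4 decimals.
    """
    ordered = sorted(
        pairs, key=lambda p: (-p.weight, str(p.donor_id), str(p.acceptor_id))
    )
    lines = ["\t".join(PAIR_TABLE_COLUMNS)]
    for p in ordered:
        lines.append(
            "\t".join(
                [
                    str(p.donor_id),
                    str(p.acceptor_id),
                    f"{p.r:.4f}",
                    f"{p.cos_theta_T:.4f}",
                    f"{p.cos_theta_D:.4f}",
                    f"{p.cos_theta_A:.4f}",
                    f"{p.kappa_sq:.4f}",
                    f"{p.v_rel:.4e}",
                    f"{p.weight:.4e}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_chromophore_manifest(chroms: Iterable, path: str | Path) -> None:
    """TSV manifest: id, chain, ligand code, centroid xyz, dipole xyz."""
    lines = ["id\tchain\tligand\tcx\tcy\tcz\tdx\tdy\tdz"]
    for ch in chroms:
        c = ch.centroid
        d = ch.dipole.direction
        lines.append(
            f"{ch.id}\t{ch.parent_chain}\t{ch.ligand_code}\t"
            f"{c[0]:.4f}\t{c[1]:.4f}\t{c[2]:.4f}\t{d[0]:.6f}\t{d[1]:.6f}\t{d[2]:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
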