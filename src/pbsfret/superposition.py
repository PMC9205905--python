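"""Rigid superposition and the anchored per-unit RMSD comparison.

Two ways of comparing oligomeric assemblies are provided:

* ``kabsch_fit`` — the ordinary least-squares rigid fit of one coordinate set
  onto another (proper rotation only; reflections are corrected), used for
  single-unit comparisons such as ``region_rmsd``.

* ``anchored_rmsd`` — the assembly-level comparison: the Cα backbone of one
  designated unit (e.g. the first αβ monomer of a phycocyanin rod) is fitted,
  and that single transform is applied to the *whole* mobile assembly; every
  other unit is then scored without refitting. A unit that sits identically
  within both assemblies scores near its own best-fit RMSD; a unit whose
  placement has shifted (for instance through linker-protein contacts) scores
  much higher, exposing rearrangement rather than internal deformation.

Residue correspondence between units comes from a global sequence alignment
(match +1, mismatch 0, linear gap −1) of the one-letter sequences; aligned
non-gap positions with Cα atoms on both sides become the paired residues.
This is robust to the numbering offsets common between crystal and cryo-EM
depositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .structure_io import Chain, _is_polymer

ResidueKey = tuple[str, int, str]  # (chain_id, author seqnum, insertion code)


@dataclass
class ResiduePairing:
    unit_a: str
    unit_b: str
    pairs: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)

    def __post_init__(self) -> None:
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise DataError("a residue appears twice in a pairing")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3×3 proper orthogonal
    translation: np.ndarray    # Å
    anchor_unit: str
    anchor_rmsd: float
    per_unit_rmsd: dict[str, float]

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def report(self) -> str:
        """Human-readable comparison report with the 3×4 transform."""
        lines = ["unit\tn_pairs\trmsd_angstrom"]
        for unit in sorted(self.per_unit_rmsd, key=_unit_sort_key):
            lines.append(f"{unit}\t-\t{self.per_unit_rmsd[unit]:.3f}")
        lines.append("")
        lines.append(f"anchor = {self.anchor_unit} (rmsd {self.anchor_rmsd:.3f} A)")
        lines.append("rotation | translation:")
        for i in range(3):
            row = " ".join(f"{self.rotation[i, j]:9.6f}" for j in range(3))
            lines.append(f"  {row} | {self.translation[i]:9.4f}")
        return "\n".join(lines)


def _unit_sort_key(u: str):
    return (0, int(u)) if u.isdigit() else (1, u)


# ---------------------------------------------------------------------------
# sequence alignment pairing


def align_sequences(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Global Needleman–Wunsch alignment, match +1 / mismatch 0 / gap −1.

    Returns aligned (index_a, index_b) position pairs. Traceback ties prefer
    diagonal over gap-in-b over gap-in-a, which makes the pairing
    deterministic among co-optimal alignments.
    """
    n, m = len(seq_a), len(seq_b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = -np.arange(n + 1)
    score[0, :] = -np.arange(m + 1)
    for i in range(1, n + 1):
        s_prev = score[i - 1]
        s_cur = score[i]
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            diag = s_prev[j - 1] + (1.0 if ai == seq_b[j - 1] else 0.0)
            up = s_prev[j] - 1.0
            left = s_cur[j - 1] - 1.0
            s_cur[j] = max(diag, up, left)
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (1.0 if seq_a[i - 1] == seq_b[j - 1] else 0.0)
            if score[i, j] == diag:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] - 1.0:
            i -= 1
            continue
        j -= 1
    pairs.reverse()
    return pairs


def pair_residues(chain_a: Chain, chain_b: Chain, unit_a: str | None = None, unit_b: str | None = None) -> ResiduePairing:
    """Pair the Cα-bearing polymer residues of two chains by sequence alignment."""
    res_a = [r for r in chain_a.polymer_residues() if r.get_atom("CA") is not None]
    res_b = [r for r in chain_b.polymer_residues() if r.get_atom("CA") is not None]
    if not res_a or not res_b:
        raise DataError("insufficient correspondence: a chain has no Cα atoms")
    seq_a = "".join(_one_letter_of(r) for r in res_a)
    seq_b = "".join(_one_letter_of(r) for r in res_b)
    aligned = align_sequences(seq_a, seq_b)
    pairs = [
        (
            (chain_a.chain_id, res_a[i].seqnum, res_a[i].icode),
            (chain_b.chain_id, res_b[j].seqnum, res_b[j].icode),
        )
        for i, j in aligned
    ]
    if len(pairs) < 3:
        raise DataError(
            f"insufficient correspondence between chains {chain_a.chain_id} and {chain_b.chain_id} "
            f"({len(pairs)} pairs)"
        )
    return ResiduePairing(
        unit_a=unit_a or chain_a.chain_id, unit_b=unit_b or chain_b.chain_id, pairs=pairs
    )


def _one_letter_of(res) -> str:
    from .structure_io import _one_letter

    return _one_letter(res.name)


def pair_units(chains_a: list[Chain], chains_b: list[Chain], unit_a: str, unit_b: str) -> ResiduePairing:
    """Pair a multi-chain unit (e.g. an αβ monomer) chain-by-chain, in order."""
    if len(chains_a) != len(chains_b):
        raise DataError(
            f"unit {unit_a} has {len(chains_a)} chains but unit {unit_b} has {len(chains_b)}"
        )
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    for ca, cb in zip(chains_a, chains_b):
        pairs.extend(pair_residues(ca, cb).pairs)
    return ResiduePairing(unit_a=unit_a, unit_b=unit_b, pairs=pairs)


# ---------------------------------------------------------------------------
# rigid fits


def kabsch_fit(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit ``x → R x + t`` taking ``coords_a`` onto ``coords_b``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1; the reflection branch of the SVD solution is corrected).
    Raises on fewer than 3 points or (near-)collinear input, where the
    rotation is not uniquely determined.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise DataError("coordinate sets must be equal-length lists of 3-vectors")
    if len(a) < 3:
        raise DataError("need at least 3 points for a rigid fit")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    for pts, name in ((a0, "a"), (b0, "b")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1e-300):
            raise DataError(f"rank-deficient coordinates (set {name} is collinear)")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cb - rot @ ca
    resid = a0 @ rot.T - b0
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return rot, trans, rmsd


def rmsd_between(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Plain coordinate RMSD with no fitting."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("coordinate sets must have equal shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# anchored comparison


Assembly = dict[str, list[Chain]]  # unit label → chains of that unit


def _ca_lookup(chains: list[Chain]) -> dict[ResidueKey, np.ndarray]:
    out: dict[ResidueKey, np.ndarray] = {}
    for chain in chains:
        for res in chain.residues:
            if _is_polymer(res):
                ca = res.get_atom("CA")
                if ca is not None:
                    out[(chain.chain_id, res.seqnum, res.icode)] = ca.coords
    return out


def _paired_coords(
    pairing: ResiduePairing, mobile: Assembly, reference: Assembly
) -> tuple[np.ndarray, np.ndarray]:
    lk_m = _ca_lookup(mobile[pairing.unit_a])
    lk_r = _ca_lookup(reference[pairing.unit_b])
    am, ar = [], []
    for key_m, key_r in pairing.pairs:
        if key_m in lk_m and key_r in lk_r:
            am.append(lk_m[key_m])
            ar.append(lk_r[key_r])
    return np.array(am), np.array(ar)


def anchored_rmsd(
    mobile: Assembly,
    reference: Assembly,
    anchor: str,
    pairings: list[ResiduePairing],
) -> SuperpositionResult:
    """Fit the anchor unit, apply that one transform everywhere, score every unit.

    ``pairings`` must include one entry per unit to score, keyed by
    ``unit_a`` (mobile label); the anchor's pairing needs at least 3 pairs.
    Per-unit RMSDs are over paired Cα atoms with no refitting, so a unit's
    value can only meet (never beat) its own dedicated best-fit RMSD.
    """
    by_unit = {p.unit_a: p for p in pairings}
    if anchor not in mobile or anchor not in reference:
        raise DataError(f"anchor unit {anchor!r} missing from an assembly")
    if anchor not in by_unit:
        raise DataError(f"no pairing supplied for anchor unit {anchor!r}")
    for unit in mobile:
        if unit not in by_unit:
            raise DataError(f"no pairing supplied for unit {unit!r}")

    a_m, a_r = _paired_coords(by_unit[anchor], mobile, reference)
    if len(a_m) < 3:
        raise DataError(f"anchor pairing has {len(a_m)} pairs (<3)")
    rot, trans, anchor_rmsd = kabsch_fit(a_m, a_r)

    per_unit: dict[str, float] = {}
    for unit, pairing in by_unit.items():
        if unit not in mobile or pairing.unit_b not in reference:
            raise DataError(f"pairing references unknown unit {unit!r}/{pairing.unit_b!r}")
        m, r = _paired_coords(pairing, mobile, reference)
        if len(m) == 0:
            raise DataError(f"unit {unit!r}: no paired Cα coordinates")
        per_unit[unit] = rmsd_between(m @ rot.T + trans, r)
    # mathematically identical; keep the stored fields bit-identical too
    per_unit[anchor] = anchor_rmsd

    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        anchor_unit=anchor,
        anchor_rmsd=anchor_rmsd,
        per_unit_rmsd=per_unit,
    )


def region_rmsd(
    chain_a: Chain,
    range_a: tuple[int, int],
    chain_b: Chain,
    range_b: tuple[int, int],
) -> float:
    """Best-fit Cα RMSD between two residue intervals (author numbers, inclusive)."""
    sub_a = _slice_chain(chain_a, range_a)
    sub_b = _slice_chain(chain_b, range_b)
    pairing = pair_residues(sub_a, sub_b)
    lk_a = _ca_lookup([sub_a])
    lk_b = _ca_lookup([sub_b])
    coords_a = np.array([lk_a[k] for k, _ in pairing.pairs])
    coords_b = np.array([lk_b[k] for _, k in pairing.pairs])
    if len(coords_a) == 0:
        raise DataError("empty overlap after pairing")
    _, _, rmsd = kabsch_fit(coords_a, coords_b)
    return rmsd


def _slice_chain(chain: Chain, rng: tuple[int, int]) -> Chain:
    lo, hi = rng
    residues = [r for r in chain.residues if lo <= r.seqnum <= hi]
    if not residues:
        raise DataError(f"chain {chain.chain_id}: no residues in {lo}–{hi}")
    return Chain(chain_id=chain.chain_id, residues=residues)


def units_from_map(model, amap) -> Assembly:
    """Group a model's mapped chains into units keyed by their map unit index.

    Chains within a unit are ordered α-type roles first, then β, then
    linkers, each alphabetically — giving a stable chain order for
    :func:`pair_units`.
    """
    from .structure_io import ALPHA_ROLES, BETA_ROLES

    def role_rank(role: str) -> int:
        if role in ALPHA_ROLES:
            return 0
        if role in BETA_ROLES:
            return 1
        return 2

    units: Assembly = {}
    for chain in model.chains:
        a = amap.chain_assignments.get(chain.chain_id)
        if a is None:
            continue
        units.setdefault(str(a.unit_index), []).append(chain)
    for label, chains in units.items():
        chains.sort(
            key=lambda c: (
                role_rank(amap.chain_assignments[c.chain_id].subunit_role),
                amap.chain_assignments[c.chain_id].subunit_role,
                c.chain_id,
            )
        )
    return units
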