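"""Residue pairing, Kabsch fits, and the anchored per-unit RMSD comparison."""

from functools import lru_cache

import numpy as np
import pytest

from pbsfret import (
    DataError,
    anchored_rmsd,
    kabsch_fit,
    pair_residues,
    pair_units,
    region_rmsd,
)
from pbsfret.superposition import align_sequences, rmsd_between
from pbsfret.synthetic_data import make_helical_rod, perturb_assembly, random_rotation

from conftest import chain_from_sequence, random_sequence


# ---------------------------------------------------------------------------
# sequence pairing


def test_identical_sequences_pair_completely():
    seq = random_sequence(np.random.default_rng(0), 50)
    a = chain_from_sequence(seq, "A")
    b = chain_from_sequence(seq, "B")
    pairing = pair_residues(a, b)
    assert len(pairing.pairs) == 50
    assert all(ka[1] == kb[1] for ka, kb in pairing.pairs)


def test_internal_deletion_skips_the_gap():
    seq = "ACDEFGHIKLMNPQRSTVWY"
    deleted = seq[:8] + seq[11:]  # drop 3 residues
    a = chain_from_sequence(seq, "A")
    b = chain_from_sequence(deleted, "B")
    pairing = pair_residues(a, b)
    nums_a = [ka[1] for ka, _ in pairing.pairs]
    assert len(pairing.pairs) == len(deleted)
    assert set(range(9, 12)).isdisjoint(nums_a)  # gap positions unpaired


def _oracle_align(seq_a, seq_b):
    """Independent recursive-DP Needleman–Wunsch (match +1, mismatch 0,
    gap −1) with the same tie preference (diagonal, then gap-in-b, then
    gap-in-a)."""

    @lru_cache(maxsize=None)
    def score(i, j):
        if i == 0:
            return -j
        if j == 0:
            return -i
        return max(
            score(i - 1, j - 1) + (1 if seq_a[i - 1] == seq_b[j - 1] else 0),
            score(i - 1, j) - 1,
            score(i, j - 1) - 1,
        )

    pairs = []
    i, j = len(seq_a), len(seq_b)
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score(i, j) == score(i - 1, j - 1) + (
            1 if seq_a[i - 1] == seq_b[j - 1] else 0
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and score(i, j) == score(i - 1, j) - 1:
            i -= 1
        else:
            j -= 1
    return list(reversed(pairs)), score(len(seq_a), len(seq_b))


@pytest.mark.parametrize("seed", range(6))
def test_alignment_matches_independent_dp_oracle(seed):
    """Random 30-mers: pairing identical to a recursive-DP oracle with the
    same scoring, and the score matches biopython's global aligner."""
    rng = np.random.default_rng(seed)
    seq_a = random_sequence(rng, 30)
    seq_b = random_sequence(rng, 30)
    got = align_sequences(seq_a, seq_b)
    oracle_pairs, oracle_score = _oracle_align(seq_a, seq_b)
    assert got == oracle_pairs

    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    assert aligner.score(seq_a, seq_b) == oracle_score


def test_too_few_pairs_raises():
    a = chain_from_sequence("AC", "A")
    b = chain_from_sequence("AC", "B")
    with pytest.raises(DataError, match="insufficient correspondence"):
        pair_residues(a, b)


# ---------------------------------------------------------------------------
# Kabsch


def _helix(n=20, seed=0):
    rng = np.random.default_rng(seed)
    base = np.array([[2.3 * np.cos(1.7 * k), 2.3 * np.sin(1.7 * k), 1.5 * k] for k in range(n)])
    return base + rng.normal(scale=0.01, size=base.shape)


def test_kabsch_identity_and_exact_recovery():
    a = _helix()
    rot, trans, rmsd = kabsch_fit(a, a)
    np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(trans, np.zeros(3), atol=1e-9)
    assert rmsd == pytest.approx(0.0, abs=1e-9)

    rng = np.random.default_rng(1)
    true_rot = random_rotation(rng)
    true_t = rng.normal(size=3) * 8
    b = a @ true_rot.T + true_t
    rot, trans, rmsd = kabsch_fit(a, b)
    np.testing.assert_allclose(rot, true_rot, atol=1e-9)
    np.testing.assert_allclose(trans, true_t, atol=1e-8)
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_kabsch_mirror_still_returns_proper_rotation():
    a = _helix()
    b = a.copy()
    b[:, 0] *= -1  # reflection
    rot, _, rmsd = kabsch_fit(a, b)
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
    assert rmsd > 0.1


def test_kabsch_rejects_degenerate_input():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DataError, match="rank-deficient"):
        kabsch_fit(line, line)
    with pytest.raises(DataError):
        kabsch_fit(_helix()[:2], _helix()[:2])


# ---------------------------------------------------------------------------
# anchored comparison


def _assemblies(base, pert):
    mobile = {lab: [pert.model.chain(ch)] for lab, ch in pert.manifest["units"].items()}
    ref = {lab: [base.model.chain(ch)] for lab, ch in base.manifest["units"].items()}
    pairings = [pair_units(mobile[u], ref[u], u, u) for u in sorted(mobile)]
    return mobile, ref, pairings


def test_identical_assemblies_score_zero(rod4):
    mobile, ref, pairings = _assemblies(rod4, rod4)
    res = anchored_rmsd(mobile, ref, "1", pairings)
    for v in res.per_unit_rmsd.values():
        assert v == pytest.approx(0.0, abs=1e-9)


def test_pure_translation_gives_rmsd_equal_to_shift(rod4):
    """Unit 2 translated by (3,0,0) with unit 1 anchored: RMSD(2) = 3 Å."""
    pert = perturb_assembly(rod4, {"2": (np.eye(3), np.array([3.0, 0.0, 0.0]))}, anchor="1")
    mobile, ref, pairings = _assemblies(rod4, pert)
    res = anchored_rmsd(mobile, ref, "1", pairings)
    assert res.per_unit_rmsd["1"] == pytest.approx(0.0, abs=1e-9)
    assert res.per_unit_rmsd["2"] == pytest.approx(3.0, abs=1e-9)
    assert res.anchor_rmsd == res.per_unit_rmsd["1"]


def test_anchored_matches_generator_ground_truth_with_rotations(rod4):
    """Planted rotations+translations: pipeline per-unit RMSDs equal the
    manifest's independently computed values to 1e-6 Å."""
    rng = np.random.default_rng(21)
    transforms = {
        "2": (random_rotation(rng), rng.normal(size=3) * 4),
        "3": (np.eye(3), np.array([0.0, 2.0, 0.0])),
        "4": (random_rotation(rng), np.zeros(3)),
    }
    pert = perturb_assembly(rod4, transforms, anchor="1")
    mobile = {lab: [pert.model.chain(ch)] for lab, ch in pert.manifest["units"].items()}
    ref = {lab: [rod4.model.chain(ch)] for lab, ch in rod4.manifest["units"].items()}
    pairings = [pair_units(mobile[u], ref[u], u, u) for u in sorted(mobile)]
    res = anchored_rmsd(mobile, ref, "1", pairings)
    for unit, expected in pert.manifest["unit_rmsd"].items():
        assert res.per_unit_rmsd[unit] == pytest.approx(expected, abs=1e-6)


def test_anchored_never_beats_dedicated_fit(rod4):
    """per_unit_rmsd(u) ≥ the unit's own Kabsch-minimal RMSD, for every unit."""
    rng = np.random.default_rng(33)
    transforms = {
        lab: (random_rotation(rng), rng.normal(size=3) * 3)
        for lab in ("1", "2", "3", "4")
    }
    pert = perturb_assembly(rod4, transforms, anchor="1")
    mobile = {lab: [pert.model.chain(ch)] for lab, ch in pert.manifest["units"].items()}
    ref = {lab: [rod4.model.chain(ch)] for lab, ch in rod4.manifest["units"].items()}
    pairings = [pair_units(mobile[u], ref[u], u, u) for u in sorted(mobile)]
    res = anchored_rmsd(mobile, ref, "1", pairings)
    assert res.anchor_rmsd == pytest.approx(res.per_unit_rmsd["1"], abs=1e-12)
    for u in mobile:
        coords_m = np.array([a.coords for r in mobile[u][0].residues for a in r.atoms])
        coords_r = np.array([a.coords for r in ref[u][0].residues for a in r.atoms])
        _, _, dedicated = kabsch_fit(coords_m, coords_r)
        assert res.per_unit_rmsd[u] >= dedicated - 1e-9


def test_anchored_invariant_under_common_rigid_motion(rod4):
    """Rigidly moving the whole mobile assembly changes nothing (to 1e-6 Å)."""
    rng = np.random.default_rng(44)
    pert = perturb_assembly(rod4, {"3": (np.eye(3), np.array([1.5, 0, 0]))}, anchor="1")
    rot, t = random_rotation(rng), rng.normal(size=3) * 20
    moved = perturb_assembly(
        pert, {lab: (rot, t) for lab in pert.manifest["units"]}, anchor="1"
    )
    ref = {lab: [rod4.model.chain(ch)] for lab, ch in rod4.manifest["units"].items()}
    res_a = anchored_rmsd(
        {lab: [pert.model.chain(ch)] for lab, ch in pert.manifest["units"].items()},
        ref, "1",
        [pair_units([pert.model.chain(ch)], ref[lab], lab, lab) for lab, ch in pert.manifest["units"].items()],
    )
    res_b = anchored_rmsd(
        {lab: [moved.model.chain(ch)] for lab, ch in moved.manifest["units"].items()},
        ref, "1",
        [pair_units([moved.model.chain(ch)], ref[lab], lab, lab) for lab, ch in moved.manifest["units"].items()],
    )
    for u in res_a.per_unit_rmsd:
        assert res_b.per_unit_rmsd[u] == pytest.approx(res_a.per_unit_rmsd[u], abs=1e-6)


def test_missing_pairing_raises(rod4):
    mobile = {lab: [rod4.model.chain(ch)] for lab, ch in rod4.manifest["units"].items()}
    pairings = [pair_units(mobile["1"], mobile["1"], "1", "1")]
    with pytest.raises(DataError, match="no pairing"):
        anchored_rmsd(mobile, mobile, "1", pairings)


# ---------------------------------------------------------------------------
# region RMSD


def test_region_rmsd_self_and_rigid_copy():
    seq = random_sequence(np.random.default_rng(2), 60)
    a = chain_from_sequence(seq, "A")
    assert region_rmsd(a, (10, 40), a, (10, 40)) == pytest.approx(0.0, abs=1e-9)

    rng = np.random.default_rng(3)
    rot, t = random_rotation(rng), rng.normal(size=3) * 5
    coords = [r.atoms[0].coords @ rot.T + t for r in a.residues]
    b = chain_from_sequence(seq, "B", coords=coords)
    assert region_rmsd(a, (10, 40), b, (10, 40)) == pytest.approx(0.0, abs=1e-9)


def test_region_rmsd_empty_range_raises():
    a = chain_from_sequence("ACDEFGHIKL", "A")
    with pytest.raises(DataError):
        region_rmsd(a, (90, 99), a, (1, 10))
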