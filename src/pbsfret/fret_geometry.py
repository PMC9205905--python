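"""Pairwise Förster (point-dipole) geometry.

In the weak-coupling limit the excitation-energy-transfer rate between a
donor D and acceptor A is proportional to V²Θ, where Θ is the spectral
overlap integral and V the dipole–dipole coupling

    V ≈ μ_D μ_A (cosθ_T − 3 cosθ_D cosθ_A) / r³,

with θ_T the angle between the two transition dipoles and θ_D, θ_A the
angles each dipole makes with the center-to-center vector r. The geometric
part is the orientation factor

    κ² = (cosθ_T − 3 cosθ_D cosθ_A)²  ∈ [0, 4],

whose average over isotropically oriented dipoles is 2/3. No spectra are
computed here: Θ is a fixed constant (default 1) and all couplings and rate
weights are relative, with unit dipole magnitudes unless configured.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .chromophores import Chromophore, ChromophoreID
from .errors import DataError

#: fixed relative spectral-overlap factor Θ (no spectra are modelled)
OVERLAP_FACTOR = 1.0

#: default distance gate (Å) for pair enumeration; beyond this, couplings are
#: negligible on the 1/r⁶ scale relevant to inter-cylinder hops
DEFAULT_CUTOFF = 35.0


@dataclass(frozen=True)
class PairGeometry:
    donor_id: ChromophoreID
    acceptor_id: ChromophoreID
    r_vec: np.ndarray          # donor centroid → acceptor centroid, Å
    r: float                   # |r_vec|, Å
    cos_theta_T: float
    cos_theta_D: float
    cos_theta_A: float
    kappa_sq: float            # (cosθT − 3 cosθD cosθA)²
    v_rel: float               # relative coupling μDμA(cosθT − 3cosθDcosθA)/r³
    weight: float              # κ²/r⁶ — relative rate proxy (Θ fixed)
    overlap_factor: float = OVERLAP_FACTOR


def kappa_squared(mu_d: np.ndarray, mu_a: np.ndarray, r_vec: np.ndarray) -> float:
    """Orientation factor κ² for unit dipoles ``mu_d``, ``mu_a`` separated by ``r_vec``."""
    mu_d = np.asarray(mu_d, dtype=float)
    mu_a = np.asarray(mu_a, dtype=float)
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise DataError("coincident centroids: r_vec has zero length")
    for mu, name in ((mu_d, "mu_d"), (mu_a, "mu_a")):
        if abs(np.linalg.norm(mu) - 1.0) > 1e-6:
            raise DataError(f"{name} is not a unit vector")
    r_hat = r_vec / r
    cos_t = float(mu_d @ mu_a)
    cos_d = float(mu_d @ r_hat)
    cos_a = float(mu_a @ r_hat)
    return (cos_t - 3.0 * cos_d * cos_a) ** 2


def pair_geometry(donor: Chromophore, acceptor: Chromophore) -> PairGeometry:
    """Full Förster geometry of one donor/acceptor pair."""
    if donor.dipole is None:
        raise DataError(f"chromophore {donor.id} has no dipole")
    if acceptor.dipole is None:
        raise DataError(f"chromophore {acceptor.id} has no dipole")
    r_vec = np.asarray(acceptor.centroid, dtype=float) - np.asarray(donor.centroid, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise DataError(f"coincident centroids: {donor.id} and {acceptor.id}")
    r_hat = r_vec / r
    mu_d = donor.dipole.direction
    mu_a = acceptor.dipole.direction
    cos_t = float(mu_d @ mu_a)
    cos_d = float(mu_d @ r_hat)
    cos_a = float(mu_a @ r_hat)
    kappa = cos_t - 3.0 * cos_d * cos_a
    mags = donor.dipole.magnitude * acceptor.dipole.magnitude
    return PairGeometry(
        donor_id=donor.id,
        acceptor_id=acceptor.id,
        r_vec=r_vec,
        r=r,
        cos_theta_T=cos_t,
        cos_theta_D=cos_d,
        cos_theta_A=cos_a,
        kappa_sq=kappa * kappa,
        v_rel=mags * kappa / r**3,
        weight=kappa * kappa / r**6,
    )


def all_pairs(chroms: list[Chromophore], cutoff: float = DEFAULT_CUTOFF) -> list[PairGeometry]:
    """Every unordered chromophore pair with r ≤ cutoff, once each.

    Donor/acceptor ordering within a pair is lexicographic by rendered ID;
    the list is sorted by descending weight (ties by donor then acceptor ID).
    """
    if cutoff <= 0:
        raise DataError("cutoff must be positive")
    pairs: list[PairGeometry] = []
    for a, b in itertools.combinations(chroms, 2):
        if str(a.id) > str(b.id):
            a, b = b, a
        r = float(np.linalg.norm(np.asarray(b.centroid) - np.asarray(a.centroid)))
        if r <= cutoff:
            pairs.append(pair_geometry(a, b))
    pairs.sort(key=lambda p: (-p.weight, str(p.donor_id), str(p.acceptor_id)))
    return pairs


def sample_unit_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` unit vectors uniform on S², via normalized 3D Gaussian draws."""
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def isotropic_kappa_mean(n: int, seed: int) -> float:
    """Monte-Carlo mean of κ² over ``n`` isotropic dipole-orientation pairs.

    The separation vector is held fixed (κ² does not depend on its length),
    both dipoles drawn independently and uniformly on the sphere. Converges
    to 2/3 as n → ∞ with standard error ∝ n^(−1/2); reproducible per seed.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu_d = sample_unit_sphere(n, rng)
    mu_a = sample_unit_sphere(n, rng)
    r_hat = np.array([0.0, 0.0, 1.0])
    cos_t = np.einsum("ij,ij->i", mu_d, mu_a)
    cos_d = mu_d @ r_hat
    cos_a = mu_a @ r_hat
    return float(np.mean((cos_t - 3.0 * cos_d * cos_a) ** 2))
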