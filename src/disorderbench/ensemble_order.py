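"""Per-residue structural order parameters from a conformer ensemble.

Two complementary order parameters are computed for every residue of a
multi-conformer (NMR-style) ensemble:

* **S** — from the circular concentration of the backbone dihedral angles
  phi/psi across conformers (the Hyberts-Wagner circular order parameter,
  averaged over a three-residue window and converted to a torsion-angle
  standard deviation);
* **T** — from the ensemble variance of CA-CA internal distances (the
  inter-atomic variance matrix), a superposition-free measure of
  coordinate variability.

Both map onto (0, 1], with 1 = rigid and values near 0 = disordered.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    DihedralSet,
    EnsembleStructure,
    OrderConfig,
    OrderParameterProfile,
    VarianceMatrix,
)
from .errors import DisorderBenchError, EnsembleTooSmallError

#: CA-CA distance (Å) above which consecutive residues are treated as a
#: chain break; standard trans-peptide CA-CA is ~3.8 Å.
CHAIN_BREAK_CUTOFF = 4.5


def _dihedral_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Signed dihedral a-b-c-d in degrees on (-180, 180], vectorized over
    leading axes."""
    b0 = a - b
    b1 = c - b
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = d - c
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 to keep the (-180, 180] convention
    return np.where(ang <= -180.0, ang + 360.0, ang)


def compute_dihedrals(ensemble: EnsembleStructure) -> DihedralSet:
    """Backbone phi/psi angles per residue and conformer.

    phi(i) = C'(i-1)-N(i)-CA(i)-C'(i); psi(i) = N(i)-CA(i)-C'(i)-N(i+1)
    (IUPAC convention, degrees).  phi of the first residue and psi of the
    last are undefined, as are angles spanning a chain break: a different
    chain id or a consecutive CA-CA distance above ``CHAIN_BREAK_CUTOFF``
    in *any* conformer.  Missing N or C atoms make the dependent angles
    undefined in all conformers (never an error).
    """
    K, L = ensemble.n_conformers, ensemble.n_residues
    xyz = ensemble.coords  # (K, L, 3, 3); atoms N, CA, C
    N, CA, C = xyz[:, :, 0], xyz[:, :, 1], xyz[:, :, 2]

    phi = np.full((L, K), np.nan)
    psi = np.full((L, K), np.nan)
    if L >= 2:
        # link[i] True <=> residues i, i+1 are consecutive in the same chain
        chains = [r[0] for r in ensemble.residues]
        same_chain = np.array([chains[i] == chains[i + 1] for i in range(L - 1)])
        ca_gap = np.linalg.norm(CA[:, 1:] - CA[:, :-1], axis=-1)  # (K, L-1)
        link = same_chain & (ca_gap <= CHAIN_BREAK_CUTOFF).all(axis=0)

        # phi_i for i >= 1, defined when link[i-1]
        ph = _dihedral_deg(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])  # (K, L-1)
        phi[1:, :] = np.where(link[:, None], ph.T, np.nan)
        # psi_i for i <= L-2, defined when link[i]
        ps = _dihedral_deg(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])  # (K, L-1)
        psi[:-1, :] = np.where(link[:, None], ps.T, np.nan)

    # an angle must be defined in all conformers or in none
    for arr in (phi, psi):
        partial = np.isnan(arr).any(axis=1)
        arr[partial, :] = np.nan
    return DihedralSet(ensemble.residue_numbers, phi, psi)


def shw(angles: np.ndarray) -> float:
    """Circular order parameter of one dihedral across an ensemble.

    ``(1/N) * sqrt((sum sin t_i)^2 + (sum cos t_i)^2)`` for angles in
    degrees; 1 when all angles coincide, 0 under symmetric dispersion.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0 or not np.isfinite(angles).all():
        raise DisorderBenchError("shw requires at least one defined angle")
    rad = np.radians(angles)
    return float(np.hypot(np.sin(rad).sum(), np.cos(rad).sum()) / angles.size)


def _shw_rows(angles: np.ndarray) -> np.ndarray:
    """Row-wise shw for an (L, K) angle array; NaN rows stay NaN."""
    rad = np.radians(angles)
    with np.errstate(invalid="ignore"):
        return np.hypot(
            np.sin(rad).sum(axis=1), np.cos(rad).sum(axis=1)
        ) / angles.shape[1]


def dihedral_order_profile(dihedrals: DihedralSet) -> np.ndarray:
    """Windowed dihedral order D_i per residue.

    D_i averages the circular order parameters of phi and psi over the
    three-residue window {i-1, i, i+1} (six terms when all are defined).
    Undefined terms (termini, chain breaks) are omitted and the divisor is
    the count of defined terms, keeping D_i in [0, 1]; a residue with no
    defined term has D_i = NaN.
    """
    L = dihedrals.n_residues
    if L < 3:
        raise DisorderBenchError("dihedral order profile needs at least 3 residues")
    s_phi = _shw_rows(dihedrals.phi)
    s_psi = _shw_rows(dihedrals.psi)
    terms = np.full((L, 6), np.nan)
    for off, col in zip((-1, 0, 1), (0, 2, 4)):
        lo, hi = max(0, -off), min(L, L - off)
        terms[lo:hi, col] = s_phi[lo + off:hi + off]
        terms[lo:hi, col + 1] = s_psi[lo + off:hi + off]
    n_def = np.isfinite(terms).sum(axis=1)
    with np.errstate(invalid="ignore"):
        D = np.nansum(terms, axis=1) / n_def
    D[n_def == 0] = np.nan
    return D


def angle_std(D: np.ndarray | float) -> np.ndarray | float:
    """Convert dihedral order D to a torsion-angle standard deviation (deg).

    ``s = 2 * arccos(1 + ln(D)/2)``, with the arccos argument clamped to
    [-1, 1] (the clamp engages only for D < e^-4, where s saturates at
    360°).  D must be strictly positive.
    """
    arr = np.asarray(D, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise DisorderBenchError("angle_std requires D > 0")
    with np.errstate(invalid="ignore"):
        s = 2.0 * np.degrees(np.arccos(np.clip(1.0 + np.log(arr) / 2.0, -1.0, 1.0)))
    return float(s) if np.isscalar(D) else s


def build_ivm(ensemble: EnsembleStructure) -> VarianceMatrix:
    """Inter-atomic variance matrix of CA-CA distances.

    ``v[i, j]`` is the population variance (divisor N) over conformers of
    the CA(i)-CA(j) distance; superposition-free, hence invariant under
    per-conformer rigid-body motion.
    """
    if ensemble.n_conformers < 2:
        raise EnsembleTooSmallError(
            "variance matrix needs at least 2 conformers"
        )
    if ensemble.n_residues < 4:
        raise DisorderBenchError("variance matrix needs at least 4 residues")
    ca = ensemble.ca_coords()  # (K, L, 3)
    d = np.linalg.norm(ca[:, :, None, :] - ca[:, None, :, :], axis=-1)  # (K, L, L)
    mean_d = d.mean(axis=0)
    v = ((d - mean_d) ** 2).mean(axis=0)
    return VarianceMatrix(ensemble.residue_numbers, v, mean_d)


def coord_variation(vm: VarianceMatrix, beta: float = 10.0) -> np.ndarray:
    """Per-residue coordinate variation t_i (Å) from the variance matrix.

    For each residue the row of variances is taken excluding the diagonal
    and nearest neighbours (|i-j| <= 1), sorted ascending into lambda_1 <
    ... < lambda_n, and averaged as ``t_i = sum_j w_j sqrt(lambda_j) /
    sum_j w_j`` with ``w_j = exp(-beta (j/n)^2)``.  The rank weighting
    emphasises the most invariant distances, so rigid cores score low even
    when remote parts of the molecule move.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    v = vm.v
    L = v.shape[0]
    t = np.full(L, np.nan)
    idx = np.arange(L)
    for i in range(L):
        keep = np.abs(idx - i) > 1
        lam = np.sort(v[i, keep])
        n = lam.size
        if n == 0:
            continue
        ranks = np.arange(1, n + 1)
        w = np.exp(-beta * (ranks / n) ** 2)
        t[i] = float(np.sum(w * np.sqrt(lam)) / np.sum(w))
    return t


def order_params(
    s: np.ndarray | float, t: np.ndarray | float, config: OrderConfig | None = None
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Lorentzian mapping of variations onto order parameters in (0, 1].

    ``S = 1/(1+(s/s0)^2)`` and ``T = 1/(1+(t/t0)^2)``; s0 = 75°, t0 = 1.5 Å
    by default, so S = T = 0.5 at the reference variation.
    """
    config = config or OrderConfig()
    s_arr, t_arr = np.asarray(s, dtype=float), np.asarray(t, dtype=float)
    if np.any(s_arr[np.isfinite(s_arr)] < 0) or np.any(t_arr[np.isfinite(t_arr)] < 0):
        raise DisorderBenchError("variations must be non-negative")
    S = 1.0 / (1.0 + (s_arr / config.s0) ** 2)
    T = 1.0 / (1.0 + (t_arr / config.t0) ** 2)
    if np.isscalar(s) and np.isscalar(t):
        return float(S), float(T)
    return S, T


def ensemble_order_profile(
    ensemble: EnsembleStructure, config: OrderConfig | None = None
) -> OrderParameterProfile:
    """Full per-residue order-parameter profile (D, s, S, t, T).

    Positions where a quantity cannot be computed (chain termini for the
    dihedral route) are NaN-flagged, never silently zero.
    """
    config = config or OrderConfig()
    if ensemble.n_conformers < 2:
        raise EnsembleTooSmallError("order profile needs at least 2 conformers")
    D = dihedral_order_profile(compute_dihedrals(ensemble))
    s = np.full_like(D, np.nan)
    ok = np.isfinite(D) & (D > 0)
    s[ok] = angle_std(D[ok])
    t = coord_variation(build_ivm(ensemble), beta=config.beta)
    S = np.full_like(D, np.nan)
    T = np.full_like(D, np.nan)
    S[np.isfinite(s)] = order_params(s[np.isfinite(s)], 0.0, config)[0]
    T[np.isfinite(t)] = order_params(0.0, t[np.isfinite(t)], config)[1]
    return OrderParameterProfile(
        entry_id=ensemble.entry_id,
        residue_numbers=ensemble.residue_numbers,
        residue_names=[r[2] for r in ensemble.residues],
        D=D,
        s=s,
        S=S,
        t=t,
        T=T,
    )
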