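"""Synthetic inputs with planted ground truth.

Every stage of the analysis can be exercised without downloads: the
generators emulate the statistical structure the analysis assumes —

* bimodal per-residue Z-score profiles over planted ordered/disordered
  segments (disordered Z ~ N(3, 2²), ordered Z ~ N(12, 2²) by default, so
  the two classes straddle the Z = 8 criterion with modest overlap);
* predictor probabilities with controllable bias b and discrimination d:
  p = b + d/2 + noise on disordered residues and b - d/2 + noise on
  ordered ones, making the expected bias metrics exactly pZA = b and
  pZD = d while clamping is inactive;
* conformer ensembles built on ideal poly-alanine backbone geometry with
  per-residue dihedral perturbation amplitudes (small in the core, large
  in disordered segments);
* X-ray missing-residue labels that reproduce the sparse-disorder regime
  of crystallographic data.

All generators are pure functions of their configuration: the same seed
reproduces the same output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    EnsembleStructure,
    MissingResidueLabels,
    DisorderPrediction,
    ZScoreProfile,
)

_AA20 = list("ACDEFGHIKLMNPQRSTVWY")

# ideal trans-peptide backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``segments`` (1-based, inclusive, state "D" or "O") takes priority over
    ``fraction_disordered`` (i.i.d. per-residue disorder).  Z mixture
    components default to 3.0 ± 2.0 (disordered) and 12.0 ± 2.0 (ordered).
    Predictor bias ``b`` and discrimination ``d`` are on the probability
    scale; ensemble perturbation amplitudes are dihedral-space standard
    deviations in degrees.
    """

    seed: int = 0
    length: int = 100
    segments: list[tuple[int, int, str]] | None = None
    fraction_disordered: float = 0.5
    z_mean_disordered: float = 3.0
    z_sd_disordered: float = 2.0
    z_mean_ordered: float = 12.0
    z_sd_ordered: float = 2.0
    bias: float = 0.5
    discrimination: float = 0.5
    noise_sd: float = 0.1
    n_conformers: int = 10
    core_amplitude: float = 3.0
    tail_amplitude: float = 60.0

    def __post_init__(self) -> None:
        if self.length < 5:
            raise ValueError("length must be at least 5")
        if not 0.0 <= self.fraction_disordered <= 1.0:
            raise ValueError("fraction_disordered must be in [0, 1]")
        if self.core_amplitude < 0 or self.tail_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.segments is not None:
            for lo, hi, state in self.segments:
                if not (1 <= lo <= hi <= self.length):
                    raise ValueError(f"segment ({lo}, {hi}) outside [1, {self.length}]")
                if state not in ("D", "O"):
                    raise ValueError("segment state must be 'D' or 'O'")


def _rng(config: GeneratorConfig, tag: int) -> np.random.Generator:
    # one independent stream per operation, all derived from the single seed
    return np.random.default_rng([config.seed, tag])


def _disorder_mask(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if config.segments is not None:
        mask = np.zeros(config.length, dtype=bool)
        for lo, hi, state in config.segments:
            mask[lo - 1:hi] = state == "D"
        return mask
    return rng.random(config.length) < config.fraction_disordered


def gen_zscores(config: GeneratorConfig) -> tuple[ZScoreProfile, np.ndarray]:
    """Bimodal Z-score profile plus the planted disorder mask.

    Each residue draws Z from the mixture component matching its planted
    state; the mask (True = disordered) is returned for recovery tests.
    """
    rng = _rng(config, 1)
    mask = _disorder_mask(config, rng)
    z = np.where(
        mask,
        rng.normal(config.z_mean_disordered, config.z_sd_disordered, config.length),
        rng.normal(config.z_mean_ordered, config.z_sd_ordered, config.length),
    )
    aas = [_AA20[i] for i in rng.integers(0, 20, config.length)]
    profile = ZScoreProfile(
        entry_id=f"synthetic-{config.seed}",
        residue_numbers=np.arange(1, config.length + 1),
        amino_acids=aas,
        z=z,
    )
    return profile, mask


def gen_predictions(
    z: ZScoreProfile,
    mask: np.ndarray,
    config: GeneratorConfig,
    method_name: str = "planted",
) -> DisorderPrediction:
    """Two-level predictor with planted bias b and discrimination d.

    p = clamp(b + d/2 + eps) on planted-disordered residues and
    clamp(b - d/2 + eps) on ordered ones, eps ~ N(0, noise_sd²).  While
    clamping is inactive the expected pZL is b + d/2 and pZH is b - d/2,
    so pZA recovers b and pZD recovers d.
    """
    b, d = config.bias, config.discrimination
    lo, hi = b - d / 2.0, b + d / 2.0
    if lo < -3 * config.noise_sd or hi > 1 + 3 * config.noise_sd:
        import warnings

        warnings.warn("b ± d/2 far outside [0, 1]: clamping will bias recovery")
    rng = _rng(config, 2)
    eps = rng.normal(0.0, config.noise_sd, len(z))
    p = np.clip(np.where(mask, hi, lo) + eps, 0.0, 1.0)
    return DisorderPrediction(
        method_name=method_name, residue_numbers=z.residue_numbers, p=p
    )


def gen_predictions_logistic(
    z: ZScoreProfile,
    config: GeneratorConfig,
    method_name: str = "logistic",
    midpoint: float = 8.0,
    width: float = 2.0,
) -> DisorderPrediction:
    """Logistic-in-Z predictor, a smoother alternative with realistic ROC
    shape (the two-level generator above is the recovery surface)."""
    rng = _rng(config, 3)
    p = 1.0 / (1.0 + np.exp((z.z - midpoint) / width))
    p = np.clip(p + rng.normal(0.0, config.noise_sd, len(z)), 0.0, 1.0)
    return DisorderPrediction(
        method_name=method_name, residue_numbers=z.residue_numbers, p=p
    )


# ---------------------------------------------------------------------------
# backbone construction


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom D so that |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = torsion (natural-extension reference frame)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone N/CA/C coordinates for a chain with the given dihedrals.

    ``phi[0]`` and ``psi[-1]`` are ignored (undefined at the termini);
    omega is fixed at 180° (trans).  Returns an (L, 3, 3) array with atom
    order N, CA, C.
    """
    L = len(phi)
    if len(psi) != L:
        raise ValueError("phi and psi must have equal length")
    xyz = np.zeros((L, 3, 3))
    theta = np.radians(ANGLE_N_CA_C)
    xyz[0, 0] = [0.0, 0.0, 0.0]
    xyz[0, 1] = [BOND_N_CA, 0.0, 0.0]
    xyz[0, 2] = xyz[0, 1] + BOND_CA_C * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    for i in range(1, L):
        n_prev, ca_prev, c_prev = xyz[i - 1]
        ni = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        cai = _place_atom(ca_prev, c_prev, ni, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        ci = _place_atom(c_prev, ni, cai, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        xyz[i] = [ni, cai, ci]
    return xyz


def gen_ensemble(
    config: GeneratorConfig,
) -> tuple[EnsembleStructure, np.ndarray]:
    """Poly-alanine conformer ensemble with planted per-residue disorder.

    A base backbone (extended polyproline-II-like, phi = -120°, psi =
    130°) is rebuilt for each conformer after perturbing every residue's
    phi/psi with Gaussian noise whose standard deviation is
    ``core_amplitude`` on ordered residues and ``tail_amplitude`` on
    disordered ones (degrees).  Returns the ensemble and the disorder
    mask.  When no explicit segmentation is given, the disordered
    residues are the trailing ``fraction_disordered`` of the chain (a
    disordered tail), which is the realistic geometry for an ensemble.
    """
    if config.n_conformers < 2:
        raise ValueError("an ensemble needs at least 2 conformers")
    L = config.length
    rng = _rng(config, 4)
    if config.segments is not None:
        mask = _disorder_mask(config, rng)
    else:
        n_dis = int(round(config.fraction_disordered * L))
        mask = np.zeros(L, dtype=bool)
        if n_dis:
            mask[L - n_dis:] = True
    amp = np.where(mask, config.tail_amplitude, config.core_amplitude)
    base_phi = np.full(L, -120.0)
    base_psi = np.full(L, 130.0)
    coords = np.empty((config.n_conformers, L, 3, 3))
    for k in range(config.n_conformers):
        phi = base_phi + rng.normal(0.0, 1.0, L) * amp
        psi = base_psi + rng.normal(0.0, 1.0, L) * amp
        coords[k] = build_backbone(phi, psi)
    residues = [("A", i + 1, "ALA") for i in range(L)]
    ensemble = EnsembleStructure(
        entry_id=f"synthetic-{config.seed}", residues=residues, coords=coords
    )
    return ensemble, mask


def gen_xray_labels(
    z: ZScoreProfile,
    mask: np.ndarray,
    missing_rate_given_disorder: float,
    seed: int,
) -> MissingResidueLabels:
    """X-ray missing-residue labels from the planted disorder mask.

    Disordered residues go missing with the stated rate; ordered residues
    are always observed.  With a low disordered fraction this reproduces
    the strong class imbalance of crystallographic disorder data.
    """
    if not 0.0 <= missing_rate_given_disorder <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng([seed, 5])
    missing = np.asarray(mask, dtype=bool) & (
        rng.random(len(z)) < missing_rate_given_disorder
    )
    from .io_formats import ONE_TO_THREE

    names = [ONE_TO_THREE.get(a, "UNK") for a in z.amino_acids]
    return MissingResidueLabels(
        entry_id=z.entry_id,
        residue_numbers=z.residue_numbers,
        residue_names=names,
        missing=missing,
    )
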