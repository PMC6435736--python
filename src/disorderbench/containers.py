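"""Core in-memory containers shared across the package.

The containers are thin, validated wrappers around numpy arrays.  Per-residue
quantities are stored in residue order; undefined values are NaN and carry an
explicit definedness semantics (NaN = undefined, never silently zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DisorderBenchError

#: amino-acid one-letter alphabet accepted in Z-score profiles
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: backbone atom order used in EnsembleStructure coordinate arrays
BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class EnsembleStructure:
    """A multi-conformer structure restricted to backbone N, CA, C atoms.

    Parameters
    ----------
    entry_id :
        Identifier of the entry (PDB id, file stem, or synthetic tag).
    residues :
        Ordered list of ``(chain_id, residue_number, residue_name)`` keys,
        identical across conformers.
    coords :
        Array of shape ``(n_conformers, n_residues, 3, 3)``: conformer,
        residue, atom (N, CA, C), xyz in Å.  Missing N or C atoms are NaN;
        every residue has a finite CA in every conformer.
    """

    entry_id: str
    residues: list[tuple[str, int, str]]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[2:] != (3, 3):
            raise ValueError(
                f"coords must have shape (N, L, 3, 3), got {self.coords.shape}"
            )
        if self.n_conformers < 1:
            raise ValueError("an ensemble needs at least one conformer")
        if self.coords.shape[1] != len(self.residues):
            raise ValueError("coords and residue list disagree on length")
        ca = self.coords[:, :, 1, :]
        if not np.isfinite(ca).all():
            raise ValueError("every residue must have a finite CA in every conformer")

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.array([r[1] for r in self.residues], dtype=int)

    def ca_coords(self) -> np.ndarray:
        """CA coordinates, shape ``(n_conformers, n_residues, 3)``."""
        return self.coords[:, :, 1, :]


@dataclass
class ZScoreProfile:
    """Per-residue continuous disorder ground truth (CheZOD-style Z-scores).

    High Z = ordered, low Z = disordered; Z < 8 is the conventional binary
    disorder criterion.
    """

    entry_id: str
    residue_numbers: np.ndarray
    amino_acids: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.z = np.asarray(self.z, dtype=float)
        if not (
            len(self.residue_numbers) == len(self.amino_acids) == len(self.z)
        ):
            raise ValueError("field lengths disagree")
        if len(self.z) == 0:
            raise DisorderBenchError(f"{self.entry_id}: empty Z-score profile")
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise DisorderBenchError(
                f"{self.entry_id}: residue numbers must be strictly increasing"
            )
        if not np.isfinite(self.z).all():
            raise DisorderBenchError(f"{self.entry_id}: non-finite Z-score")
        bad = sorted({a for a in self.amino_acids if a not in AA_ALPHABET})
        if bad:
            raise DisorderBenchError(
                f"{self.entry_id}: unknown amino-acid code(s) {bad}"
            )

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class DisorderPrediction:
    """Per-residue estimated probability of disorder for one method."""

    method_name: str
    residue_numbers: np.ndarray
    p: np.ndarray
    is_binary: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.residue_numbers) != len(self.p):
            raise ValueError("field lengths disagree")
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise DisorderBenchError(
                f"{self.method_name}: residue numbers must be strictly increasing"
            )
        if len(self.p) and (np.nanmin(self.p) < 0 or np.nanmax(self.p) > 1):
            raise DisorderBenchError(
                f"{self.method_name}: probability outside [0, 1]"
            )
        detected = bool(len(self.p)) and bool(np.isin(self.p, (0.0, 1.0)).all())
        if self.is_binary is None:
            self.is_binary = detected
        elif self.is_binary and not detected:
            raise DisorderBenchError(
                f"{self.method_name}: is_binary set but probabilities are not all 0/1"
            )

    def __len__(self) -> int:
        return len(self.p)


@dataclass
class MissingResidueLabels:
    """Observed/missing label for every residue of an X-ray SEQRES sequence.

    ``missing[i]`` is True when SEQRES residue ``residue_numbers[i]`` is
    listed in REMARK 465 or absent from the coordinate section.
    """

    entry_id: str
    residue_numbers: np.ndarray
    residue_names: list[str]
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (
            len(self.residue_numbers)
            == len(self.residue_names)
            == len(self.missing)
        ):
            raise ValueError("field lengths disagree")

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    @property
    def n_observed(self) -> int:
        return int((~self.missing).sum())

    def __len__(self) -> int:
        return len(self.missing)


@dataclass
class DihedralSet:
    """Backbone phi/psi angles per residue and conformer, degrees in (-180, 180].

    ``phi`` and ``psi`` have shape ``(n_residues, n_conformers)``; NaN marks
    an undefined angle (termini, chain breaks, missing atoms).  An angle is
    undefined either in every conformer or in none.
    """

    residue_numbers: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.phi.shape[0]

    @property
    def n_conformers(self) -> int:
        return self.phi.shape[1]


@dataclass
class VarianceMatrix:
    """Ensemble variance (and mean) of every CA(i)-CA(j) distance.

    ``v[i, j]`` is the population variance over conformers of the CA
    distance between residues i and j (Å²); ``mean_d`` is the companion
    mean-distance matrix (Å).  Symmetric, zero diagonal.
    """

    residue_numbers: np.ndarray
    v: np.ndarray
    mean_d: np.ndarray


@dataclass
class OrderConfig:
    """Reference scales for converting angle/coordinate variation to order.

    ``s0`` (degrees) and ``t0`` (Å) are the half-order reference points of
    the Lorentzian mapping S = 1/(1+(s/s0)²), T = 1/(1+(t/t0)²); ``beta``
    weights the rank-sorted variance elements in the coordinate variation.
    """

    s0: float = 75.0
    t0: float = 1.5
    beta: float = 10.0

    def __post_init__(self) -> None:
        if not (self.s0 > 0 and self.t0 > 0 and self.beta > 0):
            raise ValueError("s0, t0, beta must be strictly positive")


@dataclass
class OrderParameterProfile:
    """Per-residue structural order parameters from an ensemble.

    Arrays are aligned with ``residue_numbers``; NaN marks undefined
    positions.  ``D`` is the dihedral concentration in [0, 1], ``s`` its
    torsion standard-deviation equivalent in degrees, ``t`` the coordinate
    variation in Å, and ``S``/``T`` the (0, 1] order parameters.
    """

    entry_id: str
    residue_numbers: np.ndarray
    residue_names: list[str]
    D: np.ndarray
    s: np.ndarray
    S: np.ndarray
    t: np.ndarray
    T: np.ndarray

    @property
    def s_defined(self) -> np.ndarray:
        return np.isfinite(self.S)

    @property
    def t_defined(self) -> np.ndarray:
        return np.isfinite(self.T)

    def __len__(self) -> int:
        return len(self.residue_numbers)
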