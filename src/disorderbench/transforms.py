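"""Conversion of raw NMR-trained predictor outputs to disorder probabilities.

Two predictors trained on continuous NMR observables do not emit disorder
probabilities directly: s2D emits per-residue secondary-structure
populations, and DynaMine emits backbone order parameters S².  Both are
mapped here onto a pseudo-probability of disorder p in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DisorderBenchError

#: slack allowed on population sums / ranges (server outputs are low precision)
POPULATION_TOL = 1e-6


@dataclass
class SecondaryPopulations:
    """Per-residue populations of helix, sheet and coil, each in [0, 1]."""

    p_helix: np.ndarray
    p_sheet: np.ndarray
    p_coil: np.ndarray

    def __post_init__(self) -> None:
        self.p_helix = np.asarray(self.p_helix, dtype=float)
        self.p_sheet = np.asarray(self.p_sheet, dtype=float)
        self.p_coil = np.asarray(self.p_coil, dtype=float)
        for name, arr in (
            ("p_helix", self.p_helix),
            ("p_sheet", self.p_sheet),
            ("p_coil", self.p_coil),
        ):
            if np.any(arr < -POPULATION_TOL) or np.any(arr > 1 + POPULATION_TOL):
                raise DisorderBenchError(f"{name} outside [0, 1]")
        if np.any(self.p_helix + self.p_sheet > 1 + POPULATION_TOL):
            raise DisorderBenchError("p_helix + p_sheet exceeds 1")


@dataclass
class OrderParameterS2:
    """Per-residue backbone order parameter S² in [0, 1]."""

    s2: np.ndarray

    def __post_init__(self) -> None:
        self.s2 = np.asarray(self.s2, dtype=float)
        if np.any(self.s2 < 0) or np.any(self.s2 > 1):
            raise DisorderBenchError("S² outside [0, 1]")


def s2d_to_pdis(pops: SecondaryPopulations) -> np.ndarray:
    """Probability of disorder from secondary-structure populations.

    The summed helix + sheet population is read as a probability of order,
    so ``p = 1 - (p_helix + p_sheet)``, clamped to [0, 1] against rounding.
    """
    return np.clip(1.0 - (pops.p_helix + pops.p_sheet), 0.0, 1.0)


def dynamine_to_pdis(s2: OrderParameterS2) -> np.ndarray:
    """Probability of disorder from the order parameter S².

    The bijective transform ``p = sqrt(1 - S²)`` maps [0, 1] onto [0, 1];
    its inverse is S² = 1 - p².
    """
    return np.sqrt(1.0 - s2.s2)
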