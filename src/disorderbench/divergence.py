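"""Jensen-Shannon divergence between discrete Z-score distributions.

Used to ask how strongly a structural classification (order parameter
above/below its reference, or X-ray observed vs. missing) separates the
Z-score distribution: JSD = 0 when the two conditional distributions are
identical, log 2 when their supports are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BinningMismatchError, DisorderBenchError, EmptyClassError

#: default Z-score binning: unit-width bins on [-5, 20], outer bins open
DEFAULT_Z_EDGES = np.arange(-5.0, 21.0, 1.0)


@dataclass
class DiscreteDistribution:
    """Normalized masses over shared uniform bins (outer bins open)."""

    edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.masses) != len(self.edges) - 1:
            raise ValueError("need len(edges) = len(masses) + 1")
        if np.any(self.masses < 0) or abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("masses must be non-negative and sum to 1")

    def same_binning(self, other: "DiscreteDistribution") -> bool:
        return self.edges.shape == other.edges.shape and np.allclose(
            self.edges, other.edges
        )


def histogram_z(
    values: np.ndarray, edges: np.ndarray | None = None
) -> DiscreteDistribution:
    """Histogram Z values into a normalized discrete distribution.

    The outer bins are open: values beyond the edge range are counted in
    the first/last bin rather than dropped.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DisorderBenchError("cannot histogram an empty sample")
    edges = DEFAULT_Z_EDGES if edges is None else np.asarray(edges, dtype=float)
    clipped = np.clip(values, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return DiscreteDistribution(edges, counts / counts.sum())


def kl(
    P: DiscreteDistribution, M: DiscreteDistribution, base: float | None = None
) -> float:
    """Kullback-Leibler divergence D(P||M) = sum P_i log(P_i/M_i).

    Natural log by default (``base=2`` for bits); terms with P_i = 0
    contribute 0.  M must dominate P (M_i > 0 wherever P_i > 0), which the
    Jensen-Shannon mixture guarantees.
    """
    if not P.same_binning(M):
        raise BinningMismatchError("distributions use different bin edges")
    p, m = P.masses, M.masses
    support = p > 0
    if np.any(m[support] <= 0):
        raise DisorderBenchError("M must be positive on the support of P")
    val = float(np.sum(p[support] * np.log(p[support] / m[support])))
    return val / np.log(base) if base is not None else val


def jsd(
    P: DiscreteDistribution, Q: DiscreteDistribution, base: float | None = None
) -> float:
    """Jensen-Shannon divergence: symmetric, bounded by log 2.

    ``JSD(P, Q) = D(P||M)/2 + D(Q||M)/2`` with the mixture M = (P+Q)/2.
    """
    if not P.same_binning(Q):
        raise BinningMismatchError("distributions use different bin edges")
    M = DiscreteDistribution(P.edges, (P.masses + Q.masses) / 2.0)
    return 0.5 * kl(P, M, base) + 0.5 * kl(Q, M, base)


def jsd_by_classification(
    z_values: np.ndarray,
    labels: np.ndarray,
    edges: np.ndarray | None = None,
    base: float | None = None,
) -> float:
    """JSD between the Z distributions of the two sides of a binary split.

    ``labels`` is a boolean array aligned with ``z_values`` (e.g. order
    parameter below its reference, or residue missing in the X-ray
    structure).  Both classes must be nonempty.
    """
    z_values = np.asarray(z_values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if z_values.shape != labels.shape:
        raise ValueError("z_values and labels must be aligned")
    if not labels.any():
        raise EmptyClassError("no residues in the positive class")
    if labels.all():
        raise EmptyClassError("no residues in the negative class")
    edges = DEFAULT_Z_EDGES if edges is None else np.asarray(edges, dtype=float)
    P = histogram_z(z_values[labels], edges)
    Q = histogram_z(z_values[~labels], edges)
    return jsd(P, Q, base)
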