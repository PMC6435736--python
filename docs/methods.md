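# Methods

## Ensemble order parameters

The dihedral route measures local conformational heterogeneity as the
circular concentration of backbone φ/ψ angles across conformers. The
per-angle statistic S_HW is the mean resultant length of the angles on the
unit circle: 1 when all conformers agree, 0 under symmetric dispersion.
The per-residue parameter D_i averages the φ and ψ statistics over the
three-residue window {i−1, i, i+1}; the nominal divisor is six (all window
terms defined). At chain termini and across chain breaks some terms are
undefined; we divide by the count of defined terms so that D_i remains a
mean of values in [0, 1], and flag a residue with no defined term as
undefined rather than reporting a value. D converts to an equivalent
torsion standard deviation s = 2·arccos(1 + ln D / 2) (degrees). For
D < e⁻⁴ the arccos argument falls below −1; we clamp to [−1, 1], a
continuous saturation at s = 360°.

The coordinate route is superposition-free: the inter-atomic variance
matrix holds the population variance (divisor N, not N−1) of every
Cα–Cα distance over the N conformers, which is invariant under
per-conformer rigid-body motion by construction. For residue i the row of
variances — excluding the diagonal and the |i−j| = 1 neighbours, whose
distances are fixed by covalent geometry — is sorted ascending and the
square roots averaged with rank weights w_j = exp(−β (j/n)²), β = 10.
The weighting emphasises the *most invariant* distances, so a rigid core
residue scores low even when a distant tail flaps. We take n as the
per-row count of retained elements: for interior residues this equals the
chain length minus three; edge rows retain one element more, and using the
per-row count keeps the weights well-defined for every row.

Both variations map onto order parameters through the Lorentzian
S = 1/(1+(s/s₀)²), T = 1/(1+(t/t₀)²) with s₀ = 75° and t₀ = 1.5 Å as the
half-order reference points (s in degrees — the reference value only makes
sense on the degree scale). S and T lie in (0, 1], are strictly decreasing
in their variation, and are NaN-flagged (never silently zero) where
undefined.

Dihedrals follow the IUPAC convention, degrees in (−180, 180]. A chain
break is declared when consecutive Cα atoms are further apart than 4.5 Å
in any conformer (trans-peptide Cα–Cα is ~3.8 Å); the spanning φ/ψ are
then undefined in all conformers, so each angle is defined either in every
conformer or in none.

## Benchmark metrics

Residues are matched between a Z-score profile and a prediction on residue
number alone; residues present in only one profile are excluded from all
metrics, and metrics are computed over all residues pooled across proteins
(a per-protein mode exists for diagnostics). Binarization uses the strict
inequality Z < 8 for disorder; a residue with Z exactly 8 is ordered for
classification and excluded from both conditional means of the bias
decomposition (which is defined by Z < 8 and Z > 8).

The ROC curve is built over unique probability cutoffs with ties grouped,
and the trapezoidal area then coincides exactly with the tie-corrected
Mann–Whitney statistic (the test suite checks this identity against
exhaustive pair enumeration and scikit-learn). MCC uses the zero-marginal
convention (0 when any row or column of the confusion table is empty),
which keeps ranking total; FPR/FNR are NaN when their denominator is
empty. Binary predictors get R_P, confusion and bias metrics but no
Spearman or AUC (reported as n.a.), since rank-based statistics are not
meaningful on two-valued output.

The optimal Z threshold is the grid argmax of the *mean MCC across
methods*, each method at its configured probability cutoff; MCC is chosen
as the objective because it is the balanced confusion summary used
throughout. Ties break toward 8.0, then toward the smaller threshold.
Ranking sorts by |R_P| descending (ties: AUC, then name).

## Jensen–Shannon divergence

Z-score distributions conditioned on a binary structural classification
(S or T above/below 0.5, i.e. variation above/below its reference value;
or X-ray observed vs. missing) are discretized on shared unit-width bins
over [−5, 20] with open outer bins — wide enough to resolve the bimodal
Z structure without empty-bin noise — and compared with
JSD = ½D(P‖M) + ½D(Q‖M), M = (P+Q)/2. Natural log is the default (bound
ln 2); base 2 is exposed. No pseudo-counts are needed because the mixture
M is positive on the union support. A documented inconsistency in the
source description of the reference values (units swapped between the
order-parameter definition and the JSD classification) is resolved in
favour of the order-parameter pairing: s₀ = 75° for the angular variation,
t₀ = 1.5 Å for the coordinate variation.

## Synthetic data: what it emulates, and what not

`gen_zscores` draws per-residue Z from a two-component normal mixture,
disordered 3.0 ± 2.0 and ordered 12.0 ± 2.0 by default: the classes
straddle Z = 8 with modest overlap, reproducing the four-quadrant
structure seen when predictions are plotted against real Z-scores. The
exact component parameters are a modelling choice; real Z distributions
are heavier-tailed and protein-dependent.

`gen_predictions` is deliberately a *two-level additive-noise* model:
p = b + d/2 + ε on planted-disordered residues, b − d/2 + ε on ordered
ones (ε ~ N(0, σ²), clamped to [0, 1]). This makes the planted bias b and
discrimination d analytically exact targets for the bias decomposition
(E[pZA] = b, E[pZD] = d while clamping is inactive), which is what the
recovery tests need. It does not mimic any real predictor's error profile;
a logistic-in-Z variant is provided for more realistic ROC shapes. Two
effects attenuate recovery: clamping when b ± d/2 approaches 0 or 1, and
the Z-mixture overlap (a few planted-disordered residues land above Z = 8
and vice versa), which shrinks measured pZD by roughly the overlap
fraction. Recovery measurements therefore use noise σ = 0.05 and operating
points with b ± d/2 ∈ [0.05, 0.95]; the generator default σ = 0.1
represents a noisier, more realistic predictor.

`gen_ensemble` builds ideal trans poly-alanine backbones (N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å; angles 111.2°/116.2°/121.7°; ω = 180°) around
a polyproline-II-like base conformation (φ = −120°, ψ = 130°, chosen to
avoid self-collapse of long perturbed chains), then perturbs each
residue's φ/ψ per conformer with Gaussian amplitude 3° in the core and
60° in planted-disordered segments. This plants a clean
order/disorder contrast in both the dihedral and the coordinate route; it
is not physically realistic conformational sampling (no excluded volume,
no side chains, no correlated motions). Passing tests therefore
demonstrate that the order parameters recover *planted* variation
contrasts, not that they reproduce any particular experimental ensemble.

`gen_xray_labels` flags planted-disordered residues as missing with a
configurable rate and never flags ordered ones, reproducing the strong
class imbalance of crystallographic disorder data (a few percent missing).

All generators derive every draw from a single seed through independent
named streams; identical configuration gives bit-identical output.

## Problem sizes and numerical choices

Recovery tests use cohorts of 5 proteins × 200–1000 residues and
single-profile sizes of 2000–5000 residues with 10 seeds per measurement —
large enough that binomial noise sits well inside the stated recovery
bands, small enough that the full suite runs in seconds. Order-parameter
exactness is checked on 6-residue, 4-conformer ensembles against
brute-force evaluation at 1e−9; correlation/AUC implementations are
checked against textbook formulas and exhaustive pair counts at 1e−12.
Undefined metric values are propagated as None/n.a. (TSV) and null
(JSON); NaN never reaches a report. Altloc 'A' (or blank) is kept when
parsing PDB files, other altlocs ignored; insertion codes are rejected
outright rather than silently mishandled.

## Known limitations

- Z-scores are consumed (or simulated), never computed from chemical
  shifts; predictor web services are not queried.
- The variance-matrix route uses all Cα pairs as written in its
  definition; distance-cutoff variants used by some core-finding
  algorithms are not implemented.
- Only single-chain, protein-only, insertion-code-free PDB inputs are
  supported; mmCIF is out of scope.
- No bootstrap confidence intervals or significance tests on metric
  differences.
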