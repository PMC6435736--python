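"""Readers and writers for all external representations.

Handled formats:

* multi-model PDB ensembles (MODEL/ENDMDL; backbone N, CA, C atoms);
* X-ray missing-residue labels (SEQRES + REMARK 465 + coordinate section);
* plain-text Z-score tables (columns: 1-letter code, residue number, Z);
* plain-text predictor tables (residue number + value column(s), raw s2D
  populations or DynaMine S² converted via :mod:`disorderbench.transforms`);
* the benchmark report (TSV for reading, JSON twin for machines).

PDB coordinate parsing is backed by gemmi; REMARK 465 is read from the raw
remark lines (fixed-width record).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import gemmi
import numpy as np

from .containers import (
    BACKBONE_ATOMS,
    DisorderPrediction,
    EnsembleStructure,
    MissingResidueLabels,
    ZScoreProfile,
)
from .errors import DisorderBenchError, FormatError, InconsistencyError
from .metrics import BenchmarkResult, BiasMetrics, ConfusionCounts

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


# ---------------------------------------------------------------------------
# PDB ensembles


def _read_pdb_tolerant(path: Path) -> gemmi.Structure:
    """Parse PDB text, tolerating MODEL blocks not closed by ENDMDL."""
    text = Path(path).read_text()
    lines = text.splitlines()
    fixed: list[str] = []
    open_model = False
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            if open_model:
                fixed.append("ENDMDL")
            open_model = True
        elif rec == "ENDMDL":
            open_model = False
        elif rec == "END" and open_model:
            fixed.append("ENDMDL")
            open_model = False
        fixed.append(line)
    if open_model:
        fixed.append("ENDMDL")
    return gemmi.read_pdb_string("\n".join(fixed) + "\n")


def read_pdb_ensemble(path: str | Path, chain: str | None = None) -> EnsembleStructure:
    """Read a multi-model PDB file into an :class:`EnsembleStructure`.

    Models are split on MODEL/ENDMDL (a file without MODEL records is a
    single-conformer ensemble).  Only backbone N, CA, C atoms of the
    requested chain (default: first chain) are kept; altloc ' '/'A' wins,
    others are ignored.  Residues lacking a CA in any conformer are
    dropped from all conformers; insertion codes are rejected.
    """
    path = Path(path)
    st = _read_pdb_tolerant(path)
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    per_model: list[dict[tuple[str, int, str], dict[str, np.ndarray]]] = []
    orders: list[list[tuple[str, int, str]]] = []
    for model in st:
        chains = [ch.name for ch in model]
        if not chains:
            raise FormatError(f"{path}: model {model.num} has no chains")
        want = chain if chain is not None else chains[0]
        if want not in chains:
            raise FormatError(f"{path}: chain {want!r} not present")
        resmap: dict[tuple[str, int, str], dict[str, np.ndarray]] = {}
        order: list[tuple[str, int, str]] = []
        for res in model[want]:
            if res.seqid.icode not in (" ", "\x00", ""):
                raise FormatError(
                    f"{path}: insertion code at residue {res.seqid.num} not supported"
                )
            key = (want, res.seqid.num, res.name)
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.name in BACKBONE_ATOMS and atom.altloc in ("\x00", "A", " "):
                    atoms.setdefault(
                        atom.name, np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    )
            if atoms:
                resmap[key] = atoms
                order.append(key)
        per_model.append(resmap)
        orders.append(order)

    keys = orders[0]
    if any(set(o) != set(keys) for o in orders[1:]):
        diffs = sorted(
            set().union(*[set(o) for o in orders]) - set.intersection(*[set(o) for o in orders])
        )
        raise InconsistencyError(
            f"{path}: conformers disagree on residues {diffs}"
        )
    kept = [
        k for k in keys if all("CA" in m[k] for m in per_model)
    ]
    if not kept:
        raise FormatError(f"{path}: no CA atoms found in chain")
    coords = np.full((len(per_model), len(kept), 3, 3), np.nan)
    for mi, resmap in enumerate(per_model):
        for ri, key in enumerate(kept):
            for ai, aname in enumerate(BACKBONE_ATOMS):
                if aname in resmap[key]:
                    coords[mi, ri, ai] = resmap[key][aname]
    return EnsembleStructure(entry_id=path.stem, residues=kept, coords=coords)


def write_pdb_ensemble(ensemble: EnsembleStructure, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB text file."""
    lines: list[str] = []
    for k in range(ensemble.n_conformers):
        lines.append(f"MODEL     {k + 1:4d}")
        serial = 1
        for ri, (chain_id, resnum, resname) in enumerate(ensemble.residues):
            for ai, aname in enumerate(BACKBONE_ATOMS):
                x, y, z = ensemble.coords[k, ri, ai]
                if not np.isfinite((x, y, z)).all():
                    continue
                element = aname[0]
                lines.append(
                    f"ATOM  {serial:5d} {aname:^4s} {resname:>3s} {chain_id}"
                    f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# missing residues


def _parse_remark_465(raw_remarks: list[str]) -> set[int]:
    """Residue numbers listed in REMARK 465 (the missing-residue record)."""
    missing: set[int] = set()
    for line in raw_remarks:
        if not line.startswith("REMARK 465"):
            continue
        fields = line.split()
        # data lines end in: [model] RES CHAIN SSSEQ; skip the column header
        if len(fields) >= 4 and fields[-1] != "SSSEQI":
            try:
                missing.add(int(fields[-1]))
            except ValueError:
                continue
    return missing


def read_missing_residues(path: str | Path) -> MissingResidueLabels:
    """Observed/missing labels for every SEQRES residue of an X-ray entry.

    A residue is labelled missing when it appears in REMARK 465 or is in
    SEQRES but absent from the coordinate section.  The file must carry
    SEQRES records.
    """
    path = Path(path)
    st = _read_pdb_tolerant(path)
    seqres: list[str] = []
    for ent in st.entities:
        if ent.full_sequence:
            seqres = [gemmi.Entity.first_mon(m) for m in ent.full_sequence]
            break
    if not seqres:
        raise FormatError(f"{path}: SEQRES records required but absent")
    remark_missing = _parse_remark_465(st.raw_remarks)
    observed: set[int] = set()
    if len(st) > 0:
        for ch in st[0]:
            for res in ch:
                observed.add(res.seqid.num)
    known = observed | remark_missing
    if not known:
        raise FormatError(f"{path}: no residues in coordinates or REMARK 465")
    # SEQRES gives no numbering; assume it spans a contiguous range that
    # starts at the first known residue number (gaps inside it are residues
    # unobserved without a REMARK 465 entry).
    start = min(known)
    numbers = list(range(start, start + len(seqres)))
    stray = known - set(numbers)
    if stray:
        raise FormatError(
            f"{path}: residues {sorted(stray)} fall outside the SEQRES range "
            f"{numbers[0]}..{numbers[-1]}"
        )
    missing = np.array(
        [n in remark_missing or n not in observed for n in numbers], dtype=bool
    )
    return MissingResidueLabels(
        entry_id=path.stem,
        residue_numbers=np.array(numbers, dtype=int),
        residue_names=seqres,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# Z-score tables


def read_zscores(path: str | Path) -> ZScoreProfile:
    """Read a whitespace-separated Z-score table.

    Lines hold ``<1-letter code> <residue number> <Z>``; ``#`` comment
    lines and blank lines are ignored.
    """
    path = Path(path)
    aas: list[str] = []
    numbers: list[int] = []
    zs: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        aa, num_s, z_s = fields[:3]
        try:
            num = int(num_s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad residue number {num_s!r}") from exc
        try:
            z = float(z_s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad Z-score {z_s!r}") from exc
        if not math.isfinite(z):
            raise FormatError(f"{path}:{lineno}: non-finite Z-score")
        if numbers and num <= numbers[-1]:
            raise FormatError(
                f"{path}:{lineno}: residue numbers must be strictly increasing"
            )
        aas.append(aa)
        numbers.append(num)
        zs.append(z)
    if not numbers:
        raise FormatError(f"{path}: empty Z-score table")
    return ZScoreProfile(path.stem, np.array(numbers), aas, np.array(zs))


def write_zscores(profile: ZScoreProfile, path: str | Path) -> None:
    """Write a Z-score profile in the table layout read_zscores expects."""
    lines = [
        f"{aa} {num} {float(z)!r}"
        for aa, num, z in zip(
            profile.amino_acids, profile.residue_numbers, profile.z
        )
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# prediction tables


def read_predictions(
    path: str | Path, method_name: str, kind: str = "probability"
) -> DisorderPrediction:
    """Read a predictor output table.

    ``kind`` declares the column semantics: ``probability`` (residue
    number, p), ``s2d`` (residue number, p_helix, p_sheet[, p_coil]) or
    ``dynamine`` (residue number, S²); raw columns are converted to
    probabilities of disorder before the profile is built.  Missing
    residues are allowed (sparse predictions).
    """
    from . import transforms

    path = Path(path)
    numbers: list[int] = []
    rows: list[list[float]] = []
    n_cols = {"probability": 1, "s2d": 2, "dynamine": 1}
    if kind not in n_cols:
        raise ValueError(f"unknown prediction kind {kind!r}")
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 1 + n_cols[kind]:
            raise FormatError(
                f"{path}:{lineno}: expected at least {1 + n_cols[kind]} columns"
            )
        try:
            num = int(fields[0])
            vals = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable value") from exc
        if numbers and num <= numbers[-1]:
            raise FormatError(
                f"{path}:{lineno}: residue numbers must be strictly increasing"
            )
        numbers.append(num)
        rows.append(vals)
    if not numbers:
        raise FormatError(f"{path}: empty prediction table")
    arr = np.array([r[: max(len(r) for r in rows)] for r in rows], dtype=float)
    if kind == "probability":
        p = arr[:, 0]
        if np.any(p < 0) or np.any(p > 1):
            raise DisorderBenchError(f"{path}: probability outside [0, 1]")
    elif kind == "s2d":
        coil = arr[:, 2] if arr.shape[1] > 2 else 1.0 - arr[:, 0] - arr[:, 1]
        pops = transforms.SecondaryPopulations(arr[:, 0], arr[:, 1], coil)
        p = transforms.s2d_to_pdis(pops)
    else:  # dynamine
        p = transforms.dynamine_to_pdis(transforms.OrderParameterS2(arr[:, 0]))
    return DisorderPrediction(method_name, np.array(numbers), p)


def write_predictions(pred: DisorderPrediction, path: str | Path) -> None:
    """Write a probability table in the layout read_predictions expects."""
    lines = [
        f"{num} {float(p)!r}" for num, p in zip(pred.residue_numbers, pred.p)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# benchmark reports

REPORT_COLUMNS = [
    "Method", "R_P", "R_S", "AUC", "MCC",
    "pZL", "pZH", "pZA", "pZD", "TP", "FP", "TN", "FN",
]


def _fmt(value: float | None, digits: int = 3) -> str:
    return "n.a." if value is None else f"{value:.{digits}f}"


def _result_row(r: BenchmarkResult) -> dict:
    bias = r.bias
    return {
        "Method": r.method_name,
        "R_P": r.r_p,
        "R_S": r.r_s,
        "AUC": r.auc,
        "MCC": r.mcc,
        "pZL": None if bias is None else bias.pZL,
        "pZH": None if bias is None else bias.pZH,
        "pZA": None if bias is None else bias.pZA,
        "pZD": None if bias is None else bias.pZD,
        "TP": r.confusion.tp,
        "FP": r.confusion.fp,
        "TN": r.confusion.tn,
        "FN": r.confusion.fn,
        "n": r.n,
        "is_binary": r.is_binary,
        "FPR": r.fpr,
        "FNR": r.fnr,
    }


def write_benchmark_report(
    results: list[BenchmarkResult], path: str | Path
) -> None:
    """Write the per-method metric table as TSV plus a JSON twin.

    The TSV rounds metrics to 3 decimals and writes ``n.a.`` for fields
    that do not apply (Spearman and AUC of binary methods); the JSON file
    (same stem, ``.json`` suffix) keeps full precision with ``null`` for
    undefined fields.
    """
    if not results:
        raise ValueError("need at least one result")
    path = Path(path)
    rows = [_result_row(r) for r in results]
    lines = ["\t".join(REPORT_COLUMNS)]
    for row in rows:
        cells = [str(row["Method"])]
        for col in REPORT_COLUMNS[1:]:
            val = row[col]
            if col in ("TP", "FP", "TN", "FN"):
                cells.append(str(val))
            else:
                nan = isinstance(val, float) and math.isnan(val)
                cells.append(_fmt(None if nan else val))
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    json_rows = [
        {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in row.items()}
        for row in rows
    ]
    path.with_suffix(".json").write_text(json.dumps(json_rows, indent=1) + "\n")


def read_benchmark_report(json_path: str | Path) -> list[BenchmarkResult]:
    """Re-read the JSON twin of a benchmark report."""
    rows = json.loads(Path(json_path).read_text())
    results = []
    for row in rows:
        bias = None
        if row["pZL"] is not None:
            bias = BiasMetrics(
                row["pZL"], row["pZH"], row["pZA"], row["pZD"], nL=-1, nH=-1
            )
        results.append(
            BenchmarkResult(
                method_name=row["Method"],
                n=row["n"],
                r_p=row["R_P"],
                r_s=row["R_S"],
                auc=row["AUC"],
                confusion=ConfusionCounts(row["TP"], row["FP"], row["TN"], row["FN"]),
                mcc=row["MCC"],
                fpr=float("nan") if row["FPR"] is None else row["FPR"],
                fnr=float("nan") if row["FNR"] is None else row["FNR"],
                bias=bias,
                is_binary=row["is_binary"],
            )
        )
    return results
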