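"""Readers and writers for all external formats consumed by the pipeline.

Downstream modules operate only on the domain containers defined here:
:class:`ShiftTable` (per-residue backbone chemical shifts and intensities),
:class:`TitrationSeries` (ligand concentration vs. observable, replicated),
:class:`MeltingCurve` (nanoDSF two-channel fluorescence vs. temperature),
:class:`RelaxationSeries` (delay/intensity decays), RDC coupling tables, and
:class:`DomainRecord` (sequence plus domain architecture).

Shift tables are read either from a plain TSV dialect
(``residue aa dH dN dCa dCb intensity``, empty field = missing) or from the
atom-chemical-shift loop of an NMR-STAR file (the subset needed to populate
per-residue backbone shifts; full STAR semantics are out of scope).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "SpxlabError",
    "ValidationError",
    "ParseError",
    "InsufficientDataError",
    "ShiftRecord",
    "ShiftTable",
    "TitrationSeries",
    "MeltingCurve",
    "RelaxationSeries",
    "DomainRecord",
    "read_shift_table",
    "write_shift_table",
    "read_titration_csv",
    "write_titration_csv",
    "read_melting_csv",
    "write_melting_csv",
    "read_relaxation_csv",
    "write_relaxation_csv",
    "read_rdc_csv",
    "write_rdc_csv",
    "read_structure_nh_vectors",
    "read_fasta",
    "write_fasta",
    "read_domain_table",
    "write_domain_table",
]

AA1 = set("ACDEFGHIKLMNPQRSTVWY")

SHIFT_TSV_COLUMNS = ["residue", "aa", "dH", "dN", "dCa", "dCb", "intensity"]


class SpxlabError(Exception):
    """Base class for all package errors."""


class ValidationError(SpxlabError):
    """Input violates a documented invariant."""


class ParseError(SpxlabError):
    """A file could not be parsed under the requested dialect."""


class InsufficientDataError(SpxlabError):
    """Fewer data points than the operation requires."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftRecord:
    """Backbone chemical shifts for one residue of one sample state.

    Residue indices are 1-based in the numbering of the construct. Missing
    assignments are ``None`` — never zero-filled.
    """

    residue_index: int
    aa: str
    dH: float | None = None
    dN: float | None = None
    dCa: float | None = None
    dCb: float | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValidationError(f"residue_index must be >= 1, got {self.residue_index}")
        if self.aa not in AA1:
            raise ValidationError(f"unknown amino-acid letter {self.aa!r}")
        if self.aa == "G" and self.dCb is not None:
            raise ValidationError(
                f"glycine (residue {self.residue_index}) cannot carry a Cb shift"
            )
        for name in ("dH", "dN", "dCa", "dCb", "intensity"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValidationError(
                    f"non-finite {name} at residue {self.residue_index}"
                )


@dataclass(frozen=True)
class ShiftTable:
    """Chemical-shift table for one sample state.

    ``isotope_scheme`` records whether the sample was perdeuterated
    (2H isotope corrections then apply to Ca/Cb secondary shifts) or
    protonated.
    """

    entries: tuple[ShiftRecord, ...]
    sample_label: str = ""
    isotope_scheme: str = "protonated"

    def __post_init__(self) -> None:
        if self.isotope_scheme not in ("protonated", "perdeuterated"):
            raise ValidationError(f"unknown isotope_scheme {self.isotope_scheme!r}")
        idx = [r.residue_index for r in self.entries]
        if len(set(idx)) != len(idx):
            dup = sorted({i for i in idx if idx.count(i) > 1})
            raise ValidationError(f"duplicate residue indices {dup}")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_residue(self) -> dict[int, ShiftRecord]:
        return {r.residue_index: r for r in self.entries}

    @classmethod
    def from_records(
        cls,
        records: Iterable[ShiftRecord],
        sample_label: str = "",
        isotope_scheme: str = "protonated",
    ) -> "ShiftTable":
        recs = tuple(sorted(records, key=lambda r: r.residue_index))
        return cls(recs, sample_label=sample_label, isotope_scheme=isotope_scheme)


@dataclass(frozen=True)
class TitrationSeries:
    """Replicated titration: total ligand concentration vs. an observable.

    ``concentrations`` is the sorted unique concentration grid (µM);
    ``observable`` has shape (n_concentrations, n_replicates). Missing
    replicate points are NaN.
    """

    concentrations: np.ndarray
    observable: np.ndarray
    replicate_ids: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.ndim != 1 or np.unique(c).size != c.size or np.any(np.diff(c) <= 0):
            raise ValidationError("concentrations must be strictly ascending and unique")
        if np.any(c < 0):
            raise ValidationError("negative ligand concentration")
        if np.unique(c).size < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct concentrations, got {c.size}"
            )
        obs = np.asarray(self.observable, dtype=float)
        if obs.shape != (c.size, len(self.replicate_ids)):
            raise ValidationError(
                f"observable shape {obs.shape} does not match "
                f"({c.size}, {len(self.replicate_ids)})"
            )

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All (concentration, observable) pairs with NaNs dropped."""
        L = np.repeat(self.concentrations, self.n_replicates)
        y = np.asarray(self.observable, dtype=float).ravel()
        ok = np.isfinite(y)
        return L[ok], y[ok]


@dataclass(frozen=True)
class MeltingCurve:
    """nanoDSF melting curve: temperature grid with F330/F350 channels."""

    temperature: np.ndarray
    f330: np.ndarray
    f350: np.ndarray
    capillary_id: str = ""
    heating_rate_c_per_min: float = 1.0  # carried metadata; never alters Tm

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        if t.size < 20:
            raise ValidationError(f"need >= 20 temperature points, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("temperature grid must be strictly ascending")
        if t.min() < 15 - 1e-9 or t.max() > 95 + 1e-9:
            raise ValidationError("temperatures must lie within 15-95 degC")
        f330 = np.asarray(self.f330, dtype=float)
        f350 = np.asarray(self.f350, dtype=float)
        if f330.shape != t.shape or f350.shape != t.shape:
            raise ValidationError("channel arrays must match the temperature grid")
        if np.any(f330 <= 0):
            raise ValidationError("F330 must be positive")

    @property
    def ratio(self) -> np.ndarray:
        return np.asarray(self.f350, float) / np.asarray(self.f330, float)


@dataclass(frozen=True)
class RelaxationSeries:
    """Intensity decay of one residue over relaxation delays (seconds)."""

    residue_index: int
    delays: np.ndarray
    intensities: np.ndarray
    experiment: str = "T2"

    def __post_init__(self) -> None:
        if self.experiment not in ("T1", "T2"):
            raise ValidationError(f"experiment must be T1 or T2, got {self.experiment!r}")
        d = np.asarray(self.delays, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if d.shape != i.shape:
            raise ValidationError("delays and intensities must have equal length")
        if np.unique(d).size < 4:
            raise ValidationError("need >= 4 distinct relaxation delays")
        if np.any(d < 0):
            raise ValidationError("delays must be >= 0 seconds")
        if not np.all(np.isfinite(i)):
            raise ValidationError("intensities must be finite")


@dataclass(frozen=True)
class DomainRecord:
    """Protein sequence with its ordered, non-overlapping domain annotation."""

    protein_id: str
    sequence: str
    domains: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        prev_end = 0
        for name, start, end in self.domains:
            if not (1 <= start <= end <= n):
                raise ValidationError(
                    f"{self.protein_id}: domain {name} [{start},{end}] outside 1..{n}"
                )
            if start <= prev_end:
                raise ValidationError(
                    f"{self.protein_id}: domains overlap or are unsorted at {name}"
                )
            prev_end = end


# ---------------------------------------------------------------------------
# Shift tables (TSV + NMR-STAR subset)
# ---------------------------------------------------------------------------


def _parse_opt_float(tok: str, path: str, lineno: int, col: str) -> float | None:
    tok = tok.strip()
    if tok == "" or tok == ".":
        return None
    try:
        return float(tok)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad {col} value {tok!r}") from exc


def _read_shift_tsv(path: Path) -> list[ShiftRecord]:
    records: list[ShiftRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if cols[: len(SHIFT_TSV_COLUMNS)] != SHIFT_TSV_COLUMNS:
            raise ParseError(
                f"{path}:1: expected header {' '.join(SHIFT_TSV_COLUMNS)!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            toks = line.split("\t")
            if len(toks) != len(SHIFT_TSV_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(SHIFT_TSV_COLUMNS)} fields, "
                    f"got {len(toks)}"
                )
            try:
                idx = int(toks[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad residue index {toks[0]!r}") from exc
            records.append(
                ShiftRecord(
                    residue_index=idx,
                    aa=toks[1].strip(),
                    dH=_parse_opt_float(toks[2], str(path), lineno, "dH"),
                    dN=_parse_opt_float(toks[3], str(path), lineno, "dN"),
                    dCa=_parse_opt_float(toks[4], str(path), lineno, "dCa"),
                    dCb=_parse_opt_float(toks[5], str(path), lineno, "dCb"),
                    intensity=_parse_opt_float(toks[6], str(path), lineno, "intensity"),
                )
            )
    return records


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# NMR-STAR atom names accepted per shift field; both H and HN denote the
# amide proton in circulating BMRB depositions.
_STAR_ATOM_FIELD = {"H": "dH", "HN": "dH", "N": "dN", "CA": "dCa", "CB": "dCb"}


def _read_shift_nmrstar(path: Path) -> list[ShiftRecord]:
    """Parse the Atom_chem_shift loop of an NMR-STAR 3.x file.

    Only the columns needed to populate :class:`ShiftRecord` are consumed
    (sequence code, residue type, atom id, shift value).
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    collecting = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.startswith("loop_"):
            in_loop, collecting, tags = True, False, []
            continue
        if in_loop and line.startswith("_"):
            if collecting:  # a new tag block ends the data section
                in_loop = collecting = False
            else:
                tags.append(line.split()[0])
            continue
        if in_loop and (line.startswith("stop_") or line == ""):
            if line.startswith("stop_"):
                if collecting and any(t.startswith("_Atom_chem_shift.") for t in tags):
                    break
                in_loop = collecting = False
            continue
        if in_loop and tags:
            collecting = True
            if not any(t.startswith("_Atom_chem_shift.") for t in tags):
                continue
            toks = line.split()
            if len(toks) != len(tags):
                raise ParseError(
                    f"{path}:{lineno}: {len(toks)} values for {len(tags)} loop tags"
                )
            rows.append(toks)
    if not rows:
        raise ParseError(f"{path}: no _Atom_chem_shift loop found")

    def col(name: str) -> int:
        for cand in (f"_Atom_chem_shift.{name}",):
            if cand in tags:
                return tags.index(cand)
        raise ParseError(f"{path}: missing loop tag _Atom_chem_shift.{name}")

    i_seq = col("Seq_ID")
    i_aa = col("Comp_ID")
    i_atom = col("Atom_ID")
    i_val = col("Val")

    per_res: dict[int, dict] = {}
    for toks in rows:
        atom = toks[i_atom].upper()
        if atom not in _STAR_ATOM_FIELD:
            continue
        idx = int(toks[i_seq])
        aa3 = toks[i_aa].upper()
        if aa3 not in _THREE_TO_ONE:
            warnings.warn(f"{path}: skipping non-canonical residue {aa3} at {idx}")
            continue
        entry = per_res.setdefault(idx, {"aa": _THREE_TO_ONE[aa3]})
        entry[_STAR_ATOM_FIELD[atom]] = float(toks[i_val])
    return [
        ShiftRecord(residue_index=idx, **fields)
        for idx, fields in sorted(per_res.items())
    ]


def read_shift_table(
    path: str | Path,
    dialect: str = "tsv",
    sample_label: str = "",
    isotope_scheme: str = "protonated",
) -> ShiftTable:
    """Read a backbone shift table from TSV or the NMR-STAR shift loop.

    Unassigned residues are simply absent from the result; they are never
    zero-filled. Duplicate residue indices raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        records = _read_shift_tsv(path)
    elif dialect == "nmrstar":
        records = _read_shift_nmrstar(path)
    else:
        raise ValidationError(f"unknown shift-table dialect {dialect!r}")
    records.sort(key=lambda r: r.residue_index)
    return ShiftTable(
        tuple(records),
        sample_label=sample_label or path.stem,
        isotope_scheme=isotope_scheme,
    )


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    """Write the TSV dialect (round-trips bit-identically through repr)."""

    def fmt(v: float | None) -> str:
        return "" if v is None else repr(float(v))

    with open(path, "w") as fh:
        fh.write("\t".join(SHIFT_TSV_COLUMNS) + "\n")
        for r in table:
            fh.write(
                "\t".join(
                    [
                        str(r.residue_index),
                        r.aa,
                        fmt(r.dH),
                        fmt(r.dN),
                        fmt(r.dCa),
                        fmt(r.dCb),
                        fmt(r.intensity),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Titrations, melting curves, relaxation, RDC tables (CSV)
# ---------------------------------------------------------------------------


def titration_from_dataframe(df: pd.DataFrame, label: str = "") -> TitrationSeries:
    required = {"ligand_total", "observable", "replicate_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"titration table missing columns {sorted(missing)}")
    if (df["ligand_total"] < 0).any():
        bad = df.loc[df["ligand_total"] < 0, "ligand_total"].iloc[0]
        raise ValidationError(f"negative ligand concentration {bad}")
    conc = np.sort(df["ligand_total"].unique().astype(float))
    if conc.size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {conc.size}"
        )
    reps = tuple(str(r) for r in sorted(df["replicate_id"].unique(), key=str))
    obs = np.full((conc.size, len(reps)), np.nan)
    ci = {c: i for i, c in enumerate(conc)}
    ri = {r: j for j, r in enumerate(reps)}
    for _, row in df.iterrows():
        obs[ci[float(row["ligand_total"])], ri[str(row["replicate_id"])]] = float(
            row["observable"]
        )
    return TitrationSeries(conc, obs, reps, label=label)


def read_titration_csv(path: str | Path) -> TitrationSeries:
    """Read ``ligand_total,observable,replicate_id`` rows (µM, a.u., id).

    Rows may appear in any order; replicates are grouped and concentrations
    sorted ascending.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return titration_from_dataframe(df, label=path.stem)


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    rows = []
    for i, c in enumerate(series.concentrations):
        for j, rep in enumerate(series.replicate_ids):
            v = series.observable[i, j]
            if np.isfinite(v):
                rows.append({"ligand_total": c, "observable": v, "replicate_id": rep})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_melting_csv(path: str | Path) -> list[MeltingCurve]:
    """Read ``temperature_C,F330,F350,capillary_id`` rows, one curve per id."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"temperature_C", "F330", "F350", "capillary_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"melting table missing columns {sorted(missing)}")
    curves = []
    for cid, grp in df.groupby("capillary_id", sort=True):
        grp = grp.sort_values("temperature_C")
        curves.append(
            MeltingCurve(
                grp["temperature_C"].to_numpy(float),
                grp["F330"].to_numpy(float),
                grp["F350"].to_numpy(float),
                capillary_id=str(cid),
            )
        )
    return curves


def write_melting_csv(curves: Sequence[MeltingCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, a, b in zip(c.temperature, c.f330, c.f350):
            rows.append(
                {"temperature_C": t, "F330": a, "F350": b, "capillary_id": c.capillary_id}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_relaxation_csv(path: str | Path, experiment: str = "T2") -> list[RelaxationSeries]:
    """Read ``residue,delay_s,intensity`` rows (optional ``replicate``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"residue", "delay_s", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"relaxation table missing columns {sorted(missing)}")
    out = []
    for res, grp in df.groupby("residue", sort=True):
        out.append(
            RelaxationSeries(
                residue_index=int(res),
                delays=grp["delay_s"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                experiment=experiment,
            )
        )
    return out


def write_relaxation_csv(series: Sequence[RelaxationSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for d, i in zip(s.delays, s.intensities):
            rows.append({"residue": s.residue_index, "delay_s": d, "intensity": i})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_rdc_csv(path: str | Path) -> pd.DataFrame:
    """Read ``residue,J_iso_Hz,J_aligned_Hz`` coupling rows."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"residue", "J_iso_Hz", "J_aligned_Hz"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"RDC table missing columns {sorted(missing)}")
    return df


def write_rdc_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# PDB N-H vectors
# ---------------------------------------------------------------------------


def read_structure_nh_vectors(
    pdb_path: str | Path, chain: str = "A"
) -> list[tuple[int, np.ndarray]]:
    """Extract unit N-H bond vectors per residue from a PDB file.

    If the amide proton is absent it is reconstructed on the bisector of the
    N-CA and N-C'(previous residue) directions (1.02 Å bond). Prolines have
    no amide proton and are excluded; residues where no reconstruction is
    possible are skipped with a warning rather than failing.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValidationError(f"chain {chain!r} not present in {pdb_path}")
    residues = [r for r in model[chain] if r.id[0] == " "]
    out: list[tuple[int, np.ndarray]] = []
    prev = None
    for res in residues:
        idx = res.id[1]
        if res.get_resname() == "PRO":
            prev = res
            continue
        if "N" not in res:
            warnings.warn(f"residue {idx}: no backbone N; skipped")
            prev = res
            continue
        n = res["N"].coord.astype(float)
        h = None
        for hname in ("H", "HN"):
            if hname in res:
                h = res[hname].coord.astype(float)
                break
        if h is None:
            # reconstruct from N, CA and preceding C'
            if prev is not None and "C" in prev and "CA" in res:
                u1 = n - res["CA"].coord.astype(float)
                u2 = n - prev["C"].coord.astype(float)
                u1 /= np.linalg.norm(u1)
                u2 /= np.linalg.norm(u2)
                d = u1 + u2
                nrm = np.linalg.norm(d)
                if nrm > 1e-6:
                    h = n + 1.02 * d / nrm
            if h is None:
                warnings.warn(f"residue {idx}: amide H missing and not reconstructable")
                prev = res
                continue
        v = h - n
        v = v / np.linalg.norm(v)
        out.append((idx, v))
        prev = res
    return out


# ---------------------------------------------------------------------------
# FASTA and domain-architecture tables
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_domain_table(
    tsv_path: str | Path, sequences: dict[str, str]
) -> list[DomainRecord]:
    """Combine a ``protein_id<TAB>domain<TAB>start<TAB>end`` table with FASTA."""
    per_protein: dict[str, list[tuple[str, int, int]]] = {}
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) != 4:
                raise ParseError(f"{tsv_path}:{lineno}: expected 4 fields, got {len(toks)}")
            pid, dom, start, end = toks
            per_protein.setdefault(pid, []).append((dom, int(start), int(end)))
    records = []
    for pid, doms in per_protein.items():
        if pid not in sequences:
            raise ValidationError(f"{pid}: annotated but absent from FASTA")
        doms.sort(key=lambda d: d[1])
        records.append(DomainRecord(pid, sequences[pid], tuple(doms)))
    records.sort(key=lambda r: r.protein_id)
    return records


def write_domain_table(records: Sequence[DomainRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            for name, start, end in rec.domains:
                fh.write(f"{rec.protein_id}\t{name}\t{start}\t{end}\n")
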