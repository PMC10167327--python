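"""SPX domain-architecture filtering and helix-motif PSSM analysis.

A local database of SPX-containing proteins (sequence + domain architecture)
is filtered by four rules before motif scanning:

(i)   the SPX domain is the first annotated domain (configurable N-terminal
      slack in domain index 1 position),
(ii)  at least one other domain is annotated,
(iii) the SPX domain spans >= 130 residues,
(iv)  the interdomain linker between the SPX end and the next domain start
      is <= 300 residues.

A position-specific scoring matrix is built from a gapless alignment block
of the C-terminal SPX helix region; scores are base-2 log-likelihood ratios
against a background distribution with additive background-scaled
pseudocounts:

    score(pos, aa) = log2( (count + pc * bg_aa) / (n + pc) / bg_aa ).

Each interdomain linker is scanned with every window of the matrix width;
windows scoring above 0.4 x the consensus score are reported as motif hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from spxlab.io import DomainRecord, ValidationError

__all__ = [
    "ALPHABET",
    "PssmModel",
    "MotifHit",
    "FilterResult",
    "filter_spxdb",
    "interdomain_linker",
    "build_pssm",
    "logo_information",
    "scan_linkers",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass(frozen=True)
class PssmModel:
    """Log-likelihood scoring matrix (bits) with consensus and background."""

    matrix: np.ndarray  # (width, 20)
    background: np.ndarray  # (20,), sums to 1
    pseudocount: float
    consensus: str
    log_base: int = 2  # scores are in bits

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, float)
        if not np.isclose(bg.sum(), 1.0):
            raise ValidationError("background frequencies must sum to 1")
        if np.asarray(self.matrix).shape != (len(self.consensus), 20):
            raise ValidationError("matrix shape must be (width, 20)")

    @property
    def width(self) -> int:
        return len(self.consensus)

    @property
    def consensus_score(self) -> float:
        return self.score(self.consensus)

    def score(self, window: str) -> float:
        if len(window) != self.width:
            raise ValidationError(
                f"window length {len(window)} != matrix width {self.width}"
            )
        try:
            cols = [_AA_INDEX[a] for a in window]
        except KeyError as exc:
            raise ValidationError(f"non-canonical residue in window {window!r}") from exc
        return float(np.sum(self.matrix[np.arange(self.width), cols]))


@dataclass(frozen=True)
class MotifHit:
    """One above-threshold window in an interdomain linker."""

    protein_id: str
    start: int  # 1-based within the linker
    window: str
    score: float
    score_fraction: float


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the architecture filter with per-record rejection reasons."""

    kept: tuple[DomainRecord, ...]
    rejected: tuple[tuple[DomainRecord, str], ...]


def interdomain_linker(record: DomainRecord, spx_name: str = "SPX") -> str:
    """Sequence between the end of the SPX domain and the next domain start."""
    doms = record.domains
    spx_pos = next((k for k, d in enumerate(doms) if d[0] == spx_name), None)
    if spx_pos is None or spx_pos + 1 >= len(doms):
        return ""
    spx_end = doms[spx_pos][2]
    next_start = doms[spx_pos + 1][1]
    return record.sequence[spx_end : next_start - 1]


def filter_spxdb(
    records: list[DomainRecord],
    spx_name: str = "SPX",
    min_spx_len: int = 130,
    max_linker_len: int = 300,
    nterm_slack: int = 0,
) -> FilterResult:
    """Apply the four SPX-database architecture rules in order i-iv.

    ``nterm_slack`` allows the SPX domain to sit up to that many domain
    positions after the first (default 0: it must be the first domain).
    Each rejected record carries the first violated rule as its reason.
    """
    kept, rejected = [], []
    for rec in records:
        doms = rec.domains
        spx_pos = next((k for k, d in enumerate(doms) if d[0] == spx_name), None)
        if spx_pos is None:
            rejected.append((rec, "no SPX domain annotated"))
            continue
        if spx_pos > nterm_slack:
            rejected.append((rec, "rule i: SPX is not the first domain"))
            continue
        if len(doms) < 2:
            rejected.append((rec, "rule ii: no adjacent domain"))
            continue
        name, start, end = doms[spx_pos]
        if end - start + 1 < min_spx_len:
            rejected.append(
                (rec, f"rule iii: SPX length {end - start + 1} < {min_spx_len}")
            )
            continue
        if spx_pos + 1 < len(doms):
            linker_len = doms[spx_pos + 1][1] - end - 1
            if linker_len > max_linker_len:
                rejected.append(
                    (rec, f"rule iv: linker length {linker_len} > {max_linker_len}")
                )
                continue
        kept.append(rec)
    return FilterResult(tuple(kept), tuple(rejected))


def build_pssm(
    block: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> PssmModel:
    """Build a PSSM from a gapless, equal-length alignment block.

    Consensus ties break alphabetically; duplicating the whole block leaves
    the matrix unchanged (scores depend on column proportions only through
    counts and the shared pseudocount mass).
    """
    if not block:
        raise ValidationError("empty alignment block")
    width = len(block[0])
    if any(len(s) != width for s in block):
        raise ValidationError("alignment block sequences differ in length")
    for s in block:
        bad = set(s) - set(ALPHABET)
        if bad:
            raise ValidationError(f"non-canonical letters {sorted(bad)} in block")
    bg = (
        np.full(20, 1.0 / 20.0)
        if background is None
        else np.asarray(background, float)
    )
    if not np.isclose(bg.sum(), 1.0):
        raise ValidationError("background frequencies must sum to 1")
    n = len(block)
    counts = np.zeros((width, 20))
    for s in block:
        for pos, aa in enumerate(s):
            counts[pos, _AA_INDEX[aa]] += 1
    with np.errstate(divide="ignore"):
        matrix = np.log2((counts + pseudocount * bg) / (n + pseudocount) / bg)
    consensus = "".join(
        ALPHABET[int(np.argmax(matrix[pos]))] for pos in range(width)
    )  # np.argmax returns the first (alphabetically lowest) maximum
    return PssmModel(matrix, bg, float(pseudocount), consensus)


def logo_information(model: PssmModel) -> np.ndarray:
    """Per-position information content (bits) of the sequence logo.

    IC(pos) = log2(20) + sum_a p_a log2 p_a over the pseudocounted frequency
    estimate encoded in the matrix (p_a = bg_a * 2**score).
    """
    p = model.background[None, :] * np.exp2(model.matrix)
    p = p / p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return np.log2(20.0) + plogp.sum(axis=1)


def write_pssm(model: PssmModel, path: str | Path) -> None:
    """Serialize a PSSM as a plain TSV matrix with a commented header block."""
    with open(path, "w") as fh:
        fh.write(f"# width\t{model.width}\n")
        fh.write(f"# pseudocount\t{model.pseudocount!r}\n")
        fh.write(f"# consensus\t{model.consensus}\n")
        fh.write(f"# log_base\t{model.log_base}\n")
        fh.write("# background\t" + "\t".join(repr(float(b)) for b in model.background) + "\n")
        fh.write("pos\t" + "\t".join(ALPHABET) + "\n")
        for pos in range(model.width):
            fh.write(
                f"{pos + 1}\t" + "\t".join(repr(float(v)) for v in model.matrix[pos]) + "\n"
            )


def read_pssm(path: str | Path) -> PssmModel:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                toks = line[1:].strip().split("\t")
                header[toks[0]] = toks[1:]
            elif line.startswith("pos\t") or not line.strip():
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
    matrix = np.array(rows)
    background = np.array([float(x) for x in header["background"]])
    return PssmModel(
        matrix,
        background,
        float(header["pseudocount"][0]),
        header["consensus"][0],
        log_base=int(header["log_base"][0]),
    )


def scan_linkers(
    records: list[DomainRecord],
    model: PssmModel,
    threshold_factor: float = 0.4,
    spx_name: str = "SPX",
) -> list[MotifHit]:
    """Scan every interdomain linker with the PSSM.

    All windows of the matrix width are scored; windows with
    score > threshold_factor * consensus_score become hits (overlaps are all
    reported). Linkers shorter than the matrix width are skipped.
    """
    cscore = model.consensus_score
    thr = threshold_factor * cscore
    hits: list[MotifHit] = []
    for rec in records:
        linker = interdomain_linker(rec, spx_name=spx_name)
        if len(linker) < model.width:
            continue
        for start in range(len(linker) - model.width + 1):
            window = linker[start : start + model.width]
            s = model.score(window)
            if s > thr:
                hits.append(
                    MotifHit(
                        protein_id=rec.protein_id,
                        start=start + 1,
                        window=window,
                        score=s,
                        score_fraction=s / cscore,
                    )
                )
    return hits
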