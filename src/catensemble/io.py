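"""Input/output and integer encoding of categorical data.

Categorical tables (CSV/TSV) and pre-aligned FASTA files are read into a
:class:`CategoricalMatrix`: an ``n x J`` matrix of positive integer category
codes with a boolean missing-value mask. Alignment gaps map to missing, so a
gap is treated as absence of information rather than as a fifth nucleotide
state.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO


class FormatError(ValueError):
    """Malformed input file (ragged table, unequal sequence lengths, ...)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a data contract."""


@dataclass
class CategoricalMatrix:
    """n x J integer-coded categorical observations with a missing mask.

    Parameters
    ----------
    codes
        Integer category codes, ``>= 1`` wherever observed. Entries under
        the missing mask are ignored (stored as 0 by convention).
    missing_mask
        True exactly where a value is absent (empty cell, alignment gap).
    row_labels
        One identifier per observation.
    col_cardinalities
        Observed number of distinct codes per column. For alphabet-encoded
        sequence data the codes are alphabet-global, so a column's codes
        need not be contiguous from 1.
    code_maps
        Optional per-column label->code dictionaries retained for
        round-tripping tables read from disk.
    """

    codes: np.ndarray
    missing_mask: np.ndarray
    row_labels: list[str]
    col_cardinalities: np.ndarray
    code_maps: list[dict] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.codes.ndim != 2:
            raise ValidationError("codes must be a 2-D matrix")
        if self.codes.shape != self.missing_mask.shape:
            raise ValidationError("codes and missing_mask shapes differ")
        n, j = self.codes.shape
        if n < 2 or j < 1:
            raise ValidationError(f"need n >= 2 and J >= 1, got n={n}, J={j}")
        if len(self.row_labels) != n:
            raise ValidationError("row_labels length does not match n")
        obs = ~self.missing_mask
        if obs.any() and self.codes[obs].min() < 1:
            raise ValidationError("observed codes must be >= 1")
        self.col_cardinalities = np.asarray(self.col_cardinalities, dtype=np.int64)
        if self.col_cardinalities.shape != (j,):
            raise ValidationError("col_cardinalities must have one entry per column")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def J(self) -> int:
        return self.codes.shape[1]

    def take_rows(self, idx) -> "CategoricalMatrix":
        """Row subset (used by bootstrap resampling)."""
        idx = np.asarray(idx, dtype=np.intp)
        return CategoricalMatrix(
            self.codes[idx],
            self.missing_mask[idx],
            [self.row_labels[i] for i in idx],
            self.col_cardinalities.copy(),
            self.code_maps,
        )

    def take_columns(self, idx) -> "CategoricalMatrix":
        """Column subset (used by random-subspace draws)."""
        idx = np.asarray(idx, dtype=np.intp)
        return CategoricalMatrix(
            self.codes[:, idx],
            self.missing_mask[:, idx],
            list(self.row_labels),
            self.col_cardinalities[idx],
            [self.code_maps[i] for i in idx] if self.code_maps else None,
        )


def _observed_cardinalities(codes: np.ndarray, missing: np.ndarray) -> np.ndarray:
    cards = np.zeros(codes.shape[1], dtype=np.int64)
    for j in range(codes.shape[1]):
        col = codes[~missing[:, j], j]
        cards[j] = len(np.unique(col))
    return cards


@dataclass(frozen=True)
class AlphabetMap:
    """Character -> integer-code map; characters mapping to ``None`` are missing.

    Matching is case-insensitive. Every character in the input must be
    covered, otherwise encoding raises with the offending character.
    """

    mapping: dict

    def __post_init__(self):
        norm = {str(k).upper(): v for k, v in self.mapping.items()}
        codes = [v for v in norm.values() if v is not None]
        if len(codes) != len(set(codes)):
            raise ValidationError("alphabet codes must be injective on non-missing characters")
        object.__setattr__(self, "mapping", norm)

    def code(self, ch: str):
        up = ch.upper()
        if up not in self.mapping:
            raise ValidationError(f"character {ch!r} not covered by the alphabet")
        return self.mapping[up]

    def decoder(self) -> dict:
        return {v: k for k, v in self.mapping.items() if v is not None}


#: Nucleotides A,T,C,G -> 1,2,3,4; gaps and IUPAC ambiguity codes -> missing.
DEFAULT_DNA_ALPHABET = AlphabetMap(
    {
        "A": 1,
        "T": 2,
        "C": 3,
        "G": 4,
        "-": None,
        ".": None,
        "N": None,
        "R": None,
        "Y": None,
        "K": None,
        "M": None,
        "S": None,
        "W": None,
        "B": None,
        "D": None,
        "H": None,
        "V": None,
        "U": None,
    }
)


def read_categorical_table(path, delimiter: str = ",", header: bool = False) -> CategoricalMatrix:
    """Read a rectangular table of category labels into a CategoricalMatrix.

    Each column's distinct labels are coded 1, 2, ... in order of first
    appearance; empty cells become missing. Code identity across columns
    carries no meaning — Hamming distance only ever tests equality.
    """
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delimiter)]
    if header and rows:
        rows = rows[1:]
    rows = [r for r in rows if r]
    if not rows:
        raise FormatError(f"{path}: no data rows")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(f"{path}: ragged table (row {i + 1} has {len(r)} fields, expected {width})")
    n, j = len(rows), width
    codes = np.zeros((n, j), dtype=np.int64)
    missing = np.zeros((n, j), dtype=bool)
    code_maps: list[dict] = [dict() for _ in range(j)]
    for cidx in range(j):
        cmap = code_maps[cidx]
        for ridx in range(n):
            cell = rows[ridx][cidx].strip()
            if cell == "":
                missing[ridx, cidx] = True
                continue
            if cell not in cmap:
                cmap[cell] = len(cmap) + 1
            codes[ridx, cidx] = cmap[cell]
        if not cmap:
            raise ValidationError(f"{path}: column {cidx + 1} has no non-missing values")
    labels = [f"row{i + 1}" for i in range(n)]
    return CategoricalMatrix(codes, missing, labels, _observed_cardinalities(codes, missing), code_maps)


def read_aligned_fasta(path, alphabet: AlphabetMap = DEFAULT_DNA_ALPHABET) -> CategoricalMatrix:
    """Read pre-aligned, equal-length FASTA records into a CategoricalMatrix.

    Headers (up to the first whitespace) become row labels; gap characters
    become missing values. Unequal record lengths indicate unaligned input
    and raise a :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) < 2:
        raise ValidationError(f"{path}: need at least two sequences to cluster")
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise FormatError(
                f"{path}: record {rec.id!r} has length {len(rec.seq)} != {length}; "
                "sequences must be aligned to equal length first"
            )
    chars = np.array([list(str(rec.seq)) for rec in records])
    out = ctn_encode(chars, alphabet, row_labels=[rec.id for rec in records])
    return out


def ctn_encode(chars, alphabet: AlphabetMap = DEFAULT_DNA_ALPHABET, row_labels=None) -> CategoricalMatrix:
    """Encode an n x J character matrix to integer codes (gap -> missing)."""
    chars = np.asarray(chars, dtype=str)
    if chars.ndim != 2:
        raise ValidationError("character matrix must be 2-D")
    n, j = chars.shape
    codes = np.zeros((n, j), dtype=np.int64)
    missing = np.zeros((n, j), dtype=bool)
    lut: dict = {}
    for ridx in range(n):
        for cidx in range(j):
            ch = chars[ridx, cidx]
            if ch not in lut:
                try:
                    lut[ch] = alphabet.code(ch)
                except ValidationError as exc:
                    raise ValidationError(f"record {ridx + 1} ({row_labels[ridx] if row_labels else '?'}): {exc}") from None
            code = lut[ch]
            if code is None:
                missing[ridx, cidx] = True
            else:
                codes[ridx, cidx] = code
    if row_labels is None:
        row_labels = [f"seq{i + 1}" for i in range(n)]
    return CategoricalMatrix(codes, missing, list(row_labels), _observed_cardinalities(codes, missing))


def ctn_decode(X: CategoricalMatrix, alphabet: AlphabetMap = DEFAULT_DNA_ALPHABET, gap: str = "-") -> np.ndarray:
    """Inverse of :func:`ctn_encode` on non-missing cells; missing -> ``gap``."""
    dec = alphabet.decoder()
    out = np.full(X.codes.shape, gap, dtype="<U1")
    obs = ~X.missing_mask
    for code, ch in dec.items():
        out[obs & (X.codes == code)] = ch
    return out


def write_fasta(X: CategoricalMatrix, path, alphabet: AlphabetMap = DEFAULT_DNA_ALPHABET) -> None:
    """Write encoded sequence data back to FASTA (fixture/round-trip helper)."""
    chars = ctn_decode(X, alphabet)
    with open(path, "w") as fh:
        for label, row in zip(X.row_labels, chars):
            fh.write(f">{label}\n{''.join(row)}\n")


def write_table(X: CategoricalMatrix, path, delimiter: str = ",") -> None:
    """Write integer codes as a headerless table; missing cells are empty."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for i in range(X.n):
            row = [
                "" if X.missing_mask[i, j] else str(int(X.codes[i, j]))
                for j in range(X.J)
            ]
            writer.writerow(row)


def write_labels(labels, path, row_labels=None) -> None:
    """Write a cluster assignment as a two-column TSV (row label, cluster)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("empty label vector")
    if row_labels is None:
        row_labels = [f"row{i + 1}" for i in range(len(labels))]
    with open(path, "w") as fh:
        for name, lab in zip(row_labels, labels):
            fh.write(f"{name}\t{int(lab)}\n")


def write_matrix(D, path, delimiter: str = "\t") -> None:
    """Write a dissimilarity matrix in full symmetric form with labels."""
    values = D.values
    labels = D.row_labels
    with open(path, "w") as fh:
        fh.write(delimiter.join([""] + list(labels)) + "\n")
        for name, row in zip(labels, values):
            fh.write(delimiter.join([name] + [repr(float(v)) for v in row]) + "\n")


def read_matrix(path, delimiter: str = "\t"):
    """Read a matrix written by :func:`write_matrix`."""
    from .hamming import DissimilarityMatrix

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split(delimiter)
            rows.append([float(v) for v in parts[1:]])
    values = np.asarray(rows, dtype=float)
    return DissimilarityMatrix(values, header)
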