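"""Feature encoders turning peptide windows into named numeric vectors.

Six encoders are provided, mirroring the descriptor families commonly used in
PTM-site prediction:

* **PCP** — per-position values of standardised AAindex physicochemical
  properties (centre lysine excluded by default, it being constant);
* **PSSM** — per-position PSI-BLAST substitution scores (19 x 20 = 380 dims);
* **AC** — auto-covariation of each property at lags 1 and 2 within the window;
* **RC** — residue composition, the frequencies of the 20 amino acids;
* **SS** — per-position 7-bit one-hot DSSP secondary-structure state;
* **ASA** — per-position accessible surface area in squared angstroms.

With the default configuration (4 properties, flank 9, lags {1, 2}) the
assembled matrix has 72 + 380 + 8 + 20 + 133 + 19 = 632 columns, each entry
tracked in a registry mapping column name -> (encoder, position/lag, detail).

Property standardisation: for property j with per-residue values P_ij, the
encoder uses X_ij = (P_ij - mean_j) / sd_j where mean and population SD are
taken over the 20 standard amino acids.  The padding letter 'X' carries the
raw value 0, i.e. its standardised value is (0 - mean_j) / sd_j under the
default ``x_policy='raw-zero'`` (``'z-zero'`` maps it to 0 after
standardisation instead).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .sequence_io import STANDARD_AA, PeptideWindow, Protein

logger = logging.getLogger(__name__)

#: Column order of a PSI-BLAST ASCII PSSM header.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: DSSP secondary-structure letters carrying a one-hot bit ('-' = coil/blank).
SS_STATES = "HBEGITS"
#: Bit layout of the 7-bit one-hot code, leftmost (most significant) first:
#: S -> 1000000, T -> 0100000, ..., H -> 0000001.
SS_BIT_ORDER = "STIGEBH"
_SS_BIT_INDEX = {letter: i for i, letter in enumerate(SS_BIT_ORDER)}

DEFAULT_ENCODERS = ("pcp", "pssm", "ac", "rc", "ss", "asa")


class AAIndexError(ValueError):
    """Problem loading or validating an AAindex property table."""


class PSSMParseError(ValueError):
    """An ASCII PSSM file could not be parsed."""


# ---------------------------------------------------------------------------
# physicochemical property tables


@dataclass(frozen=True)
class PropertyTable:
    """Raw per-amino-acid values of one physicochemical index."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(STANDARD_AA):
            raise AAIndexError(
                f"property {self.name!r}: need exactly the 20 standard amino acids, "
                f"got {len(keys)} keys"
            )
        for aa, v in self.values.items():
            if v is None or not math.isfinite(v):
                raise AAIndexError(f"property {self.name!r}: non-finite value for {aa!r}")


@dataclass(frozen=True)
class NormalizedProperty:
    """A property standardised to zero mean / unit population SD over the 20 AAs."""

    name: str
    z_values: Mapping[str, float]
    x_for_X: float

    def z(self, letter: str) -> float:
        """Standardised value for a window letter ('X' -> the configured x_for_X)."""
        v = self.z_values.get(letter)
        return self.x_for_X if v is None else v


def _parse_aaindex(path: str | Path) -> dict[str, dict[str, float | None]]:
    """Parse an AAindex1 flat file into accession -> letter -> value (None = NA)."""
    entries: dict[str, dict[str, float | None]] = {}
    accession: str | None = None
    letter_rows: list[list[str]] | None = None
    data_rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("H "):
                accession = line.split()[1]
            elif line.startswith("I ") and accession is not None:
                pairs = line.split()[1:]
                if len(pairs) != 10 or any("/" not in p for p in pairs):
                    raise AAIndexError(f"{path}:{lineno}: malformed AAindex I header")
                letter_rows = [[p.split("/")[0] for p in pairs], [p.split("/")[1] for p in pairs]]
                data_rows = []
            elif letter_rows is not None:
                if line.startswith("//"):
                    if len(data_rows) != 2:
                        raise AAIndexError(
                            f"{path}:{lineno}: entry {accession!r} has "
                            f"{len(data_rows)} value rows, expected 2"
                        )
                    values: dict[str, float | None] = {}
                    for letters, row in zip(letter_rows, data_rows):
                        for aa, tok in zip(letters, row):
                            values[aa] = None if tok.upper() == "NA" else float(tok)
                    entries[accession] = values  # type: ignore[index]
                    accession, letter_rows = None, None
                else:
                    toks = line.split()
                    if toks:
                        if len(toks) != 10:
                            raise AAIndexError(
                                f"{path}:{lineno}: expected 10 values, got {len(toks)}"
                            )
                        data_rows.append(toks)
    return entries


def load_aaindex(
    path: str | Path, accessions: Sequence[str] | None = None
) -> list[PropertyTable]:
    """Load property tables from an AAindex1 flat file.

    ``accessions`` selects (and orders) the requested indices; ``None`` loads
    every complete entry in file order.  An entry containing 'NA' values is
    rejected when explicitly requested, and silently skipped otherwise —
    mirroring the usual curation step of dropping incomplete indices.
    """
    entries = _parse_aaindex(path)
    if accessions is None:
        return [
            PropertyTable(name=acc, values=vals)  # type: ignore[arg-type]
            for acc, vals in entries.items()
            if all(v is not None for v in vals.values())
        ]
    tables = []
    for acc in accessions:
        if acc not in entries:
            raise KeyError(f"accession {acc!r} not found in {path}")
        vals = entries[acc]
        if any(v is None for v in vals.values()):
            raise AAIndexError(f"accession {acc!r} contains 'NA' values and was rejected")
        tables.append(PropertyTable(name=acc, values=vals))  # type: ignore[arg-type]
    return tables


#: Accessions of the four synthetic property tables shipped with the package.
DEFAULT_PROPERTY_ACCESSIONS = ("SYNH490101", "SYNG890102", "SYNF900103", "SYNT910104")


def default_property_tables() -> list[PropertyTable]:
    """The four synthetic physicochemical property tables shipped as package data."""
    ref = resources.files("kascade.data").joinpath("aaindex_synthetic.txt")
    with resources.as_file(ref) as path:
        return load_aaindex(path, DEFAULT_PROPERTY_ACCESSIONS)


def normalize_property(
    table: PropertyTable, x_policy: str = "raw-zero"
) -> NormalizedProperty:
    """Standardise a property to zero mean and unit population SD.

    ``x_policy='raw-zero'`` (default) maps 'X' through the same transform with
    raw value 0; ``'z-zero'`` assigns 'X' the standardised value 0 directly.
    """
    if x_policy not in ("raw-zero", "z-zero"):
        raise ValueError(f"unknown x_policy {x_policy!r}")
    vals = np.array([table.values[aa] for aa in STANDARD_AA], dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0.0:
        raise AAIndexError(f"property {table.name!r} is constant (SD = 0)")
    z = {aa: (table.values[aa] - mean) / sd for aa in STANDARD_AA}
    x_for_X = (0.0 - mean) / sd if x_policy == "raw-zero" else 0.0
    return NormalizedProperty(name=table.name, z_values=z, x_for_X=x_for_X)


# ---------------------------------------------------------------------------
# PSSM


@dataclass
class PSSMMatrix:
    """Per-residue substitution scores from a PSI-BLAST ASCII PSSM."""

    protein_id: str
    letters: str  # column order as given by the file header
    scores: np.ndarray  # (L, 20) integer log-odds block
    sequence: str  # residue column of the file

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM scores must be (L, 20)")
        if len(self.sequence) != self.scores.shape[0]:
            raise ValueError("PSSM residue column length != score row count")


def read_ascii_pssm(
    path: str | Path, protein_id: str | None = None, protein: Protein | None = None
) -> PSSMMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file (log-odds block).

    The first 20 score columns are retained.  When ``protein`` is supplied the
    residue column is checked against its sequence; mismatches log a
    consistency warning rather than failing (PSI-BLAST masks some residues).
    """
    path = Path(path)
    letters: str | None = None
    rows: list[list[int]] = []
    residues: list[str] = []
    expected_idx = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            toks = line.split()
            if letters is None:
                if len(toks) >= 20 and all(len(t) == 1 and t.isalpha() for t in toks[:20]):
                    letters = "".join(toks[:20])
                continue
            if not toks:
                if rows:
                    break  # blank line after the matrix ends it
                continue
            if not toks[0].lstrip("-").isdigit():
                break  # footer (K, Lambda, ...)
            if len(toks) < 22:
                raise PSSMParseError(
                    f"{path}:{lineno}: truncated PSSM row ({len(toks)} fields)"
                )
            idx = int(toks[0])
            if idx != expected_idx:
                raise PSSMParseError(
                    f"{path}:{lineno}: residue index {idx}, expected {expected_idx}"
                )
            expected_idx += 1
            residues.append(toks[1])
            try:
                rows.append([int(t) for t in toks[2:22]])
            except ValueError as exc:
                raise PSSMParseError(f"{path}:{lineno}: non-integer score: {exc}") from None
    if letters is None or not rows:
        raise PSSMParseError(f"{path}: no PSSM matrix found")
    pid = protein_id or (protein.id if protein is not None else path.stem)
    matrix = PSSMMatrix(
        protein_id=pid,
        letters=letters,
        scores=np.array(rows, dtype=np.int32),
        sequence="".join(residues),
    )
    if protein is not None:
        if len(protein) != len(matrix.sequence):
            logger.warning(
                "%s: PSSM has %d rows but protein %s has %d residues",
                path, len(matrix.sequence), protein.id, len(protein),
            )
        elif protein.sequence != matrix.sequence:
            n_bad = sum(a != b for a, b in zip(protein.sequence, matrix.sequence))
            logger.warning(
                "%s: PSSM residue column differs from protein %s at %d positions",
                path, protein.id, n_bad,
            )
    return matrix


def write_ascii_pssm(pssm: PSSMMatrix, path: str | Path, percentages: np.ndarray | None = None) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect read by :func:`read_ascii_pssm`."""
    L = pssm.scores.shape[0]
    if percentages is None:
        percentages = np.zeros((L, 20), dtype=int)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapped matches\n"
        )
        hdr = "           " + "".join(f"{c:>4}" for c in pssm.letters)
        fh.write(hdr + " " + "".join(f"{c:>4}" for c in pssm.letters) + "\n")
        for i in range(L):
            fh.write(
                f"{i + 1:5d} {pssm.sequence[i]} "
                + "".join(f"{int(v):4d}" for v in pssm.scores[i])
                + " "
                + "".join(f"{int(v):4d}" for v in percentages[i])
                + f"  {0.0:4.2f} {0.0:8.2f}\n"
            )
        fh.write("\n")
        fh.write(f"{'K':>22}{0.0410:12.4f}\n")
        fh.write(f"{'Lambda':>22}{0.2670:12.4f}\n")


# ---------------------------------------------------------------------------
# structure annotations


@dataclass
class StructureAnnotation:
    """Per-residue DSSP secondary-structure letter and ASA for one chain."""

    protein_id: str
    ss: str  # letters in SS_STATES plus '-' for coil/blank
    asa: np.ndarray  # (L,) float, squared angstroms

    def __post_init__(self) -> None:
        self.asa = np.asarray(self.asa, dtype=float)
        if len(self.ss) != self.asa.shape[0]:
            raise ValueError(
                f"{self.protein_id}: ss length {len(self.ss)} != asa length {self.asa.shape[0]}"
            )
        bad = set(self.ss) - set(SS_STATES) - {"-"}
        if bad:
            raise ValueError(f"{self.protein_id}: invalid SS letters {sorted(bad)}")
        if not np.all(np.isfinite(self.asa)) or np.any(self.asa < 0):
            raise ValueError(f"{self.protein_id}: ASA must be finite and non-negative")


def read_structure_tsv(path: str | Path) -> dict[str, StructureAnnotation]:
    """Read the fallback per-residue TSV ``protein_id  position  ss  asa``.

    Positions are 1-based and must be contiguous from 1 within each protein.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "ss": str})
    required = {"protein_id", "position", "ss", "asa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: structure table missing columns {sorted(missing)}")
    out: dict[str, StructureAnnotation] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"{path}: protein {pid!r}: positions not contiguous from 1")
        out[str(pid)] = StructureAnnotation(
            protein_id=str(pid),
            ss="".join(grp["ss"].astype(str)),
            asa=grp["asa"].to_numpy(dtype=float),
        )
    return out


def write_structure_tsv(
    annotations: Iterable[StructureAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tss\tasa\n")
        for ann in annotations:
            for i, (s, a) in enumerate(zip(ann.ss, ann.asa), 1):
                fh.write(f"{ann.protein_id}\t{i}\t{s}\t{a:.1f}\n")


def read_dssp(path: str | Path, protein_id: str | None = None) -> StructureAnnotation:
    """Parse secondary structure and ACC from a DSSP v2/v3 output file.

    Fixed-column parse of the per-residue block: amino acid at column 14,
    structure letter at column 17, ACC at columns 35-38 (1-based).  Blank
    structure (coil) maps to '-'; chain-break rows ('!') are skipped.
    """
    path = Path(path)
    ss_chars: list[str] = []
    asa_vals: list[float] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            if not in_data:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_data = True
                continue
            if len(line) < 38:
                continue
            aa = line[13]
            if aa == "!":
                continue
            ss = line[16]
            ss_chars.append("-" if ss == " " else ss)
            asa_vals.append(float(line[34:38]))
    if not ss_chars:
        raise ValueError(f"{path}: no DSSP residue records found")
    return StructureAnnotation(
        protein_id=protein_id or path.stem, ss="".join(ss_chars), asa=np.array(asa_vals)
    )


# ---------------------------------------------------------------------------
# per-window encoders


def _rel_positions(flank: int, include_center: bool) -> list[int]:
    rel = list(range(-flank, flank + 1))
    if not include_center:
        rel.remove(0)
    return rel


def encode_pcp(
    window: PeptideWindow,
    properties: Sequence[NormalizedProperty],
    include_center: bool = False,
) -> np.ndarray:
    """Per-position standardised property values, property-major.

    The centre lysine is excluded by default (it is constant across samples),
    giving ``len(properties) * 2 * flank`` values ordered upstream->downstream
    within each property block.
    """
    flank = window.flank
    rel = _rel_positions(flank, include_center)
    out = np.empty(len(properties) * len(rel))
    k = 0
    for prop in properties:
        for r in rel:
            out[k] = prop.z(window.residues[flank + r])
            k += 1
    return out


def encode_ac(
    window: PeptideWindow,
    properties: Sequence[NormalizedProperty],
    lags: Sequence[int] = (1, 2),
) -> np.ndarray:
    """Auto-covariation of each standardised property at each lag.

    For property j over the n window letters x_1..x_n (padding included with
    its 'X' value), with m = mean(x),

        AC(lag, j) = (1 / (n - lag)) * sum_{i=1}^{n-lag} (x_i - m) (x_{i+lag} - m).

    Output is property-major, then lag order as given.
    """
    n = len(window)
    for lag in lags:
        if not 1 <= lag < n:
            raise ValueError(f"lag {lag} must be in [1, {n - 1}] for window length {n}")
    out = np.empty(len(properties) * len(lags))
    k = 0
    for prop in properties:
        x = np.array([prop.z(c) for c in window.residues])
        dev = x - x.mean()
        for lag in lags:
            out[k] = float(dev[: n - lag] @ dev[lag:]) / (n - lag)
            k += 1
    return out


def encode_pssm(window: PeptideWindow, pssm: PSSMMatrix | None) -> np.ndarray:
    """Window-position-major PSSM scores, 20 per position (380 for flank 9).

    Padding positions (and in-sequence 'X') contribute all-zero rows, as does
    every position when ``pssm`` is None (missing-PSSM fallback).
    """
    flank = window.flank
    n_rows = 0 if pssm is None else pssm.scores.shape[0]
    out = np.zeros((len(window), 20))
    for k, c in enumerate(window.residues):
        if c == "X" or pssm is None:
            continue
        p = window.center_position - flank + k  # 1-based protein coordinate
        if not 1 <= p <= n_rows:
            raise ValueError(
                f"PSSM for {window.protein_id!r} does not cover position {p} "
                f"(has {n_rows} rows)"
            )
        out[k] = pssm.scores[p - 1]
    return out.ravel()


def encode_rc(window: PeptideWindow, count_x: bool = False) -> np.ndarray:
    """Residue composition: frequency of each of the 20 amino acids (A..Y order).

    By default 'X' is excluded from both numerator and denominator so the 20
    frequencies sum to 1; ``count_x=True`` keeps 'X' in the denominator (its
    own mass is not reported), so the sum can fall below 1.
    """
    counts = np.zeros(20)
    n = 0
    for c in window.residues:
        if c == "X":
            n += count_x
            continue
        counts[STANDARD_AA.index(c)] += 1
        n += 1
    return counts / n


def window_ss_letters(
    window: PeptideWindow, annotation: StructureAnnotation | None
) -> list[str]:
    """The 19 per-position SS letters for a window; 'X' marks padding/missing."""
    flank = window.flank
    length = 0 if annotation is None else len(annotation.ss)
    out = []
    for k in range(len(window)):
        p = window.center_position - flank + k
        out.append(annotation.ss[p - 1] if annotation is not None and 1 <= p <= length else "X")
    return out


def window_asa_values(
    window: PeptideWindow, annotation: StructureAnnotation | None
) -> list[float | None]:
    """Per-position ASA values for a window; None marks padding/missing."""
    flank = window.flank
    length = 0 if annotation is None else annotation.asa.shape[0]
    out: list[float | None] = []
    for k in range(len(window)):
        p = window.center_position - flank + k
        out.append(float(annotation.asa[p - 1]) if annotation is not None and 1 <= p <= length else None)
    return out


def encode_ss(letters: Sequence[str]) -> np.ndarray:
    """Position-major 7-bit one-hot secondary-structure encoding.

    Bit layout per position, most significant first: S T I G E B H, so
    H -> 0000001, B -> 0000010, ..., S -> 1000000.  Coil ('-'), padding and
    missing annotation ('X') map to 0000000.
    """
    out = np.zeros((len(letters), 7))
    for i, letter in enumerate(letters):
        if letter in ("-", "X"):
            continue
        idx = _SS_BIT_INDEX.get(letter)
        if idx is None:
            raise ValueError(f"unknown secondary-structure letter {letter!r}")
        out[i, idx] = 1.0
    return out.ravel()


def encode_asa(values: Sequence[float | None]) -> np.ndarray:
    """Raw per-position ASA vector; absent (padding) positions become 0."""
    out = np.zeros(len(values))
    for i, v in enumerate(values):
        if v is None:
            continue
        if v < 0:
            raise ValueError(f"negative ASA value {v}")
        out[i] = v
    return out


# ---------------------------------------------------------------------------
# assembly


class ColumnInfo(NamedTuple):
    """Registry entry: which encoder produced a column and from what."""

    encoder: str
    position: int | None  # window-relative position, or lag for 'ac'
    detail: str | None  # property name, amino acid or SS letter


@dataclass
class FeatureMatrix:
    """Samples x named feature columns with a provenance registry."""

    X: np.ndarray
    columns: list[str]
    registry: dict[str, ColumnInfo]
    labels: np.ndarray | None = None
    meta: list[tuple[str, int]] = field(default_factory=list)  # (protein_id, position)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("feature matrix width != number of column names")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate feature column names")
        if set(self.registry) != set(self.columns):
            raise ValueError("registry does not cover the columns exactly")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains NaN")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != self.X.shape[0]:
                raise ValueError("labels length != sample count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, columns: Sequence[str]) -> "FeatureMatrix":
        """A new matrix restricted to ``columns``, in the given order."""
        idx = [self.columns.index(c) for c in columns]
        return FeatureMatrix(
            X=self.X[:, idx],
            columns=list(columns),
            registry={c: self.registry[c] for c in columns},
            labels=None if self.labels is None else self.labels.copy(),
            meta=list(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        if self.meta:
            df.insert(0, "protein_id", [m[0] for m in self.meta])
            df.insert(1, "position", [m[1] for m in self.meta])
        if self.labels is not None:
            df.insert(2 if self.meta else 0, "label", self.labels)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def parse_column_name(name: str) -> ColumnInfo:
    """Reconstruct a registry entry from a column name written by :func:`assemble`."""
    parts = name.split(":")
    enc = parts[0]
    if enc == "pcp":
        return ColumnInfo("pcp", int(parts[2][1:]), parts[1])
    if enc == "pssm":
        return ColumnInfo("pssm", int(parts[1][1:]), parts[2])
    if enc == "ac":
        return ColumnInfo("ac", int(parts[2][3:]), parts[1])
    if enc == "rc":
        return ColumnInfo("rc", None, parts[1])
    if enc == "ss":
        return ColumnInfo("ss", int(parts[1][1:]), parts[2])
    if enc == "asa":
        return ColumnInfo("asa", int(parts[1][1:]), None)
    raise ValueError(f"unrecognised feature column name {name!r}")


def read_feature_tsv(path: str | Path) -> FeatureMatrix:
    """Read a feature TSV written by :meth:`FeatureMatrix.to_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    meta: list[tuple[str, int]] = []
    labels = None
    if "protein_id" in df.columns:
        meta = list(zip(df.pop("protein_id").astype(str), df.pop("position").astype(int)))
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    columns = list(df.columns)
    registry = {c: parse_column_name(c) for c in columns}
    return FeatureMatrix(
        X=df.to_numpy(dtype=float), columns=columns, registry=registry,
        labels=labels, meta=meta,
    )


def assemble(
    windows: Sequence[PeptideWindow],
    properties: Sequence[NormalizedProperty] | None = None,
    pssms: Mapping[str, PSSMMatrix] | None = None,
    structures: Mapping[str, StructureAnnotation] | None = None,
    encoders: Sequence[str] = DEFAULT_ENCODERS,
    lags: Sequence[int] = (1, 2),
    pcp_include_center: bool = False,
    missing_pssm: str = "error",
    missing_structure: str = "error",
) -> FeatureMatrix:
    """Encode windows into a single feature matrix, blocks in the order
    PCP, PSSM, AC, RC, SS, ASA (only enabled encoders appear).

    With the defaults (4 properties, flank 9, lags {1, 2}) the width is
    72 + 380 + 8 + 20 + 133 + 19 = 632.  ``missing_pssm``/``missing_structure``
    choose between ``'error'`` and ``'zero'`` (all-zero block with a warning)
    when a protein's resource is absent.
    """
    if not windows:
        raise ValueError("no windows to encode")
    for mode, name in ((missing_pssm, "missing_pssm"), (missing_structure, "missing_structure")):
        if mode not in ("error", "zero"):
            raise ValueError(f"{name} must be 'error' or 'zero', got {mode!r}")
    unknown = set(encoders) - set(DEFAULT_ENCODERS)
    if unknown:
        raise ValueError(f"unknown encoders {sorted(unknown)}")
    encoders = [e for e in DEFAULT_ENCODERS if e in encoders]  # canonical order
    flank = windows[0].flank
    if any(w.flank != flank for w in windows):
        raise ValueError("windows have inconsistent flank sizes")

    needs_props = {"pcp", "ac"} & set(encoders)
    if needs_props and not properties:
        raise ValueError(f"encoders {sorted(needs_props)} require property tables")
    properties = properties or []

    def _resource(table: Mapping | None, pid: str, kind: str, mode: str):
        res = None if table is None else table.get(pid)
        if res is None and mode == "error":
            missing_ids = sorted(
                {w.protein_id for w in windows if table is None or w.protein_id not in table}
            )
            raise ValueError(
                f"{kind} missing for protein(s) {missing_ids}; pass the resource "
                f"or set missing_{kind}='zero'"
            )
        return res

    # column names + registry, built once
    columns: list[str] = []
    registry: dict[str, ColumnInfo] = {}

    def _add(name: str, info: ColumnInfo) -> None:
        columns.append(name)
        registry[name] = info

    rel_noncenter = _rel_positions(flank, pcp_include_center)
    rel_all = list(range(-flank, flank + 1))
    for enc in encoders:
        if enc == "pcp":
            for prop in properties:
                for r in rel_noncenter:
                    _add(f"pcp:{prop.name}:p{r:+d}", ColumnInfo("pcp", r, prop.name))
        elif enc == "pssm":
            for r in rel_all:
                for aa in PSSM_ALPHABET:
                    _add(f"pssm:p{r:+d}:{aa}", ColumnInfo("pssm", r, aa))
        elif enc == "ac":
            for prop in properties:
                for lag in lags:
                    _add(f"ac:{prop.name}:lag{lag}", ColumnInfo("ac", lag, prop.name))
        elif enc == "rc":
            for aa in STANDARD_AA:
                _add(f"rc:{aa}", ColumnInfo("rc", None, aa))
        elif enc == "ss":
            for r in rel_all:
                for letter in SS_BIT_ORDER:
                    _add(f"ss:p{r:+d}:{letter}", ColumnInfo("ss", r, letter))
        elif enc == "asa":
            for r in rel_all:
                _add(f"asa:p{r:+d}", ColumnInfo("asa", r, None))

    warned: set[str] = set()
    rows = np.empty((len(windows), len(columns)))
    for i, w in enumerate(windows):
        blocks = []
        for enc in encoders:
            if enc == "pcp":
                blocks.append(encode_pcp(w, properties, include_center=pcp_include_center))
            elif enc == "pssm":
                pssm = _resource(pssms, w.protein_id, "pssm", missing_pssm)
                if pssm is None and w.protein_id not in warned:
                    logger.warning("no PSSM for %s; using zeros", w.protein_id)
                    warned.add(w.protein_id)
                blocks.append(encode_pssm(w, pssm))
            elif enc == "ac":
                blocks.append(encode_ac(w, properties, lags=lags))
            elif enc == "rc":
                blocks.append(encode_rc(w))
            elif enc == "ss":
                ann = _resource(structures, w.protein_id, "structure", missing_structure)
                blocks.append(encode_ss(window_ss_letters(w, ann)))
            elif enc == "asa":
                ann = _resource(structures, w.protein_id, "structure", missing_structure)
                blocks.append(encode_asa(window_asa_values(w, ann)))
        rows[i] = np.concatenate(blocks)

    labels = None
    if all(w.label is not None for w in windows):
        labels = np.array([w.label for w in windows], dtype=int)
    fm = FeatureMatrix(
        X=rows,
        columns=columns,
        registry=registry,
        labels=labels,
        meta=[(w.protein_id, w.center_position) for w in windows],
    )
    logger.info("assembled feature matrix: %d samples x %d columns", fm.n_samples, fm.n_features)
    return fm
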