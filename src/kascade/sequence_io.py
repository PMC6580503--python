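"""Protein and acetylation-site I/O plus peptide-window extraction.

All coordinates are 1-based and inclusive, following biological convention.
Candidate sites are lysine (K) residues; a :class:`PeptideWindow` is the
``2*flank + 1``-residue fragment centred on one, padded with ``'X'`` where the
chain ends leave fewer than ``flank`` residues on a side.  Ambiguous amino-acid
letters (B, Z, J, U, O, ``*`` and anything else non-standard) are normalised to
``'X'`` on input and treated identically to padding by every encoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: Default number of residues on each side of the centre lysine (window 19).
DEFAULT_FLANK = 9


class FastaParseError(ValueError):
    """A FASTA record could not be parsed or validated."""


class SiteValidationError(ValueError):
    """A site record is inconsistent with its protein sequence."""


def normalize_sequence(raw: str) -> str:
    """Uppercase a sequence and collapse every non-standard letter to 'X'."""
    up = raw.upper()
    return "".join(c if c in _STANDARD_SET else "X" for c in up)


@dataclass(frozen=True)
class Protein:
    """A protein chain over the 20 standard letters plus 'X'."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD_SET - {"X"}
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid letters {sorted(bad)}; "
                "normalise with normalize_sequence() first"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """One candidate lysine with its experimental label (1 positive, 0 negative)."""

    protein_id: str
    position: int  # 1-based
    label: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class PeptideWindow:
    """A ``2*flank+1``-mer centred on a lysine, 'X'-padded at chain ends."""

    protein_id: str
    center_position: int
    residues: str
    label: int | None = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n % 2 != 1:
            raise ValueError(f"window length must be odd, got {n}")
        if self.residues[n // 2] != "K":
            raise ValueError(
                f"window centre must be 'K', got {self.residues[n // 2]!r} "
                f"({self.protein_id} position {self.center_position})"
            )

    @property
    def flank(self) -> int:
        return len(self.residues) // 2

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[Protein]:
    """Read a FASTA file into a list of :class:`Protein`, in file order.

    Non-standard letters are normalised to 'X'.  An empty file yields an empty
    list (with a warning); a record with an empty sequence raises
    :class:`FastaParseError` naming the record.
    """
    path = Path(path)
    proteins: list[Protein] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = normalize_sequence(str(rec.seq))
        if not rec.id:
            raise FastaParseError(f"{path}: record {i + 1} has no identifier")
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        proteins.append(Protein(id=rec.id, sequence=seq))
    if not proteins:
        logger.warning("no FASTA records found in %s", path)
    return proteins


def write_fasta(proteins: list[Protein], path: str | Path, width: int = 60) -> None:
    """Write proteins as FASTA with fixed line wrapping (deterministic output)."""
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for start in range(0, len(p.sequence), width):
                fh.write(p.sequence[start : start + width] + "\n")


def enumerate_lysines(protein: Protein) -> list[int]:
    """All 1-based positions of 'K' in the protein, ascending."""
    return [i + 1 for i, c in enumerate(protein.sequence) if c == "K"]


def extract_window(
    protein: Protein,
    position: int,
    flank: int = DEFAULT_FLANK,
    label: int | None = None,
) -> PeptideWindow:
    """Extract the ``2*flank+1`` window centred at ``position`` (1-based).

    Positions before the N-terminus or past the C-terminus are filled with
    'X'.  The residue at ``position`` must be 'K'.
    """
    n = len(protein)
    if not 1 <= position <= n:
        raise IndexError(
            f"position {position} out of range for protein {protein.id!r} (length {n})"
        )
    if protein.sequence[position - 1] != "K":
        raise SiteValidationError(
            f"protein {protein.id!r} position {position}: residue is "
            f"{protein.sequence[position - 1]!r}, expected 'K'"
        )
    chars = []
    for p in range(position - flank, position + flank + 1):
        chars.append(protein.sequence[p - 1] if 1 <= p <= n else "X")
    return PeptideWindow(
        protein_id=protein.id,
        center_position=position,
        residues="".join(chars),
        label=label,
    )


def site_windows(
    proteins: list[Protein] | dict[str, Protein],
    sites: list[SiteRecord],
    flank: int = DEFAULT_FLANK,
) -> list[PeptideWindow]:
    """Extract one window per site record, preserving site order."""
    index = proteins if isinstance(proteins, dict) else {p.id: p for p in proteins}
    out = []
    for s in sites:
        try:
            prot = index[s.protein_id]
        except KeyError:
            raise KeyError(f"site references unknown protein {s.protein_id!r}") from None
        out.append(extract_window(prot, s.position, flank=flank, label=s.label))
    return out


def read_site_table(
    path: str | Path,
    proteins: list[Protein] | dict[str, Protein] | None = None,
    on_invalid: str = "raise",
) -> list[SiteRecord]:
    """Read a TSV of sites (columns ``protein_id``, ``position``, ``label``).

    Positions are 1-based; labels are serialised as ``1``/``0``.  When
    ``proteins`` is given each row is validated (known protein, position in
    range, residue 'K').  ``on_invalid='raise'`` (default) raises on the first
    bad row; ``'drop'`` discards invalid rows and logs how many were rejected.
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError(f"on_invalid must be 'raise' or 'drop', got {on_invalid!r}")
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: site table missing columns {sorted(missing)}")
    index: dict[str, Protein] | None = None
    if proteins is not None:
        index = proteins if isinstance(proteins, dict) else {p.id: p for p in proteins}

    records: list[SiteRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=True):
        problem = None
        pid, pos, lab = str(row.protein_id), int(row.position), int(row.label)
        if lab not in (0, 1):
            problem = f"label {lab!r} not in {{0,1}}"
        elif index is not None:
            prot = index.get(pid)
            if prot is None:
                problem = f"unknown protein {pid!r}"
            elif not 1 <= pos <= len(prot):
                problem = f"position {pos} out of range (length {len(prot)})"
            elif prot.sequence[pos - 1] != "K":
                problem = f"residue at {pos} is {prot.sequence[pos - 1]!r}, not 'K'"
        if problem is None:
            records.append(SiteRecord(protein_id=pid, position=pos, label=lab))
        elif on_invalid == "raise":
            raise SiteValidationError(f"{path}: row {row.Index + 1}: {problem}")
        else:
            n_rejected += 1
    if n_rejected:
        logger.warning("%s: rejected %d invalid site rows", path, n_rejected)
    return records


def write_site_table(sites: list[SiteRecord], path: str | Path) -> None:
    """Write sites as the TSV dialect read by :func:`read_site_table`."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.label}\n")
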