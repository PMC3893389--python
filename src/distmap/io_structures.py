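"""Readers/writers for the structure, alignment and annotation formats the
pipeline touches, plus the domain types they normalize into.

Coordinates are in Angstrom throughout; residue indexing inside the package
is 0-based with half-open ranges.  Original PDB residue numbers are kept
only for round-tripping.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

AA1 = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."

#: DSSP 8-state -> 3-state collapse: helices (H, G, I) -> H,
#: strand/bridge (E, B) -> E, everything else -> C.
DSSP_3STATE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C", "P": "C",
}

#: gap between consecutive CA atoms above which a chain-break warning is logged
CHAIN_BREAK_CUTOFF = 4.2


class PdbFormatError(ValueError):
    """Raised for malformed or unusable PDB input."""


@dataclass
class CaTrace:
    """Ordered Calpha coordinates of one protein chain.

    Parameters
    ----------
    coords
        (L, 3) float array of Calpha positions in Angstrom.
    sequence
        One-letter amino-acid string of length L ('X' when unknown).
    residue_ids
        Ordered list of (chain_id, residue_number) pairs; defaults to
        chain 'A' numbered from 1.
    """

    coords: np.ndarray
    sequence: str = ""
    residue_ids: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (L, 3) array")
        n = len(self.coords)
        if n < 2:
            raise ValueError("a CaTrace needs at least 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.sequence:
            self.sequence = "X" * n
        if len(self.sequence) != n:
            raise ValueError("sequence length must match coords")
        if not self.residue_ids:
            self.residue_ids = [("A", i + 1) for i in range(n)]
        if len(self.residue_ids) != n:
            raise ValueError("residue_ids length must match coords")
        if len(set(self.residue_ids)) != n:
            raise ValueError("duplicate residue identifiers")

    def __len__(self) -> int:
        return len(self.coords)

    def with_coords(self, coords: np.ndarray) -> "CaTrace":
        return CaTrace(np.asarray(coords, float), self.sequence, list(self.residue_ids))


@dataclass
class SecondaryStructure:
    """Three-state secondary-structure string over {H, E, C}."""

    states: str

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("empty secondary-structure string")
        bad = set(self.states) - set("HEC")
        if bad:
            raise ValueError(f"unknown secondary-structure state(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def segments(self) -> list[tuple[str, int, int]]:
        """Maximal runs as (state, start, end) with half-open [start, end)."""
        segs = []
        start = 0
        for i in range(1, len(self.states) + 1):
            if i == len(self.states) or self.states[i] != self.states[start]:
                segs.append((self.states[start], start, i))
                start = i
        return segs

    def strand_runs(self) -> list[tuple[int, int]]:
        """Half-open [start, end) spans of every maximal E-run."""
        return [(a, b) for s, a, b in self.segments if s == "E"]


@dataclass
class Msa:
    """A multiple sequence alignment; row ``query_index`` is the query."""

    rows: list[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: row {i} has length {len(row)}, expected {width}"
                )
        if not 0 <= self.query_index < len(self.rows):
            raise ValueError("query_index out of range")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


# ---------------------------------------------------------------------------
# PDB (CA-subset)
# ---------------------------------------------------------------------------

_AA3TO1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}
_AA1TO3["X"] = "UNK"


def read_ca_trace(pdb_text: str, chain: str = "first") -> CaTrace:
    """Extract the Calpha trace of one chain from PDB-format text.

    Only ATOM records with atom name CA are considered.  For alternate
    locations the highest-occupancy copy is kept (ties: first seen).
    Residues are emitted in residue-number order; a warning is logged when
    consecutive Calpha atoms are more than 4.2 A apart (possible chain
    break -- the chain is still treated as contiguous).
    """
    # residue key -> (occupancy, serial, coord, aa1)
    per_residue: dict[tuple[str, int, str], tuple[float, int, np.ndarray, str]] = {}
    chains_seen: list[str] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise PdbFormatError(f"malformed ATOM line {lineno}: too short")
        name = line[12:16].strip()
        if name != "CA":
            continue
        try:
            serial = int(line[6:11])
            resseq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PdbFormatError(f"malformed ATOM line {lineno}: {exc}") from None
        ch = line[21]
        if ch not in chains_seen:
            chains_seen.append(ch)
        occ = 1.0
        if len(line) >= 60 and line[54:60].strip():
            try:
                occ = float(line[54:60])
            except ValueError:
                raise PdbFormatError(f"malformed ATOM line {lineno}: bad occupancy")
        icode = line[26] if len(line) > 26 else " "
        aa = _AA3TO1.get(line[17:20].strip(), "X")
        key = (ch, resseq, icode)
        if key in per_residue and per_residue[key][0] >= occ:
            continue  # keep higher occupancy; ties keep the first
        if key in per_residue and per_residue[key][0] == occ:
            continue
        per_residue[key] = (occ, serial, np.array([x, y, z]), aa)

    if not chains_seen:
        raise PdbFormatError("no CA ATOM records found")
    target = chains_seen[0] if chain == "first" else chain
    keys = sorted(
        (k for k in per_residue if k[0] == target), key=lambda k: (k[1], k[2])
    )
    if not keys:
        raise PdbFormatError(f"no CA atoms for chain {target!r}")
    if len(keys) < 2:
        raise PdbFormatError(f"chain {target!r} has fewer than 2 CA atoms")
    coords = np.array([per_residue[k][2] for k in keys])
    seq = "".join(per_residue[k][3] for k in keys)
    rids = [(k[0], k[1]) for k in keys]
    if len(set(rids)) != len(rids):  # insertion codes collapsing onto one number
        rids = [(k[0], i + 1) for i, k in enumerate(keys)]
    gaps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    n_breaks = int(np.sum(gaps > CHAIN_BREAK_CUTOFF))
    if n_breaks:
        log.warning(
            "chain %s: %d consecutive-CA gap(s) > %.1f A; treating as contiguous",
            target, n_breaks, CHAIN_BREAK_CUTOFF,
        )
    return CaTrace(coords, seq, rids)


def write_pdb(trace: CaTrace) -> str:
    """Render a CaTrace as fixed-column PDB text (one CA ATOM per residue)."""
    lines = []
    for i, ((ch, resnum), xyz) in enumerate(zip(trace.residue_ids, trace.coords)):
        res3 = _AA1TO3.get(trace.sequence[i], "UNK")
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {res3:>3s} {ch[:1]}{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_msa(fasta_text: str, query_index: int = 0) -> Msa:
    """Parse an aligned FASTA into an :class:`Msa` (query = first record)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    rows = [str(r.seq) for r in records]
    width = len(rows[0])
    for rec, row in zip(records, rows):
        if len(row) != width:
            raise ValueError(
                f"ragged alignment: record {rec.id!r} has length {len(row)}, "
                f"expected {width}"
            )
    return Msa(rows, query_index=query_index)


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def read_ss(text: str) -> SecondaryStructure:
    """Parse secondary structure from a 3-state/8-state string or DSSP output.

    A plain string may use the 3 states H/E/C directly or any DSSP 8-state
    code, which is collapsed as H,G,I->H; E,B->E; rest->C.  Full DSSP output
    files (with the '#  RESIDUE' header) are also accepted: the structure
    code is taken from column 17 of each residue line.
    """
    if not text.strip():
        raise ValueError("empty secondary-structure input")
    if "#  RESIDUE" in text:
        states = []
        in_body = False
        for line in text.splitlines():
            if "#  RESIDUE" in line:
                in_body = True
                continue
            if not in_body or len(line) < 17:
                continue
            if line[13] == "!":  # chain break marker
                continue
            states.append(line[16] if line[16] != " " else "C")
        raw = "".join(states)
        if not raw:
            raise ValueError("DSSP file contains no residue lines")
    else:
        raw = text.strip().upper()
    collapsed = []
    for ch in raw:
        if ch not in DSSP_3STATE:
            raise ValueError(f"unknown secondary-structure state {ch!r}")
        collapsed.append(DSSP_3STATE[ch])
    return SecondaryStructure("".join(collapsed))
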