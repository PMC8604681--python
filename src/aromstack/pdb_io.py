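"""Reading and writing PDB-format structures, plus structure-level filters.

Parsing is delegated to :mod:`gemmi`; this module adapts the result into the
small immutable containers the rest of the package works with (ordinal residue
indices along each chain, one coordinate set per atom name after alternate
locations are resolved) and applies the dataset filters used to build a
nonredundant X-ray structure set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "ParseError",
    "StructureMeta",
    "Residue",
    "Chain",
    "Structure",
    "read_structure",
    "write_structure",
    "passes_filters",
]

log = logging.getLogger(__name__)

#: 3-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class ParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


@dataclass(frozen=True)
class StructureMeta:
    """Experimental metadata: method (e.g. ``X-RAY DIFFRACTION``) and resolution in Å."""

    method: str | None = None
    resolution: float | None = None

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")


@dataclass
class Residue:
    """One residue: ordinal index along its chain, author numbering and atoms.

    ``seq_index`` is the 1-based ordinal of the residue in order of appearance;
    sequence separation is always computed on these ordinals, not on author
    residue numbers (robust to numbering gaps and insertion codes).
    """

    seq_index: int
    name: str
    auth_seqid: str  # author resSeq plus insertion code, e.g. "52" or "52A"
    atoms: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    meta: StructureMeta = field(default_factory=StructureMeta)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain identifiers")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


def _validate_atom_lines(pdb_text: str) -> int:
    """Check coordinate fields of ATOM/HETATM records; return the record count."""
    n = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n += 1
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fld = line[lo:hi]
            try:
                float(fld)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed {what} coordinate field {fld!r}"
                ) from None
    return n


def _resolve_altlocs(residue: gemmi.Residue) -> dict[str, np.ndarray]:
    """Keep one position per atom name: highest occupancy, ties prefer altloc 'A'
    then the lexicographically smallest altloc."""
    groups: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        groups.setdefault(atom.name, []).append(atom)
    out: dict[str, np.ndarray] = {}
    for name, atoms in groups.items():
        best = min(
            atoms,
            key=lambda a: (-a.occ, a.altloc != "A", a.altloc),
        )
        out[name] = np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float)
    return out


def read_structure(pdb_text: str, structure_id: str | None = None) -> Structure:
    """Parse PDB text into a :class:`Structure` (first MODEL only).

    Alternate locations are resolved to a single atom per name; residues are
    keyed by (chain, resSeq, iCode) and assigned ordinal ``seq_index`` by order
    of appearance.

    Raises
    ------
    ParseError
        If the text contains no ATOM record or a coordinate field is malformed.
    """
    if not pdb_text.strip():
        raise ParseError("empty input")
    if _validate_atom_lines(pdb_text) == 0:
        raise ParseError("no ATOM records found")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ParseError("no model found")
    info = dict(st.info)
    method = info.get("_exptl.method") or None
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    meta = StructureMeta(method=method, resolution=resolution)

    model = st[0]  # first MODEL only
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for i, gres in enumerate(gchain, start=1):
            icode = gres.seqid.icode.strip()
            residues.append(
                Residue(
                    seq_index=i,
                    name=gres.name,
                    auth_seqid=f"{gres.seqid.num}{icode}",
                    atoms=_resolve_altlocs(gres),
                )
            )
        chains.append(Chain(chain_id=gchain.name, residues=residues))
    name = st.name if st.name not in ("", "string") else None  # gemmi placeholder
    sid = structure_id or info.get("_entry.id") or name or "struct"
    return Structure(id=sid, chains=chains, meta=meta)


_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resn:>3s} {chain:1s}{resseq:>4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}"
)


def _atom_name_field(name: str) -> str:
    # PDB convention: single-letter elements start in column 14
    return f" {name:<3s}" if len(name) < 4 else name


def write_structure(structure: Structure) -> str:
    """Serialize a :class:`Structure` to minimal PDB text (ATOM/TER/END)."""
    lines: list[str] = []
    if structure.meta.method:
        lines.append(f"EXPDTA    {structure.meta.method}")
    if structure.meta.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.meta.resolution:7.2f} ANGSTROMS."
        )
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            # author numbering: split trailing insertion code if present
            sid = res.auth_seqid
            icode = sid[-1] if sid and sid[-1].isalpha() else " "
            num = int(sid[:-1]) if icode != " " else int(sid)
            for name, xyz in res.atoms.items():
                serial += 1
                lines.append(
                    _ATOM_FMT.format(
                        serial=serial,
                        name=_atom_name_field(name),
                        altloc=" ",
                        resn=res.name,
                        chain=chain.chain_id[:1] or "A",
                        resseq=num,
                        icode=icode,
                        x=xyz[0],
                        y=xyz[1],
                        z=xyz[2],
                        occ=1.0,
                        b=0.0,
                        elem=name[0],
                    )
                )
        serial += 1
        lines.append(f"TER   {serial:>5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def passes_filters(meta: StructureMeta, n_residues: int) -> bool:
    """Dataset filter: X-ray structures, resolution strictly better than 3 Å,
    at least 40 residues. Entries lacking a resolution are rejected."""
    if meta.method is None or "X-RAY" not in meta.method.upper():
        return False
    if meta.resolution is None or not meta.resolution < 3.0:
        return False
    return n_residues >= 40
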