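"""Structure and table I/O.

Reads protein coordinates from PDB text (ATOM/MODEL records), reads
delimited data tables against a declared schema, and writes structures
whose B-factor column carries an arbitrary per-residue quantity so any
molecular viewer can colour by it.

Residue numbering is 1-based as in the PDB and residue intervals are
closed. Hetero atoms, waters and hydrogens are excluded by default:
heavy-atom surface area is the crystallographic convention and typical
X-ray depositions carry no hydrogens.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._tables import AA_1TO3, AA_3TO1, STANDARD_AA

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identity of one residue: chain label, 1-based number, one-letter code."""

    chain: str
    number: int
    code: str

    def __post_init__(self) -> None:
        if self.number < 1:
            raise ValueError(f"residue number must be >= 1, got {self.number}")
        if self.code not in STANDARD_AA and self.code != "X":
            raise ValueError(f"unknown residue code {self.code!r}")

    def __str__(self) -> str:
        return f"{self.chain}:{self.code}{self.number}"

    @classmethod
    def parse(cls, text: str) -> "ResidueId":
        """Parse 'A:W17' style residue labels."""
        chain, _, rest = text.strip().partition(":")
        if not rest or len(chain) != 1:
            raise ValueError(f"cannot parse residue label {text!r}")
        return cls(chain=chain, number=int(rest[1:]), code=rest[0])


@dataclass(frozen=True)
class SiteAssignment:
    """A mapped oxidation site: one residue, or two sequence-adjacent
    candidates when the MS/MS localization is ambiguous."""

    residues: tuple[ResidueId, ...]
    ambiguous: bool = False

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n not in (1, 2):
            raise ValueError("a site covers 1 or 2 residues")
        if n == 2:
            a, b = sorted(self.residues, key=lambda r: r.number)
            if a.chain != b.chain or b.number - a.number != 1:
                raise ValueError("ambiguous site residues must be sequence-adjacent")
            if not self.ambiguous:
                raise ValueError("two-residue sites must be flagged ambiguous")

    def __str__(self) -> str:
        return "|".join(str(r) for r in self.residues)

    @classmethod
    def parse(cls, text: str) -> "SiteAssignment":
        parts = [ResidueId.parse(p) for p in text.split("|")]
        return cls(residues=tuple(parts), ambiguous=len(parts) > 1)


@dataclass(frozen=True)
class Atom:
    residue: ResidueId
    name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class Structure:
    """A single-model protein structure: atoms plus per-chain sequence."""

    atoms: list[Atom]
    sequence: dict[str, list[ResidueId]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            seq: dict[str, list[ResidueId]] = {}
            for atom in self.atoms:
                lst = seq.setdefault(atom.residue.chain, [])
                if not lst or lst[-1] != atom.residue:
                    lst.append(atom.residue)
            self.sequence = seq

    @property
    def residues(self) -> list[ResidueId]:
        return [r for chain in self.sequence.values() for r in chain]

    def chain_sequence(self, chain: str) -> str:
        return "".join(r.code for r in self.sequence[chain])


class StructureParseError(ValueError):
    pass


def _element_from_record(line: str, atom_name: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if elem:
        return elem.capitalize()
    # fall back to the first alphabetic character of the atom name
    stripped = atom_name.strip("0123456789 ")
    return stripped[0].upper() if stripped else "C"


def read_structure(
    path: str | Path,
    model_index: int = 1,
    include_hydrogens: bool = False,
) -> Structure:
    """Read one model of a PDB file as a :class:`Structure`.

    Keeps non-hydrogen, non-water ATOM records only; alternate locations
    are resolved to the highest-occupancy conformer. ``model_index`` is
    1-based; files without MODEL records are treated as a single model.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise StructureParseError(f"cannot read {path}: {exc}") from exc

    current_model = 1
    saw_model_records = False
    # key -> (occupancy, Atom); key identifies the atom irrespective of altloc
    best: dict[tuple, tuple[float, Atom]] = {}
    order: list[tuple] = []

    for line in text.splitlines():
        record = line[:6].strip()
        if record == "MODEL":
            saw_model_records = True
            current_model = int(line.split()[1])
            continue
        if record == "ENDMDL":
            current_model += 0  # next MODEL record sets the index
            continue
        if record != "ATOM":
            continue
        if saw_model_records and current_model != model_index:
            continue
        resname = line[17:20].strip()
        if resname in _WATER_NAMES:
            continue
        atom_name = line[12:16].strip()
        element = _element_from_record(line, atom_name)
        if element == "H" and not include_hydrogens:
            continue
        chain = line[21].strip() or "A"
        try:
            resnum = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise StructureParseError(f"malformed ATOM record: {line!r}") from exc
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        code = AA_3TO1.get(resname, "X")
        atom = Atom(ResidueId(chain, resnum, code), atom_name, element, x, y, z)
        key = (chain, resnum, atom_name)
        if key not in best:
            order.append(key)
            best[key] = (occupancy, atom)
        elif occupancy > best[key][0]:
            best[key] = (occupancy, atom)

    atoms = [best[k][1] for k in order]
    if not atoms:
        raise StructureParseError(
            f"model {model_index} of {path} contains no protein atoms"
        )
    return Structure(atoms=atoms)


@dataclass
class TableSchema:
    """Declared columns for a delimited table: required name->dtype and
    optional name->(dtype, default)."""

    required: dict[str, type]
    optional: dict[str, tuple[type, object]] = field(default_factory=dict)


#: Schema of the oxidation dose-response table emitted by MS quantification.
RATES_TABLE_SCHEMA = TableSchema(
    required={
        "peptide_id": str,
        "site": str,
        "mod_mass": float,
        "time_ms": float,
        "area_unmod": float,
        "area_mod": float,
    },
    optional={"replicate": (str, "1")},
)

#: Schema of BRET dose-response tables.
BRET_TABLE_SCHEMA = TableSchema(
    required={"ligand": str, "conc_M": float, "response": float},
    optional={
        "construct": (str, "WT"),
        "session": (str, "1"),
        "replicate": (str, "1"),
    },
)


class TableSchemaError(ValueError):
    pass


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a comma- or tab-delimited table against a schema.

    The delimiter is auto-detected from the header line; column order is
    free; unknown columns are kept but logged; missing optional columns are
    filled with their declared defaults.
    """
    path = Path(path)
    header = path.open().readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]

    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise TableSchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    known = set(schema.required) | set(schema.optional)
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, ", ".join(extra))

    for col, dtype in schema.required.items():
        df[col] = _coerce(df, col, dtype, path)
    for col, (dtype, default) in schema.optional.items():
        if col not in df.columns:
            df[col] = default
        df[col] = _coerce(df, col, dtype, path)
    return df


def _coerce(df: pd.DataFrame, col: str, dtype: type, path: Path) -> pd.Series:
    if dtype is str:
        return df[col].astype(str)
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise TableSchemaError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
            f"in column {col!r} (line {row})"
        )
    return converted.astype(float)


_B_MIN, _B_MAX = -99.99, 999.99


def write_annotated_structure(
    structure: Structure,
    values: dict[ResidueId, float],
    path: str | Path,
    sentinel: float = 0.0,
) -> None:
    """Write a PDB file whose B-factor column carries ``values`` per residue.

    Residues absent from ``values`` get ``sentinel``; values outside the
    fixed-width B-factor field are clamped with a warning. Only ATOM and
    TER records are written, so the output colours cleanly in any viewer.
    """
    path = Path(path)
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for atom in structure.atoms:
        if prev_chain is not None and atom.residue.chain != prev_chain:
            lines.append("TER")
        prev_chain = atom.residue.chain
        serial += 1
        b = values.get(atom.residue, sentinel)
        if b < _B_MIN or b > _B_MAX:
            clamped = min(max(b, _B_MIN), _B_MAX)
            warnings.warn(
                f"B-factor {b} for {atom.residue} clamped to {clamped}",
                stacklevel=2,
            )
            b = clamped
        resname = AA_1TO3.get(atom.residue.code, "UNK")
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        lines.append(
            f"ATOM  {serial:>5d} {name:<4s}{'':1s}{resname:>3s} "
            f"{atom.residue.chain:1s}{atom.residue.number:>4d}    "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{1.00:6.2f}{b:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
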