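"""Domain types and parsing for antibody V regions, mutations and Fab structures.

The unit of analysis is the antibody variable (V) region: a heavy- or
light-chain sequence partitioned into framework regions (FR1..FR4) and
complementarity-determining regions (CDR1..CDR3).  Point mutations are
written in ``HC:G54I`` notation — chain, wild-type residue, 1-based position
in the mature V region, mutant residue.  No Kabat/IMGT renumbering is done:
positions index the mature sequence directly and region labels are supplied
as annotations, never computed.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class MutationParseError(ValueError):
    """Raised for malformed mutation notation."""


class SequenceError(ValueError):
    """Raised for invalid sequences or inconsistent mutation application."""


class StructureError(ValueError):
    """Raised for invalid or unusable structural input."""


# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class VRegionSequence:
    """An antibody V-region amino-acid sequence with region annotations.

    ``region_map`` assigns each position one label from FR1..FR4 / CDR1..CDR3,
    and labels must appear in the canonical FR1, CDR1, FR2, CDR2, FR3, CDR3,
    FR4 order (trailing regions may be absent for fragments).
    """

    chain_kind: str                 # "heavy" | "light"
    residues: str                   # one-letter codes
    region_map: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.chain_kind not in ("heavy", "light"):
            raise SequenceError(f"chain_kind must be heavy/light, got {self.chain_kind!r}")
        if len(self.residues) != len(self.region_map):
            raise SequenceError("region_map length must equal sequence length")
        bad = set(self.residues) - set(AA1)
        if bad:
            raise SequenceError(f"non-standard amino acids: {sorted(bad)}")
        seen: list[str] = []
        for label in self.region_map:
            if label not in REGION_ORDER:
                raise SequenceError(f"unknown region label {label!r}")
            if not seen or seen[-1] != label:
                seen.append(label)
        order = [r for r in REGION_ORDER if r in seen]
        if seen != order:
            raise SequenceError(f"region labels out of canonical order: {seen}")

    def __len__(self) -> int:
        return len(self.residues)

    def framework_only(self) -> str:
        """Concatenated framework residues (CDR positions masked out)."""
        return "".join(
            aa for aa, lab in zip(self.residues, self.region_map) if lab.startswith("FR")
        )


@dataclass(frozen=True)
class PointMutation:
    """A single substitution, e.g. ``HC:G54I``.

    ``position`` is 1-based into the mature V region.  ``identity`` permits
    wt == mut, used only for scanner self-tests.
    """

    chain: str              # "HC" | "LC"
    position: int
    wt_aa: str
    mut_aa: str
    location_label: str = ""
    identity: bool = False

    def __post_init__(self) -> None:
        if self.chain not in ("HC", "LC"):
            raise MutationParseError(f"chain must be HC or LC, got {self.chain!r}")
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AA1:
                raise MutationParseError(f"non-standard amino acid {aa!r}")
        if self.wt_aa == self.mut_aa and not self.identity:
            raise MutationParseError(
                f"identity mutation {self.notation()} not allowed unless flagged"
            )

    def notation(self) -> str:
        return f"{self.chain}:{self.wt_aa}{self.position}{self.mut_aa}"


_MUT_RE = re.compile(r"^\s*(HC|LC)\s*:\s*([A-Za-z])(\d+)([A-Za-z])\s*$",
                     re.IGNORECASE)


def parse_mutation_notation(text: str, location_label: str = "",
                            allow_identity: bool = False) -> PointMutation:
    """Parse ``"HC:G54I"``-style notation into a :class:`PointMutation`."""
    m = _MUT_RE.match(text)
    if not m:
        raise MutationParseError(f"malformed mutation string {text!r}")
    chain = m.group(1).upper()
    wt, pos, mut = m.group(2).upper(), int(m.group(3)), m.group(4).upper()
    if wt not in AA1:
        raise MutationParseError(f"non-standard amino acid {wt!r} in {text!r}")
    if mut not in AA1:
        raise MutationParseError(f"non-standard amino acid {mut!r} in {text!r}")
    if pos < 1:
        raise MutationParseError(f"position 0 in {text!r}")
    return PointMutation(chain=chain, position=pos, wt_aa=wt, mut_aa=mut,
                         location_label=location_label,
                         identity=allow_identity and wt == mut)


def _chain_code(seq: VRegionSequence) -> str:
    return "HC" if seq.chain_kind == "heavy" else "LC"


def apply_mutations(seq: VRegionSequence, muts: list[PointMutation]) -> VRegionSequence:
    """Apply substitutions to a V region; region annotations are unchanged."""
    positions = [m.position for m in muts]
    if len(set(positions)) != len(positions):
        raise SequenceError("duplicate mutation positions")
    res = list(seq.residues)
    code = _chain_code(seq)
    for m in muts:
        if m.chain != code:
            raise SequenceError(f"mutation {m.notation()} targets {m.chain}, sequence is {code}")
        if m.position > len(res):
            raise SequenceError(f"position {m.position} beyond sequence length {len(res)}")
        found = res[m.position - 1]
        if found != m.wt_aa:
            raise SequenceError(
                f"wild-type mismatch at {m.position}: expected {m.wt_aa}, found {found}"
            )
        res[m.position - 1] = m.mut_aa
    return replace(seq, residues="".join(res))


def diff_sequences(a: VRegionSequence, b: VRegionSequence) -> list[PointMutation]:
    """Point mutations turning ``a`` into ``b`` (sorted by position)."""
    if len(a) != len(b):
        raise SequenceError(f"length mismatch: {len(a)} vs {len(b)}")
    if a.chain_kind != b.chain_kind:
        raise SequenceError("chain kinds differ")
    code = _chain_code(a)
    return [
        PointMutation(chain=code, position=i + 1, wt_aa=x, mut_aa=y)
        for i, (x, y) in enumerate(zip(a.residues, b.residues))
        if x != y
    ]


# ---------------------------------------------------------------------------
# FASTA and region annotations

def read_fasta_vregions(handle_or_path, region_map_by_name: dict | None = None):
    """Read V regions from FASTA; descriptions are ``name|heavy`` / ``name|light``.

    Without a region map a single FR1 pseudo-annotation is assigned (enough
    for full-length scoring; framework-only scoring needs real annotations).
    """
    out = []
    for rec in SeqIO.parse(handle_or_path, "fasta"):
        desc = rec.description
        if "|" not in desc:
            raise SequenceError(f"FASTA description {desc!r} lacks '|heavy'/'|light' tag")
        name, kind = desc.rsplit("|", 1)
        kind = kind.strip().lower()
        seq = str(rec.seq).upper()
        if region_map_by_name and name.strip() in region_map_by_name:
            rmap = tuple(region_map_by_name[name.strip()])
        else:
            rmap = ("FR1",) * len(seq)
        out.append(VRegionSequence(chain_kind=kind, residues=seq,
                                   region_map=rmap, name=name.strip()))
    return out


def write_fasta_vregions(seqs, handle_or_path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=f"{s.name}|{s.chain_kind}",
                  description="")
        for s in seqs
    ]
    SeqIO.write(records, handle_or_path, "fasta")


def read_region_annotations(handle_or_path) -> dict[str, tuple[str, ...]]:
    """Read a region-annotation CSV (columns chain, start, end, label).

    Returns per-chain position->label tuples; start/end are 1-based inclusive.
    """
    import pandas as pd

    df = pd.read_csv(handle_or_path)
    need = {"chain", "start", "end", "label"}
    if not need.issubset(df.columns):
        raise SequenceError(f"annotation CSV must have columns {sorted(need)}")
    out: dict[str, tuple[str, ...]] = {}
    for chain, grp in df.groupby("chain"):
        grp = grp.sort_values("start")
        labels: list[str] = []
        for _, row in grp.iterrows():
            if int(row["start"]) != len(labels) + 1:
                raise SequenceError(f"annotation gap/overlap at {chain}:{row['start']}")
            labels.extend([str(row["label"])] * (int(row["end"]) - int(row["start"]) + 1))
        out[str(chain)] = tuple(labels)
    return out


# ---------------------------------------------------------------------------
# structures


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray          # shape (3,), Å

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.xyz.copy())


@dataclass
class Residue:
    name: str                # 3-letter code
    seq_number: int
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not in {self.name}{self.seq_number}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def has_complete_backbone(self) -> bool:
        return all(self.has_atom(n) for n in BACKBONE_ATOMS)

    @property
    def aa1(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_number, [a.copy() for a in self.atoms], self.icode)


@dataclass
class ChainModel:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.aa1 for r in self.residues)

    def copy(self) -> "ChainModel":
        return ChainModel(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class FabStructure:
    """Atomic model of a Fab (or any small protein) for the energy scanner."""

    chains: list[ChainModel] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def residue(self, chain_id: str, seq_number: int) -> Residue:
        for r in self.chain(chain_id).residues:
            if r.seq_number == seq_number:
                return r
        raise KeyError(f"no residue {chain_id}:{seq_number}")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def copy(self) -> "FabStructure":
        return FabStructure([c.copy() for c in self.chains], list(self.warnings))


def read_pdb(source) -> FabStructure:
    """Read ATOM records from PDB text or a path into a :class:`FabStructure`.

    HETATM records and waters are ignored; altlocs resolve to the highest
    occupancy; hydrogens are dropped (the energy model is heavy-atom only).
    Residues with an incomplete backbone are kept out of the model and
    reported in ``FabStructure.warnings``.
    """
    if isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    else:
        handle = source
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("fab", handle)
    model = next(iter(structure), None)
    fab = FabStructure()
    if model is None:
        raise StructureError("no ATOM records found")
    seen_ids = set()
    for chain in model:
        if chain.id in seen_ids:
            raise StructureError(f"duplicate chain id {chain.id!r}")
        seen_ids.add(chain.id)
        cm = ChainModel(chain_id=chain.id)
        for res in chain:
            hetflag, seqnum, icode = res.id
            if hetflag.strip():            # HETATM / water
                continue
            rr = Residue(name=res.get_resname().strip(), seq_number=seqnum,
                         icode=icode.strip())
            for atom in res:
                if atom.element == "H" or atom.get_name().startswith("H"):
                    continue
                # Bio.PDB disordered atoms already select highest occupancy
                rr.atoms.append(Atom(name=atom.get_name(),
                                     element=(atom.element or atom.get_name()[0]).upper(),
                                     xyz=np.asarray(atom.coord, dtype=float)))
            if not rr.atoms:
                continue
            if not np.all(np.isfinite(np.array([a.xyz for a in rr.atoms]))):
                raise StructureError(f"non-finite coordinates in {chain.id}:{seqnum}")
            if not rr.has_complete_backbone():
                fab.warnings.append(
                    f"{chain.id}:{rr.name}{seqnum} incomplete backbone, excluded"
                )
                continue
            cm.residues.append(rr)
        if cm.residues:
            fab.chains.append(cm)
    if not fab.chains:
        raise StructureError("no ATOM records found")
    return fab


def write_pdb(fab: FabStructure, handle_or_path=None) -> str:
    """Serialize to standard 80-column ATOM records; returns the text."""
    lines = []
    serial = 1
    for chain in fab.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name
                # column-13 convention: 1-letter elements start in column 14
                aname = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM  {serial:5d} {aname}{'':1s}{res.name:>3s} {chain.chain_id}"
                    f"{res.seq_number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} "
                     f"{chain.chain_id}{chain.residues[-1].seq_number:4d}")
        serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if handle_or_path is not None:
        if hasattr(handle_or_path, "write"):
            handle_or_path.write(text)
        else:
            with open(handle_or_path, "w") as fh:
                fh.write(text)
    return text


@dataclass
class ConstructDesign:
    """A named set of selected mutations with their net context energies."""

    name: str
    mutations: list[PointMutation]
    phenotype_per_mutation: list[str]          # "Murine" | "Human"
    net_energy_murine_context: float
    net_energy_humanized_context: float

    def __post_init__(self) -> None:
        keys = [(m.chain, m.position) for m in self.mutations]
        if len(set(keys)) != len(keys):
            raise SequenceError("duplicate (chain, position) in construct design")
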