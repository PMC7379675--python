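"""DNA structure geometry: PDB parsing, strand pairing and B-DNA fixtures.

The scoring layer needs a duplex DNA model in which every nucleotide knows
its strand (1 or 2), its position along the duplex axis (``bp_index``) and
which of its atoms belong to the sugar-phosphate backbone.  This module
builds that model either from a PDB file (e.g. the 1ZBB tetranucleosome) or
from an ideal generated B-DNA double helix, so that nothing in the package
requires a structure download.

All internal lengths are nanometres; PDB angstroms are converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Nucleotide",
    "DnaGeometry",
    "BACKBONE_ATOM_NAMES",
    "parse_pdb",
    "pair_strands",
    "build_bdna_fixture",
    "write_fixture_pdb",
    "scoring_mass",
]

# Sugar-phosphate group of a deoxyribonucleotide.  Energy deposited nearest
# to one of these atoms is what can sever the phosphodiester backbone.
BACKBONE_ATOM_NAMES = frozenset(
    {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"}
)

# Residue names accepted as DNA nucleotides (modern and legacy PDB styles).
_NUCLEIC_RESIDUES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "P"}

#: Default C1'-C1' pairing cutoff, nm.
PAIRING_CUTOFF_NM = 1.2

_ANGSTROM_TO_NM = 0.1
_WATER_DENSITY_KG_PER_NM3 = 1.0e-24  # 1 g/cm^3
_AMU_TO_KG = 1.66053906660e-27


@dataclass(frozen=True)
class Atom:
    """A single atom with its position in nanometres."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), nm
    residue_seq: int
    chain_id: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Nucleotide:
    """One nucleotide: strand membership, duplex position and atom groups."""

    chain_id: str
    strand: int  # 1 or 2
    bp_index: int  # 0-based position along the duplex axis
    base: str  # A, C, G or T
    backbone_atoms: list[Atom]
    base_atoms: list[Atom]
    residue_seq: int = 0
    paired: bool = True

    def __post_init__(self) -> None:
        if self.strand not in (1, 2):
            raise ValueError(f"strand must be 1 or 2, got {self.strand}")
        if self.base not in _COMPLEMENT:
            raise ValueError(f"unknown base {self.base!r}")
        if not self.backbone_atoms:
            raise ValueError("nucleotide must have at least one backbone atom")


@dataclass
class DnaGeometry:
    """A duplex DNA molecule indexed for damage scoring.

    ``obstacle_atoms`` holds non-nucleic atoms (protein, ions, water) that
    compete for nearest-atom deposit assignment but never accumulate
    backbone energy.
    """

    nucleotides: list[Nucleotide]
    n_bp: int
    box_min: np.ndarray  # nm
    box_max: np.ndarray  # nm
    source_label: str = "fixture"
    obstacle_atoms: list[Atom] = field(default_factory=list)
    pairing: dict[int, tuple[int, int]] = field(default_factory=dict)

    _atom_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.box_min = np.asarray(self.box_min, dtype=float)
        self.box_max = np.asarray(self.box_max, dtype=float)
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        if not np.all(self.box_max > self.box_min):
            raise ValueError("bounding box extents must be positive")

    @property
    def bounding_box(self) -> np.ndarray:
        """Bounding-box extents (dx, dy, dz) in nm."""
        return self.box_max - self.box_min

    @property
    def scoring_volume_mass(self) -> float:
        """Mass of the scoring volume (kg), water-equivalent box by default."""
        return scoring_mass(self, "box-water")

    def strand_nucleotides(self, strand: int) -> list[Nucleotide]:
        return [n for n in self.nucleotides if n.strand == strand]

    def atom_table(self):
        """Flat arrays over every atom, ordered deterministically.

        Returns ``(positions, nucleotide_index, is_backbone)`` where
        ``nucleotide_index`` is -1 for obstacle and base atoms that can
        capture a deposit but never score.  Ordering is by
        (chain_id, residue_seq, atom name) so nearest-atom ties resolve
        reproducibly.
        """
        if self._atom_cache is not None:
            return self._atom_cache
        rows = []
        for i, nuc in enumerate(self.nucleotides):
            for atom in nuc.backbone_atoms:
                rows.append((atom.chain_id, atom.residue_seq, atom.name,
                             atom.position, i))
            for atom in nuc.base_atoms:
                rows.append((atom.chain_id, atom.residue_seq, atom.name,
                             atom.position, -1))
        for atom in self.obstacle_atoms:
            rows.append((atom.chain_id, atom.residue_seq, atom.name,
                         atom.position, -1))
        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        positions = np.array([r[3] for r in rows], dtype=float)
        nuc_index = np.array([r[4] for r in rows], dtype=int)
        is_backbone = nuc_index >= 0
        self._atom_cache = (positions, nuc_index, is_backbone)
        return self._atom_cache

    def all_atoms(self) -> list[Atom]:
        out: list[Atom] = []
        for nuc in self.nucleotides:
            out.extend(nuc.backbone_atoms)
            out.extend(nuc.base_atoms)
        out.extend(self.obstacle_atoms)
        return out


def _bounding_box(atoms: list[Atom]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([a.position for a in atoms])
    return pos.min(axis=0), pos.max(axis=0)


def parse_pdb(path, histones_absorb: bool = True) -> DnaGeometry:
    """Read a PDB file into a strand/base-pair indexed :class:`DnaGeometry`.

    Chains containing DNA residues (DA/DC/DG/DT or legacy A/C/G/T) become
    the two strands: nucleic chains are taken in file order, alternating
    strand 1 / strand 2.  Non-nucleic residues are kept as obstacle atoms
    when ``histones_absorb`` is true (they capture nearby deposits without
    scoring) and dropped otherwise.

    Raises ``ValueError`` ("not a DNA structure") when no nucleic residue
    is present.
    """
    structure = gemmi.read_pdb(str(path))
    structure.setup_entities()
    model = structure[0]

    nucleotides: list[Nucleotide] = []
    obstacles: list[Atom] = []
    nucleic_chains: list[str] = []

    for chain in model:
        chain_has_nucleic = False
        for residue in chain:
            resname = residue.name.strip()
            base = _NUCLEIC_RESIDUES.get(resname)
            if base is not None:
                chain_has_nucleic = True
                backbone, base_atoms = [], []
                for at in residue:
                    atom = Atom(
                        name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z])
                        * _ANGSTROM_TO_NM,
                        residue_seq=residue.seqid.num,
                        chain_id=chain.name,
                    )
                    if at.name in BACKBONE_ATOM_NAMES:
                        backbone.append(atom)
                    else:
                        base_atoms.append(atom)
                if not backbone:
                    # terminal residue missing its phosphate still has sugar
                    # atoms; a residue with no backbone at all cannot break
                    continue
                nucleotides.append(
                    Nucleotide(
                        chain_id=chain.name,
                        strand=1,  # reassigned below from chain grouping
                        bp_index=len(nucleotides),
                        base=base,
                        backbone_atoms=backbone,
                        base_atoms=base_atoms,
                        residue_seq=residue.seqid.num,
                    )
                )
            elif histones_absorb:
                for at in residue:
                    if at.element.name == "H":
                        continue
                    obstacles.append(
                        Atom(
                            name=at.name,
                            element=at.element.name,
                            position=np.array([at.pos.x, at.pos.y, at.pos.z])
                            * _ANGSTROM_TO_NM,
                            residue_seq=residue.seqid.num,
                            chain_id=chain.name,
                        )
                    )
        if chain_has_nucleic:
            nucleic_chains.append(chain.name)

    if not nucleotides:
        raise ValueError(f"not a DNA structure: {path} contains no nucleic residues")

    strand_of_chain = {c: 1 + (k % 2) for k, c in enumerate(nucleic_chains)}
    for nuc in nucleotides:
        nuc.strand = strand_of_chain[nuc.chain_id]

    atoms = [a for n in nucleotides for a in n.backbone_atoms + n.base_atoms]
    atoms += obstacles
    box_min, box_max = _bounding_box(atoms)

    geometry = DnaGeometry(
        nucleotides=nucleotides,
        n_bp=max(1, sum(1 for n in nucleotides if n.strand == 1)),
        box_min=box_min,
        box_max=box_max,
        source_label=str(path),
        obstacle_atoms=obstacles,
    )
    if len({n.strand for n in nucleotides}) == 2:
        pair_strands(geometry)
    return geometry


def _pairing_anchor(nuc: Nucleotide) -> np.ndarray:
    """C1' position if present, else the backbone centroid."""
    for atom in nuc.backbone_atoms:
        if atom.name == "C1'":
            return atom.position
    return np.mean([a.position for a in nuc.backbone_atoms], axis=0)


def pair_strands(geometry: DnaGeometry,
                 cutoff_nm: float = PAIRING_CUTOFF_NM) -> DnaGeometry:
    """Assign ``bp_index`` by geometric strand pairing (in place).

    Strand-1 nucleotides are numbered 0..n1-1 in (chain, residue) order.
    Each strand-2 nucleotide takes the bp_index of its nearest strand-1
    partner by C1'-C1' distance, subject to ``cutoff_nm``; each partner is
    used at most once (closest claim wins, ties to the lowest residue_seq).
    Nucleotides left without a partner keep a sequential bp_index and are
    flagged ``paired=False``.
    """
    strand1 = sorted(geometry.strand_nucleotides(1),
                     key=lambda n: (n.chain_id, n.residue_seq))
    strand2 = sorted(geometry.strand_nucleotides(2),
                     key=lambda n: (n.chain_id, n.residue_seq))
    if not strand1 or not strand2:
        raise ValueError("strand pairing requires nucleotides on both strands")

    for i, nuc in enumerate(strand1):
        nuc.bp_index = i
        nuc.paired = False

    anchors1 = np.array([_pairing_anchor(n) for n in strand1])
    anchors2 = np.array([_pairing_anchor(n) for n in strand2])
    d = np.linalg.norm(anchors2[:, None, :] - anchors1[None, :, :], axis=2)

    candidates = [
        (d[j, i], strand2[j].residue_seq, j, i)
        for j in range(len(strand2))
        for i in range(len(strand1))
        if d[j, i] <= cutoff_nm
    ]
    candidates.sort()
    taken1: set[int] = set()
    matched2: dict[int, int] = {}
    for _, _, j, i in candidates:
        if j in matched2 or i in taken1:
            continue
        matched2[j] = i
        taken1.add(i)

    geometry.pairing = {}
    next_free = len(strand1)
    for j, nuc in enumerate(strand2):
        if j in matched2:
            i = matched2[j]
            nuc.bp_index = i
            nuc.paired = True
            strand1[i].paired = True
            geometry.pairing[i] = (strand1[i].residue_seq, nuc.residue_seq)
        else:
            nuc.bp_index = next_free
            next_free += 1
            nuc.paired = False
    geometry.n_bp = len(strand1)
    geometry._atom_cache = None
    return geometry


# --- ideal B-DNA fixture ---------------------------------------------------

# (name, element, helical radius nm, angular offset deg, axial offset nm)
# C1' sits at a reduced radius diametrically across the axis so that the
# nearest cross-strand C1' is always the Watson-Crick partner; with the
# crystallographic ~0.59 nm radius and a 36 deg twist the nearest C1' on
# the complementary strand is the i-1 neighbour, which would defeat
# nearest-neighbour pairing on this coarse model.
_FIXTURE_BACKBONE = [
    ("P", "P", 0.94, -18.0, -0.17),
    ("O5'", "O", 0.90, -10.0, -0.10),
    ("C5'", "C", 0.86, -4.0, -0.05),
    ("C4'", "C", 0.78, 0.0, 0.00),
    ("C3'", "C", 0.77, 8.0, 0.06),
    ("O3'", "O", 0.75, 14.0, 0.12),
    ("C1'", "C", 0.25, 0.0, 0.00),
]
_FIXTURE_BASE = [("N1", "N", 0.08, 0.0, 0.00)]

_DEFAULT_RISE_NM = 0.34
_DEFAULT_TWIST_DEG = 36.0


def build_bdna_fixture(
    n_bp: int,
    sequence: str | None = None,
    rise_nm: float = _DEFAULT_RISE_NM,
    twist_deg: float = _DEFAULT_TWIST_DEG,
) -> DnaGeometry:
    """Generate an ideal B-DNA duplex with coarse pseudo-atom nucleotides.

    Two antiparallel helical strands with the canonical 0.34 nm rise and
    36 degree twist; base pair i on strand 1 pairs with i on strand 2.
    ``sequence`` gives the strand-1 bases 5'->3' (default: repeating ACGT).
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    if sequence is None:
        sequence = ("ACGT" * (n_bp // 4 + 1))[:n_bp]
    sequence = sequence.upper()
    if len(sequence) != n_bp:
        raise ValueError("sequence length must equal n_bp")
    if set(sequence) - set("ACGT"):
        raise ValueError("sequence must contain only A, C, G, T")

    twist = math.radians(twist_deg)
    nucleotides: list[Nucleotide] = []

    def make_atoms(spec_rows, i, strand_phase, z_sign, chain_id, resseq):
        atoms = []
        for name, element, radius, dphi_deg, dz in spec_rows:
            phi = i * twist + strand_phase + z_sign * math.radians(dphi_deg)
            z = i * rise_nm + z_sign * dz
            atoms.append(
                Atom(
                    name=name,
                    element=element,
                    position=np.array(
                        [radius * math.cos(phi), radius * math.sin(phi), z]
                    ),
                    residue_seq=resseq,
                    chain_id=chain_id,
                )
            )
        return atoms

    for i, base in enumerate(sequence):
        nucleotides.append(
            Nucleotide(
                chain_id="A",
                strand=1,
                bp_index=i,
                base=base,
                backbone_atoms=make_atoms(_FIXTURE_BACKBONE, i, 0.0, +1, "A", i + 1),
                base_atoms=make_atoms(_FIXTURE_BASE, i, 0.0, +1, "A", i + 1),
                residue_seq=i + 1,
            )
        )
    # strand 2 runs antiparallel: residue 1 sits at the top of the helix
    for j in range(n_bp):
        i = n_bp - 1 - j  # bp level of strand-2 residue j+1
        base = _COMPLEMENT[sequence[i]]
        nucleotides.append(
            Nucleotide(
                chain_id="B",
                strand=2,
                bp_index=i,
                base=base,
                backbone_atoms=make_atoms(
                    _FIXTURE_BACKBONE, i, math.pi, -1, "B", j + 1
                ),
                base_atoms=make_atoms(_FIXTURE_BASE, i, math.pi, -1, "B", j + 1),
                residue_seq=j + 1,
            )
        )

    atoms = [a for n in nucleotides for a in n.backbone_atoms + n.base_atoms]
    box_min, box_max = _bounding_box(atoms)
    geometry = DnaGeometry(
        nucleotides=nucleotides,
        n_bp=n_bp,
        box_min=box_min,
        box_max=box_max,
        source_label="fixture",
        pairing={i: (i + 1, n_bp - i) for i in range(n_bp)},
    )
    return geometry


def write_fixture_pdb(geometry: DnaGeometry, path) -> None:
    """Write a geometry as standard PDB ATOM records (nm converted to A).

    ``parse_pdb`` on the output reproduces strand count, n_bp, the bp_index
    map and atom positions at PDB column precision (0.001 A).
    """
    if not geometry.nucleotides:
        raise ValueError("cannot write an empty geometry")
    structure = gemmi.Structure()
    structure.name = "dsbkit fixture"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 1
    order = sorted(geometry.nucleotides,
                   key=lambda n: (n.chain_id, n.residue_seq))
    for nuc in order:
        chain = chains.get(nuc.chain_id)
        if chain is None:
            chain = gemmi.Chain(nuc.chain_id)
            chains[nuc.chain_id] = chain
        residue = gemmi.Residue()
        residue.name = "D" + nuc.base
        residue.seqid = gemmi.SeqId(nuc.residue_seq, " ")
        for atom in nuc.backbone_atoms + nuc.base_atoms:
            at = gemmi.Atom()
            at.name = atom.name
            at.element = gemmi.Element(atom.element)
            x, y, z = atom.position / _ANGSTROM_TO_NM
            at.pos = gemmi.Position(x, y, z)
            at.serial = serial
            serial += 1
            residue.add_atom(at)
        chain.add_residue(residue)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.write_pdb(str(path))


def scoring_mass(geometry: DnaGeometry, mode: str = "box-water") -> float:
    """Mass (kg) of the scoring volume used as the dose denominator.

    ``"box-water"``: bounding-box volume at liquid-water density (1 g/cm^3),
    matching dose defined as energy imparted to the molecule's volume.
    ``"atomic"``: sum of atomic masses of every atom in the geometry, for
    sensitivity analysis.
    """
    if mode == "box-water":
        volume_nm3 = float(np.prod(geometry.bounding_box))
        return volume_nm3 * _WATER_DENSITY_KG_PER_NM3
    if mode == "atomic":
        total_amu = sum(
            gemmi.Element(a.element).weight for a in geometry.all_atoms()
        )
        return total_amu * _AMU_TO_KG
    raise ValueError(f"unknown scoring-mass mode {mode!r}")
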