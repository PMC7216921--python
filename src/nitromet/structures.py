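"""Structure parsing, cofactor-shell residue identification, and reference
position mapping.

The active site of a nitrogenase D-subunit is defined geometrically: every
protein residue with at least one atom within a distance cutoff (5 A by
default) of any atom of the active-site cofactor. Positions are then mapped
onto a reference numbering frame (A. vinelandii NifD) through pairwise global
alignment, so that residues from different homologs and from ancestors can be
compared at the same numbered sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from scipy.spatial import cKDTree

from .align import LabeledAlignment

#: Solvent residue names excluded from protein-residue candidates.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclass
class Structure:
    """Flat atom table of one model of a PDB entry.

    ``cofactor_selector`` designates the ligand group whose atoms define the
    active site: either a het residue name (e.g. ``"ICS"``) or a
    ``(chain, residue_seq)`` pair.
    """

    serials: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    residue_names: np.ndarray
    residue_seqs: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    occupancies: np.ndarray
    is_hetero: np.ndarray
    cofactor_selector: str | tuple[str, int] | None = None

    def __post_init__(self):
        n = len(self.serials)
        if self.coords.shape != (n, 3):
            raise ValueError("coordinate array must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atomic coordinates")

    def __len__(self) -> int:
        return len(self.serials)

    def cofactor_mask(self) -> np.ndarray:
        sel = self.cofactor_selector
        if sel is None:
            raise ValueError("structure has no cofactor selector set")
        if isinstance(sel, str):
            mask = self.residue_names == sel
        else:
            chain, seq = sel
            mask = (self.chains == chain) & (self.residue_seqs == int(seq))
        if not mask.any():
            het = sorted({(str(c), int(s), str(r)) for c, s, r in zip(
                self.chains[self.is_hetero], self.residue_seqs[self.is_hetero],
                self.residue_names[self.is_hetero])})
            raise ValueError(
                f"cofactor selector {sel!r} matches no atoms; "
                f"available het groups: {het if het else 'none'}")
        return mask


def parse_structure(pdb_text: str,
                    cofactor_selector: str | tuple[str, int] | None = None
                    ) -> Structure:
    """Parse PDB-format text into a flat :class:`Structure`.

    All ATOM/HETATM records of the first model are kept; alternate locations
    are resolved to the highest-occupancy conformer per (residue, atom name).
    """
    if not pdb_text.strip():
        raise ValueError("empty PDB input")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = next(parser.get_structure("s", StringIO(pdb_text)).get_models())
    except PDBConstructionException as exc:
        raise ValueError(f"malformed PDB record: {exc}") from exc
    except StopIteration:
        raise ValueError("no atoms found in PDB input") from None

    rows = []
    for chain in model:
        for residue in chain:
            het_flag, resseq, _ = residue.id
            for atom in residue:
                # altloc: keep the highest-occupancy conformer only
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(),
                               key=lambda a: a.get_occupancy() or 0.0)
                rows.append((
                    atom.serial_number, atom.get_name(),
                    (atom.element or "").strip().upper() or atom.get_name()[0],
                    residue.get_resname().strip(), resseq, chain.id,
                    atom.get_coord(), atom.get_occupancy() or 1.0,
                    het_flag.strip() != "",
                ))
    if not rows:
        raise ValueError("no atoms found in PDB input")
    return Structure(
        serials=np.array([r[0] for r in rows]),
        names=np.array([r[1] for r in rows]),
        elements=np.array([r[2] for r in rows]),
        residue_names=np.array([r[3] for r in rows]),
        residue_seqs=np.array([r[4] for r in rows], dtype=int),
        chains=np.array([r[5] for r in rows]),
        coords=np.array([r[6] for r in rows], dtype=float),
        occupancies=np.array([r[7] for r in rows], dtype=float),
        is_hetero=np.array([r[8] for r in rows], dtype=bool),
        cofactor_selector=cofactor_selector,
    )


@dataclass(frozen=True)
class ActiveSiteConfig:
    """Active-site shell definition: distance cutoff and reference frame."""

    cutoff: float = 5.0
    reference_sequence: str | None = None

    def __post_init__(self):
        if self.cutoff < 0:
            raise ValueError("cutoff must be non-negative")


def residues_near_cofactor(structure: Structure,
                           config: ActiveSiteConfig | None = None
                           ) -> set[tuple[str, int, str]]:
    """Protein residues with any non-hydrogen atom within ``cutoff`` of any
    cofactor atom. Waters and the cofactor group itself are excluded."""
    config = config or ActiveSiteConfig()
    cof = structure.cofactor_mask()
    candidate = (~cof
                 & ~np.isin(structure.residue_names, list(WATER_NAMES))
                 & (structure.elements != "H")
                 & (structure.elements != "D"))
    if not candidate.any():
        return set()
    tree = cKDTree(structure.coords[cof])
    dmin, _ = tree.query(structure.coords[candidate])
    hits = dmin <= config.cutoff
    idx = np.flatnonzero(candidate)[hits]
    return {(str(structure.chains[i]), int(structure.residue_seqs[i]),
             str(structure.residue_names[i])) for i in idx}


@dataclass
class SiteMap:
    """Map from reference numbering to positions in a query sequence.

    ``positions`` are 1-based reference positions in increasing order;
    ``query_indices`` are the matching 0-based indices in the query (``None``
    where the reference position has no aligned query residue).
    """

    positions: list[int]
    query_indices: list[int | None]
    reference_length: int = 0

    def __post_init__(self):
        if len(self.positions) != len(self.query_indices):
            raise ValueError("positions and query_indices length mismatch")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("reference positions must be strictly increasing")

    def subset(self, positions: list[int]) -> "SiteMap":
        lookup = dict(zip(self.positions, self.query_indices))
        missing = [p for p in positions if p not in lookup]
        if missing:
            raise KeyError(f"reference positions not in map: {missing}")
        pos = sorted(positions)
        return SiteMap(pos, [lookup[p] for p in pos], self.reference_length)

    def to_tsv(self, query: str | None = None) -> str:
        lines = ["reference_position\tquery_index\tresidue"]
        for p, q in zip(self.positions, self.query_indices):
            res = query[q] if (query is not None and q is not None) else "-"
            lines.append(f"{p}\t{q if q is not None else 'absent'}\t{res}")
        return "\n".join(lines) + "\n"


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def map_positions(query_sequence: str, reference_sequence: str) -> SiteMap:
    """Reference-position -> query-index map via pairwise global alignment
    (BLOSUM62, affine gaps). Unaligned reference positions map to ``None``."""
    if not query_sequence or not reference_sequence:
        raise ValueError("sequences must be non-empty")
    aln = _global_aligner().align(query_sequence, reference_sequence)[0]
    mapping: dict[int, int] = {}
    for (qs, qe), (rs, re) in zip(*aln.aligned):
        for off in range(re - rs):
            mapping[rs + off + 1] = qs + off  # 1-based reference numbering
    n = len(reference_sequence)
    return SiteMap(list(range(1, n + 1)),
                   [mapping.get(p) for p in range(1, n + 1)],
                   reference_length=n)


def extract_active_site(alignment: LabeledAlignment,
                        site_map: SiteMap) -> LabeledAlignment:
    """Slice an alignment down to the columns realizing the mapped reference
    positions, in reference-numbering order.

    The alignment must contain the reference row (``alignment.reference_name``);
    its non-gap characters define which alignment column realizes each
    reference-sequence position.
    """
    if alignment.reference_name is None:
        raise ValueError("alignment has no designated reference row")
    try:
        ref_row = alignment.row(alignment.reference_name)
    except KeyError:
        raise ValueError(
            f"reference row {alignment.reference_name!r} missing from alignment"
        ) from None

    # ungapped reference position (1-based) -> alignment column
    pos_to_col: dict[int, int] = {}
    p = 0
    for col, ch in enumerate(ref_row):
        if ch not in "-.":
            p += 1
            pos_to_col[p] = col

    columns = []
    for refpos, qidx in zip(site_map.positions, site_map.query_indices):
        if qidx is None:
            raise ValueError(f"reference position {refpos} absent from query map")
        col = pos_to_col.get(qidx + 1)
        if col is None:
            raise ValueError(
                f"reference position {refpos} (reference-row residue {qidx + 1}) "
                f"not realized in the alignment")
        columns.append(col)
    return alignment.take_columns(columns)
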