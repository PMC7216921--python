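"""Seeded generator of a nitrogenase-like protein family with known ground
truth, plus toy receptor geometries with analytically known cavity volumes.

The family emulates the structure of the nitrogenase D(HDK) phylogeny: two
Mo-dependent clades (Nif-I, Nif-II) sister to a lineage of three
uncharacterized clades (Clfx, F-Mc, Mb-Mc) crowned by the V- and Fe-dependent
clades (Vnf, Anf). Sequences evolve by JTT along a fixed rooted tree;
30 active-site positions (reference numbering) carry the planted structure:

* ten universally conserved residues (invariant everywhere),
* clade-signature residues, exclusively conserved in one metal-dependence
  group or in the V/Fe union, switched in on the stem of the owning clade,
* at signature positions a clade does NOT own, a deterministic two-residue
  polymorphism (the clade is split block-wise between two decoy residues
  disjoint from every signature residue at that position, mimicking one
  internal substitution), so that no spurious group-exclusive conservation
  can arise,
* six filler active-site positions evolving at a reduced rate, with one
  anchor taxon per clade pinned to the ancestral state so drift cannot
  manufacture accidental clade-unique residues there.

The true tree, the true sequence at every internal node, the labels and the
planted signature table are returned alongside the alignment, so ancestral
reconstruction, classification and unique-residue tabulation can all be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .align import LabeledAlignment
from .asr import load_tree
from .substitution import AMINO_ACIDS, SubstitutionModel, jtt

# ---- planted active-site structure (reference numbering) --------------------

CONSERVED_SITES: dict[int, str] = {
    70: "V", 191: "Q", 195: "H", 275: "C", 277: "R",
    278: "S", 356: "G", 381: "F", 424: "G", 442: "H",
}

#: Group-exclusive conserved residues: 3 Mo-specific, 6 V-specific,
#: 5 Fe-specific, 6 shared by the V/Fe union.
SIGNATURE_TABLE: dict[str, dict[int, str]] = {
    "Nif": {65: "A", 96: "R", 440: "Q"},
    "Vnf": {69: "L", 300: "W", 355: "T", 358: "P", 425: "P", 427: "V"},
    "Anf": {69: "H", 355: "P", 359: "K", 427: "P", 441: "A"},
    "VnfAnf": {65: "C", 96: "K", 360: "L", 380: "K", 426: "R", 440: "N"},
}

#: Two-residue polymorphic pairs planted in clades that own no signature at
#: the position; pairs avoid every signature residue at that position. The
#: first members at 355-360 spell the Mo-form IGGLRP-like loop.
DECOY_PAIRS: dict[int, tuple[str, str]] = {
    65: (),  # every group owns a residue here (and at 96, 440)
    69: ("M", "I"),
    300: ("C", "R"),
    355: ("I", "M"),
    358: ("S", "A"),
    359: ("R", "S"),
    360: ("P", "A"),
    380: ("E", "D"),
    425: ("A", "S"),
    426: ("Q", "E"),
    427: ("I", "L"),
    441: ("S", "T"),
}

#: Root states of the six filler active-site positions (evolve at the
#: reduced active-site rate); 357 = G completes the 355-360 loop motif.
FILLER_ROOT: dict[int, str] = {
    59: "F", 66: "G", 192: "S", 196: "T", 357: "G", 382: "S",
}

CLADE_LABELS = {"NifI": "Nif", "NifII": "Nif", "Clfx": "unknown",
                "FMc": "unknown", "MbMc": "unknown",
                "Vnf": "Vnf", "Anf": "Anf"}

DEFAULT_CLADE_SIZES = {"NifI": 30, "NifII": 20, "Clfx": 3, "FMc": 8,
                       "MbMc": 8, "Vnf": 14, "Anf": 14}

DEFAULT_CLADE_DEPTHS = {"NifI": 0.15, "NifII": 0.15, "Clfx": 0.10,
                        "FMc": 0.12, "MbMc": 0.12, "Vnf": 0.10, "Anf": 0.10}

#: Stem branch length above each clade crown. The V stem is short and the
#: Fe stem long: Fe-nitrogenases are the more derived, faster-diverging
#: lineage, which also makes the V/Fe ancestor lean toward the V clade.
DEFAULT_CLADE_STEMS = {"NifI": 0.05, "NifII": 0.05, "Clfx": 0.08,
                       "FMc": 0.08, "MbMc": 0.08, "Vnf": 0.015, "Anf": 0.22}

#: Backbone branch lengths (above the named internal nodes). The long edge
#: above the V/Fe ancestor separates it from the Mo-like backbone.
DEFAULT_BACKBONE = {"anc_nif": 0.06, "anc_clfx": 0.05, "anc_f_mc": 0.04,
                    "anc_mb_mc": 0.04, "anc_vnf_anf": 0.40}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of the synthetic nitrogenase-like family."""

    clade_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLADE_SIZES))
    sequence_length: int = 500
    conserved_sites: dict[int, str] = field(
        default_factory=lambda: dict(CONSERVED_SITES))
    signature_table: dict[str, dict[int, str]] = field(
        default_factory=lambda: {g: dict(d) for g, d in SIGNATURE_TABLE.items()})
    decoy_pairs: dict[int, tuple[str, str]] = field(
        default_factory=lambda: dict(DECOY_PAIRS))
    filler_root: dict[int, str] = field(
        default_factory=lambda: dict(FILLER_ROOT))
    active_site_rate: float = 0.2
    background_rate: float = 1.0
    clade_depths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLADE_DEPTHS))
    clade_stems: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLADE_STEMS))
    backbone: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKBONE))
    seed: int = 0

    @property
    def signature_positions(self) -> set[int]:
        return {p for table in self.signature_table.values() for p in table}

    @property
    def active_site_positions(self) -> list[int]:
        return sorted(set(self.conserved_sites) | self.signature_positions
                      | set(self.filler_root))

    def validate(self) -> None:
        for clade, size in self.clade_sizes.items():
            if clade not in CLADE_LABELS:
                raise ValueError(f"unknown clade {clade!r}")
            if size < 2:
                raise ValueError(f"clade {clade} needs >= 2 members, got {size}")
        positions = self.active_site_positions
        if positions and max(positions) > self.sequence_length:
            raise ValueError("active-site positions exceed sequence length")
        overlap = set(self.conserved_sites) & self.signature_positions
        if overlap:
            raise ValueError(f"conserved and signature positions overlap: "
                             f"{sorted(overlap)}")
        for p in self.signature_positions:
            used = {t[p] for t in self.signature_table.values() if p in t}
            decoy = set(self.decoy_pairs.get(p, ()))
            if decoy & used:
                raise ValueError(f"decoy pair at {p} collides with signature "
                                 f"residues {sorted(decoy & used)}")
            owners = sum(1 for g in ("Nif", "Vnf", "Anf", "VnfAnf")
                         if p in self.signature_table.get(g, {}))
            covered = (p in self.signature_table["Nif"]
                       or p in self.signature_table["VnfAnf"])
            if not covered and not self.decoy_pairs.get(p):
                raise ValueError(f"signature position {p} has no decoy pair "
                                 "for non-owning clades")
            del owners
        if self.active_site_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated family."""

    tree_newick: str
    ancestral_sequences: dict[str, str]
    labels: dict[str, str]
    signature_table: dict[str, dict[int, str]]
    conserved_sites: dict[int, str]
    active_site_positions: list[int]
    clades: dict[str, list[str]]
    vnf_anf_ancestor: str = "anc_vnf_anf"
    deep_ancestors: tuple[str, ...] = ("anc_mb_mc", "anc_f_mc", "anc_clfx",
                                       "anc_nif", "root")

    @property
    def site_columns(self) -> list[int]:
        """0-based alignment columns of the active-site positions
        (simulation is gap-free, column i realizes reference position i+1)."""
        return [p - 1 for p in self.active_site_positions]

    def signature_counts(self) -> dict[str, int]:
        return {g: len(t) for g, t in self.signature_table.items()}


def _balanced_newick(names: list[str], depth: float) -> str:
    """Ultrametric balanced subtree over ``names`` with root-to-tip ``depth``."""
    levels = max(1, int(np.ceil(np.log2(len(names)))))
    step = depth / levels

    def rec(sub: list[str], remaining: int) -> str:
        if len(sub) == 1:
            return f"{sub[0]}:{step * remaining:.6f}"
        k = len(sub) // 2
        return (f"({rec(sub[:k], remaining - 1)},"
                f"{rec(sub[k:], remaining - 1)}):{step:.6f}")

    s = rec(names, levels)
    # strip the top edge; the caller attaches the stem
    return s[:s.rfind(":")] if s.startswith("(") else s.split(":")[0]


def build_family_tree(spec: FamilySpec) -> str:
    """Newick for the fixed labeled topology
    ((Nif-I,Nif-II),(Clfx,(F-Mc,(Mb-Mc,(Vnf,Anf)))))."""
    crowns = {}
    for clade, size in spec.clade_sizes.items():
        names = [f"{clade}_{i + 1}" for i in range(size)]
        sub = _balanced_newick(names, spec.clade_depths[clade])
        crowns[clade] = (f"{sub}crown_{clade}:{spec.clade_stems[clade]:.6f}"
                         if sub.startswith("(")
                         else f"{names[0]}:{spec.clade_stems[clade]:.6f}")
    bb = spec.backbone
    return (
        f"(({crowns['NifI']},{crowns['NifII']})anc_nif:{bb['anc_nif']:.6f},"
        f"({crowns['Clfx']},"
        f"({crowns['FMc']},"
        f"({crowns['MbMc']},"
        f"({crowns['Vnf']},{crowns['Anf']})anc_vnf_anf:{bb['anc_vnf_anf']:.6f}"
        f")anc_mb_mc:{bb['anc_mb_mc']:.6f}"
        f")anc_f_mc:{bb['anc_f_mc']:.6f}"
        f")anc_clfx:{bb['anc_clfx']:.6f}"
        f")root;"
    )


def _leaf_clade(name: str) -> str:
    return name.rsplit("_", 1)[0]


def _node_regime(node: dendropy.Node) -> str:
    """Metal regime of a node: Vnf below the V stem and at the V/Fe ancestor,
    Anf below the Fe stem, Nif (Mo-like) everywhere else."""
    if node.is_leaf():
        clade = _leaf_clade(node.taxon.label)
        return {"Vnf": "Vnf", "Anf": "Anf"}.get(clade, "Nif")
    if node.label == "anc_vnf_anf":
        return "Vnf"
    leaves = {_leaf_clade(lf.taxon.label) for lf in node.leaf_iter()}
    if leaves == {"Vnf"}:
        return "Vnf"
    if leaves == {"Anf"}:
        return "Anf"
    return "Nif"


def _profile_residue(spec: FamilySpec, regime: str, pos: int,
                     member_index: int | None,
                     clade_size: int | None = None) -> str:
    """Planted residue for a signature position under a regime.

    Clades that own no signature there get the two-residue decoy pair,
    split block-wise across the clade (the first half of the members carry
    the first residue, mirroring a single internal substitution), which
    rules out accidental group-exclusive conservation.
    """
    table = spec.signature_table
    if regime == "Nif" and pos in table["Nif"]:
        return table["Nif"][pos]
    if regime in ("Vnf", "Anf"):
        if pos in table[regime]:
            return table[regime][pos]
        if pos in table["VnfAnf"]:
            return table["VnfAnf"][pos]
    pair = spec.decoy_pairs[pos]
    if member_index is None:
        return pair[0]
    # Split point varies with the position (multiplicative hash) so that
    # within-clade polymorphism directions decohere across sites instead of
    # stacking into one dominant principal component.
    size = clade_size or 2
    split = 1 + (pos * 2654435761) % (size - 1) if size > 2 else 1
    return pair[0] if member_index < split else pair[1]


def _sample_children(parent_states: np.ndarray, P: np.ndarray,
                     idx: np.ndarray, rng: np.random.Generator,
                     out: np.ndarray) -> None:
    if len(idx) == 0:
        return
    cum = np.cumsum(P[parent_states[idx]], axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(idx))
    out[idx] = (u[:, None] > cum).sum(axis=1)


def generate_family(spec: FamilySpec | None = None
                    ) -> tuple[LabeledAlignment, SyntheticTruth, str]:
    """Simulate the labeled family; deterministic under ``spec.seed``."""
    spec = spec or FamilySpec()
    spec.validate()
    model: SubstitutionModel = jtt()
    rng = np.random.default_rng(spec.seed)
    newick = build_family_tree(spec)
    tree = load_tree(newick)

    L = spec.sequence_length
    aa = np.array(list(AMINO_ACIDS))
    aa_index = {c: i for i, c in enumerate(AMINO_ACIDS)}
    conserved_idx = np.array(sorted(spec.conserved_sites)) - 1
    signature_idx = np.array(sorted(spec.signature_positions)) - 1
    filler_idx = np.array(sorted(spec.filler_root)) - 1
    frozen = np.zeros(L, dtype=bool)
    frozen[conserved_idx] = True
    frozen[signature_idx] = True
    background_idx = np.flatnonzero(~frozen)
    background_idx = np.setdiff1d(background_idx, filler_idx)

    def overlay(states: np.ndarray, regime: str, member_index: int | None,
                clade_size: int | None = None) -> None:
        for p, r in spec.conserved_sites.items():
            states[p - 1] = aa_index[r]
        for p in spec.signature_positions:
            states[p - 1] = aa_index[
                _profile_residue(spec, regime, p, member_index, clade_size)]

    # root sequence: equilibrium draw, then planted states
    root_states = rng.choice(20, size=L, p=model.equilibrium_freqs)
    for p, r in spec.filler_root.items():
        root_states[p - 1] = aa_index[r]
    overlay(root_states, "Nif", None)

    member_counter: dict[str, int] = {}
    node_states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    ancestral: dict[str, str] = {}
    leaf_seqs: dict[str, str] = {}
    node_no = 0
    for node in tree.preorder_node_iter():
        node_no += 1
        if node is not tree.seed_node:
            parent = node_states[id(node.parent_node)]
            t = node.edge.length or 0.0
            states = parent.copy()
            if t > 0:
                Pb = model.transition_matrix(t * spec.background_rate)
                Pa = model.transition_matrix(t * spec.active_site_rate)
                _sample_children(parent, Pb, background_idx, rng, states)
                _sample_children(parent, Pa, filler_idx, rng, states)
            if node.is_leaf():
                name = node.taxon.label
                clade = _leaf_clade(name)
                k = member_counter.setdefault(clade, 0)
                member_counter[clade] = k + 1
                overlay(states, _node_regime(node), k,
                        spec.clade_sizes[clade])
                if k == 0:  # anchor taxon: pinned ancestral filler states
                    states[filler_idx] = root_states[filler_idx]
                leaf_seqs[name] = "".join(aa[states])
            else:
                overlay(states, _node_regime(node), None)
            node_states[id(node)] = states
        if not node.is_leaf():
            label = node.label or f"node{node_no}"
            ancestral[label] = "".join(aa[node_states[id(node)]])

    clades: dict[str, list[str]] = {c: [] for c in spec.clade_sizes}
    for lf in tree.leaf_node_iter():
        clades[_leaf_clade(lf.taxon.label)].append(lf.taxon.label)
    names = [n for c in spec.clade_sizes for n in clades[c]]
    labels = {n: CLADE_LABELS[_leaf_clade(n)] for n in names}
    alignment = LabeledAlignment(
        names, [leaf_seqs[n] for n in names], [labels[n] for n in names],
        reference_name=names[0])
    truth = SyntheticTruth(
        tree_newick=newick,
        ancestral_sequences=ancestral,
        labels=labels,
        signature_table={g: dict(t) for g, t in spec.signature_table.items()},
        conserved_sites=dict(spec.conserved_sites),
        active_site_positions=spec.active_site_positions,
        clades=clades,
    )
    return alignment, truth, newick


# ---- structural fixtures ----------------------------------------------------

def _pdb_atom(serial: int, name: str, resname: str, chain: str, resseq: int,
              xyz, element: str, hetatm: bool = False, occ: float = 1.0) -> str:
    record = "HETATM" if hetatm else "ATOM"
    x, y, z = xyz
    return (f"{record:<6s}{serial % 100000:>5d} {name:<4s} {resname:>3s} "
            f"{chain}{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}")


def _fibonacci_shell(center, radius: float, n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return np.asarray(center) + radius * pts


def _shell_atoms(center, radius: float, element: str, resseq_start: int,
                 serial_start: int, spacing: float = 0.35) -> list[str]:
    n = max(64, int(np.ceil(4.0 * np.pi * radius ** 2 / spacing ** 2)))
    lines = []
    for k, xyz in enumerate(_fibonacci_shell(center, radius, n)):
        # unique atom name within each residue (PDB atom ids are per-residue)
        lines.append(_pdb_atom(serial_start + k, f"{element}{k % 10}", "SHL",
                               "A", resseq_start + k // 10, xyz, element))
    return lines


def generate_pocket_fixture(kind: str, params: dict
                            ) -> tuple[str, float]:
    """Toy receptor with an analytically known cavity volume.

    ``sphere-shell``: atoms densely covering a sphere of ``radius``; the
    cavity the carve step leaves is a ball of radius
    ``radius - vdw(element) - pad``.

    ``two-chamber``: two disjoint shells of ``radius_large``/``radius_small``;
    after the contiguity filter only the larger chamber's cavity remains.

    Returns (pdb_text, expected_volume_A3).
    """
    if not params:
        raise ValueError("fixture parameters must be provided")
    from .pocket import VDW_RADII
    element = params.get("element", "C")
    pad = params.get("vdw_pad", 1.09)
    rv = VDW_RADII[element.upper()]
    if kind == "sphere-shell":
        radius = float(params["radius"])
        if radius <= 0:
            raise ValueError("radius must be positive")
        cavity = radius - rv - pad
        if cavity <= 0:
            raise ValueError("shell too small to contain a cavity")
        lines = _shell_atoms((0.0, 0.0, 0.0), radius, element, 1, 1)
        expected = 4.0 / 3.0 * np.pi * cavity ** 3
        return "\n".join(lines) + "\nEND\n", float(expected)
    if kind == "two-chamber":
        r1 = float(params["radius_large"])
        r2 = float(params["radius_small"])
        if not 0 < r2 <= r1:
            raise ValueError("need 0 < radius_small <= radius_large")
        gap = float(params.get("gap", 4.0))
        d = r1 + r2 + gap
        lines = _shell_atoms((0.0, 0.0, 0.0), r1, element, 1, 1)
        lines += _shell_atoms((d, 0.0, 0.0), r2, element, 5000, len(lines) + 1)
        cavity = r1 - rv - pad
        if cavity <= 0 or r2 - rv - pad <= 0:
            raise ValueError("shells too small to contain cavities")
        expected = 4.0 / 3.0 * np.pi * cavity ** 3
        return "\n".join(lines) + "\nEND\n", float(expected)
    raise ValueError(f"unknown fixture kind {kind!r}")


def generate_toy_complex(n_residues: int, ligand_atoms: list[str],
                         placement_radii: list[float]
                         ) -> tuple[str, list[tuple[int, float]]]:
    """Single-atom residues at known distances from a central ligand.

    Returns (pdb_text, [(residue_seq, distance), ...]); the expected
    within-cutoff residue set for any cutoff c is those with distance <= c.
    """
    if not ligand_atoms:
        raise ValueError("at least one ligand atom is required")
    if n_residues != len(placement_radii):
        raise ValueError("need one placement radius per residue")
    if list(placement_radii) != sorted(placement_radii):
        raise ValueError("placement radii must be sorted ascending")
    dirs = _fibonacci_shell((0, 0, 0), 1.0, max(n_residues, 8))
    lines = []
    placed = []
    for i, r in enumerate(placement_radii):
        xyz = dirs[i] * r
        lines.append(_pdb_atom(i + 1, "CA", "ALA", "A", i + 1, xyz, "C"))
        placed.append((i + 1, float(r)))
    for j, el in enumerate(ligand_atoms):
        lines.append(_pdb_atom(n_residues + j + 1, el, "LIG", "A", 900,
                               (0.0, 0.0, 0.0), el, hetatm=True))
    return "\n".join(lines) + "\nEND\n", placed
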