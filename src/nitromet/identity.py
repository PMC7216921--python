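"""Percent-identity matrices and clade-unique residue tabulation.

Identity between two aligned sequences is the percentage of matching
characters over the columns where at least one of the pair holds a residue
(gap-gap columns are ignored; gap-residue columns count as mismatches).
Group-mean matrices average all cross pairs between two label groups,
excluding self-pairs within a group.

A residue is "unique" to a label group at a position when every member of
the group carries it there and no member of any other labeled group does;
the V/Fe union (Vnf + Anf) is additionally tested as a composite group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import LABELS, LabeledAlignment

GAP_SET = frozenset("-.")


def percent_identity(seq_a: str, seq_b: str,
                     scope_columns: list[int] | None = None) -> float:
    """Pairwise percent identity over the scoped columns (see module docs)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    cols = range(len(seq_a)) if scope_columns is None else scope_columns
    matches = total = 0
    for c in cols:
        a, b = seq_a[c].upper(), seq_b[c].upper()
        if a in GAP_SET and b in GAP_SET:
            continue
        total += 1
        if a == b:
            matches += 1
    if total == 0:
        return 100.0  # no comparable columns: vacuously identical
    return 100.0 * matches / total


@dataclass
class IdentityReport:
    """Pairwise and group-mean identity matrices for one comparison scope."""

    pairwise: pd.DataFrame
    group_means: pd.DataFrame
    scope: str

    def to_tsv(self) -> str:
        return self.group_means.to_csv(sep="\t", float_format="%.3f")


def group_mean_identity(alignment: LabeledAlignment,
                        scope_columns: list[int] | None = None,
                        scope: str = "full") -> IdentityReport:
    """All-pairs identity plus label-group means (self-pairs excluded).

    Rows labeled ``unknown`` form their own group so uncharacterized clades
    can be compared against the labeled ones, as in the family-wide identity
    heat-map analyses.
    """
    names = alignment.names
    n = len(names)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(alignment.sequences[i],
                                   alignment.sequences[j], scope_columns)
            mat[i, j] = mat[j, i] = pid
    pairwise = pd.DataFrame(mat, index=names, columns=names)

    labels = np.asarray(alignment.labels)
    present = [l for l in LABELS if (labels == l).any()]
    gm = pd.DataFrame(np.nan, index=present, columns=present)
    for a in present:
        ia = np.flatnonzero(labels == a)
        for b in present:
            ib = np.flatnonzero(labels == b)
            if a == b:
                if len(ia) < 2:
                    continue
                iu, ju = np.triu_indices(len(ia), k=1)
                gm.loc[a, b] = mat[np.ix_(ia, ia)][iu, ju].mean()
            else:
                gm.loc[a, b] = mat[np.ix_(ia, ib)].mean()
    return IdentityReport(pairwise, gm, scope)


@dataclass
class UniqueResidueTable:
    """(position, residue, group) records of group-exclusive conserved residues."""

    entries: list[tuple[int, str, str]]

    GROUPS = ("Nif", "Vnf", "Anf", "VnfAnf")

    def by_group(self, group: str) -> list[tuple[int, str]]:
        return [(p, r) for p, r, g in self.entries if g == group]

    def counts(self) -> dict[str, int]:
        return {g: len(self.by_group(g)) for g in self.GROUPS}

    def to_tsv(self) -> str:
        lines = ["position\tresidue\tgroup"]
        lines += [f"{p}\t{r}\t{g}" for p, r, g in self.entries]
        return "\n".join(lines) + "\n"


def unique_residues(active_site_alignment: LabeledAlignment,
                    positions: list[int] | None = None) -> UniqueResidueTable:
    """Tabulate residues exclusively conserved in one labeled group.

    ``positions`` supplies reference numbering for the alignment columns
    (defaults to 1-based column numbers). Unknown-label rows are excluded:
    uniqueness is defined among homologs of known metal dependence.
    """
    labels = np.asarray(active_site_alignment.labels)
    known = np.isin(labels, ("Nif", "Vnf", "Anf"))
    if not known.any():
        raise ValueError("no rows labeled Nif/Vnf/Anf")
    chars = active_site_alignment.as_matrix()[known]
    chars = np.char.upper(chars)
    labels = labels[known]
    ncol = chars.shape[1]
    if positions is None:
        positions = list(range(1, ncol + 1))
    if len(positions) != ncol:
        raise ValueError("positions length must equal alignment width")

    member_sets = {g: chars[labels == g] for g in ("Nif", "Vnf", "Anf")
                   if (labels == g).any()}
    composite = {}
    if "Vnf" in member_sets and "Anf" in member_sets:
        composite["VnfAnf"] = (np.vstack([member_sets["Vnf"],
                                          member_sets["Anf"]]),
                               ("Nif",))

    entries: list[tuple[int, str, str]] = []
    for c in range(ncol):
        for g, rows in member_sets.items():
            col = rows[:, c]
            res = col[0]
            if res in GAP_SET or not (col == res).all():
                continue
            others = [member_sets[o][:, c] for o in member_sets if o != g]
            if any((oc == res).any() for oc in others):
                continue
            entries.append((positions[c], str(res), g))
        for g, (rows, excluded) in composite.items():
            col = rows[:, c]
            res = col[0]
            if res in GAP_SET or not (col == res).all():
                continue
            if any((member_sets[o][:, c] == res).any()
                   for o in excluded if o in member_sets):
                continue
            entries.append((positions[c], str(res), g))

    seen = {}
    for p, r, g in entries:
        if (p, r) in seen:
            raise AssertionError(
                f"residue {r} at {p} attributed to both {seen[(p, r)]} and {g}")
        seen[(p, r)] = g
    return UniqueResidueTable(entries)
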