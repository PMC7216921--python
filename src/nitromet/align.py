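"""Labeled protein alignment container with FASTA/TSV round-trips."""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Closed label set: the three metal-dependence classes plus "unknown".
LABELS = ("Nif", "Vnf", "Anf", "unknown")


@dataclass
class LabeledAlignment:
    """Aligned protein sequences with per-row metal-dependence labels.

    ``reference_name`` designates the row defining the reference numbering
    frame (A. vinelandii NifD coordinates in the real-data analyses).
    """

    names: list[str]
    sequences: list[str]
    labels: list[str]
    reference_name: str | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if not (len(self.names) == len(self.sequences) == len(self.labels)):
            raise ValueError("names, sequences and labels must have equal length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal aligned lengths: {sorted(lengths)}")
        bad = [l for l in self.labels if l not in LABELS]
        if bad:
            raise ValueError(f"labels outside {LABELS}: {sorted(set(bad))}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate row names")
        self._index = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def row(self, name: str) -> str:
        try:
            return self.sequences[self._index[name]]
        except KeyError:
            raise KeyError(f"no row named {name!r} in alignment") from None

    def label_of(self, name: str) -> str:
        return self.labels[self._index[name]]

    def take_columns(self, columns: list[int]) -> "LabeledAlignment":
        """Column-sliced copy (labels and reference row preserved)."""
        ncol = self.n_columns
        for c in columns:
            if not 0 <= c < ncol:
                raise IndexError(f"column {c} outside alignment of width {ncol}")
        seqs = ["".join(s[c] for c in columns) for s in self.sequences]
        return LabeledAlignment(list(self.names), seqs, list(self.labels),
                                self.reference_name)

    def as_matrix(self) -> np.ndarray:
        """Character matrix view (n_rows x n_columns, dtype '<U1')."""
        return np.array([list(s) for s in self.sequences])

    # ---- I/O ----------------------------------------------------------------

    def to_fasta(self) -> str:
        recs = [SeqRecord(Seq(s), id=n, description="")
                for n, s in zip(self.names, self.sequences)]
        buf = StringIO()
        SeqIO.write(recs, buf, "fasta")
        return buf.getvalue()

    def to_label_tsv(self) -> str:
        return "".join(f"{n}\t{l}\n" for n, l in zip(self.names, self.labels))

    @classmethod
    def from_fasta(cls, fasta_text: str,
                   labels: dict[str, str] | None = None,
                   reference_name: str | None = None) -> "LabeledAlignment":
        recs = list(SeqIO.parse(StringIO(fasta_text), "fasta"))
        if not recs:
            raise ValueError("no sequences found in FASTA input")
        names = [r.id for r in recs]
        seqs = [str(r.seq).upper() for r in recs]
        labels = labels or {}
        labs = [labels.get(n, "unknown") for n in names]
        return cls(names, seqs, labs, reference_name)


def parse_label_tsv(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"label TSV line {ln}: expected 'name<TAB>label'")
        out[parts[0]] = parts[1].strip()
    return out
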