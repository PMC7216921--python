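"""Amino-acid substitution model machinery and per-site feature distributions.

The family analyses in this package are built on a reversible 20-state
continuous-time Markov model of amino-acid replacement (JTT by default).
The model supplies two things:

* transition probabilities ``P(t) = expm(Q t)`` used by the ancestral
  reconstruction and by the sequence simulator, and
* the three-component probability distribution over amino acids that encodes
  an observed active-site residue as a classifier feature: the average of a
  point mass on the observed residue, the JTT transition row at a short
  evolutionary distance (0.01 substitutions/site), and a diffuse regularizer
  that keeps every amino acid at non-zero probability.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

#: Canonical amino-acid ordering (PAML dat-file order).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_STATES = 20

#: Symbols treated as "no information at this site".
GAP_CHARS = frozenset("-.*?X")


class UnknownResidueError(ValueError):
    """A sequence character outside the declared alphabet."""

    def __init__(self, char: str, position: int | None = None, name: str | None = None):
        loc = ""
        if name is not None:
            loc += f" in sequence {name!r}"
        if position is not None:
            loc += f" at position {position}"
        super().__init__(f"unknown residue character {char!r}{loc}; "
                         f"expected one of {AMINO_ACIDS} or a gap symbol")
        self.char = char
        self.position = position


def encode_sequence(seq: str, name: str | None = None) -> np.ndarray:
    """Map a protein string to integer states; gaps/ambiguities become -1."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        if ch in AA_INDEX:
            out[i] = AA_INDEX[ch]
        elif ch in GAP_CHARS:
            out[i] = -1
        else:
            raise UnknownResidueError(ch, position=i + 1, name=name)
    return out


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible amino-acid replacement model.

    Parameters
    ----------
    exchangeabilities
        Symmetric non-negative 20x20 matrix ``S`` (diagonal ignored).
    equilibrium_freqs
        Stationary distribution ``pi`` (length 20, sums to 1).

    The rate matrix is ``Q_ij = S_ij * pi_j`` off-diagonal, diagonal set so
    rows sum to zero, globally rescaled so the expected replacement rate
    ``sum_i pi_i * (-Q_ii)`` equals 1 substitution per unit time.
    """

    exchangeabilities: np.ndarray
    equilibrium_freqs: np.ndarray
    name: str = "custom"
    rate_matrix: np.ndarray = field(init=False, repr=False)
    # spectral decomposition of the symmetrized rate matrix, for fast expm
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] = field(
        init=False, repr=False)

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.equilibrium_freqs, dtype=float)
        if S.shape != (N_STATES, N_STATES):
            raise ValueError(f"exchangeability matrix must be 20x20, got {S.shape}")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(S < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ValueError("equilibrium frequencies must be 20 positive values")
        pi = pi / pi.sum()

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q = Q / mu

        # Pi^(1/2) Q Pi^(-1/2) is symmetric under detailed balance -> eigh.
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        B = 0.5 * (B + B.T)
        w, U = np.linalg.eigh(B)
        object.__setattr__(self, "equilibrium_freqs", pi)
        object.__setattr__(self, "exchangeabilities", S)
        object.__setattr__(self, "rate_matrix", Q)
        object.__setattr__(self, "_eig", (w, U, sq, 1.0 / sq))

    def transition_matrix(self, t: float) -> np.ndarray:
        """Row-stochastic ``P(t) = expm(Q t)`` for branch length ``t`` (subst/site)."""
        if t < 0:
            raise ValueError(f"evolutionary distance must be non-negative, got {t}")
        w, U, sq, inv_sq = self._eig
        # P = Pi^(-1/2) U exp(w t) U^T Pi^(1/2)
        P = (inv_sq[:, None] * U) @ (np.exp(w * t)[:, None] * (U.T * sq[None, :]))
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrix_dense(self, t: float) -> np.ndarray:
        """Reference propagator via scipy's matrix exponential (slow path)."""
        if t < 0:
            raise ValueError(f"evolutionary distance must be non-negative, got {t}")
        return expm(self.rate_matrix * t)


def load_paml_dat(text: str, name: str = "custom") -> SubstitutionModel:
    """Parse a PAML-dialect amino-acid model file.

    Layout: 19 lines of the lower-triangular exchangeabilities (row for R has
    1 value, ..., row for V has 19), followed by the 20 equilibrium
    frequencies. Blank lines and trailing commentary are ignored.
    """
    values: list[float] = []
    for line in text.splitlines():
        for tok in line.split():
            try:
                values.append(float(tok))
            except ValueError:
                break  # trailing prose in some published files
    need = 190 + 20
    if len(values) < need:
        raise ValueError(f"model file holds {len(values)} numbers; expected >= {need}")
    tri, freqs = values[:190], values[190:210]
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    return SubstitutionModel(S, np.asarray(freqs), name=name)


def jtt() -> SubstitutionModel:
    """The Jones–Taylor–Thornton replacement model (packaged data table)."""
    text = (importlib.resources.files("nitromet") / "data" / "jtt.dat").read_text()
    return load_paml_dat(text, name="JTT")


@dataclass(frozen=True)
class DistributionConfig:
    """Configuration of the three-component site feature distribution.

    ``component_weights`` orders the components (observed point mass, short
    JTT diffusion, regularizer); the default is the plain unweighted average.
    The regularizer defaults to the model's equilibrium frequencies, which
    places low but strictly positive probability on every amino acid.
    """

    evo_distance: float = 0.01
    component_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    regularizer: np.ndarray | None = None

    def __post_init__(self):
        if self.evo_distance < 0:
            raise ValueError("evo_distance must be >= 0")
        w = np.asarray(self.component_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or np.any(w > 1):
            raise ValueError("component_weights must be three values in [0, 1]")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("component_weights must sum to 1")
        if self.regularizer is not None:
            r = np.asarray(self.regularizer, dtype=float)
            if r.shape != (N_STATES,) or np.any(r <= 0):
                raise ValueError("regularizer must be 20 strictly positive values")
            object.__setattr__(self, "regularizer", r / r.sum())


def site_distribution(observed_residue: str,
                      model: SubstitutionModel,
                      config: DistributionConfig | None = None,
                      *,
                      position: int | None = None,
                      sequence_name: str | None = None) -> np.ndarray:
    """Probability vector over the 20 amino acids encoding one observed residue.

    Weighted average of (a) a point mass on the observed residue, (b) the JTT
    transition row after ``evo_distance`` substitutions/site starting from it,
    and (c) the diffuse regularizer. Gap and ambiguity symbols carry no
    residue information and return the regularizer alone.
    """
    if config is None:
        config = DistributionConfig()
    reg = (config.regularizer if config.regularizer is not None
           else model.equilibrium_freqs)
    ch = observed_residue.upper()
    if ch in GAP_CHARS:
        return reg.copy()
    if ch not in AA_INDEX:
        raise UnknownResidueError(ch, position=position, name=sequence_name)
    i = AA_INDEX[ch]
    point = np.zeros(N_STATES)
    point[i] = 1.0
    diffused = model.transition_matrix(config.evo_distance)[i]
    w = np.asarray(config.component_weights)
    out = w[0] * point + w[1] * diffused + w[2] * reg
    return out / out.sum()
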