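"""Marginal ancestral sequence reconstruction on a fixed rooted tree.

Given a rooted tree with branch lengths (substitutions/site), a gap-aware
protein alignment, and a reversible substitution model, this module computes
exact per-node per-site marginal posterior distributions by Felsenstein
pruning (inside/"down" partial likelihoods from the tips, outside/"up"
messages from the root, equilibrium root prior, sites independent).

From the posteriors it derives maximum-likelihood point ancestors (per-site
argmax, alphabetical tie-break), Bayesian-sampled ancestor variants (each
site drawn independently from its posterior), and per-node support summaries
(mean +/- SD of the per-site maximum posterior). Gap presence/absence at
internal nodes is inferred separately by Fitch parsimony with ambiguities
resolved toward residue presence.

Organised as a model/results pair: :class:`AncestralReconstruction` holds the
inputs, ``fit()`` returns an :class:`ASRResults` carrying the posteriors and
derived quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .align import LabeledAlignment
from .substitution import (AMINO_ACIDS, N_STATES, SubstitutionModel,
                           encode_sequence)


def load_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick tree, preserving underscores in labels."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _node_id(node: dendropy.Node, i: int) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{i}"


@dataclass(frozen=True)
class ASRConfig:
    """Bayesian ancestor sampling configuration."""

    n_samples: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


class ASRResults:
    """Posteriors and derived reconstructions for every internal node.

    Attributes
    ----------
    posteriors
        node id -> (L, 20) array of marginal posterior probabilities.
    gap_flags
        node id -> (L,) boolean array, True where the node is inferred gapped.
    log_likelihood
        Total log-likelihood of the alignment on the tree.
    """

    def __init__(self, posteriors: dict[str, np.ndarray],
                 gap_flags: dict[str, np.ndarray],
                 log_likelihood: float,
                 internal_nodes: list[str],
                 leaf_names: list[str]):
        self.posteriors = posteriors
        self.gap_flags = gap_flags
        self.log_likelihood = log_likelihood
        self.internal_nodes = internal_nodes
        self.leaf_names = leaf_names

    def _node_posteriors(self, node: str) -> np.ndarray:
        try:
            return self.posteriors[node]
        except KeyError:
            raise KeyError(
                f"unknown internal node {node!r}; available: "
                f"{self.internal_nodes}") from None

    def ml_ancestor(self, node: str) -> str:
        """Per-site argmax ancestor; '-' where the gap flag is set.

        Exact posterior ties are broken toward the alphabetically first
        residue (argmax over an alphabetically sorted state order).
        """
        post = self._node_posteriors(node)
        gaps = self.gap_flags[node]
        alpha_order = np.argsort(list(AMINO_ACIDS), kind="stable")
        best = alpha_order[np.argmax(post[:, alpha_order], axis=1)]
        chars = np.array(list(AMINO_ACIDS))[best]
        chars[gaps] = "-"
        return "".join(chars)

    def sample_ancestors(self, node: str,
                         config: ASRConfig | None = None) -> list[str]:
        """Bayesian-sampled ancestor variants: each site drawn independently
        from its posterior; reproducible under the config seed."""
        config = config or ASRConfig()
        post = self._node_posteriors(node)
        gaps = self.gap_flags[node]
        rng = np.random.default_rng(config.seed)
        L = post.shape[0]
        cum = np.cumsum(post, axis=1)
        cum[:, -1] = 1.0
        aa = np.array(list(AMINO_ACIDS))
        out = []
        for _ in range(config.n_samples):
            u = rng.random(L)
            states = (u[:, None] > cum).sum(axis=1)
            chars = aa[states]
            chars[gaps] = "-"
            out.append("".join(chars))
        return out

    def support_summary(self, node: str,
                        site_subset: list[int] | None = None
                        ) -> tuple[float, float]:
        """Mean and population SD of the per-site maximum posterior.

        ``site_subset`` holds 0-based site indices and must avoid gapped
        sites; by default all non-gap sites of the node are used.
        """
        post = self._node_posteriors(node)
        gaps = self.gap_flags[node]
        if site_subset is None:
            sites = np.flatnonzero(~gaps)
        else:
            sites = np.asarray(site_subset, dtype=int)
            if gaps[sites].any():
                bad = sites[gaps[sites]]
                raise ValueError(f"site subset includes gapped sites: {bad.tolist()}")
        maxima = post[sites].max(axis=1)
        return float(maxima.mean()), float(maxima.std())

    def to_tsv(self, node: str) -> str:
        post = self._node_posteriors(node)
        header = "node\tsite\t" + "\t".join(AMINO_ACIDS)
        lines = [header]
        for s in range(post.shape[0]):
            probs = "\t".join(f"{p:.6g}" for p in post[s])
            lines.append(f"{node}\t{s + 1}\t{probs}")
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        lines = ["Marginal ancestral reconstruction",
                 f"  leaves: {len(self.leaf_names)}   "
                 f"internal nodes: {len(self.internal_nodes)}",
                 f"  log-likelihood: {self.log_likelihood:.4f}",
                 "  node            mean max-posterior   SD"]
        for node in self.internal_nodes:
            m, s = self.support_summary(node)
            lines.append(f"  {node:<15s} {m:18.4f} {s:6.4f}")
        return "\n".join(lines)


class AncestralReconstruction:
    """Marginal ASR model: fixed rooted tree + alignment + substitution model."""

    def __init__(self, tree: dendropy.Tree | str,
                 alignment: LabeledAlignment,
                 model: SubstitutionModel):
        if isinstance(tree, str):
            tree = load_tree(tree)
        self.tree = tree
        self.alignment = alignment
        self.model = model
        self._check_taxa()

    def _check_taxa(self):
        leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        rows = set(self.alignment.names)
        missing = leaves - rows
        extra = rows - leaves
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"tree leaves missing from alignment: {sorted(missing)}")
            if extra:
                parts.append(f"alignment rows missing from tree: {sorted(extra)}")
            raise ValueError("; ".join(parts))
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    def fit(self) -> ASRResults:
        tree, aln, model = self.tree, self.alignment, self.model
        pi = model.equilibrium_freqs
        L = aln.n_columns

        nodes = list(tree.postorder_node_iter())
        node_ids = {id(n): _node_id(n, i) for i, n in enumerate(nodes)}
        states = {name: encode_sequence(aln.row(name), name)
                  for name in aln.names}

        # Inside (down) pass: per-node (L, 20) conditional likelihoods with
        # per-site log-scalers to avoid underflow on large trees.
        down: dict[int, np.ndarray] = {}
        logscale: dict[int, np.ndarray] = {}
        P_edge: dict[int, np.ndarray] = {}
        for node in nodes:
            if node.is_leaf():
                s = states[node.taxon.label]
                F = np.zeros((L, N_STATES))
                F[s < 0, :] = 1.0            # gap/ambiguity: uninformative
                ok = s >= 0
                F[np.flatnonzero(ok), s[ok]] = 1.0
                scale = np.zeros(L)
            else:
                F = np.ones((L, N_STATES))
                scale = np.zeros(L)
                for child in node.child_nodes():
                    t = child.edge.length or 0.0
                    P = model.transition_matrix(t)
                    P_edge[id(child)] = P
                    F *= down[id(child)] @ P.T
                    scale += logscale[id(child)]
                m = F.max(axis=1)
                m[m == 0] = 1.0
                F /= m[:, None]
                scale += np.log(m)
            down[id(node)] = F
            logscale[id(node)] = scale

        root = tree.seed_node
        site_like = down[id(root)] @ pi
        log_likelihood = float(np.log(site_like).sum() + logscale[id(root)].sum())

        # Outside (up) pass: message G[v]_j = P(data outside v, state j at v).
        up: dict[int, np.ndarray] = {id(root): np.tile(pi, (L, 1))}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            children = node.child_nodes()
            msgs = [down[id(c)] @ P_edge[id(c)].T for c in children]
            for k, child in enumerate(children):
                sib = up[id(node)].copy()
                for j, m in enumerate(msgs):
                    if j != k:
                        sib *= m
                G = sib @ P_edge[id(child)]
                m = G.max(axis=1)
                m[m == 0] = 1.0
                up[id(child)] = G / m[:, None]

        internal = [n for n in nodes if not n.is_leaf()]
        posteriors: dict[str, np.ndarray] = {}
        for node in internal:
            post = down[id(node)] * up[id(node)]
            tot = post.sum(axis=1, keepdims=True)
            tot[tot == 0] = 1.0
            posteriors[node_ids[id(node)]] = post / tot

        gap_flags = self._fitch_gaps(states, node_ids)

        return ASRResults(
            posteriors=posteriors,
            gap_flags=gap_flags,
            log_likelihood=log_likelihood,
            internal_nodes=[node_ids[id(n)] for n in internal],
            leaf_names=list(aln.names),
        )

    def _fitch_gaps(self, states: dict[str, np.ndarray],
                    node_ids: dict[int, str]) -> dict[str, np.ndarray]:
        """Fitch parsimony on per-site presence/absence, ambiguity -> present.

        State sets are encoded as bitmasks: 1 = present, 2 = absent (gap).
        """
        L = self.alignment.n_columns
        down: dict[int, np.ndarray] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                s = states[node.taxon.label]
                down[id(node)] = np.where(s >= 0, 1, 2).astype(np.int8)
            else:
                masks = [down[id(c)] for c in node.child_nodes()]
                inter = masks[0].copy()
                union = masks[0].copy()
                for m in masks[1:]:
                    inter &= m
                    union |= m
                down[id(node)] = np.where(inter != 0, inter, union).astype(np.int8)

        final: dict[int, np.ndarray] = {}
        flags: dict[str, np.ndarray] = {}
        root = self.tree.seed_node
        rset = down[id(root)]
        final[id(root)] = np.where(rset & 1, 1, 2).astype(np.int8)
        for node in self.tree.preorder_node_iter():
            if node is not root:
                parent_state = final[id(node.parent_node)]
                own = down[id(node)]
                # keep parent state when optimal, else prefer presence
                keep = (own & parent_state) != 0
                pref = np.where(own & 1, 1, 2).astype(np.int8)
                final[id(node)] = np.where(keep, parent_state, pref)
            if not node.is_leaf():
                flags[node_ids[id(node)]] = final[id(node)] == 2
        assert all(f.shape == (L,) for f in flags.values())
        return flags


# ---- thin functional surface ------------------------------------------------

def site_posteriors(tree, alignment: LabeledAlignment,
                    model: SubstitutionModel) -> ASRResults:
    """Marginal per-node per-site posteriors (see :class:`AncestralReconstruction`)."""
    return AncestralReconstruction(tree, alignment, model).fit()


def ml_ancestor(results: ASRResults, node: str) -> str:
    return results.ml_ancestor(node)


def sample_ancestors(results: ASRResults, node: str,
                     config: ASRConfig | None = None) -> list[str]:
    return results.sample_ancestors(node, config)


def infer_gaps(tree, alignment: LabeledAlignment) -> dict[str, np.ndarray]:
    """Per-node per-site gap flags by Fitch parsimony (no model needed)."""
    from .substitution import jtt
    recon = AncestralReconstruction(tree, alignment, jtt())
    states = {name: encode_sequence(alignment.row(name), name)
              for name in alignment.names}
    nodes = list(recon.tree.postorder_node_iter())
    node_ids = {id(n): _node_id(n, i) for i, n in enumerate(nodes)}
    return recon._fitch_gaps(states, node_ids)


def posterior_support_summary(results: ASRResults, node: str,
                              site_subset: list[int] | None = None
                              ) -> tuple[float, float]:
    return results.support_summary(node, site_subset)
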