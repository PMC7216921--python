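"""Probabilistic metal-dependence classification of nitrogenase sequences.

Every sequence (extant or ancestral) is represented by the concatenation of
per-active-site probability distributions over the 20 amino acids: observed
residues are encoded through the three-component site distribution
(:func:`nitromet.substitution.site_distribution`), ancestral sites use their
reconstruction posteriors directly. A weighted one-versus-rest support-vector
machine with a radial-basis kernel is trained on sequences of known metal
dependence (Nif / Vnf / Anf), with

* kernel coefficient  gamma = 1 / (n_features * Var(features))  computed on
  the training split,
* per-sample class weights  w(c) = n_train / (3 * count(c)),
* the regularization parameter C chosen by k-fold cross-validation on the
  training split, and
* out-of-sample accuracy measured on a held-out split, the whole protocol
  replicated over independent random 60/40 splits.

Classification support is the signed distance of a sample from each
class-defining hyperplane; the predicted label attains the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .align import LabeledAlignment
from .asr import ASRResults
from .substitution import (N_STATES, DistributionConfig, SubstitutionModel,
                           site_distribution)

KNOWN_CLASSES = ("Nif", "Vnf", "Anf")


@dataclass
class FeatureMatrix:
    """n_samples x (n_sites * 20) matrix of per-site amino-acid probabilities."""

    data: np.ndarray
    row_names: list[str]
    site_positions: list[int]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n_sites = len(self.site_positions)
        if self.data.ndim != 2 or self.data.shape[1] != n_sites * N_STATES:
            raise ValueError(
                f"feature matrix must be (n, {n_sites * N_STATES}); "
                f"got {self.data.shape}")
        if len(self.row_names) != self.data.shape[0]:
            raise ValueError("row_names length mismatch")
        if np.any(self.data < -1e-12) or np.any(self.data > 1 + 1e-12):
            raise ValueError("feature entries must lie in [0, 1]")
        blocks = self.data.reshape(self.data.shape[0], n_sites, N_STATES)
        if not np.allclose(blocks.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("each 20-block must sum to 1")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def encode_extant(active_site_alignment: LabeledAlignment,
                  model: SubstitutionModel,
                  dist_config: DistributionConfig | None = None
                  ) -> FeatureMatrix:
    """Feature rows for observed sequences restricted to active-site columns."""
    dist_config = dist_config or DistributionConfig()
    n_sites = active_site_alignment.n_columns
    rows = []
    for name, seq in zip(active_site_alignment.names,
                         active_site_alignment.sequences):
        vecs = [site_distribution(ch, model, dist_config,
                                  position=i + 1, sequence_name=name)
                for i, ch in enumerate(seq)]
        rows.append(np.concatenate(vecs))
    return FeatureMatrix(np.array(rows), list(active_site_alignment.names),
                         list(range(1, n_sites + 1)))


def encode_ancestor(results: ASRResults, node: str,
                    site_columns: list[int],
                    site_positions: list[int] | None = None,
                    gap_policy: str = "error") -> FeatureMatrix:
    """One feature row for an ancestral node: the reconstruction posteriors at
    the given 0-based alignment columns, used directly as the 20-blocks.

    ``gap_policy`` controls sites where the ancestor is inferred gapped:
    ``"error"`` (default) raises; ``"uniform"`` substitutes a flat
    distribution so classification can proceed.
    """
    post = results.posteriors[node] if node in results.posteriors else None
    if post is None:
        raise KeyError(f"unknown internal node {node!r}")
    gaps = results.gap_flags[node]
    cols = np.asarray(site_columns, dtype=int)
    if gaps[cols].any():
        bad = cols[gaps[cols]].tolist()
        if gap_policy == "error":
            raise ValueError(
                f"ancestor {node!r} is gapped at active-site columns {bad}; "
                f"set gap_policy='uniform' to substitute a flat distribution")
        if gap_policy != "uniform":
            raise ValueError(f"unknown gap_policy {gap_policy!r}")
    block = post[cols].copy()
    if gap_policy == "uniform":
        block[gaps[cols]] = 1.0 / N_STATES
    block /= block.sum(axis=1, keepdims=True)
    positions = (list(site_positions) if site_positions is not None
                 else [c + 1 for c in site_columns])
    return FeatureMatrix(block.reshape(1, -1), [node], positions)


@dataclass(frozen=True)
class TrainConfig:
    """Replicated split / cross-validation protocol for classifier training."""

    train_fraction: float = 0.6
    n_replicates: int = 10
    cv_folds: int = 5
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    seed: int = 0
    stratified: bool = False

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(c <= 0 for c in self.C_grid):
            raise ValueError("C values must be positive")


@dataclass
class ClassificationResult:
    """Predicted label with per-class signed hyperplane distances."""

    name: str
    label: str
    distances: dict[str, float]


@dataclass
class MetalClassifier:
    """Fitted one-vs-rest RBF support-vector model (one machine per class)."""

    estimators: dict[str, SVC]
    classes: tuple[str, ...]
    gamma: float
    class_weights: dict[str, float]
    C: float
    n_features: int = field(default=0)

    def decision_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimensionality {X.shape} does not match the "
                f"{self.n_features} training features")
        return np.column_stack([self.estimators[c].decision_function(X)
                                for c in self.classes])

    def classify(self, features: FeatureMatrix | np.ndarray,
                 names: list[str] | None = None) -> list[ClassificationResult]:
        if isinstance(features, FeatureMatrix):
            X = features.data
            names = names or features.row_names
        else:
            X = np.asarray(features, dtype=float)
            names = names or [f"sample{i}" for i in range(X.shape[0])]
        D = self.decision_matrix(X)
        out = []
        for name, drow in zip(names, D):
            label = self.classes[int(np.argmax(drow))]
            out.append(ClassificationResult(
                name, label, {c: float(d) for c, d in zip(self.classes, drow)}))
        return out


def compute_class_weights(y: np.ndarray | list[str],
                          classes: tuple[str, ...]) -> dict[str, float]:
    """Per-sample class weights: w(c) = n_samples / (n_classes * count(c))."""
    y = np.asarray(y)
    return {c: len(y) / (len(classes) * int((y == c).sum())) for c in classes}


def compute_gamma(X: np.ndarray) -> float:
    """RBF kernel coefficient: 1 / (n_features * Var(features)), with the
    variance pooled over the whole training feature matrix."""
    X = np.asarray(X, dtype=float)
    var = X.var()
    return 1.0 / (X.shape[1] * var) if var > 0 else 1.0


def _fit_ovr(X: np.ndarray, y: np.ndarray, classes: tuple[str, ...],
             C: float) -> MetalClassifier:
    """Fit one weighted binary RBF-SVC per class on (X, y)."""
    n, p = X.shape
    gamma = compute_gamma(X)
    weights = compute_class_weights(y, classes)
    sw = np.array([weights[c] for c in y])
    estimators = {}
    for c in classes:
        svc = SVC(kernel="rbf", gamma=gamma, C=C)
        svc.fit(X, (y == c).astype(int), sample_weight=sw)
        estimators[c] = svc
    return MetalClassifier(estimators, classes, gamma, weights, C, n_features=p)


def _cv_choose_C(X: np.ndarray, y: np.ndarray, classes: tuple[str, ...],
                 config: TrainConfig) -> float:
    """Pick C from the grid by k-fold CV accuracy on the training split
    (deterministic contiguous folds; ties resolved toward the smallest C)."""
    n = len(y)
    folds = np.array_split(np.arange(n), config.cv_folds)
    best_C, best_acc = config.C_grid[0], -1.0
    for C in config.C_grid:
        correct = total = 0
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            if len(set(y[mask])) < len(classes):
                continue  # degenerate fold: a class absent from training part
            clf = _fit_ovr(X[mask], y[mask], classes, C)
            D = clf.decision_matrix(X[fold])
            pred = np.array(classes)[D.argmax(axis=1)]
            correct += int((pred == y[fold]).sum())
            total += len(fold)
        acc = correct / total if total else 0.0
        if acc > best_acc + 1e-12:
            best_C, best_acc = C, acc
    return best_C


@dataclass
class ReplicateRecord:
    accuracy: float
    chosen_C: float
    n_train: int
    n_test: int


class MetalDependenceResults:
    """Fitted classifier plus the replicated out-of-sample evaluation report.

    ``model`` is the deployed classifier refit on all labeled data (used to
    classify ancestors and uncharacterized sequences); ``eval_model`` is the
    final replicate's training-split model, retained for audit.
    """

    def __init__(self, model: MetalClassifier, eval_model: MetalClassifier,
                 replicates: list[ReplicateRecord], config: TrainConfig,
                 classes: tuple[str, ...]):
        self.model = model
        self.eval_model = eval_model
        self.replicates = replicates
        self.config = config
        self.classes = classes

    @property
    def replicate_accuracies(self) -> list[float]:
        return [r.accuracy for r in self.replicates]

    def classify(self, features, names=None) -> list[ClassificationResult]:
        return self.model.classify(features, names)

    def summary(self) -> str:
        accs = np.array(self.replicate_accuracies)
        lines = [
            "Metal-dependence support-vector classifier (one-vs-rest, RBF)",
            f"  classes: {', '.join(self.classes)}",
            f"  replicates: {len(self.replicates)}  "
            f"train fraction: {self.config.train_fraction:.2f}  "
            f"CV folds: {self.config.cv_folds}",
            f"  out-of-sample accuracy: mean {accs.mean():.4f}  "
            f"min {accs.min():.4f}  max {accs.max():.4f}",
            f"  deployed model: gamma {self.model.gamma:.6g}, "
            f"C {self.model.C:g}, class weights "
            + ", ".join(f"{c}={w:.3f}"
                        for c, w in self.model.class_weights.items()),
        ]
        for i, r in enumerate(self.replicates, 1):
            lines.append(f"    replicate {i:2d}: accuracy {r.accuracy:.4f} "
                         f"(C={r.chosen_C:g}, {r.n_train}/{r.n_test} split)")
        return "\n".join(lines)


class MetalDependenceModel:
    """Trainable metal-dependence model over encoded active-site features."""

    def __init__(self, features: FeatureMatrix | np.ndarray,
                 labels: list[str]):
        X = features.data if isinstance(features, FeatureMatrix) else \
            np.asarray(features, dtype=float)
        y = np.asarray(labels)
        if X.shape[0] != len(y):
            raise ValueError("features and labels length mismatch")
        known = np.isin(y, KNOWN_CLASSES)
        if not known.all():
            bad = sorted(set(y[~known]))
            raise ValueError(f"labels outside {KNOWN_CLASSES}: {bad} "
                             "(drop unknown-label rows before training)")
        present = tuple(c for c in KNOWN_CLASSES if (y == c).any())
        if len(present) < 2:
            raise ValueError("training requires >= 2 distinct classes, "
                             f"got {present}")
        for c in present:
            if (y == c).sum() < 2:
                raise ValueError(f"class {c!r} has fewer than 2 members")
        self.X = X
        self.y = y
        self.classes = present

    def fit(self, config: TrainConfig | None = None) -> MetalDependenceResults:
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)
        n = len(self.y)
        n_train = int(round(config.train_fraction * n))
        if not 0 < n_train < n:
            raise ValueError("train fraction leaves an empty split")

        replicates: list[ReplicateRecord] = []
        eval_model: MetalClassifier | None = None
        for _ in range(config.n_replicates):
            if config.stratified:
                train_idx: list[int] = []
                for c in self.classes:
                    idx = np.flatnonzero(self.y == c)
                    k = max(1, int(round(config.train_fraction * len(idx))))
                    train_idx.extend(rng.permutation(idx)[:k])
                train_idx = np.sort(np.array(train_idx))
                mask = np.zeros(n, dtype=bool)
                mask[train_idx] = True
            else:
                perm = rng.permutation(n)
                mask = np.zeros(n, dtype=bool)
                mask[perm[:n_train]] = True
            y_tr = self.y[mask]
            if len(set(y_tr)) < len(self.classes):
                missing = set(self.classes) - set(y_tr)
                raise RuntimeError(
                    f"random split left class(es) {sorted(missing)} without "
                    f"training members; use stratified=True")
            C = _cv_choose_C(self.X[mask], y_tr, self.classes, config)
            clf = _fit_ovr(self.X[mask], y_tr, self.classes, C)
            D = clf.decision_matrix(self.X[~mask])
            pred = np.array(self.classes)[D.argmax(axis=1)]
            acc = float((pred == self.y[~mask]).mean())
            replicates.append(ReplicateRecord(acc, C, int(mask.sum()),
                                              int((~mask).sum())))
            eval_model = clf

        # deployed model: refit on 100% of the labeled data with the last
        # replicate's cross-validated C
        final_C = replicates[-1].chosen_C
        model = _fit_ovr(self.X, self.y, self.classes, final_C)
        return MetalDependenceResults(model, eval_model, replicates, config,
                                      self.classes)


# ---- PCA separability check -------------------------------------------------

def _strictly_separable(A: np.ndarray, B: np.ndarray) -> bool:
    """Exact strict linear separability via an LP feasibility problem:
    find w, b with w.x + b >= 1 on A and <= -1 on B."""
    k = A.shape[1]
    # variables: w (k), b;  constraints as A_ub x <= b_ub
    A_ub = np.vstack([np.hstack([-A, -np.ones((len(A), 1))]),
                      np.hstack([B, np.ones((len(B), 1))])])
    b_ub = -np.ones(len(A) + len(B))
    res = linprog(c=np.zeros(k + 1), A_ub=A_ub, b_ub=b_ub,
                  bounds=[(None, None)] * (k + 1), method="highs")
    return bool(res.success)


def pca_separability(features: FeatureMatrix | np.ndarray,
                     labels: list[str], max_components: int = 3
                     ) -> dict[str, int | None]:
    """Minimal number of principal components on which the stated class
    contrasts are perfectly linearly separable.

    Contrasts follow the family structure: Mo-nitrogenases against the
    V/Fe union, and V against Fe. On one component separability means
    disjoint ranges; on k >= 2 a strict separating hyperplane must exist.
    Returns ``None`` for a contrast not separable within ``max_components``.
    """
    X = features.data if isinstance(features, FeatureMatrix) else \
        np.asarray(features, dtype=float)
    y = np.asarray(labels)
    known = np.isin(y, KNOWN_CLASSES)
    X, y = X[known], y[known]
    if len(set(y)) < 2:
        raise ValueError("need >= 2 classes for a separability check")
    n_comp = min(max_components, X.shape[0] - 1, X.shape[1])
    Z = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)

    contrasts = {
        "Nif_vs_VnfAnf": (y == "Nif", np.isin(y, ("Vnf", "Anf"))),
        "Vnf_vs_Anf": (y == "Vnf", y == "Anf"),
    }
    report: dict[str, int | None] = {}
    for name, (ma, mb) in contrasts.items():
        if not (ma.any() and mb.any()):
            continue
        report[name] = None
        for k in range(1, n_comp + 1):
            A, B = Z[ma, :k], Z[mb, :k]
            if k == 1:
                sep = A.max() < B.min() or B.max() < A.min()
            else:
                sep = _strictly_separable(A, B)
            if sep:
                report[name] = k
                break
    return report
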