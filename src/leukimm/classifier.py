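"""Probabilistic TCR-specificity classification on CDR3beta sequences.

Sequences are center-gapped to a fixed length and encoded position-wise with
unit-normalized BLOSUM62 rows; a variational Gaussian-process classifier with
a squared-exponential kernel on the encodings maps each CDR3beta to a
probability of antigen specificity.  Stratified cross-validation reports
per-fold and mean AUROC; repertoire-level prediction sums the clone
frequencies of clonotypes called specific (the read-weighted fraction of the
repertoire predicted antigen-specific).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .gp import VariationalGPClassifier, rbf_kernel_matrix
from .repertoire import Repertoire
from .simulate import AMINO_ACIDS

__all__ = [
    "ClassifierConfig",
    "CVReport",
    "TCRSpecificityClassifier",
    "encode_cdr3",
    "kernel_matrix",
    "train",
    "cross_validate",
    "predict_repertoire",
    "auroc",
]


def _blosum_rows() -> dict[str, np.ndarray]:
    mat = substitution_matrices.load("BLOSUM62")
    rows = {}
    for aa in AMINO_ACIDS:
        row = np.array([float(mat[aa, bb]) for bb in AMINO_ACIDS])
        rows[aa] = row / np.linalg.norm(row)
    return rows


_BLOSUM_ROWS = _blosum_rows()


def encode_cdr3(cdr3_aa: str, max_len: int = 22) -> np.ndarray:
    """Encode a CDR3 as a center-gapped stack of BLOSUM62 rows.

    The first ceil(L/2) residues are left-aligned, the remainder
    right-aligned; middle gap positions are zero vectors.  Each residue maps
    to its unit-normalized BLOSUM62 row, giving a vector of length
    max_len * 20.
    """
    L = len(cdr3_aa)
    if L == 0:
        raise ValueError("empty CDR3 sequence")
    if L > max_len:
        raise ValueError(f"CDR3 longer than max_len={max_len}: {cdr3_aa!r}")
    illegal = set(cdr3_aa) - set(AMINO_ACIDS)
    if illegal:
        raise ValueError(f"illegal character(s) {sorted(illegal)} in {cdr3_aa!r}")
    out = np.zeros((max_len, 20))
    n_left = -(-L // 2)  # ceil
    for i in range(n_left):
        out[i] = _BLOSUM_ROWS[cdr3_aa[i]]
    for j, i in enumerate(range(n_left, L)):
        out[max_len - (L - n_left) + j] = _BLOSUM_ROWS[cdr3_aa[i]]
    return out.ravel()


def encode_many(seqs: Sequence[str], max_len: int = 22) -> np.ndarray:
    return np.array([encode_cdr3(s, max_len) for s in seqs])


def kernel_matrix(
    X1: np.ndarray,
    X2: np.ndarray,
    lengthscale: float = 1.0,
    signal_variance: float = 1.0,
) -> np.ndarray:
    """Squared-exponential kernel on encodings (see `gp.rbf_kernel_matrix`)."""
    return rbf_kernel_matrix(X1, X2, lengthscale, signal_variance)


@dataclass(frozen=True)
class ClassifierConfig:
    """Training settings for the CDR3beta specificity classifier."""

    max_len: int = 22
    lengthscale: float = 1.0
    signal_variance: float = 1.0
    iterations: int = 2000
    learning_rate: float = 0.005
    folds: int = 10
    threshold: float = 0.5
    jitter: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class CVReport:
    """Stratified cross-validation summary."""

    fold_aurocs: list[float]
    mean_auroc: float
    fold_assignments: np.ndarray  # fold index per training item


class TCRSpecificityClassifier(BaseEstimator, ClassifierMixin):
    """GP classifier from CDR3beta strings to specificity probabilities.

    A scikit-learn estimator: `fit` takes a sequence of CDR3 amino-acid
    strings and binary labels (1 = antigen-specific), `predict_proba` returns
    calibrated probabilities from the GP posterior.  Class imbalance is
    handled by the natural prior of the training design (no reweighting).
    """

    def __init__(
        self,
        max_len: int = 22,
        lengthscale: float = 1.0,
        signal_variance: float = 1.0,
        iterations: int = 2000,
        learning_rate: float = 0.005,
        jitter: float = 1e-6,
        random_state: int = 0,
    ):
        self.max_len = max_len
        self.lengthscale = lengthscale
        self.signal_variance = signal_variance
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.jitter = jitter
        self.random_state = random_state

    def fit(self, X: Sequence[str], y):
        y = np.asarray(y).astype(int)
        enc = encode_many(list(X), self.max_len)
        self.gp_ = VariationalGPClassifier(
            lengthscale=self.lengthscale,
            signal_variance=self.signal_variance,
            iterations=self.iterations,
            learning_rate=self.learning_rate,
            jitter=self.jitter,
            random_state=self.random_state,
        ).fit(enc, y)
        self.classes_ = self.gp_.classes_
        self.n_positives_ = int(np.sum(y == 1))
        self.n_controls_ = int(np.sum(y == 0))
        return self

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        enc = encode_many(list(X), self.max_len)
        return self.gp_.predict_proba(enc)

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        return self.gp_.decision_function(encode_many(list(X), self.max_len))

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model to a JSON file (arrays as lists)."""
        gp = self.gp_
        payload = {
            "params": self.get_params(),
            "lengthscale_": gp.lengthscale_,
            "signal_variance_": gp.signal_variance_,
            "m_": gp.m_.tolist(),
            "s_": gp.s_.tolist(),
            "X_train_": gp.X_train_.tolist(),
            "y_train_": gp.y_train_.tolist(),
            "classes_": gp.classes_.tolist(),
            "n_positives_": self.n_positives_,
            "n_controls_": self.n_controls_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TCRSpecificityClassifier":
        from scipy.linalg import cholesky
        from scipy.spatial.distance import cdist
        from numpy.polynomial.hermite_e import hermegauss

        payload = json.loads(Path(path).read_text())
        clf = cls(**payload["params"])
        gp = VariationalGPClassifier(
            iterations=clf.iterations,
            learning_rate=clf.learning_rate,
            jitter=clf.jitter,
        )
        gp.X_train_ = np.array(payload["X_train_"])
        gp.y_train_ = np.array(payload["y_train_"])
        gp.m_ = np.array(payload["m_"])
        gp.s_ = np.array(payload["s_"])
        gp.lengthscale_ = payload["lengthscale_"]
        gp.signal_variance_ = payload["signal_variance_"]
        gp.classes_ = np.array(payload["classes_"])
        K = rbf_kernel_matrix(
            gp.X_train_, gp.X_train_, gp.lengthscale_, gp.signal_variance_
        )
        K[np.diag_indices_from(K)] += gp.jitter
        gp.L_ = cholesky(K, lower=True)
        t, w = hermegauss(gp.n_quad)
        gp._t_nodes, gp._w_nodes = t, w / np.sqrt(2.0 * np.pi)
        clf.gp_ = gp
        clf.classes_ = gp.classes_
        clf.n_positives_ = payload["n_positives_"]
        clf.n_controls_ = payload["n_controls_"]
        return clf


# ---------------------------------------------------------------------------
# Functional interface


def _assemble(positives: Sequence[str], controls: Sequence[str]):
    X = list(positives) + list(controls)
    y = np.r_[np.ones(len(positives), dtype=int), np.zeros(len(controls), dtype=int)]
    return X, y


def train(
    positives: Sequence[str],
    controls: Sequence[str],
    config: ClassifierConfig = ClassifierConfig(),
) -> TCRSpecificityClassifier:
    """Train a specificity classifier on positive and control CDR3 sets."""
    if len(positives) < 10 or len(controls) < 10:
        raise ValueError("need at least 10 positives and 10 controls")
    X, y = _assemble(positives, controls)
    clf = TCRSpecificityClassifier(
        max_len=config.max_len,
        lengthscale=config.lengthscale,
        signal_variance=config.signal_variance,
        iterations=config.iterations,
        learning_rate=config.learning_rate,
        jitter=config.jitter,
        random_state=config.seed,
    )
    return clf.fit(X, y)


def cross_validate(
    positives: Sequence[str],
    controls: Sequence[str],
    config: ClassifierConfig = ClassifierConfig(),
) -> CVReport:
    """Stratified k-fold cross-validation with held-out AUROC per fold."""
    if len(positives) < 10 or len(controls) < 10:
        raise ValueError("need at least 10 positives and 10 controls")
    X, y = _assemble(positives, controls)
    X = np.asarray(X, dtype=object)
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.seed
    )
    folds = np.empty(len(y), dtype=int)
    aurocs = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        folds[te] = k
        clf = TCRSpecificityClassifier(
            max_len=config.max_len,
            lengthscale=config.lengthscale,
            signal_variance=config.signal_variance,
            iterations=config.iterations,
            learning_rate=config.learning_rate,
            jitter=config.jitter,
            random_state=config.seed + k,
        ).fit(list(X[tr]), y[tr])
        scores = clf.predict_proba(list(X[te]))[:, 1]
        aurocs.append(auroc(scores, y[te]))
    return CVReport(
        fold_aurocs=aurocs,
        mean_auroc=float(np.mean(aurocs)),
        fold_assignments=folds,
    )


def predict_repertoire(
    clf: TCRSpecificityClassifier,
    rep: Repertoire,
    threshold: float = 0.5,
) -> tuple[np.ndarray, float, int]:
    """Score every clonotype and quantify the predicted-specific repertoire share.

    Returns per-clonotype probabilities, the read-weighted specific fraction
    (sum of clone frequencies with probability >= threshold) and the number of
    such clonotypes.  Clonotypes that cannot be encoded (longer than max_len
    or with non-standard letters) receive probability 0.
    """
    probs = np.zeros(len(rep))
    encodable = []
    idx = []
    for i, c in enumerate(rep.clonotypes):
        seq = c.cdr3_aa
        if 0 < len(seq) <= clf.max_len and not (set(seq) - set(AMINO_ACIDS)):
            encodable.append(seq)
            idx.append(i)
    if encodable:
        probs[np.array(idx)] = clf.predict_proba(encodable)[:, 1]
    positive = probs >= threshold
    specific_fraction = float(np.sum(rep.frequencies()[positive]))
    return probs, specific_fraction, int(np.sum(positive))


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    The probability that a random positive outscores a random negative, with
    ties counted 1/2: U / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    r_pos = float(np.sum(ranks[labels == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
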