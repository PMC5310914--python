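"""Mutational-signature extraction by non-negative matrix factorization.

The intensity matrix X (96 classes x n samples) is factored as X ~ W H with
W (96 x k) the signature weights and H (k x n) the per-sample loadings,
using the multiplicative updates of Lee & Seung for the Euclidean
(Frobenius) objective ||X - WH||_F^2, which is non-increasing under the
updates. Initialization is either random or from the non-negative parts of
a fastICA decomposition; ICA-based starts tend to avoid the CpG-dominated
local optima that random starts can fall into (for which the explicit
`subtract_cpg_floor` correction exists).

The multiplicative updates are implemented here rather than delegated to a
generic solver because the per-iteration objective trajectory, the rank
diagnostics (consensus dispersion, best-of-starts RSS, silhouette), and the
warm-started rank nesting are all part of the analysis surface; scikit-learn
is used for the FastICA initializer and PCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA, FastICA
from sklearn.metrics import silhouette_score

from .io import canonical_contexts
from .variant_spectrum import CLASSES, CLASS_LABELS, IntensityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSet",
    "RankDiagnostics",
    "nmf_fit",
    "ica_init",
    "random_init",
    "rank_diagnostics",
    "rescale_signature",
    "compare_catalog",
    "read_catalog",
    "pca_spectrum",
    "subtract_cpg_floor",
]

_EPS = 1e-9


@dataclass
class SignatureSet:
    """An NMF factorization: weights (96 x k), loadings (k x n)."""

    weights: np.ndarray
    loadings: np.ndarray
    rank: int
    rss: float
    n_iterations: int
    objective_history: np.ndarray | None = None
    init: str = "random"

    def __post_init__(self) -> None:
        if (self.weights < 0).any() or (self.loadings < 0).any():
            raise ValueError("factors must be non-negative")

    def reconstruction(self) -> np.ndarray:
        return self.weights @ self.loadings

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights,
            index=list(CLASS_LABELS),
            columns=[f"signature_{i + 1}" for i in range(self.rank)],
        )

    def loadings_frame(self, sample_names=None) -> pd.DataFrame:
        cols = sample_names if sample_names is not None else range(self.loadings.shape[1])
        return pd.DataFrame(
            self.loadings,
            index=[f"signature_{i + 1}" for i in range(self.rank)],
            columns=list(cols),
        )


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, IntensityMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    if (X < 0).any():
        raise ValueError("X must be non-negative")
    if (X.sum(axis=1) == 0).any():
        raise ValueError(
            "X has an all-zero row; drop unobserved classes before factorizing"
        )
    if (X.sum(axis=0) == 0).any():
        raise ValueError("X has an all-zero column; drop empty samples first")
    return X


def random_init(X: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    scale = np.sqrt(X.mean() / k)
    return (
        scale * rng.random((X.shape[0], k)) + _EPS,
        scale * rng.random((k, X.shape[1])) + _EPS,
    )


def ica_init(X, k: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative initial factors from a fastICA decomposition.

    Each independent component's sign is chosen so that its entries sum to a
    positive value, negative entries are then zeroed, and a small epsilon is
    added so no entry is absorbed at zero by the multiplicative updates. If
    ICA fails to converge a random initialization is returned instead
    (logged)."""
    X = _as_matrix(X)
    rng = np.random.default_rng(seed)
    max_iter = 500
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # the "exp" contrast converges much more reliably than logcosh on
        # sparse gamma-like signature data
        ica = FastICA(
            n_components=k,
            random_state=int(rng.integers(2**31)),
            max_iter=max_iter,
            tol=1e-3,
            fun="exp",
        )
        try:
            sources = ica.fit_transform(X.T)  # (n_samples, k)
        except Exception as e:  # numerical failure: fall back
            logger.warning("fastICA failed (%s); falling back to random init", e)
            return random_init(X, k, rng)
    if ica.n_iter_ >= max_iter:
        logger.warning("fastICA did not converge; falling back to random init")
        return random_init(X, k, rng)
    mixing = ica.mixing_  # (96, k)
    signs = np.where(mixing.sum(axis=0) >= 0, 1.0, -1.0)
    W0 = np.clip(mixing * signs, 0, None) + _EPS
    H0 = np.clip(sources.T * signs[:, None], 0, None) + _EPS
    return W0, H0


def nmf_fit(
    X,
    rank: int,
    init: str = "ica",
    seed: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    init_factors: tuple[np.ndarray, np.ndarray] | None = None,
) -> SignatureSet:
    """Fit NMF by Lee-Seung multiplicative updates (Euclidean objective).

    Converges when the relative change of ||X - WH||_F^2 drops below ``tol``
    or after ``max_iter`` iterations. Factors are gauge-fixed so each
    signature (column of W) sums to 1, and ordered by descending total
    loading."""
    X = _as_matrix(X)
    if not 1 <= rank <= min(X.shape):
        raise ValueError(f"rank must be in [1, {min(X.shape)}]")
    rng = np.random.default_rng(seed)
    if init_factors is not None:
        W, H = (np.array(f, dtype=float) for f in init_factors)
        if (W < 0).any() or (H < 0).any():
            raise ValueError("initial factors must be non-negative")
        W, H = W + _EPS, H + _EPS
    elif init == "ica":
        W, H = ica_init(X, rank, seed=None if seed is None else seed)
    elif init == "random":
        W, H = random_init(X, rank, rng)
    else:
        raise ValueError(f"unknown init {init!r}")

    history = []
    obj = float(((X - W @ H) ** 2).sum())
    history.append(obj)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ H @ H.T + _EPS)
        new_obj = float(((X - W @ H) ** 2).sum())
        history.append(new_obj)
        if obj > 0 and (obj - new_obj) / obj < tol:
            obj = new_obj
            break
        obj = new_obj

    # gauge: push scale into the loadings, order by total loading
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W = W / col
    H = H * col[:, None]
    order = np.argsort(-H.sum(axis=1), kind="stable")
    return SignatureSet(
        weights=W[:, order],
        loadings=H[order],
        rank=rank,
        rss=obj,
        n_iterations=n_iter,
        objective_history=np.array(history),
        init=init if init_factors is None else "custom",
    )


@dataclass
class RankDiagnostics:
    """Per-rank model-selection diagnostics over repeated random starts."""

    table: pd.DataFrame  # columns: rank, dispersion, rss, silhouette
    n_starts: int

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _dominant_labels(loadings: np.ndarray) -> np.ndarray:
    return loadings.argmax(axis=0)


def rank_diagnostics(
    X,
    ranks=range(2, 9),
    n_starts: int = 50,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> RankDiagnostics:
    """Consensus dispersion, best-of-starts RSS, and silhouette per rank.

    Dispersion is mean(4 (C_ij - 1/2)^2) of the consensus co-clustering
    matrix C over starts (1 = perfectly reproducible). Silhouette uses the
    best run's dominant-factor assignment with distance 1 - Pearson
    correlation between sample loading profiles. One start per rank is
    warm-started from the previous rank's best factors (augmented with a
    small extra component), which makes best-of-starts RSS non-increasing
    in rank.
    """
    if n_starts < 2:
        raise ValueError("need at least 2 starts")
    X = _as_matrix(X)
    n = X.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    prev_best: SignatureSet | None = None
    for rank in ranks:
        consensus = np.zeros((n, n))
        best: SignatureSet | None = None
        for s in range(n_starts):
            fit = nmf_fit(
                X, rank, init="random", seed=int(rng.integers(2**31)),
                max_iter=max_iter, tol=tol,
            )
            labels = _dominant_labels(fit.loadings)
            consensus += labels[:, None] == labels[None, :]
            if best is None or fit.rss < best.rss:
                best = fit
        if prev_best is not None:
            # warm start nested in the previous rank's best solution
            extra = rank - prev_best.rank
            if extra > 0:
                scale = max(prev_best.weights.mean(), _EPS)
                W0 = np.hstack(
                    [prev_best.weights, scale * 1e-3 * rng.random((X.shape[0], extra))]
                )
                H0 = np.vstack(
                    [prev_best.loadings, 1e-3 * rng.random((extra, n))]
                )
                warm = nmf_fit(X, rank, init_factors=(W0, H0), max_iter=max_iter, tol=tol)
                if warm.rss < best.rss:
                    best = warm
        consensus /= n_starts
        dispersion = float((4 * (consensus - 0.5) ** 2).mean())
        labels = _dominant_labels(best.loadings)
        if len(np.unique(labels)) < 2:
            sil = float("nan")
        else:
            corr = np.corrcoef(best.loadings.T)
            dist = np.clip(1.0 - corr, 0, None)
            np.fill_diagonal(dist, 0.0)
            sil = float(silhouette_score(dist, labels, metric="precomputed"))
        rows.append((rank, dispersion, best.rss, sil))
        prev_best = best
    return RankDiagnostics(
        pd.DataFrame(rows, columns=["rank", "dispersion", "rss", "silhouette"]),
        n_starts,
    )


def rescale_signature(weights: np.ndarray, trinuc_freqs) -> np.ndarray:
    """Rescale class weights by the reference trinucleotide frequency of
    each class's context (the plotted scale; not interpretable in absolute
    terms)."""
    weights = np.asarray(weights, dtype=float)
    freqs = dict(trinuc_freqs) if not isinstance(trinuc_freqs, dict) else trinuc_freqs
    missing = {c.context for c in CLASSES} - set(freqs)
    if missing:
        raise ValueError(f"missing context frequencies: {sorted(missing)}")
    scale = np.array([freqs[c.context] for c in CLASSES])
    if (scale <= 0).any():
        raise ValueError("context frequencies must be positive")
    return weights * (scale[:, None] if weights.ndim == 2 else scale)


def compare_catalog(weights: np.ndarray, catalog: pd.DataFrame) -> pd.Series:
    """Pearson correlation of one 96-class signature against each catalog
    column, sorted descending (best match first)."""
    w = np.asarray(weights, dtype=float).ravel()
    if len(w) != 96 or len(catalog) != 96:
        raise ValueError("signature and catalog must cover the 96 classes")
    if np.std(w) == 0:
        raise ValueError("zero-variance signature: correlation undefined")
    rhos = {}
    for name in catalog.columns:
        v = catalog[name].to_numpy(dtype=float)
        if np.std(v) == 0:
            raise ValueError(f"zero-variance catalog entry {name!r}")
        rhos[name] = float(stats.pearsonr(w, v)[0])
    return pd.Series(rhos).sort_values(ascending=False)


def _normalize_catalog_label(label: str) -> str:
    """Accept either ``ACA>A`` or COSMIC-style ``A[C>A]A`` labels."""
    label = label.strip()
    if "[" in label:
        left, rest = label.split("[")
        sub, right = rest.split("]")
        anc, der = sub.split(">")
        return f"{left}{anc}{right}>{der}"
    return label


def read_catalog(path) -> pd.DataFrame:
    """Read a 96-row signature catalog TSV (first column: class label),
    reordering rows to the canonical class order and normalizing each
    signature to sum 1."""
    df = pd.read_csv(path, sep="\t")
    labels = df.iloc[:, 0].map(_normalize_catalog_label)
    df = df.iloc[:, 1:].set_index(labels)
    try:
        df = df.loc[list(CLASS_LABELS)]
    except KeyError:
        raise ValueError("catalog does not cover all 96 canonical classes") from None
    return df / df.sum(axis=0)


@dataclass
class PCAResult:
    sample_positions: np.ndarray  # (n_samples, n_components)
    components: np.ndarray  # (n_components, n_kept_rows)
    explained_variance_ratio: np.ndarray
    kept_rows: np.ndarray  # indices of rows with nonzero variance


def pca_spectrum(X, n_components: int | None = None) -> PCAResult:
    """PCA of samples after scaling each class row to unit variance.

    Constant rows carry no signal and are dropped (logged)."""
    X = np.asarray(X.values if isinstance(X, IntensityMatrix) else X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two samples for PCA")
    sd = X.std(axis=1, ddof=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < X.shape[0]:
        logger.warning("dropping %d constant class row(s)", X.shape[0] - kept.size)
    if kept.size == 0:
        raise ValueError("all rows constant")
    Z = X[kept] / sd[kept, None]
    pca = PCA(n_components=n_components)
    pos = pca.fit_transform(Z.T)
    return PCAResult(pos, pca.components_, pca.explained_variance_ratio_, kept)


_CPG_ROWS = np.array([i for i, c in enumerate(CLASSES) if c.is_cpg], dtype=int)


def subtract_cpg_floor(signatures: SignatureSet) -> SignatureSet:
    """Remove a constant CpG floor from every signature.

    For each CpG class (NCG context), the minimum weight across signatures
    is subtracted from all signatures' weights in that class; non-CpG
    classes are untouched. This corrects the model-fitting artifact in which
    every factor absorbs a share of the ubiquitous CpG mutations. The
    recorded ``rss`` still refers to the uncorrected fit. Idempotent.
    """
    if signatures.rank < 2:
        raise ValueError("CpG floor correction needs at least two signatures")
    W = signatures.weights.copy()
    W[_CPG_ROWS] -= W[_CPG_ROWS].min(axis=1, keepdims=True)
    return replace(signatures, weights=W)
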