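"""Evaluation metrics: ARI, NMI, and the local inverse Simpson's index.

ARI and NMI score agreement between a predicted domain partition and an
annotation; LISI measures the effective number of classes (batches or
domains) in each spot's perplexity-calibrated neighborhood of an embedding
— higher batch-LISI means better mixing, lower domain-LISI means crisper
separation.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn import metrics as _skm
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

DEFAULT_PERPLEXITY = 30.0


def _check_pair(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return a, b


def ari(a, b) -> float:
    """Adjusted Rand index between two labelings (permutation-invariant,
    at most 1, zero in expectation under chance)."""
    a, b = _check_pair(a, b)
    return float(_skm.adjusted_rand_score(a, b))


def nmi(a, b) -> float:
    """Normalized mutual information, normalized by the arithmetic mean of
    the two entropies; in [0, 1].  Two single-class labelings — identical
    as partitions — score 1.0."""
    a, b = _check_pair(a, b)
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        return 1.0
    return float(_skm.normalized_mutual_info_score(a, b, average_method="arithmetic"))


def _calibrated_weights(d2: np.ndarray, perplexity: float, tol: float = 1e-5):
    """Gaussian-kernel weights over one spot's neighbor distances, with the
    bandwidth bisected so the weight entropy matches log(perplexity)."""
    target = np.log(perplexity)
    beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
    for _ in range(64):
        w = np.exp(-d2 * beta)
        s = w.sum()
        if s <= 0:
            return None
        w = w / s
        h = -np.sum(w * np.log(np.maximum(w, 1e-300)))
        if abs(h - target) < tol:
            return w
        if h > target:  # too flat: sharpen
            beta_lo = beta
            beta = beta * 2.0 if not np.isfinite(beta_hi) else 0.5 * (beta + beta_hi)
        else:
            beta_hi = beta
            beta = 0.5 * (beta + beta_lo)
    return w


def lisi(
    embedding: np.ndarray,
    labels,
    perplexity: float = DEFAULT_PERPLEXITY,
) -> np.ndarray:
    """Per-spot local inverse Simpson's index of ``labels`` in ``embedding``.

    For each spot, neighborhood weights over its ~3*perplexity nearest
    neighbors are calibrated to the target perplexity by bisection on the
    Gaussian bandwidth; the index is 1 / sum_k p_k^2 of the weighted label
    distribution, between 1 and the number of classes.  Spots whose
    neighborhood collapses (duplicate points) fall back to uniform weights.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels).ravel()
    n = X.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must match the number of embedding rows")
    if perplexity >= n:
        raise ValueError(f"perplexity={perplexity} must be < n={n}")
    classes, enc = np.unique(labels, return_inverse=True)
    q = len(classes)
    if q == 1:
        return np.ones(n)

    k = int(min(n - 1, max(np.ceil(3 * perplexity), 5)))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    out = np.empty(n)
    n_fallback = 0
    for i in range(n):
        w = _calibrated_weights(dist[i] ** 2, perplexity)
        if w is None:
            w = np.full(k, 1.0 / k)
            n_fallback += 1
        pk = np.bincount(enc[idx[i]], weights=w, minlength=q)
        out[i] = 1.0 / np.sum(pk**2)
    if n_fallback:
        logger.info("lisi: uniform-weight fallback used for %d spots", n_fallback)
    return out


def evaluate_partition(pred, truth) -> dict:
    """ARI and NMI of a predicted partition against an annotation."""
    return {"ari": ari(pred, truth), "nmi": nmi(pred, truth)}


def evaluate_embedding(
    embedding: np.ndarray,
    batch_labels,
    domain_labels=None,
    perplexity: float = DEFAULT_PERPLEXITY,
) -> dict:
    """Median and mean batch-LISI (and domain-LISI when domain labels are
    given) of an embedding."""
    out = {}
    bl = lisi(embedding, batch_labels, perplexity)
    out["batch_lisi_median"] = float(np.median(bl))
    out["batch_lisi_mean"] = float(np.mean(bl))
    if domain_labels is not None:
        dl = lisi(embedding, domain_labels, perplexity)
        out["domain_lisi_median"] = float(np.median(dl))
        out["domain_lisi_mean"] = float(np.mean(dl))
    return out
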