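"""Simulated-doublet nearest-neighbour scoring.

Synthetic doublets are built by summing the raw counts of random droplet
pairs. Observed and simulated profiles are depth-normalized, log1p
transformed and embedded with centered PCA; each observed droplet is
scored by the fraction of simulated doublets among its cosine-metric
nearest neighbours, converted to a doublet likelihood in [0, 1] by a Bayes
correction for the simulated-to-observed ratio and the expected doublet
rate. Droplets that look like the sum of two distinct expression profiles
— true doublets, and heavily contaminated "pseudo-doublets" — score high.
Cosine neighbours (rather than Euclidean) avoid a high-dimensional
artifact where the lower sampling noise of depth-doubled simulated sums
concentrates them into an inner shell that soaks up all neighbours.

The scorer is pluggable: any callable ``(counts, seed) -> scores`` with the
same contract can be substituted in the pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


def _normalize_log(X: sp.csr_matrix, target: float) -> sp.csr_matrix:
    depth = np.asarray(X.sum(axis=1)).ravel()
    scale = np.where(depth > 0, target / np.where(depth > 0, depth, 1), 0.0)
    Xn = sp.diags(scale) @ X
    Xn = sp.csr_matrix(Xn)
    Xn.data = np.log1p(Xn.data)
    return Xn


def score_doublets(
    counts: sp.spmatrix,
    seed: int = 0,
    sim_doublet_ratio: float = 2.0,
    expected_doublet_rate: float = 0.06,
    n_components: int = 30,
    n_neighbors: int | None = None,
) -> np.ndarray:
    """Per-droplet doublet scores in [0, 1].

    ``sim_doublet_ratio`` is the number of simulated doublets per observed
    droplet; ``expected_doublet_rate`` the prior doublet frequency;
    ``n_neighbors`` defaults to ``round(0.5 * sqrt(n))``. Fewer than two
    droplets yields all-zero scores with a warning.
    """
    X = sp.csr_matrix(counts)
    n = X.shape[0]
    if n < 2:
        warnings.warn("fewer than 2 droplets; doublet scores set to 0", UserWarning)
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    n_sim = max(int(round(sim_doublet_ratio * n)), 1)
    r = n_sim / n
    pairs = np.column_stack(
        [rng.integers(0, n, size=n_sim), rng.integers(0, n, size=n_sim)]
    )
    # avoid self-pairs, which simulate scaled singlets rather than doublets
    same = pairs[:, 0] == pairs[:, 1]
    pairs[same, 1] = (pairs[same, 1] + 1) % n
    sim = X[pairs[:, 0]] + X[pairs[:, 1]]

    target = float(np.median(np.asarray(X.sum(axis=1)).ravel())) or 1.0
    obs_n = _normalize_log(X, target)
    sim_n = _normalize_log(sim, target)

    k_components = min(n_components, min(X.shape) - 1, n - 1)
    pca = PCA(n_components=max(k_components, 1), random_state=seed)
    emb_obs = pca.fit_transform(obs_n.toarray())
    emb_sim = pca.transform(sim_n.toarray())

    if n_neighbors is None:
        n_neighbors = max(int(round(0.5 * np.sqrt(n))), 3)
    # expand k in proportion to the enlarged (observed + simulated) pool
    k_adj = int(round(n_neighbors * (1 + r)))
    k_adj = min(k_adj, n + n_sim - 1)
    pool = np.vstack([emb_obs, emb_sim])
    is_sim = np.zeros(n + n_sim, dtype=bool)
    is_sim[n:] = True
    nn = NearestNeighbors(n_neighbors=k_adj + 1, metric="cosine").fit(pool)
    _, idx = nn.kneighbors(emb_obs)
    idx = idx[:, 1:]  # drop self
    q = (is_sim[idx].sum(axis=1) + 1) / (k_adj + 2)  # rule-of-succession smoothing

    rho = expected_doublet_rate
    scores = q * rho / r / (1.0 - rho - q * (1.0 - rho - rho / r))
    return np.clip(scores, 0.0, 1.0)
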