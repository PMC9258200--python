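"""Per-gene vector representations of variants from association matrices.

Three interchangeable backends:

``lcw_sg``
    Local context window: weighted random walks over the association network
    (transition probability proportional to exp(LOA), the network's natural
    nonnegative weight) fed to a SkipGram model — each walk is treated as a
    sentence of variant "words".
``gmf_pca``
    Global matrix factorization via PCA: rows of the LOA matrix projected
    onto its top principal components (columns centred first).
``gmf_nmf``
    Global matrix factorization via NMF of the exponentiated matrix
    (elementwise exp makes every entry positive, as NMF requires); a
    variant's vector is its row of the W factor.

All backends are deterministic: seeds are explicit, SkipGram trains on a
single thread, PCA component signs are fixed by convention, and NMF uses a
deterministic data-derived initialisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .cohort import ValidationError
from .network import AssociationMatrix, to_ajnm
from .skipgram import train_sgns

logger = logging.getLogger(__name__)

BACKENDS = ("lcw_sg", "gmf_pca", "gmf_nmf")


@dataclass
class WalkCorpus:
    """Random-walk corpus over one gene's association network."""

    gene_id: str
    walks: list[list[str]]
    walks_per_node: int
    walk_length: int

    def __post_init__(self) -> None:
        if any(len(w) != self.walk_length for w in self.walks):
            raise ValidationError("walk length mismatch")


@dataclass
class EmbeddingTable:
    """Variant -> d-dimensional vector for one gene, with provenance params."""

    gene_id: str
    backend: str
    dim: int
    vectors: dict[str, np.ndarray]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, x in self.vectors.items():
            x = np.asarray(x, dtype=float)
            if x.shape != (self.dim,) or not np.isfinite(x).all():
                raise ValidationError(f"bad embedding vector for {v!r}")
            self.vectors[v] = x

    def matrix(self, order: list[str] | None = None) -> np.ndarray:
        order = list(self.vectors) if order is None else order
        return np.vstack([self.vectors[v] for v in order])

    @property
    def variant_order(self) -> list[str]:
        return list(self.vectors)


def sample_walks(
    ajm: AssociationMatrix,
    walks_per_node: int = 10,
    walk_length: int = 10,
    seed: int = 0,
) -> WalkCorpus:
    """Weighted random walks: `walks_per_node` walks started at every node.

    At each step the next node is drawn among the *other* nodes (self-loops
    excluded) with probability proportional to exp(LOA(current, next)), so
    strongly associated neighbours are visited preferentially while negative
    associations suppress transitions. Deterministic given `seed`.
    """
    n = ajm.n_variants
    if n < 2:
        raise ValidationError("walks need at least 2 nodes")
    weights = np.exp(ajm.loa)
    np.fill_diagonal(weights, 0.0)
    cum = np.cumsum(weights / weights.sum(axis=1, keepdims=True), axis=1)

    rng = np.random.default_rng(seed)
    current = np.repeat(np.arange(n), walks_per_node)
    steps = np.empty((current.size, walk_length), dtype=np.int64)
    steps[:, 0] = current
    for t in range(1, walk_length):
        u = rng.random(current.size)
        current = np.minimum((cum[current] < u[:, None]).sum(axis=1), n - 1)
        steps[:, t] = current

    names = ajm.variant_order
    walks = [[names[i] for i in row] for row in steps]
    return WalkCorpus(ajm.gene_id, walks, walks_per_node, walk_length)


def embed_skipgram(
    corpus: WalkCorpus,
    dim: int = 8,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    negative: int = 5,
) -> EmbeddingTable:
    """SkipGram embedding of a walk corpus (every node kept; min-count 0)."""
    if not corpus.walks:
        raise ValidationError("empty walk corpus")
    vocab: dict[str, int] = {}
    for walk in corpus.walks:
        for tok in walk:
            vocab.setdefault(tok, len(vocab))
    walks_idx = np.array([[vocab[t] for t in walk] for walk in corpus.walks])
    mat = train_sgns(
        walks_idx,
        n_nodes=len(vocab),
        dim=dim,
        window=window,
        epochs=epochs,
        negative=negative,
        seed=seed,
    )
    params = {"window": window, "epochs": epochs, "negative": negative, "seed": seed,
              "walks_per_node": corpus.walks_per_node, "walk_length": corpus.walk_length}
    return EmbeddingTable(
        corpus.gene_id, "lcw_sg", dim, {v: mat[i] for v, i in vocab.items()}, params
    )


def embed_pca(ajm: AssociationMatrix, dim: int = 2) -> EmbeddingTable:
    """Project LOA-matrix rows onto the top `dim` principal components.

    Columns are centred first. Component signs follow the convention that the
    largest-magnitude loading of each component is positive, making results
    reproducible across runs and platforms. When the gene has fewer than
    dim + 1 variants the missing trailing components are zero-padded (warned).
    """
    X = ajm.loa
    n = X.shape[0]
    d_eff = min(dim, max(1, n - 1))
    if n < dim + 1:
        logger.warning(
            "gene %s: %d variants < dim+1=%d; padding embedding with zeros",
            ajm.gene_id, n, dim + 1,
        )
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:d_eff].copy()
    for i in range(d_eff):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    scores = Xc @ comps.T
    if d_eff < dim:
        scores = np.hstack([scores, np.zeros((n, dim - d_eff))])
    vectors = {v: scores[i] for i, v in enumerate(ajm.variant_order)}
    return EmbeddingTable(ajm.gene_id, "gmf_pca", dim, vectors, {})


def embed_nmf(
    ajm: AssociationMatrix,
    dim: int = 2,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    init: str = "nndsvda",
) -> EmbeddingTable:
    """Nonnegative factorization AJNM ~ W.H; variant i's vector is row i of W.

    The exponentiated matrix is used because NMF requires nonnegative input.
    The default NNDSVDa initialisation is deterministic and data-derived, and
    the multiplicative-update solver keeps the factorization equivariant
    under permutations of the variant order; `seed` only matters if a caller
    switches to ``init="random"``. Non-convergence within `max_iter` logs a
    warning and returns the best iterate.
    """
    ajnm = to_ajnm(ajm)
    n = ajnm.shape[0]
    k = min(dim, n)
    model = NMF(
        n_components=k,
        init=init,
        solver="mu",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            W = model.fit_transform(ajnm)
        except ConvergenceWarning:
            logger.warning(
                "gene %s: NMF did not converge in %d iterations; using best iterate",
                ajm.gene_id, max_iter,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = NMF(n_components=k, init=init, solver="mu",
                            max_iter=max_iter, tol=tol, random_state=seed)
                W = model.fit_transform(ajnm)
    if k < dim:
        W = np.hstack([W, np.zeros((n, dim - k))])
    vectors = {v: W[i] for i, v in enumerate(ajm.variant_order)}
    params = {"init": init, "max_iter": max_iter, "tol": tol, "seed": seed}
    return EmbeddingTable(ajm.gene_id, "gmf_nmf", dim, vectors, params)


def embed(
    ajm: AssociationMatrix,
    backend: str,
    seed: int = 0,
    *,
    walks_per_node: int = 10,
    walk_length: int = 10,
    sg_dim: int = 8,
    sg_window: int = 5,
    sg_epochs: int = 5,
    gmf_dim: int = 2,
    nmf_max_iter: int = 500,
) -> EmbeddingTable:
    """Dispatch to one of the three backends with its standard parameters."""
    if backend == "lcw_sg":
        corpus = sample_walks(ajm, walks_per_node, walk_length, seed=seed)
        return embed_skipgram(corpus, dim=sg_dim, window=sg_window,
                              epochs=sg_epochs, seed=seed)
    if backend == "gmf_pca":
        return embed_pca(ajm, dim=gmf_dim)
    if backend == "gmf_nmf":
        return embed_nmf(ajm, dim=gmf_dim, seed=seed, max_iter=nmf_max_iter)
    raise ValidationError(f"unknown backend {backend!r}")
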