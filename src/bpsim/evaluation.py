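"""Relationship matrices and the GBLUP mixed-model solver.

The numerator relationship matrix A is built by the tabular (recursive)
method over the pedigree; the genomic matrix G follows VanRaden's first
method, G = (M - 2P)(M - 2P)' / (2 sum p_j (1 - p_j)); the single-step H
matrix blends A and G by replacing the genotyped block with an adjusted
tau*G + (1-tau)*A22 and propagating through A12 A22^{-1}.

GBLUP assumes known heritability: with lambda = (1 - h2) / h2, observation
counts n_i entering as residual weights D = diag(1/n_i), and a blended
K* = 0.99 K + 0.01 I for invertibility,

    mu_hat  : generalized least squares under V = K*_PP + lambda D
    g_P     = K*_PP (K*_PP + lambda D)^{-1} (y_P - mu_hat)
    g_Q     = K_QP K*_PP^{-1} g_P
"""

from __future__ import annotations

import numpy as np

from .population import Population, PopulationError, get_genotypes

__all__ = [
    "pedigree_A",
    "vanraden_G",
    "ssgblup_H",
    "gblup_solve",
    "insert_ebv",
    "BLEND",
]

#: invertibility blend weight: K* = (1 - BLEND) K + BLEND I
BLEND = 0.01


def _ancestor_closure(pop: Population, ids) -> list[int]:
    """ids plus all their ancestors, in a parents-before-children order."""
    seen: set[int] = set()
    order: list[int] = []

    def visit(i: int, path: tuple):
        if i in seen:
            return
        if i in path:
            raise PopulationError(f"cyclic pedigree at individual {i}")
        ind = pop.individuals[i]
        for p in (ind.sire_id, ind.dam_id):
            if p:
                visit(p, path + (i,))
        seen.add(i)
        order.append(i)

    for i in ids:
        visit(i, ())
    return order


def tabular_A(triples) -> tuple[np.ndarray, list[int]]:
    """Numerator relationship matrix from (id, sire, dam) triples (0 =
    unknown parent), by the tabular method. Unknown-parent individuals are
    treated as unrelated, non-inbred founders. Returns (A, id order)."""
    triples = list(triples)
    parents = {i: (s, d) for i, s, d in triples}
    order: list[int] = []
    seen: set[int] = set()

    def visit(i: int, path: tuple):
        if i in seen or i not in parents:
            return
        if i in path:
            raise PopulationError(f"cyclic pedigree at individual {i}")
        for p in parents[i]:
            if p:
                visit(p, path + (i,))
        seen.add(i)
        order.append(i)

    for i, _, _ in triples:
        visit(i, ())
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, iid in enumerate(order):
        s0, d0 = parents[iid]
        s = pos.get(s0) if s0 else None
        d = pos.get(d0) if d0 else None
        row = np.zeros(n)
        if s is not None:
            row += 0.5 * A[s]
        if d is not None:
            row += 0.5 * A[d]
        A[k, :k] = row[:k]
        A[:k, k] = row[:k]
        A[k, k] = 1.0 + (0.5 * A[s, d] if (s is not None and d is not None) else 0.0)
    return A, order


def pedigree_A(pop: Population, ids) -> np.ndarray:
    """Numerator relationship matrix over ``ids`` (tabular method).

    Computed over the full ancestor closure, then restricted to ``ids`` in
    the given order. Founders are assumed unrelated and non-inbred.
    """
    ids = list(ids)
    closure = _ancestor_closure(pop, ids)
    triples = [
        (i, pop.individuals[i].sire_id or 0, pop.individuals[i].dam_id or 0) for i in closure
    ]
    A, order = tabular_A(triples)
    pos = {iid: k for k, iid in enumerate(order)}
    sel = [pos[i] for i in ids]
    return A[np.ix_(sel, sel)]


def vanraden_G(genotypes: np.ndarray, allele_freqs: np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    ``genotypes`` is markers x individuals with dosages {0,1,2};
    ``allele_freqs`` the reference allele-1 frequencies (by convention those
    of the founder generation). Monomorphic markers (p in {0, 1}) are dropped
    from both the centering and the denominator.
    """
    M = np.asarray(genotypes, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    poly = (p > 0.0) & (p < 1.0)
    if not np.any(poly):
        raise ValueError("all markers are monomorphic; G is undefined")
    Z = M[poly] - 2.0 * p[poly][:, None]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    return (Z.T @ Z) / denom


def ssgblup_H(
    pop: Population,
    genotyped_ids,
    all_ids,
    allele_freqs: np.ndarray | None = None,
    tau: float = 0.95,
) -> np.ndarray:
    """Single-step relationship matrix H over ``all_ids``.

    The genotyped block of A is replaced by G_tau = tau * G_adj +
    (1 - tau) * A22, where G_adj is G affinely matched to A22 on mean
    diagonal and mean off-diagonal, and the change is propagated to the
    non-genotyped block via A12 A22^{-1}.
    """
    all_ids = list(all_ids)
    genotyped_ids = list(genotyped_ids)
    gset = set(genotyped_ids)
    if not gset.issubset(all_ids):
        raise PopulationError("genotyped ids must be a subset of all ids")
    if not genotyped_ids:
        return pedigree_A(pop, all_ids)
    # order: non-genotyped first, genotyped last
    ng = [i for i in all_ids if i not in gset]
    order = ng + genotyped_ids
    A = pedigree_A(pop, order)
    n1 = len(ng)
    A22 = A[n1:, n1:]
    freqs = pop.founder_allele_freqs() if allele_freqs is None else allele_freqs
    G = vanraden_G(get_genotypes(pop, genotyped_ids), freqs)
    # affine scale adjustment of G to A22
    n2 = len(genotyped_ids)
    if n2 > 1:
        off = ~np.eye(n2, dtype=bool)
        b = np.array([[np.mean(np.diag(G)), 1.0], [np.mean(G[off]), 1.0]])
        target = np.array([np.mean(np.diag(A22)), np.mean(A22[off])])
        try:
            beta, alpha = np.linalg.solve(b, target)
        except np.linalg.LinAlgError:
            beta, alpha = 1.0, 0.0
        G_adj = beta * G + alpha
    else:
        G_adj = G
    Gt = tau * G_adj + (1.0 - tau) * A22
    try:
        A22_inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "A22 is singular; consider blending (e.g. 0.99*A22 + 0.01*I) or pruning duplicates"
        )
    H = A.copy()
    D = Gt - A22
    if n1:
        P = A[:n1, n1:] @ A22_inv  # A12 A22^-1
        H[:n1, :n1] += P @ D @ P.T
        H[:n1, n1:] += P @ D
        H[n1:, :n1] = H[:n1, n1:].T
    H[n1:, n1:] = Gt
    # back to requested order
    perm = [order.index(i) for i in all_ids]
    return H[np.ix_(perm, perm)]


def gblup_solve(
    y: np.ndarray,
    K: np.ndarray,
    h2: float,
    phenotyped: np.ndarray | None = None,
    n_obs: np.ndarray | None = None,
):
    """Solve the intercept-plus-animal GBLUP model with known heritability.

    Parameters
    ----------
    y : phenotype vector over the candidate list (entries for individuals
        outside ``phenotyped`` are ignored).
    K : relationship matrix over all candidates.
    h2 : known heritability in (0, 1].
    phenotyped : boolean mask or index array of phenotyped candidates
        (default: all).
    n_obs : observation counts behind each phenotype average (default 1).

    Returns
    -------
    (mu_hat, g) with g the EBV vector over all candidates.
    """
    y = np.asarray(y, dtype=float)
    n = K.shape[0]
    if phenotyped is None:
        pidx = np.arange(n)
    else:
        phenotyped = np.asarray(phenotyped)
        pidx = np.flatnonzero(phenotyped) if phenotyped.dtype == bool else phenotyped
    if pidx.size == 0:
        raise ValueError("no phenotyped individuals")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    lam = (1.0 - h2) / h2
    counts = np.ones(pidx.size) if n_obs is None else np.asarray(n_obs, dtype=float)[: pidx.size]
    Ks = (1.0 - BLEND) * K + BLEND * np.eye(n)
    Kpp = Ks[np.ix_(pidx, pidx)]
    D = np.diag(lam / counts) if lam > 0 else np.zeros((pidx.size, pidx.size))
    V = Kpp + D
    Vinv_y = np.linalg.solve(V, y[pidx])
    Vinv_1 = np.linalg.solve(V, np.ones(pidx.size))
    mu = float(np.sum(Vinv_y) / np.sum(Vinv_1))
    resid = y[pidx] - mu
    g_p = Kpp @ np.linalg.solve(V, resid)
    g = np.zeros(n)
    g[pidx] = g_p
    qidx = np.setdiff1d(np.arange(n), pidx)
    if qidx.size:
        g[qidx] = Ks[np.ix_(qidx, pidx)] @ np.linalg.solve(Kpp, g_p)
    return mu, g


def insert_ebv(pop: Population, pairs, trait: int = 0) -> Population:
    """Overwrite stored EBVs with externally supplied values.

    ``pairs`` is an iterable of (id, value) or a mapping id -> value.
    Subsequent selection on the "ebv" criterion uses them verbatim.
    """
    items = pairs.items() if hasattr(pairs, "items") else pairs
    items = list(items)
    unknown = [i for i, _ in items if i not in pop.individuals]
    if unknown:
        raise PopulationError(f"unknown individuals in insert_ebv: {unknown}")
    n_traits = 1 if pop.traits is None else pop.traits.n_traits
    for iid, val in items:
        ind = pop.individuals[iid]
        if ind.ebv is None:
            ind.ebv = np.zeros(n_traits)
        ind.ebv[trait] = float(val)
    return pop
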