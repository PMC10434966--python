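"""Markov clustering (MCL) of the hypernetwork.

Native dense implementation of the Markov Cluster algorithm: the weighted
adjacency matrix gets self-loops, is column-normalized to a stochastic flow
matrix, and is iterated with *expansion* (matrix power e, default 2) followed
by *inflation* (element-wise power r, default 2, then column re-normalization)
until the flow stabilizes. Clusters are read off from the attractors of the
limit matrix. An optional adapter runs an installed ``mcl`` executable for
cross-validation; bit-compatibility with it is not promised.
"""

from __future__ import annotations

import subprocess
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .types import Element, HyperNetwork, ValidationError

__all__ = ["MCLParams", "inflate_normalize_step", "run_mcl", "run_mcl_binary"]


@dataclass
class MCLParams:
    """MCL tuning parameters (defaults follow common mcl practice).

    inflation : r > 1; larger values give finer clusters.
    expansion : integer matrix-power e >= 2.
    prune_threshold : entries below it are zeroed before re-normalization.
    max_iter / convergence_tol : iteration stops when the max absolute entry
        change drops below the tolerance.
    """

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 100
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValidationError("inflation must be > 1")
        if self.expansion < 2:
            raise ValidationError("expansion must be >= 2")


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    empty = sums == 0
    if empty.any():
        # dead column: restore as a self-loop-only column
        for j in np.nonzero(empty)[0]:
            m[j, j] = 1.0
        sums = m.sum(axis=0)
    return m / sums


def inflate_normalize_step(matrix: np.ndarray, r: float,
                           prune_threshold: float = 1e-5) -> np.ndarray:
    """Element-wise power r, prune small entries, re-normalize columns."""
    m = np.power(matrix, r)
    m[m < prune_threshold] = 0.0
    return _normalize_columns(m)


def _sparse_normalize_columns(m: sparse.csc_matrix) -> sparse.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    empty = np.nonzero(sums == 0)[0]
    if empty.size:
        # dead columns: restore as self-loop-only columns
        fix = sparse.coo_matrix(
            (np.ones(empty.size), (empty, empty)), shape=m.shape)
        m = (m + fix).tocsc()
        sums = np.asarray(m.sum(axis=0)).ravel()
    d = sparse.diags(1.0 / sums)
    return (m @ d).tocsc()


def _sparse_inflate_normalize(m: sparse.csc_matrix, r: float,
                              prune_threshold: float) -> sparse.csc_matrix:
    """Sparse mirror of :func:`inflate_normalize_step`."""
    m = m.tocsc(copy=True)
    m.data = np.power(m.data, r)
    m.data[m.data < prune_threshold] = 0.0
    m.eliminate_zeros()
    return _sparse_normalize_columns(m)


def _adjacency(net: HyperNetwork) -> tuple[sparse.csc_matrix, list[Element]]:
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for ea, eb, w in net.edges:
        i, j = index[ea], index[eb]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    a = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n))
    # parallel entries (cannot occur by construction) would sum; use max
    a.sum_duplicates()
    return a.tocsc(), nodes


def _extract_clusters(m: sparse.csr_matrix) -> list[set[int]]:
    """Attractor-based cluster readout yielding a partition of all nodes.

    Attractors (nonzero diagonal of the limit matrix) that occur in each
    other's rows form one attractor system; every node is assigned to the
    system holding the most of its flow, ties to the lowest-indexed system.
    """
    n = m.shape[0]
    eps = 1e-9
    diag = m.diagonal()
    attractors = np.nonzero(diag > eps)[0]
    if attractors.size == 0:  # non-converged fallback: strongest inflow
        attractors = np.unique(np.asarray(m.argmax(axis=0)).ravel())

    # union attractors that appear in one another's rows
    parent = {int(i): int(i) for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    attr_set = set(int(i) for i in attractors)
    csr = m.tocsr()
    for i in attr_set:
        row = csr.getrow(i)
        for j, v in zip(row.indices, row.data):
            if v > eps and int(j) in attr_set:
                parent[find(i)] = find(int(j))
    systems: dict[int, list[int]] = {}
    for i in attr_set:
        systems.setdefault(find(i), []).append(i)
    sys_list = [sorted(v) for v in systems.values()]
    sys_list.sort(key=lambda s: s[0])

    # mass of each node towards each attractor system
    agg = np.vstack([
        np.asarray(csr[s].sum(axis=0)).ravel() for s in sys_list
    ])
    best_mass = agg.max(axis=0)
    best_sys = agg.argmax(axis=0)  # first (lowest-indexed) system on ties

    clusters: list[set[int]] = [set() for _ in sys_list]
    for j in range(n):
        if best_mass[j] <= eps:
            clusters.append({j})  # unreachable node: its own singleton
        else:
            clusters[int(best_sys[j])].add(j)
    return [c for c in clusters if c]


def run_mcl(net: HyperNetwork,
            params: MCLParams | None = None) -> list[set[Element]]:
    """Cluster a hypernetwork; returns a partition of its node set.

    Self-loops of weight max-incident-edge are added per node before column
    normalization. Deterministic for a fixed node order; node order itself
    does not change the resulting partition.
    """
    params = params or MCLParams()
    if net.n_nodes == 0:
        raise ValidationError("cannot cluster an empty network")
    a, nodes = _adjacency(net)
    n = a.shape[0]

    # self-loop per node: max incident edge weight (1.0 for isolated nodes)
    loops = np.asarray(a.max(axis=0).todense()).ravel()
    loops[loops == 0] = 1.0
    a = a.tolil()
    a.setdiag(loops)
    m = _sparse_normalize_columns(a.tocsc())

    converged = False
    for _ in range(params.max_iter):
        prev = m
        mp = m
        for _ in range(params.expansion - 1):
            mp = mp @ m
        m = _sparse_inflate_normalize(mp, params.inflation,
                                      params.prune_threshold)
        if abs(m - prev).max() < params.convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iter} iterations on a "
            f"{n}-node network; reading clusters from the final matrix"
        )
    out = [set(nodes[i] for i in c) for c in _extract_clusters(m.tocsr())]
    out.sort(key=lambda c: min(c))
    return out


def write_abc(net: HyperNetwork, path) -> None:
    """Write the network as an ABC edge list (``a<TAB>b<TAB>weight``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for ea, eb, w in net.edges:
            fh.write(f"{ea[0]}::{ea[1]}\t{eb[0]}::{eb[1]}\t{w:.9g}\n")


def parse_mcl_output(path) -> list[set[Element]]:
    """Parse mcl's tab-separated cluster lines back into element sets."""
    clusters = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            members = set()
            for tok in line.split("\t"):
                ds, _, prot = tok.partition("::")
                members.add((ds, prot))
            clusters.append(members)
    return clusters


def run_mcl_binary(net: HyperNetwork, inflation: float = 2.0,
                   binary: str = "mcl", workdir=".") -> list[set[Element]]:
    """Cross-validation adapter invoking an installed ``mcl`` executable."""
    from pathlib import Path

    wd = Path(workdir)
    abc = wd / "mcl_in.abc"
    out = wd / "mcl_out.txt"
    write_abc(net, abc)
    subprocess.run(
        [binary, str(abc), "--abc", "-I", str(inflation), "-o", str(out)],
        check=True, capture_output=True,
    )
    return parse_mcl_output(out)
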