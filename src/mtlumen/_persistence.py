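"""Union-find merge-tree persistence of superlevel sets on a masked voxel graph.

Voxels are inserted in descending intensity order (ties broken by ascending
flat index, i.e. the earlier voxel counts as higher).  A voxel with no active
neighbour starts a new superlevel component and is a local maximum; when two
components meet at a voxel (the merging saddle), the component whose maximum
is lower dies and its persistence is the peak height minus the saddle value.
Maxima that never merge (including the global maximum) persist down to the
minimum of the masked values.
"""

import numba
import numpy as np


@numba.njit(cache=False)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:  # path compression
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@numba.njit(cache=False)
def merge_tree_persistence(values, order, rank, indptr, indices):
    """Persistence of all local maxima of a masked voxel graph.

    Parameters are local (masked) voxel arrays: ``values`` (float64),
    ``order`` (processing order, descending), ``rank`` (inverse of order),
    and a CSR adjacency (``indptr``, ``indices``).

    Returns ``(is_max, persistence)``.
    """
    n = values.shape[0]
    parent = np.full(n, -1, dtype=np.int64)
    comp_peak = np.full(n, -1, dtype=np.int64)
    is_max = np.zeros(n, dtype=np.bool_)
    persistence = np.full(n, -1.0)
    vmin = values[order[n - 1]]

    for k in range(n):
        v = order[k]
        parent[v] = v
        comp_peak[v] = v
        best_root = -1
        for e in range(indptr[v], indptr[v + 1]):
            u = indices[e]
            if parent[u] == -1:
                continue
            ru = _find(parent, u)
            if ru == v:
                continue
            if best_root == -1:
                # absorb v's own (fresh) component into the neighbour's
                parent[v] = ru
                best_root = ru
            elif ru != best_root:
                # two distinct components merge at saddle v
                pa = comp_peak[best_root]
                pb = comp_peak[ru]
                if rank[pb] < rank[pa]:  # peak b is higher; a dies
                    persistence[pa] = values[pa] - values[v]
                    parent[best_root] = ru
                    best_root = ru
                else:
                    persistence[pb] = values[pb] - values[v]
                    parent[ru] = best_root
        if best_root == -1:
            is_max[v] = True
        else:
            parent[v] = best_root

    for i in range(n):
        if is_max[i] and persistence[i] < 0:
            persistence[i] = values[i] - vmin
    return is_max, persistence
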