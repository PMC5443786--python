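"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (full enumeration, explicit
counting) and shares no code with the package implementations it checks.
"""

from __future__ import annotations

from itertools import product

GAP_OPEN = -2.0
GAP_EXTEND = -1.0
MATCH = 1.0
MISMATCH = -1.0


def enumerate_global_alignments(a: str, b: str):
    """Yield (score, aligned_a, aligned_b) for every global alignment.

    Affine gaps: a run of L gap characters costs GAP_OPEN + (L-1)*GAP_EXTEND.
    Feasible only for short sequences (Delannoy growth).
    """
    def rec(i, j, last, score, sa, sb):
        if i == len(a) and j == len(b):
            yield score, sa, sb
            return
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            yield from rec(i + 1, j + 1, "M", score + s, sa + a[i], sb + b[j])
        if i < len(a):
            s = GAP_EXTEND if last == "D" else GAP_OPEN
            yield from rec(i + 1, j, "D", score + s, sa + a[i], sb + "-")
        if j < len(b):
            s = GAP_EXTEND if last == "I" else GAP_OPEN
            yield from rec(i, j + 1, "I", score + s, sa + "-", sb + b[j])

    yield from rec(0, 0, None, 0.0, "", "")


def identity_trim_terminal(sa: str, sb: str) -> float:
    """Identity over columns with terminal-gap columns excluded."""
    lo, hi = 0, len(sa)
    while lo < hi and (sa[lo] == "-" or sb[lo] == "-"):
        lo += 1
    while hi > lo and (sa[hi - 1] == "-" or sb[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    matches = sum(1 for x, y in zip(sa[lo:hi], sb[lo:hi]) if x == y and x != "-")
    return matches / (hi - lo)


def best_global(a: str, b: str):
    """(optimal score, set of identities among optimal alignments)."""
    best_score = None
    idents: set[float] = set()
    for score, sa, sb in enumerate_global_alignments(a, b):
        if best_score is None or score > best_score + 1e-9:
            best_score = score
            idents = {identity_trim_terminal(sa, sb)}
        elif abs(score - best_score) <= 1e-9:
            idents.add(identity_trim_terminal(sa, sb))
    return best_score, idents


def best_local_score(a: str, b: str, score_fn) -> float:
    """Optimal local alignment score by enumerating all substring pairs.

    ``score_fn(x, y)`` must return the optimal *global* score of two
    non-empty strings under the target scheme; the local optimum is the
    max over substring pairs, floored at 0 (empty alignment).
    """
    best = 0.0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for l in range(j + 1, len(b) + 1):
                    best = max(best, score_fn(a[i:k], b[j:l]))
    return best


def global_protein_score(a: str, b: str, matrix, gap_open=-11.0, gap_extend=-1.0) -> float:
    """Enumerated optimal global score with a substitution matrix."""
    best = None

    def rec(i, j, last, score):
        nonlocal best
        if i == len(a) and j == len(b):
            if best is None or score > best:
                best = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "D", score + (gap_extend if last == "D" else gap_open))
        if j < len(b):
            rec(i, j + 1, "I", score + (gap_extend if last == "I" else gap_open))

    rec(0, 0, None, 0.0)
    return best


def chao1_by_counting(counts) -> float:
    """Literal bias-corrected Chao1 from explicit F1/F2 counting."""
    nonzero = [c for c in counts if c > 0]
    f1 = sum(1 for c in nonzero if c == 1)
    f2 = sum(1 for c in nonzero if c == 2)
    return len(nonzero) + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def expand_iupac_by_enumeration(primer: str) -> set[str]:
    """Exhaustive IUPAC expansion from a locally defined code table."""
    table = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    return {"".join(p) for p in product(*(table[c] for c in primer))}


def random_binary_tree_distances(n_leaves: int, rng):
    """Leaf labels and the additive path-length matrix of a random tree.

    Builds a random topology by sequential attachment, assigns uniform
    branch lengths in [0.1, 1.1], and returns path-length distances
    computed by explicit graph traversal (no tree library).
    """
    import numpy as np

    # adjacency: node -> list of (neighbor, length)
    adj: dict[int, list[tuple[int, float]]] = {0: [], 1: [], 2: []}
    next_node = 3
    center = next_node
    adj[center] = []
    next_node += 1
    for leaf in (0, 1, 2):
        w = rng.uniform(0.1, 1.1)
        adj[center].append((leaf, w))
        adj[leaf].append((center, w))
    edges = [(center, leaf) for leaf in (0, 1, 2)]
    leaves = [0, 1, 2]
    while len(leaves) < n_leaves:
        ei = rng.integers(len(edges))
        u, v = edges[ei]
        w_uv = next(w for x, w in adj[u] if x == v)
        mid, leaf = next_node, next_node + 1
        next_node += 2
        adj[u] = [(x, w) for x, w in adj[u] if x != v]
        adj[v] = [(x, w) for x, w in adj[v] if x != u]
        w1 = w_uv * rng.uniform(0.2, 0.8)
        w2 = w_uv - w1
        wl = rng.uniform(0.1, 1.1)
        adj[mid] = [(u, w1), (v, w2), (leaf, wl)]
        adj[u].append((mid, w1))
        adj[v].append((mid, w2))
        adj[leaf] = [(mid, wl)]
        edges[ei] = (u, mid)
        edges.extend([(mid, v), (mid, leaf)])
        leaves.append(leaf)

    labels = [f"L{i}" for i in range(len(leaves))]
    dist = np.zeros((len(leaves), len(leaves)))
    for a_idx, a in enumerate(leaves):
        # BFS accumulating path lengths
        seen = {a: 0.0}
        frontier = [a]
        while frontier:
            nxt = []
            for u in frontier:
                for v, w in adj[u]:
                    if v not in seen:
                        seen[v] = seen[u] + w
                        nxt.append(v)
            frontier = nxt
        for b_idx, b in enumerate(leaves):
            dist[a_idx, b_idx] = seen[b]
    dist = (dist + dist.T) / 2.0  # remove float summation-order asymmetry
    np.fill_diagonal(dist, 0.0)
    return labels, dist
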