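"""Core-gene supermatrix phylogenomics.

Per-gene protein alignments are concatenated into a partitioned supermatrix;
trees come from neighbor joining on Poisson-corrected p-distances, with
non-parametric bootstrap supports.  Log-likelihoods of fixed topologies are
computed by Felsenstein's pruning algorithm under a reversible amino-acid
model (Poisson or JTT), with branch lengths optimized one edge at a time.
The constrained-topology comparison grafts a focal taxon next to each of two
candidate groups and reports the optimized log-likelihood difference: a tool
for arguing gene origin (e.g. host-derived versus virus-derived) when a gene
could plausibly belong to either clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# JTT (Jones-Taylor-Thornton 1992) exchangeabilities, lower triangle in
# ARNDCQEGHILKMFPSTWYV order, with the accompanying stationary frequencies.
# Constants of record for the standard matrix.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]
_JTT_FREQS = [
    0.07674792, 0.05169095, 0.04264496, 0.05154395, 0.01980298, 0.04075196,
    0.06182994, 0.07315193, 0.02294398, 0.05376095, 0.09190391, 0.05867594,
    0.02382598, 0.04012596, 0.05090095, 0.06876493, 0.05856494, 0.01426099,
    0.03210197, 0.06600493,
]


class TreeNode:
    """A rooted tree node; leaves carry names, internal nodes carry support."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, children=None):
        self.name = name
        self.length = length
        self.support = None
        self.children: list[TreeNode] = children or []
        self.parent: TreeNode | None = None
        for c in self.children:
            c.parent = self

    def add(self, child: "TreeNode"):
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self):
        return [n.name for n in self.leaves()]

    def copy(self) -> "TreeNode":
        node = TreeNode(name=self.name, length=self.length)
        node.support = self.support
        for c in self.children:
            node.add(c.copy())
        return node

    def find_leaf(self, name: str) -> "TreeNode | None":
        return next((n for n in self.leaves() if n.name == name), None)

    def to_newick(self, _root=True) -> str:
        if self.is_leaf:
            s = self.name or ""
        else:
            inner = ",".join(c.to_newick(_root=False) for c in self.children)
            label = "" if self.support is None else f"{self.support:g}"
            s = f"({inner}){label}"
        if not _root and self.length is not None:
            s += f":{self.length:g}"
        return s + (";" if _root else "")

    def __repr__(self):
        return f"TreeNode({self.to_newick()})"


# ---------------------------------------------------------------------------
# supermatrix


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]  # taxon -> concatenated aligned sequence
    partitions: list[tuple[str, int, int]] = field(default_factory=list)  # (gene, start, end) 0-based half-open

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def gene_alignment(self, gene: str) -> dict[str, str]:
        for g, s, e in self.partitions:
            if g == gene:
                return {t: self.rows[t][s:e] for t in self.taxa}
        raise KeyError(gene)

    def subset(self, taxa: list[str]) -> "Supermatrix":
        return Supermatrix(
            taxa=list(taxa), rows={t: self.rows[t] for t in taxa}, partitions=list(self.partitions)
        )


def concatenate(per_gene_alignments, missing_policy: str = "pad") -> Supermatrix:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    ``per_gene_alignments``: mapping gene -> mapping taxon -> aligned seq, or
    gene -> list of (taxon, seq) records.  policy "pad" fills taxa missing a
    gene with gaps; "intersect" keeps only taxa present in every gene.
    """
    if missing_policy not in ("pad", "intersect"):
        raise ValueError("missing_policy must be 'pad' or 'intersect'")
    genes = {}
    for gene, aln in per_gene_alignments.items():
        if not isinstance(aln, dict):
            d = {}
            for taxon, seq in aln:
                if taxon in d:
                    raise ValueError(f"duplicate taxon {taxon!r} in gene {gene!r}")
                d[taxon] = seq
            aln = d
        lens = {len(s) for s in aln.values()}
        if len(lens) > 1:
            raise ValueError(f"gene {gene!r} alignment rows differ in length")
        genes[gene] = aln
    all_taxa: list[str] = []
    for aln in genes.values():
        for t in aln:
            if t not in all_taxa:
                all_taxa.append(t)
    if missing_policy == "intersect":
        all_taxa = [t for t in all_taxa if all(t in aln for aln in genes.values())]
    rows = {t: [] for t in all_taxa}
    partitions = []
    pos = 0
    for gene, aln in genes.items():
        glen = len(next(iter(aln.values())))
        for t in all_taxa:
            rows[t].append(aln.get(t, "-" * glen))
        partitions.append((gene, pos, pos + glen))
        pos += glen
    return Supermatrix(
        taxa=all_taxa, rows={t: "".join(parts) for t, parts in rows.items()}, partitions=partitions
    )


# ---------------------------------------------------------------------------
# distances + NJ

P_DIST_CEILING = 0.999  # p-distances at or above 1 are clipped here before -ln(1-p)


def protein_distance(matrix: Supermatrix) -> tuple[list[str], np.ndarray]:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the mismatch fraction over columns where neither sequence has a gap;
    p >= 1 (possible only in degenerate alignments) is clipped to
    ``P_DIST_CEILING``.
    """
    taxa = matrix.taxa
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa")
    arrs = {t: np.frombuffer(matrix.rows[t].encode(), dtype="S1") for t in taxa}
    gap = {t: (arrs[t] == b"-") | (arrs[t] == b"X") | (arrs[t] == b"?") for t in taxa}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[taxa[i]] & ~gap[taxa[j]]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {taxa[i]} and {taxa[j]}")
            p = float((arrs[taxa[i]][ok] != arrs[taxa[j]][ok]).sum()) / m
            p = min(p, P_DIST_CEILING)
            D[i, j] = D[j, i] = -np.log1p(-p)
    return taxa, D


def nj_tree(distances: np.ndarray, names: list[str]) -> TreeNode:
    """Neighbor joining with deterministic tie-breaking.

    Q-criterion ties break to the lexicographically smallest active-index
    pair; negative branch lengths are clamped to zero.  Returns a tree rooted
    at the final (trifurcating for n >= 3) join.
    """
    D = np.asarray(distances, dtype=float)
    n = len(names)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if n < 3:
        warnings.warn("fewer than 3 taxa: returning trivial tree")
        if n == 1:
            return TreeNode(name=names[0])
        root = TreeNode()
        for k, nm in enumerate(names):
            root.add(TreeNode(name=nm))
            root.children[-1].length = D[0, 1] / 2
        return root
    nodes = [TreeNode(name=nm) for nm in names]
    active = list(range(n))
    D = D.copy()
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (Q[a, b], a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        parent = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent.add(ni)
        parent.add(nj_)
        # distances from the new node to the remaining taxa
        new_idx = len(nodes)
        nodes.append(parent)
        newD = np.pad(D, ((0, 1), (0, 1)))
        for c in range(m):
            if c in (a, b):
                continue
            k = active[c]
            newD[new_idx, k] = newD[k, new_idx] = 0.5 * (sub[a, c] + sub[b, c] - dij)
        D = newD
        active = [k for k in active if k not in (i, j)] + [new_idx]
    # terminal trifurcation
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    root = TreeNode()
    for node_idx, length in (
        (i, (dij + dik - djk) / 2),
        (j, (dij + djk - dik) / 2),
        (k, (dik + djk - dij) / 2),
    ):
        nodes[node_idx].length = max(0.0, length)
        root.add(nodes[node_idx])
    return root


# ---------------------------------------------------------------------------
# substitution models + likelihood


class SubstitutionModel:
    """Reversible amino-acid model with unit expected substitution rate."""

    def __init__(self, name: str, exchangeabilities: np.ndarray, freqs: np.ndarray):
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(freqs, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be 20x20 symmetric")
        if pi.shape != (20,) or not np.isclose(pi.sum(), 1.0) or np.any(pi <= 0):
            raise ValueError("frequencies must be positive and sum to 1")
        self.name = name
        self.freqs = pi / pi.sum()
        Q = S * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self.freqs * np.diag(Q)).sum()
        Q /= mu  # 1 expected substitution per site per unit branch length
        self.Q = Q
        sqrt_pi = np.sqrt(self.freqs)
        B = sqrt_pi[:, None] * Q / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None]  # pi^{-1/2} U
        self._right = eigvec.T * sqrt_pi[None, :]  # U^T pi^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        return np.clip(P, 0.0, None)


def poisson_model() -> SubstitutionModel:
    S = np.ones((20, 20))
    np.fill_diagonal(S, 0.0)
    return SubstitutionModel("Poisson", S, np.full(20, 1 / 20))


def jtt_model() -> SubstitutionModel:
    S = np.zeros((20, 20))
    it = iter(_JTT_LOWER)
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    return SubstitutionModel("JTT", S, np.array(_JTT_FREQS) / sum(_JTT_FREQS))


def _encode_rows(matrix: Supermatrix, taxa: list[str]) -> dict[str, np.ndarray]:
    out = {}
    for t in taxa:
        out[t] = np.array([_AA_INDEX.get(c, -1) for c in matrix.rows[t]], dtype=np.int8)
    return out


def tree_lnL(tree: TreeNode, matrix: Supermatrix, model: SubstitutionModel) -> float:
    """Log-likelihood of the alignment on a fixed tree by post-order pruning.

    Gaps and unknown characters are missing data (all-ones partials); site
    log-likelihoods are summed, with per-node rescaling against underflow.
    """
    leaves = tree.leaf_names()
    missing = [t for t in leaves if t not in matrix.rows]
    if missing:
        raise ValueError(f"taxa absent from matrix: {missing}")
    codes = _encode_rows(matrix, leaves)
    n_sites = matrix.n_sites
    log_scale = np.zeros(n_sites)

    def partial(node: TreeNode) -> np.ndarray:
        nonlocal log_scale
        if node.is_leaf:
            arr = np.ones((n_sites, 20))
            c = codes[node.name]
            obs = c >= 0
            arr[obs] = 0.0
            arr[obs, c[obs]] = 1.0
            return arr
        out = np.ones((n_sites, 20))
        for child in node.children:
            t = child.length if child.length is not None else 0.0
            P = model.transition_matrix(float(t))
            out *= partial(child) @ P.T
        mx = out.max(axis=1)
        mx[mx == 0] = 1.0
        log_scale += np.log(mx)
        return out / mx[:, None]

    root_partial = partial(tree)
    site_like = root_partial @ model.freqs
    if np.any(site_like <= 0):
        bad = int(np.nonzero(site_like <= 0)[0][0])
        raise FloatingPointError(f"non-finite site likelihood at site {bad}")
    lnL = float(np.sum(np.log(site_like) + log_scale))
    return lnL


def optimize_branch_lengths(
    tree: TreeNode,
    matrix: Supermatrix,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_branch: float = 20.0,
    max_sweeps: int = 50,
) -> tuple[TreeNode, float]:
    """Round-robin single-branch optimization until lnL gain per sweep < tol.

    Each branch is optimized by bounded scalar search; a proposal is accepted
    only if it does not decrease the total lnL, so the lnL trajectory is
    monotone non-decreasing.  Returns (tree, final lnL); the tree is modified
    in place.
    """
    edges = [n for n in tree.postorder() if n is not tree]
    current = tree_lnL(tree, matrix, model)
    for _ in range(max_sweeps):
        before = current
        for node in edges:
            orig = node.length if node.length is not None else 0.0

            def negl(t):
                node.length = t
                return -tree_lnL(tree, matrix, model)

            res = minimize_scalar(negl, bounds=(1e-8, max_branch), method="bounded",
                                  options={"xatol": 1e-7})
            if -res.fun >= current:
                node.length = float(res.x)
                current = -res.fun
            else:
                node.length = orig
        if current - before < tol:
            break
    return tree, current


# ---------------------------------------------------------------------------
# constrained placement


def _adjacency(tree: TreeNode) -> dict:
    adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {}

    def visit(n: TreeNode):
        adj.setdefault(n, [])
        for c in n.children:
            length = c.length if c.length is not None else 0.0
            adj.setdefault(c, [])
            adj[n].append((c, length))
            adj[c].append((n, length))
            visit(c)

    visit(tree)
    return adj


def reroot_adjacent_to_leaf(tree: TreeNode, leaf_name: str) -> TreeNode:
    """Reroot (a copy of) the tree at the internal node adjacent to a leaf.

    Under a reversible model the likelihood is invariant to this choice; it
    is used to make clade (MRCA) queries well defined on NJ trees, whose
    root is an arbitrary trifurcation.
    """
    tree = tree.copy()
    adj = _adjacency(tree)
    leaf = next((n for n in adj if n.is_leaf and n.name == leaf_name), None)
    if leaf is None:
        raise ValueError(f"leaf {leaf_name!r} not found")
    start = adj[leaf][0][0] if adj[leaf] else leaf

    def build(node: TreeNode, parent: TreeNode | None, plen: float | None) -> TreeNode:
        nn = TreeNode(name=node.name)
        nn.length = plen
        nn.support = node.support
        for nbr, length in adj[node]:
            if nbr is parent:
                continue
            nn.add(build(nbr, node, length))
        return nn

    return build(start, None, None)


def _mrca(root: TreeNode, names: set[str]) -> TreeNode:
    best = None
    for n in root.postorder():
        under = set(n.leaf_names())
        if names <= under and (best is None or len(under) < len(set(best.leaf_names()))):
            best = n
    return best


def graft_sister(tree: TreeNode, group: list[str], focal_name: str, focal_branch: float = 0.1) -> TreeNode:
    """Attach a new leaf as sister to the clade spanned by ``group``.

    The tree is rerooted at a leaf outside the group; the focal taxon is
    inserted on the edge above the group's MRCA (with a warning if the group
    is not monophyletic there, in which case the MRCA edge is still used).
    """
    all_leaves = set(tree.leaf_names())
    outside = sorted(all_leaves - set(group))
    if not outside:
        raise ValueError("group covers the whole tree")
    rooted = mrca = None
    for anchor in outside:
        cand = reroot_adjacent_to_leaf(tree, anchor)
        m = _mrca(cand, set(group))
        if m is not cand:
            rooted, mrca = cand, m
            break
    if rooted is None:
        # group spans the root under every candidate rooting: attach at the root
        warnings.warn(f"group {sorted(group)} not monophyletic; grafting at the backbone root")
        rooted = reroot_adjacent_to_leaf(tree, outside[0])
        focal = TreeNode(name=focal_name)
        focal.length = focal_branch
        rooted.add(focal)
        return rooted
    if set(mrca.leaf_names()) != set(group):
        warnings.warn(f"group {sorted(group)} not monophyletic; grafting onto its MRCA edge")
    # locate the parent of the MRCA in the rooted copy
    parent = next(n for n in rooted.postorder() if mrca in n.children)
    old_len = mrca.length if mrca.length is not None else 0.0
    joint = TreeNode()
    joint.length = old_len / 2
    parent.children[parent.children.index(mrca)] = joint
    joint.parent = parent
    mrca.length = old_len / 2
    joint.add(mrca)
    focal = TreeNode(name=focal_name)
    focal.length = focal_branch
    joint.add(focal)
    return rooted


def constrained_topology_compare(
    matrix: Supermatrix,
    focal_taxon: str,
    group_a: list[str],
    group_b: list[str],
    model: SubstitutionModel | None = None,
    tol: float = 1e-4,
) -> tuple[float, float, float]:
    """Optimized lnL of the focal taxon constrained into group A versus group B.

    Builds the NJ backbone from all non-focal taxa, grafts the focal taxon as
    sister to each group in turn, optimizes branch lengths, and returns
    (lnL_A, lnL_B, delta) with delta = lnL_B - lnL_A; positive delta favors
    placement with group B.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if focal_taxon in set(group_a) | set(group_b):
        raise ValueError("focal taxon must not be in either group")
    model = model or poisson_model()
    backbone_taxa = [t for t in matrix.taxa if t != focal_taxon]
    names, D = protein_distance(matrix.subset(backbone_taxa))
    backbone = nj_tree(D, names)
    results = []
    for group in (group_a, group_b):
        tree = graft_sister(backbone, list(group), focal_taxon)
        _, lnl = optimize_branch_lengths(tree, matrix, model, tol=tol)
        results.append(lnl)
    lnl_a, lnl_b = results
    return lnl_a, lnl_b, lnl_b - lnl_a


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: TreeNode, ref_taxon: str) -> set[frozenset]:
    all_names = set(tree.leaf_names())
    out = set()
    for n in tree.postorder():
        if n.is_leaf or n is tree:
            continue
        side = set(n.leaf_names())
        if ref_taxon in side:
            side = all_names - side
        if 1 < len(side) < len(all_names) - 1:
            out.add(frozenset(side))
    return out


def bootstrap_support(matrix: Supermatrix, n_reps: int = 100, seed: int = 0) -> TreeNode:
    """NJ tree with non-parametric bootstrap supports on internal edges.

    Columns are resampled with replacement; each replicate is re-distanced
    and re-joined, and internal-edge bipartition frequencies are mapped onto
    the full-data tree (supports in [0, 1]).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    names, D = protein_distance(matrix)
    full = nj_tree(D, names)
    ref = matrix.taxa[0]
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(full, ref)}
    n_sites = matrix.n_sites
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        rows = {t: "".join(matrix.rows[t][c] for c in cols) for t in matrix.taxa}
        boot = Supermatrix(taxa=matrix.taxa, rows=rows)
        bnames, bD = protein_distance(boot)
        btree = nj_tree(bD, bnames)
        for bp in _bipartitions(btree, ref):
            if bp in counts:
                counts[bp] += 1
    all_names = set(full.leaf_names())
    for n in full.postorder():
        if n.is_leaf or n is full:
            continue
        side = set(n.leaf_names())
        if ref in side:
            side = all_names - side
        if 1 < len(side) < len(all_names) - 1:
            n.support = counts[frozenset(side)] / n_reps
    return full


# ---------------------------------------------------------------------------
# simulation (used by the test-bench and calibration studies)


def simulate_alignment(
    tree: TreeNode, model: SubstitutionModel, n_sites: int, seed: int = 0
) -> dict[str, str]:
    """Evolve i.i.d. sites down the tree; returns taxon -> sequence."""
    rng = np.random.default_rng(seed)
    root_states = rng.choice(20, size=n_sites, p=model.freqs)
    out: dict[str, str] = {}

    def walk(node: TreeNode, states: np.ndarray):
        if node is not tree:
            P = model.transition_matrix(float(node.length or 0.0))
            cum = P.cumsum(axis=1)
            u = rng.random(n_sites)
            states = np.array([np.searchsorted(cum[s], x) for s, x in zip(states, u)], dtype=int)
            states = np.clip(states, 0, 19)
        if node.is_leaf:
            out[node.name] = "".join(AMINO_ACIDS[s] for s in states)
        for c in node.children:
            walk(c, states)

    walk(tree, root_states)
    return out
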