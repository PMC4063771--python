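"""Family classification by homology and by clade membership.

Candidates are assigned to known snoRNA gene families two ways:

* **homology** — exact Smith--Waterman local alignment against labeled
  reference genes, gated on a Karlin--Altschul e-value (default 1e-3);
* **clade** — membership in a sufficiently supported clade (default >50%
  bootstrap) whose reference members all belong to one family, in a
  neighbor-joining tree with nonparametric bootstrap supports.

The module also provides the tree machinery those assignments need:
neighbor-joining from a distance matrix, column-resampling bootstrap,
50%-condensed consensus trees and a simple progressive multiple aligner.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import Align
from scipy.optimize import brentq

from snoevo.rates import k2p_distance

# Karlin-Altschul K for ungapped match/mismatch +2/-3 under uniform base
# frequencies (tabulated value; lambda is solved numerically below).
KARLIN_K = 0.41


@dataclass
class Scoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass
class PairwiseHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    identity: float
    q_span: tuple
    s_span: tuple


@dataclass
class FamilyAssignment:
    gene_id: str
    family: str  # "" when unassigned
    method: str  # homology | clade | both | none
    support: float  # evalue or bootstrap %

    @property
    def assigned(self) -> bool:
        return self.method != "none"


@functools.lru_cache(maxsize=None)
def karlin_lambda(match: float = 2.0, mismatch: float = -3.0) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform bases."""

    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def local_align(query: str, subject: str, scoring: Scoring | None = None,
                query_id: str = "query", subject_id: str = "subject") -> PairwiseHit:
    """Optimal Smith--Waterman local alignment with a calibrated e-value.

    ``E = K * m * n * exp(-lambda * S)`` with lambda solved numerically for
    the scoring scheme under equal base frequencies; e-values are calibrated
    approximations (ungapped theory applied to a gapped score).
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    if scoring is None:
        scoring = Scoring()
    aligner = _aligner(scoring)
    score = aligner.score(query, subject)
    matches = 0
    aligned_len = 0
    if score > 0:
        aln = next(iter(aligner.align(query, subject)))
        q_blocks, s_blocks = aln.aligned
        for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks):
            for q, s in zip(query[qa:qb], subject[sa:sb]):
                aligned_len += 1
                if q == s:
                    matches += 1
        q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
        s_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    else:
        q_span = (0, 0)
        s_span = (0, 0)
    lam = karlin_lambda(scoring.match, scoring.mismatch)
    evalue = KARLIN_K * len(query) * len(subject) * math.exp(-lam * score)
    identity = matches / aligned_len if aligned_len else 0.0
    return PairwiseHit(query_id, subject_id, float(score), evalue, identity,
                       q_span, s_span)


def assign_by_homology(candidates, references, evalue_cutoff: float = 1e-3,
                       scoring: Scoring | None = None) -> list:
    """Assign each candidate to the family of its best reference hit.

    ``candidates`` is a list of ``(id, seq)``; ``references`` a list of
    ``(id, seq, family)``.  Ties on e-value break by higher identity, then
    lexicographic subject id.  No qualifying hit leaves the candidate
    unassigned.
    """
    out = []
    for cid, cseq in candidates:
        best = None
        for rid, rseq, family in references:
            hit = local_align(cseq, rseq, scoring, query_id=cid, subject_id=rid)
            key = (hit.evalue, -hit.identity, rid)
            if best is None or key < best[0]:
                best = (key, hit, family)
        if best is not None and best[1].evalue <= evalue_cutoff:
            out.append(FamilyAssignment(cid, best[2], "homology", best[1].evalue))
        else:
            out.append(FamilyAssignment(cid, "", "none",
                                        best[1].evalue if best else math.inf))
    return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(labels, matrix) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sister edge.  The returned tree is rooted at the final
    trifurcation (i.e. effectively unrooted).
    """
    D = np.asarray(matrix, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("matrix shape does not match labels")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    tns = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        taxon = tns.new_taxon(label=str(lab))
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    active = list(range(n))
    D = D.copy()

    def clamp_pair(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, aj in itertools.combinations(active, 2):
            q = (m - 2) * D[ai, aj] - r[ai] - r[aj]
            key = (q, ai, aj)
            if best is None or key < best:
                best = key
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # new row for the merged node
        new_idx = D.shape[0]
        newrow = np.zeros((1, D.shape[1]))
        D = np.vstack([D, newrow])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    root = dendropy.Node()
    la = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lb = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lc = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, la), (j, lb), (k, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree


def k2p_matrix(alignment) -> tuple:
    """Pairwise K2P distance matrix for rows of one alignment.

    Saturated pairs fall back to twice the largest defined distance so the
    matrix stays finite for tree building.
    """
    labels = [name for name, _ in alignment]
    rows = [seq for _, seq in alignment]
    n = len(rows)
    D = np.zeros((n, n))
    undef = []
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p_distance(rows[i], rows[j])
            if res.defined:
                D[i, j] = D[j, i] = res.K
            else:
                undef.append((i, j))
    if undef:
        cap = 2.0 * (D.max() if D.max() > 0 else 1.0)
        for i, j in undef:
            D[i, j] = D[j, i] = cap
    return labels, D


def _splits(tree: dendropy.Tree) -> dict:
    """Unrooted bipartitions (internal edges) keyed by the leaf-set side not
    containing the alphabetically first leaf; values are the nodes."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor = leaves[0]
    all_set = frozenset(leaves)
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_set - side
        if 1 < len(side) < len(leaves) - 1:
            out[side] = node
    return out


def bootstrap_tree(alignment, n_reps: int = 100, seed: int = 0) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement per replicate; per replicate a
    K2P distance matrix feeds NJ; support of each internal split of the
    full-data tree is the percentage of replicates containing it.  Supports
    are stored on ``node.label`` and ``node.support``.
    """
    if len(alignment) < 4:
        raise ValueError("need at least 4 aligned sequences")
    width = len(alignment[0][1])
    short = width < 10
    if short:
        warnings.warn("alignment shorter than 10 columns; supports unreliable")
    labels, D = k2p_matrix(alignment)
    tree = nj_tree(labels, D)
    target = _splits(tree)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    names = [name for name, _ in alignment]
    arr = np.array([list(seq) for _, seq in alignment])
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep_aln = list(zip(names, ("".join(r) for r in arr[:, cols])))
        rep_labels, rep_D = k2p_matrix(rep_aln)
        rep_tree = nj_tree(rep_labels, rep_D)
        rep_splits = _splits(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    for side, node in target.items():
        support = 100.0 * counts[side] / n_reps
        node.support = support
        node.label = f"{support:g}"
    tree.short_alignment = short
    return tree


def node_support(node) -> float | None:
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def condense_tree(tree: dendropy.Tree, threshold: float = 50.0) -> dendropy.Tree:
    """Collapse every internal edge with support below ``threshold``.

    Operates on a clone; the leaf set is unchanged and the operation is
    idempotent.
    """
    tree = tree.clone(depth=1)
    to_collapse = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        sup = node_support(node)
        if sup is not None and sup < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return tree


def assign_by_clade(tree: dendropy.Tree, reference_families: dict,
                    candidate_ids=None, min_support: float = 50.0) -> list:
    """Assign candidates from supported monophyletic family clades.

    ``reference_families`` maps reference leaf label -> family.  A candidate
    gets family F iff it sits in some clade with support > ``min_support``
    that contains at least one reference, all of whose references are family
    F; the smallest such clade wins.  Star trees assign nothing (no
    supported internal edge exists).
    """
    leaf_labels = [l.taxon.label for l in tree.leaf_node_iter()]
    all_leaves = frozenset(leaf_labels)
    if candidate_ids is None:
        candidate_ids = [l for l in leaf_labels if l not in reference_families]
    # NJ trees are effectively unrooted: every supported internal edge defines
    # a bipartition, and either side is a candidate clade.
    sides = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        sup = node_support(node)
        if sup is None or sup <= min_support:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.append((below, sup))
        sides.append((all_leaves - below, sup))
    out = []
    for cid in candidate_ids:
        best = None
        for side, sup in sides:
            if cid not in side:
                continue
            ref_fams = {reference_families[m] for m in side
                        if m in reference_families}
            if len(ref_fams) != 1:
                continue
            key = (len(side), sorted(side))
            if best is None or key < best[0]:
                best = (key, ref_fams.pop(), sup)
        if best is None:
            out.append(FamilyAssignment(cid, "", "none", 0.0))
        else:
            out.append(FamilyAssignment(cid, best[1], "clade", best[2]))
    return out


def combine_assignments(homology, clade) -> list:
    """Merge homology- and clade-based assignments per gene.

    Agreement -> method "both"; a single informative method wins;
    disagreement keeps the homology call (e-values are the primary screen)
    but records method "homology".
    """
    by_id = {a.gene_id: a for a in clade}
    out = []
    for h in homology:
        c = by_id.get(h.gene_id)
        if h.assigned and c is not None and c.assigned:
            if h.family == c.family:
                out.append(FamilyAssignment(h.gene_id, h.family, "both", c.support))
            else:
                out.append(h)
        elif h.assigned:
            out.append(h)
        elif c is not None and c.assigned:
            out.append(c)
        else:
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _kmer_counts(seq: str, k: int = 4) -> dict:
    counts = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    ca, cb = _kmer_counts(a, k), _kmer_counts(b, k)
    keys = set(ca) | set(cb)
    return float(sum(abs(ca.get(x, 0) - cb.get(x, 0)) for x in keys))


def _profile_align(prof_a, prof_b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Global DP over profile columns; column score is the mean pairwise
    residue score, gaps inside profiles ignored."""

    def col(profile, j):
        return [row[j] for row in profile]

    def col_score(ca, cb):
        total = 0.0
        pairs = 0
        for x in ca:
            if x == "-":
                continue
            for y in cb:
                if y == "-":
                    continue
                total += match if x == y else mismatch
                pairs += 1
        return total / pairs if pairs else 0.0

    la, lb = len(prof_a[0]), len(prof_b[0])
    cols_a = [col(prof_a, j) for j in range(la)]
    cols_b = [col(prof_b, j) for j in range(lb)]
    score = np.zeros((la + 1, lb + 1))
    back = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, la + 1):
        score[i, 0] = i * gap
        back[i, 0] = 1
    for j in range(1, lb + 1):
        score[0, j] = j * gap
        back[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = score[i - 1, j - 1] + col_score(cols_a[i - 1], cols_b[j - 1])
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            best = max(diag, up, left)
            score[i, j] = best
            back[i, j] = 0 if best == diag else (1 if best == up else 2)
    # traceback
    out_a = [[] for _ in prof_a]
    out_b = [[] for _ in prof_b]
    i, j = la, lb
    while i > 0 or j > 0:
        move = back[i, j]
        if move == 0 and i > 0 and j > 0:
            for r, row in enumerate(prof_a):
                out_a[r].append(row[i - 1])
            for r, row in enumerate(prof_b):
                out_b[r].append(row[j - 1])
            i -= 1
            j -= 1
        elif move == 1 and i > 0:
            for r, row in enumerate(prof_a):
                out_a[r].append(row[i - 1])
            for r in range(len(prof_b)):
                out_b[r].append("-")
            i -= 1
        else:
            for r in range(len(prof_a)):
                out_a[r].append("-")
            for r, row in enumerate(prof_b):
                out_b[r].append(row[j - 1])
            j -= 1
    prof_a_new = ["".join(reversed(r)) for r in out_a]
    prof_b_new = ["".join(reversed(r)) for r in out_b]
    return prof_a_new, prof_b_new


def progressive_align(sequences) -> list:
    """Progressive multiple alignment guided by a k-mer-distance NJ tree.

    ``sequences`` is a list of ``(id, seq)``.  Profiles are merged by
    pairwise global alignment (match 1, mismatch -1, gap -2); the output
    preserves the input row order.
    """
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    names = [n for n, _ in seqs]
    if len(seqs) == 2:
        a, b = _profile_align([seqs[0][1]], [seqs[1][1]])
        return [(names[0], a[0]), (names[1], b[0])]

    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(seqs[i][1], seqs[j][1])
    guide = nj_tree(names, D)

    profiles = {}  # node -> (ids, rows)

    for node in guide.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            idx = names.index(name)
            profiles[node] = ([name], [seqs[idx][1]])
        else:
            children = node.child_nodes()
            ids, rows = profiles.pop(children[0])
            for child in children[1:]:
                cids, crows = profiles.pop(child)
                rows, crows = _profile_align(rows, crows)
                ids = ids + cids
                rows = rows + crows
            profiles[node] = (ids, rows)
    ids, rows = profiles[guide.seed_node]
    by_id = dict(zip(ids, rows))
    return [(name, by_id[name]) for name in names]
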