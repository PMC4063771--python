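"""Gene-tree / species-tree reconciliation by LCA (duplication-loss) parsimony.

Each gene-tree node is mapped to the species-tree LCA of its descendants'
species.  A gene node is a duplication iff some child maps to the same
species node; every other internal node is a speciation.  Losses follow the
standard parsimony arithmetic: a child lineage spanning ``d`` species-tree
edges implies ``d - 1`` losses under a speciation and ``d`` under a
duplication, each charged to the species branch on which the lineage
disappears.  Duplications mapped to species node ``v`` are charged to the
branch *entering* ``v`` (duplications at the species root go to a virtual
root branch, represented as the branch entering the root).

Ancestral copy numbers are obtained by lineage-interval counting: a copy
born by duplication on the branch entering ``v`` is already present at node
``v``; an edge whose child is a duplication at ``v`` terminates above ``v``.
This satisfies the conservation identity
``count(child) = count(parent) + gains - losses`` on every species branch.

Gene leaves carry their species either via an explicit mapping or a
``SPECIES|gene`` label convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class Reconciliation:
    lca_map: dict            # gene node -> species node
    dup_nodes: set
    gains_per_branch: dict   # species-branch key (label of child node) -> count
    losses_per_branch: dict
    ancestral_counts: dict   # species node label -> copies present at that node
    root_lineages: int = 1   # gene lineages entering the origin branch from above
    origin_species: str = "" # species branch on which the family originates


@dataclass
class DupModeSummary:
    n_tandem: int
    n_ectopic: int
    n_unclassified: int = 0

    @property
    def fraction_tandem(self) -> float:
        total = self.n_tandem + self.n_ectopic
        return self.n_tandem / total if total else float("nan")


def species_of_leaf(label: str) -> str:
    """Default species extraction: the part before the first '|'."""
    return label.split("|", 1)[0]


def _species_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "mrca(" + ",".join(sorted(l.taxon.label for l in node.leaf_iter())) + ")"


class _SpeciesIndex:
    """Parent/depth bookkeeping for LCA queries on the species tree."""

    def __init__(self, species_tree: dendropy.Tree):
        self.tree = species_tree
        self.parent = {}
        self.depth = {}
        self.leaf = {}
        for node in species_tree.preorder_node_iter():
            p = node.parent_node
            self.parent[node] = p
            self.depth[node] = 0 if p is None else self.depth[p] + 1
            if node.is_leaf():
                self.leaf[node.taxon.label] = node

    def lca(self, a, b):
        da, db = self.depth[a], self.depth[b]
        while da > db:
            a = self.parent[a]
            da -= 1
        while db > da:
            b = self.parent[b]
            db -= 1
        while a is not b:
            a = self.parent[a]
            b = self.parent[b]
        return a

    def path_down(self, top, bottom):
        """Species nodes from ``top`` to ``bottom`` inclusive (top first)."""
        path = [bottom]
        node = bottom
        while node is not top:
            node = self.parent[node]
            if node is None:
                raise ValueError("bottom is not a descendant of top")
            path.append(node)
        return list(reversed(path))


def lca_map(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
            species_of=species_of_leaf) -> dict:
    """Map every gene-tree node to its species-tree LCA."""
    index = _SpeciesIndex(species_tree)
    M = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            sp = species_of(node.taxon.label)
            if sp not in index.leaf:
                raise KeyError(f"unknown species label {sp!r}")
            M[node] = index.leaf[sp]
        else:
            children = node.child_nodes()
            cur = M[children[0]]
            for c in children[1:]:
                cur = index.lca(cur, M[c])
            M[node] = cur
    return M


def resolve_polytomies(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                       species_of=species_of_leaf) -> dendropy.Tree:
    """Binary resolution of soft polytomies minimizing duplications.

    At each polytomy the two children whose species-tree LCA is deepest are
    merged first (zero-length internal edge), repeated until binary.
    Deterministic: ties break on child order.
    """
    tree = gene_tree.clone(depth=1)
    index = _SpeciesIndex(species_tree)
    M = lca_map(tree, species_tree, species_of)
    for node in list(tree.postorder_node_iter()):
        while len(node.child_nodes()) > 2:
            children = node.child_nodes()
            best = None
            for i in range(len(children)):
                for j in range(i + 1, len(children)):
                    anc = index.lca(M[children[i]], M[children[j]])
                    key = (-index.depth[anc], i, j)
                    if best is None or key < best[0]:
                        best = (key, i, j, anc)
            _, i, j, anc = best
            ci, cj = children[i], children[j]
            node.remove_child(ci)
            node.remove_child(cj)
            merged = dendropy.Node()
            merged.add_child(ci)
            merged.add_child(cj)
            merged.edge.length = 0.0
            node.add_child(merged)
            M[merged] = anc
    return tree


def count_events(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                 M: dict | None = None,
                 species_of=species_of_leaf) -> Reconciliation:
    """Duplications, losses and ancestral copy numbers for one gene tree.

    Polytomies are first resolved minimally (soft-polytomy convention for
    bootstrap-condensed trees).  Branch keys are the labels of the species
    nodes the branches enter; the species root key doubles as the virtual
    root branch.
    """
    if any(len(n.child_nodes()) > 2 for n in gene_tree.preorder_internal_node_iter()):
        gene_tree = resolve_polytomies(gene_tree, species_tree, species_of)
        M = None
    if M is None:
        M = lca_map(gene_tree, species_tree, species_of)
    index = _SpeciesIndex(species_tree)

    gains = {}
    losses = {}
    counts = {}
    for node in species_tree.preorder_node_iter():
        key = _species_label(node)
        gains[key] = 0
        losses[key] = 0
        counts[key] = 0

    dup_nodes = set()
    for g in gene_tree.preorder_internal_node_iter():
        if any(M[c] is M[g] for c in g.child_nodes()):
            dup_nodes.add(g)

    for g in gene_tree.preorder_internal_node_iter():
        is_dup = g in dup_nodes
        vg = M[g]
        if is_dup:
            gains[_species_label(vg)] += len(g.child_nodes()) - 1
        for c in g.child_nodes():
            path = index.path_down(vg, M[c])  # vg .. M(c)
            start = 0 if is_dup else 1
            for i in range(start, len(path) - 1):
                s_i, s_next = path[i], path[i + 1]
                for child in s_i.child_nodes():
                    if child is not s_next:
                        losses[_species_label(child)] += 1

    # --- ancestral counts by lineage intervals -----------------------------
    def occupy(start_node, end_node):
        for s in index.path_down(start_node, end_node):
            counts[_species_label(s)] += 1

    root = gene_tree.seed_node

    def edge_interval(parent, child):
        """Species interval occupied by gene edge parent->child (either may
        be None for the virtual edge above the gene root)."""
        vc = M[child]
        child_is_dup = child in dup_nodes
        # start of lineage
        if parent is None:
            # the family originates on the branch entering M(gene root)
            if child_is_dup:
                return None  # born and duplicated on the origin branch
            return (vc, vc)
        else:
            vp = M[parent]
            if parent in dup_nodes:
                start = vp
            else:  # speciation: lineage exists strictly below vp
                if vp is vc:
                    return None  # cannot happen for speciations
                path = index.path_down(vp, vc)
                start = path[1]
        # end of lineage
        if child_is_dup:
            # terminates on the branch entering vc, above node vc
            if start is vc:
                return None  # born and duplicated on the same branch
            path = index.path_down(start, vc)
            return (start, path[-2])
        return (start, vc)

    for g in gene_tree.preorder_node_iter():
        parent = g.parent_node if g is not root else None
        interval = edge_interval(parent, g)
        if interval is not None:
            occupy(*interval)

    return Reconciliation(
        lca_map=M,
        dup_nodes=dup_nodes,
        gains_per_branch=gains,
        losses_per_branch=losses,
        ancestral_counts=counts,
        root_lineages=1,
        origin_species=_species_label(M[root]),
    )


def check_conservation(recon: Reconciliation, species_tree: dendropy.Tree) -> None:
    """Assert count(v) = count(u) + gains(u->v) - losses(u->v) on every branch.

    The single founding lineage enters on the branch where the family
    originates (the branch entering the gene root's LCA mapping); above that
    branch every count is zero.
    """
    counts = recon.ancestral_counts
    for node in species_tree.preorder_node_iter():
        key = _species_label(node)
        parent = node.parent_node
        upstream = 0 if parent is None else counts[_species_label(parent)]
        expected = upstream + recon.gains_per_branch[key] \
            - recon.losses_per_branch[key]
        if key == recon.origin_species:
            expected += recon.root_lineages
        if counts[key] != expected:
            raise AssertionError(
                f"conservation violated at {key}: count {counts[key]} != {expected}"
            )


def lineage_new_genes(recon: Reconciliation, species: str) -> int:
    """Genes gained on the terminal branch of ``species``.

    Summed over families this is the "new genes" numerator of the
    birth-rate computation.
    """
    if species not in recon.gains_per_branch:
        raise KeyError(f"unknown species {species!r}")
    return recon.gains_per_branch[species]


def classify_duplication_modes(gene_tree: dendropy.Tree, locus_table,
                               species_of=species_of_leaf) -> DupModeSummary:
    """Tandem-vs-ectopic classification of same-species cherries.

    A same-species sister pair whose genomic order indices differ by exactly
    1 is a tandem duplication; any other indexed pair is ectopic (the
    duplicate re-inserted at an unlinked cluster position).  Pairs without
    order indices are counted unclassified.
    """
    order = {}
    for rec in locus_table:
        if rec.order_index >= 0:
            order[rec.gene_id] = rec.order_index
    n_tandem = n_ectopic = n_unclassified = 0
    for node in gene_tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) != 2 or not all(c.is_leaf() for c in children):
            continue
        la, lb = (c.taxon.label for c in children)
        if species_of(la) != species_of(lb):
            continue
        ga = la.split("|", 1)[1] if "|" in la else la
        gb = lb.split("|", 1)[1] if "|" in lb else lb
        oa = order.get(ga, order.get(la))
        ob = order.get(gb, order.get(lb))
        if oa is None or ob is None:
            n_unclassified += 1
            continue
        if abs(oa - ob) == 1:
            n_tandem += 1
        else:
            n_ectopic += 1
    return DupModeSummary(n_tandem, n_ectopic, n_unclassified)
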