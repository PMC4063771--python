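"""Birth--death simulator for C/D box snoRNA gene families.

Generates families with known evolutionary truth so every pipeline stage can
be tested against a ground-truth record: a continuous-time birth--death
process per gene lineage along a dated species tree (exact event-time
sampling, so expectations have closed forms), genomic placement of
duplicates (tandem next to the parent copy or ectopic at a random cluster
position), region-constrained K2P-style sequence evolution, emergent
pseudogenization through box-disrupting substitutions, and target mRNAs
with planted antisense sites.

The simulator logs every event; the event log replays exactly to the final
per-species gene counts (asserted on every run).  Because lineages whose
descendants all died are pruned from the true gene tree, the log also
records per-branch *visible* duplications (both daughter copies left extant
descendants) — the quantity LCA reconciliation of the true tree can
recover exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from snoevo import seqio
from snoevo.config import DEFAULT_SPECIES_TREE
from snoevo.seqio import SnoRecord, reverse_complement
from snoevo.structure import MotifParams, annotate_structure

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# Relative substitution-rate multipliers of the five structural classes,
# matching the observed conservation hierarchy of imprinted C/D snoRNAs:
# boxes most conserved, then the terminal stem, then the functional ASE,
# with the non-guide ASE and the remaining sequence evolving neutrally.
DEFAULT_REGION_MULTIPLIERS = {
    "BOX": 0.05,
    "STEM": 0.075,
    "ASE1": 1.0,
    "ASE2": 0.1,
    "REST": 1.0,
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic families.

    Rates are per gene (or per site) per My.  The defaults emulate an
    imprinted snoRNA cluster expanding along a 12-species eutherian tree:
    net growth (birth - death) of ~0.03/gene/My turns one ancestral copy
    into a few tens of genes per extant species over ~100 My, a neutral
    substitution rate of 2e-3/site/My, transition bias kappa = 4, and the
    region constraint profile with boxes most conserved and ASE2 under
    strong constraint.
    """

    species_tree: str = DEFAULT_SPECIES_TREE
    root_count: int = 1
    birth_rate: float = 0.04
    death_rate: float = 0.008
    birth_rate_per_branch: dict | None = None
    pseudogenize_rate: float = 0.0
    p_ectopic: float = 0.25
    kappa: float = 4.0
    subst_rate: float = 0.002
    region_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_REGION_MULTIPLIERS)
    )
    gene_length: int = 82
    family: str = "FAM1"
    seed: int = 0
    max_lineages: int = 10_000

    def __post_init__(self):
        for name in ("birth_rate", "death_rate", "pseudogenize_rate",
                     "subst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.region_multipliers.values()):
            raise ValueError("region multipliers must be >= 0")

    def branch_birth_rate(self, branch_label: str) -> float:
        if self.birth_rate_per_branch:
            return self.birth_rate_per_branch.get(branch_label, self.birth_rate)
        return self.birth_rate


class Lineage:
    """One gene lineage segment of the true gene tree."""

    __slots__ = ("birth", "length", "children", "event", "event_branch",
                 "pseudo", "species", "name", "sequence")

    def __init__(self, birth: float, pseudo: bool = False):
        self.birth = birth
        self.length = 0.0
        self.children = []
        self.event = None  # dup | spec | extant | root
        self.event_branch = None
        self.pseudo = pseudo
        self.species = None
        self.name = None
        self.sequence = None

    def leaves(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class SimResult:
    config: SimConfig
    records: list                 # SnoRecord per extant gene
    gene_tree_root: Lineage | None
    gene_tree_newick: str | None
    event_log: list               # dicts: type, branch, time, mode
    per_branch: dict              # branch -> {dup, loss, pseudogenize, visible_dup}
    root_sequence: str
    region_labels: list           # true per-position class of the root gene
    extant_by_species: dict       # species -> ordered gene names
    has_hidden_events: bool = False

    @property
    def gene_tree(self):
        if self.gene_tree_newick is None:
            return None
        return seqio.tree_from_string(self.gene_tree_newick)


def _species_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "mrca(" + ",".join(sorted(l.taxon.label for l in node.leaf_iter())) + ")"


def default_root_snorna(length: int = 82, seed: int = 0,
                        params: MotifParams | None = None):
    """Construct a canonical ancestral snoRNA gene.

    Layout (default 82 nt): 5-nt terminal stems, exact C box at offset 5,
    ASE1, D' and C' internal boxes, random filler, an 18-nt ASE2 abutting
    the D box, which ends 5 nt before the 3' end.  The construction
    guarantees acceptance by :func:`snoevo.structure.annotate_structure`
    with score 2*7 + 3*4 + 5 = 31.

    Returns ``(sequence, annotation)``.
    """
    if length < 60:
        raise ValueError("length must be >= 60")
    if params is None:
        params = MotifParams()
    rng = np.random.default_rng(seed)
    bases = "ACGT"

    def rand(n):
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    stem5 = rand(5)
    stem3 = reverse_complement(stem5)
    ase = params.ase_len
    core = 5 + 7 + ase + 4 + 7 + ase + 4 + 5  # stems, boxes, two ASEs
    with_internal = length >= core
    if with_internal:
        filler = length - core
        parts = [stem5, "ATGATGA", rand(ase), "CTGA", "GTGATGA",
                 rand(filler), rand(ase), "CTGA", stem3]
    else:
        # shrink: drop internal boxes, ASE1 takes what room remains
        room = length - (5 + 7 + ase + 4 + 5)
        if room < 0:
            raise ValueError("length too short for the C/D layout")
        parts = [stem5, "ATGATGA", rand(room), rand(ase), "CTGA", stem3]
    seq = "".join(parts)
    assert len(seq) == length
    ann = annotate_structure(seq, params)
    return seq, ann


# ---------------------------------------------------------------------------
# Birth-death along the species tree
# ---------------------------------------------------------------------------

def _branch_process(order, label, duration, t0, rng, cfg, events):
    """Gillespie birth/death/pseudogenization over one species branch.

    ``order`` is the genomic order of active lineages and is edited in
    place.  Returns the (ordered) survivors.
    """
    lam = cfg.branch_birth_rate(label)
    mu = cfg.death_rate
    rho = cfg.pseudogenize_rate
    per_event = lam + mu + rho
    t = t0
    while order and per_event > 0:
        n = len(order)
        if n > cfg.max_lineages:
            raise RuntimeError(
                f"more than {cfg.max_lineages} lineages; reduce birth_rate"
            )
        total = n * per_event
        dt = rng.exponential(1.0 / total)
        if t + dt > t0 + duration:
            break
        t += dt
        idx = int(rng.integers(n))
        lin = order[idx]
        u = rng.random() * per_event
        if u < lam:
            mode = "ectopic" if rng.random() < cfg.p_ectopic else "tandem"
            lin.length = t - lin.birth
            lin.event = "dup"
            lin.event_branch = label
            c1 = Lineage(t, pseudo=lin.pseudo)
            c2 = Lineage(t, pseudo=lin.pseudo)
            lin.children = [c1, c2]
            order[idx] = c1
            if mode == "tandem":
                order.insert(idx + 1, c2)
            else:
                order.insert(int(rng.integers(len(order) + 1)), c2)
            events.append({"type": "dup", "branch": label, "time": t,
                           "mode": mode})
        elif u < lam + mu:
            lin.length = t - lin.birth
            lin.event = "loss"
            order.pop(idx)
            events.append({"type": "loss", "branch": label, "time": t,
                           "mode": None})
        else:
            lin.pseudo = True
            events.append({"type": "pseudogenize", "branch": label, "time": t,
                           "mode": None})
    return order


def _prune(node: Lineage):
    """Drop extinct subtrees; merge unifurcations (lengths add)."""
    if node.event == "extant":
        return node
    kept = [k for k in (_prune(c) for c in node.children) if k is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length += node.length
        return child
    node.children = kept
    return node


def _to_newick(node: Lineage) -> str:
    def fmt(n):
        if not n.children:
            return f"{n.name}:{n.length:.6f}"
        inner = ",".join(fmt(c) for c in n.children)
        return f"({inner}):{n.length:.6f}"

    if not node.children:
        return f"({node.name}:{node.length:.6f});"
    inner = ",".join(fmt(c) for c in node.children)
    return f"({inner});"


def replay_counts(event_log, species_tree, root_count: int = 1) -> dict:
    """Final per-species gene counts implied by the event log."""
    per_branch = {}
    for ev in event_log:
        d = per_branch.setdefault(ev["branch"], {"dup": 0, "loss": 0})
        if ev["type"] == "dup":
            d["dup"] += 1
        elif ev["type"] == "loss":
            d["loss"] += 1
    counts = {}
    for leaf in species_tree.leaf_node_iter():
        n = root_count
        node = leaf
        while node is not None:
            label = _species_label(node)
            d = per_branch.get(label, {"dup": 0, "loss": 0})
            n += d["dup"] - d["loss"]
            node = node.parent_node
        counts[leaf.taxon.label] = n
    return counts


def simulate_gene_tree(cfg: SimConfig, rng=None):
    """Run the birth-death process; returns
    ``(root, extant_by_species, event_log, per_branch, species_tree)``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sp_tree = seqio.tree_from_string(cfg.species_tree, species_tree=True)
    events = []
    extant = {}

    def walk(sp_node, order, t0):
        duration = sp_node.edge.length or 0.0
        label = _species_label(sp_node)
        surv = _branch_process(order, label, duration, t0, rng, cfg, events)
        t1 = t0 + duration
        if sp_node.is_leaf():
            extant[label] = list(surv)
            for lin in surv:
                lin.length = t1 - lin.birth
                lin.event = "extant"
                lin.species = label
        else:
            daughters = sp_node.child_nodes()
            buckets = [[] for _ in daughters]
            for lin in surv:
                lin.length = t1 - lin.birth
                lin.event = "spec"
                for k in range(len(daughters)):
                    child = Lineage(t1, pseudo=lin.pseudo)
                    lin.children.append(child)
                    buckets[k].append(child)
            for d, bucket in zip(daughters, buckets):
                walk(d, bucket, t1)

    if cfg.root_count == 1:
        root = Lineage(0.0)
        initial = [root]
    else:
        root = Lineage(0.0)
        root.event = "root"
        initial = []
        for _ in range(cfg.root_count):
            c = Lineage(0.0)
            root.children.append(c)
            initial.append(c)
    walk(sp_tree.seed_node, initial, 0.0)

    # event-log replay must equal the realized per-species counts
    replayed = replay_counts(events, sp_tree, cfg.root_count)
    for sp, lins in extant.items():
        if replayed[sp] != len(lins):
            raise AssertionError(
                f"event-log replay mismatch for {sp}: {replayed[sp]} != {len(lins)}"
            )

    per_branch = {}
    for ev in events:
        d = per_branch.setdefault(
            ev["branch"], {"dup": 0, "loss": 0, "pseudogenize": 0,
                           "visible_dup": 0})
        d[ev["type"]] += 1

    pruned = _prune(root)
    if pruned is not None:
        for node in pruned.walk():
            if node.children and node.event == "dup":
                d = per_branch.setdefault(
                    node.event_branch,
                    {"dup": 0, "loss": 0, "pseudogenize": 0, "visible_dup": 0})
                d["visible_dup"] += 1

    return pruned, extant, events, per_branch, sp_tree


def _evolve(seq: str, duration: float, site_rates, rng, kappa: float) -> str:
    out = list(seq)
    counts = rng.poisson(site_rates * duration)
    p_ts = kappa / (kappa + 2.0)
    for i in np.nonzero(counts)[0]:
        base = out[i]
        for _ in range(counts[i]):
            if rng.random() < p_ts:
                base = TRANSITION[base]
            else:
                base = TRANSVERSIONS[base][int(rng.integers(2))]
        out[i] = base
    return "".join(out)


def simulate_sequences(root: Lineage, root_seq: str, region_labels,
                       cfg: SimConfig, rng=None) -> dict:
    """Evolve sequences down the (pruned) gene tree.

    Per-site Markov substitution with transition bias ``kappa`` and
    region-specific rate multipliers; the total rate of the REST class is
    ``subst_rate`` substitutions/site/My, so the expected K2P distance
    between two leaves over REST columns equals the sum of their branch
    times times ``subst_rate``.  Returns ``{leaf_name: sequence}``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    mult = np.array([cfg.region_multipliers[lab] for lab in region_labels])
    site_rates = cfg.subst_rate * mult

    out = {}

    def recurse(node, seq):
        seq = _evolve(seq, node.length, site_rates, rng, cfg.kappa)
        node.sequence = seq
        if not node.children:
            out[node.name] = seq
        for c in node.children:
            recurse(c, seq)

    root_branch = _evolve(root_seq, 0.0, site_rates, rng, cfg.kappa)
    recurse(root, root_branch)
    return out


def simulate_family(cfg: SimConfig) -> SimResult:
    """Full simulation: gene tree, genomic order, sequences, records."""
    rng = np.random.default_rng(cfg.seed)
    root_seq, root_ann = default_root_snorna(cfg.gene_length,
                                             seed=int(rng.integers(2**31)))
    region_labels = root_ann.region_map()

    pruned, extant, events, per_branch, sp_tree = simulate_gene_tree(cfg, rng)

    # name extant genes in genomic order
    extant_names = {}
    for sp, lins in extant.items():
        names = []
        for i, lin in enumerate(lins):
            lin.name = f"{sp}|{cfg.family}_{i:03d}"
            names.append(lin.name)
        extant_names[sp] = names

    records = []
    newick = None
    if pruned is not None:
        seqs = simulate_sequences(pruned, root_seq, region_labels, cfg, rng)
        newick = _to_newick(pruned)
        for sp, lins in extant.items():
            for i, lin in enumerate(lins):
                records.append(
                    SnoRecord(
                        gene_id=lin.name,
                        species=sp,
                        family=cfg.family,
                        sequence=seqs[lin.name],
                        chrom="cluster",
                        order_index=i,
                    )
                )

    hidden = any(
        d["dup"] != d["visible_dup"] or d["loss"] > 0
        for d in per_branch.values()
    )
    return SimResult(
        config=cfg,
        records=records,
        gene_tree_root=pruned,
        gene_tree_newick=newick,
        event_log=events,
        per_branch=per_branch,
        root_sequence=root_seq,
        region_labels=region_labels,
        extant_by_species=extant_names,
        has_hidden_events=hidden,
    )


def make_target_mrna(ase2: str, flank_len: int = 300, planted_len: int = 18,
                     planted_offset_from_dbox: int = 0,
                     mismatch_positions=(), seed: int = 0,
                     upstream: str = ""):
    """Target mRNA with a planted antisense site.

    The reverse complement of the chosen ASE2 sub-window is embedded between
    random flanks; ``planted_offset_from_dbox`` shifts the site away from
    the D box and ``mismatch_positions`` (1-based distances upstream of the
    D box) plant non-pairing bases.  Bases flanking the site are forced
    non-complementary so the planted match is maximal by construction
    (``upstream`` supplies the snoRNA context 5' of the ASE2 window when the
    site spans the whole window).

    Returns ``(mrna, site_start, site_end)`` with 0-based half-open site
    coordinates on the forward strand.
    """
    W = len(ase2)
    offset = planted_offset_from_dbox
    if planted_len + offset > W:
        raise ValueError("planted site does not fit in the ASE window")
    rng = np.random.default_rng(seed)
    bases = "ACGT"

    def rand(n):
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    window = ase2[W - offset - planted_len : W - offset]
    site = list(reverse_complement(window))
    for pos in mismatch_positions:
        k = pos - offset - 1
        if not 0 <= k < planted_len:
            raise ValueError(f"mismatch position {pos} outside planted site")
        # same base as the guide never pairs it
        site[k] = ase2[W - pos]
    site = "".join(site)

    flank5 = list(rand(flank_len))
    flank3 = list(rand(flank_len))
    # guard the site boundaries against chance extension of the perfect run
    if offset >= 1 and flank5:
        flank5[-1] = ase2[W - offset]          # pairs nothing (same base)
    q = offset + planted_len + 1               # guide position past the site
    if flank3:
        if q <= W:
            flank3[0] = ase2[W - q]
        elif upstream and q - W <= len(upstream):
            flank3[0] = upstream[len(upstream) - (q - W)]
        else:
            flank3[0] = "N"                    # unknown context: never pairs
    mrna = "".join(flank5) + site + "".join(flank3)
    return mrna, flank_len, flank_len + planted_len
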