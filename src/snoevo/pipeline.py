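"""End-to-end pipeline: simulate/ingest -> annotate -> classify -> tree ->
reconcile -> rates -> selection -> duplex, with a reproducible report.

The report is a pure function of (inputs, config, seed): running twice with
the same configuration yields byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from snoevo import __version__, config as study_config
from snoevo import seqio
from snoevo.families import bootstrap_tree, condense_tree
from snoevo.rates import between_group_distance, birth_rate, partitioned_rates, rate_ratio
from snoevo.reconcile import (
    check_conservation,
    classify_duplication_modes,
    count_events,
    lineage_new_genes,
)
from snoevo.selection import tajimas_d
from snoevo.simulate import SimConfig, make_target_mrna, simulate_family
from snoevo.structure import (
    MotifParams,
    annotate_structure,
    call_pseudogene,
    group_average_ratio,
    pseudogene_ratio,
)
from snoevo.duplex import scan_perfect_matches, summarize_binding


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults are the package-wide
    parameter values (e-value 1e-3, support >50%, 500 bootstrap replicates,
    18-nt ASEs, acceptance score 24)."""

    seed: int = 0
    sim: SimConfig | None = None
    species_tree: str | None = study_config.DEFAULT_SPECIES_TREE
    divergence_times: dict = field(
        default_factory=lambda: dict(study_config.DIVERGENCE_TIMES_MY)
    )
    motif: MotifParams = field(default_factory=MotifParams)
    tree_bootstrap: int = 50
    tree_max_per_species: int = 6   # representative genes per species for trees
    condense_threshold: float = 50.0
    duplex_min_len: int = 7
    n_families: int = 1

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed,
                                 species_tree=self.species_tree
                                 or study_config.DEFAULT_SPECIES_TREE)


def _representatives(records, max_per_species):
    out = []
    seen = {}
    for rec in records:
        k = seen.get(rec.species, 0)
        if k < max_per_species:
            out.append(rec)
            seen[rec.species] = k + 1
    return out


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage on one simulated family set; returns the report."""
    if not cfg.species_tree:
        raise StageError("reconcile: species tree input is required")

    report = {"provenance": {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg.sim), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }}

    # --- simulate ----------------------------------------------------------
    try:
        sims = []
        for fam_idx in range(cfg.n_families):
            fam_cfg = SimConfig(**{**asdict(cfg.sim),
                                   "seed": cfg.seed + fam_idx,
                                   "family": f"FAM{fam_idx + 1}"})
            sims.append(simulate_family(fam_cfg))
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc

    records = [r for sim in sims for r in sim.records]
    counts = {}
    for rec in records:
        counts.setdefault(rec.species, {}).setdefault(rec.family, 0)
        counts[rec.species][rec.family] += 1
    report["gene_counts"] = counts

    # --- annotate ----------------------------------------------------------
    try:
        annotations = {}
        calls = []
        for rec in records:
            ann = annotate_structure(rec.sequence, cfg.motif)
            annotations[rec.gene_id] = ann
            call = call_pseudogene(ann, cfg.motif)
            calls.append((rec.species, rec.family, call.is_pseudogene))
    except Exception as exc:
        raise StageError(f"annotate: {exc}") from exc
    ratios = pseudogene_ratio(calls)
    report["pseudogene_ratios"] = ratios.to_dict(orient="records")
    report["pseudogene_group_averages"] = group_average_ratio(
        ratios, study_config.SPECIES_GROUPS
    )

    # --- tree + reconcile + duplication modes ------------------------------
    sp_tree = seqio.tree_from_string(cfg.species_tree, species_tree=True)
    recon_summary = {}
    dup_modes = {}
    birth = {}
    for sim in sims:
        fam = sim.config.family
        try:
            reps = _representatives(sim.records, cfg.tree_max_per_species)
            aln = [(r.gene_id, r.sequence) for r in reps]
            if len(aln) >= 4:
                tree = bootstrap_tree(aln, n_reps=cfg.tree_bootstrap,
                                      seed=cfg.seed)
                tree = condense_tree(tree, cfg.condense_threshold)
                recon = count_events(tree, sp_tree)
                check_conservation(recon, sp_tree)
                recon_summary[fam] = {
                    "gains": recon.gains_per_branch,
                    "losses": recon.losses_per_branch,
                    "ancestral_counts": recon.ancestral_counts,
                }
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"reconcile: {exc}") from exc

        # duplication modes + birth rates use the true gene tree
        if sim.gene_tree_newick is not None:
            gt = sim.gene_tree
            locus = seqio.LocusTable(sim.records)
            dm = classify_duplication_modes(gt, locus)
            dup_modes[fam] = {"n_tandem": dm.n_tandem,
                              "n_ectopic": dm.n_ectopic,
                              "fraction_tandem": dm.fraction_tandem}
            true_recon = count_events(gt, sp_tree)
            for sp, t in cfg.divergence_times.items():
                gains = lineage_new_genes(true_recon, sp)
                entry = birth.setdefault(sp, {"n_new": 0, "time_my": t})
                entry["n_new"] += gains
    for sp, entry in birth.items():
        br = birth_rate(entry["n_new"], entry["time_my"], cfg.n_families)
        entry["rate"] = br.rate
        entry["per_family_rate"] = br.per_family_rate
    report["reconciliation"] = recon_summary
    report["duplication_modes"] = dup_modes
    report["birth_rates"] = birth

    # --- partition rates (human vs each other species) ---------------------
    partition = {}
    sim0 = sims[0]
    by_sp = {}
    for rec in sim0.records:
        by_sp.setdefault(rec.species, []).append(rec.sequence)
    human = by_sp.get("Human", [])
    for sp, rows in sorted(by_sp.items()):
        if sp == "Human" or not human:
            continue
        try:
            partition[sp] = partitioned_rates(human, rows, sim0.region_labels)
        except ValueError:
            partition[sp] = None
    report["partition_rates"] = partition

    # --- Tajima's D per species --------------------------------------------
    tajima = {}
    for sp, rows in sorted(by_sp.items()):
        res = tajimas_d(rows)
        tajima[sp] = {"n": res.n, "S": res.S,
                      "D": res.D if res.defined else None,
                      "p": res.p_value if res.defined else None}
    report["tajimas_d"] = tajima

    # --- duplex binding ----------------------------------------------------
    try:
        ann_root = annotate_structure(sim0.root_sequence, cfg.motif)
        a2 = ann_root.ase2
        ase2_seq = sim0.root_sequence[a2[0]:a2[1]]
        mrna, s0, s1 = make_target_mrna(
            ase2_seq, seed=cfg.seed,
            upstream=sim0.root_sequence[:a2[0]],
        )
        results = []
        for rec in sim0.records:
            ann = annotations[rec.gene_id]
            if ann.d_box is None:
                continue
            _, best = scan_perfect_matches(rec.sequence, ann.d_box.start,
                                           mrna, min_len=cfg.duplex_min_len)
            results.append((rec.species, best))
        table = summarize_binding(results)
        report["duplex"] = table.to_dict(orient="records")
    except Exception as exc:
        raise StageError(f"duplex: {exc}") from exc

    return report


def report_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=2, default=str)


# ---------------------------------------------------------------------------
# Published-table arithmetic
# ---------------------------------------------------------------------------

def load_reference_counts() -> pd.DataFrame:
    """Per-species family counts of the PWS imprinted snoRNA repertoire."""
    path = importlib.resources.files("snoevo").joinpath("data/pws_gene_counts.tsv")
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def table1_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Add per-species totals and a grand-total row to a count table.

    ``counts`` has one row per species and one column per family (plus
    optional ``species``/``group`` columns).
    """
    fam_cols = [c for c in counts.columns if c not in ("species", "group")]
    out = counts.copy()
    out["total"] = out[fam_cols].sum(axis=1)
    grand = {c: out[c].sum() for c in fam_cols + ["total"]}
    grand["species"] = "ALL"
    if "group" in out.columns:
        grand["group"] = ""
    return pd.concat([out, pd.DataFrame([grand])], ignore_index=True)


def counts_from_assignments(records, assignments, calls) -> pd.DataFrame:
    """Species x family counts of accepted, assigned, non-pseudogene genes."""
    by_id_assign = {a.gene_id: a for a in assignments}
    rows = []
    for rec, call in zip(records, calls):
        a = by_id_assign.get(rec.gene_id)
        if a is None or not a.assigned or call.is_pseudogene:
            continue
        rows.append({"species": rec.species, "family": a.family})
    if not rows:
        return pd.DataFrame(columns=["species"])
    df = pd.DataFrame(rows)
    pivot = df.pivot_table(index="species", columns="family", aggfunc="size",
                           fill_value=0)
    pivot = pivot.reset_index()
    pivot.columns.name = None
    return pivot


def birth_rate_table(inputs: dict | None = None) -> dict:
    """Gene-birth-rate table at printed precision.

    Rates are rounded to 2 decimals before the per-family division (the
    published table's arithmetic), per-family rates of the many-family
    non-imprinted set to 4 decimals, and fold ratios to 2.
    """
    if inputs is None:
        inputs = study_config.BIRTH_RATE_INPUTS
    out = {"imprinted": {}, "non_imprinted": {}}
    for kind in ("imprinted", "non_imprinted"):
        for sp, row in inputs[kind].items():
            br = birth_rate(row["n_new"], row["time_my"], row["n_families"])
            rate = round(br.rate, 2)
            per_family = rate / row["n_families"]
            if kind == "non_imprinted":
                per_family = round(per_family, 4)
            else:
                per_family = round(per_family, 3)
            out[kind][sp] = {"n_new": row["n_new"],
                             "time_my": row["time_my"],
                             "n_families": row["n_families"],
                             "rate": rate,
                             "per_family_rate": per_family}
    ratios = {}
    for sp in out["imprinted"]:
        if sp in out["non_imprinted"]:
            ratios[sp] = rate_ratio(
                out["imprinted"][sp]["per_family_rate"],
                out["non_imprinted"][sp]["per_family_rate"],
            )
    out["imprinted_vs_non_imprinted_ratio"] = ratios
    return out
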