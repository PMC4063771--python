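"""Substitution-rate and gene-birth-rate statistics.

Implements the Kimura 2-parameter (K2P) distance with pairwise deletion,
between-group average distances with bootstrap standard errors, per-region
partitioned rates, gene-vs-flank comparisons, name-ordered concatenation and
gene birth-rate arithmetic.

The K2P distance separates the transition proportion ``P`` from the
transversion proportion ``Q``::

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

and is undefined (saturated) when either log argument is non-positive;
saturation is a value (``defined=False``), not an exception, so that group
averages can drop invalid pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID_BASES = {"A", "C", "G", "T"}


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass
class K2PResult:
    P: float
    Q: float
    K: float
    valid_sites: int
    defined: bool


@dataclass
class GroupDistance:
    K_mean: float
    SE: float
    n_pairs: int
    n_boot: int
    n_dropped: int = 0


@dataclass
class BirthRate:
    n_new: int
    time_my: float
    n_families: int
    rate: float
    per_family_rate: float


@dataclass
class FlankComparison:
    K_sno: float
    K_f: float


def k2p_distance(row_a: str, row_b: str, gap_policy: str = "pairwise_deletion") -> K2PResult:
    """K2P distance between two rows of one alignment.

    Sites where either row carries a gap or ``N`` are excluded (pairwise
    deletion).  ``gap_policy`` exists for signature compatibility with the
    group routines; the per-pair computation is always pairwise deletion.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    transitions = transversions = valid = 0
    for a, b in zip(row_a, row_b):
        if a not in VALID_BASES or b not in VALID_BASES:
            continue
        valid += 1
        if a != b:
            if is_transition(a, b):
                transitions += 1
            else:
                transversions += 1
    if valid == 0:
        raise ValueError("zero valid sites")
    P = transitions / valid
    Q = transversions / valid
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(P, Q, math.nan, valid, False)
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(P, Q, K, valid, True)


def _complete_deletion(rows):
    """Drop columns with a gap or N in any row."""
    arr = np.array([list(r) for r in rows])
    keep = np.all(np.isin(arr, list(VALID_BASES)), axis=0)
    return ["".join(row) for row in arr[:, keep]]


def between_group_distance(group_a, group_b, gap_policy: str = "pairwise_deletion") -> GroupDistance:
    """Arithmetic mean K2P distance over all valid inter-group pairs.

    ``group_a``/``group_b`` are lists of aligned rows sharing one alignment.
    Pairs whose K2P distance is saturated are dropped (and counted).
    """
    if gap_policy == "complete_deletion":
        all_rows = _complete_deletion(list(group_a) + list(group_b))
        group_a = all_rows[: len(group_a)]
        group_b = all_rows[len(group_a):]
    ks = []
    dropped = 0
    for a in group_a:
        for b in group_b:
            res = k2p_distance(a, b)
            if res.defined:
                ks.append(res.K)
            else:
                dropped += 1
    if not ks:
        raise ValueError("no valid inter-group pair")
    return GroupDistance(
        K_mean=float(np.mean(ks)),
        SE=0.0,
        n_pairs=len(ks),
        n_boot=0,
        n_dropped=dropped,
    )


def bootstrap_se(group_a, group_b, n_boot: int = 500, seed: int = 0) -> float:
    """Bootstrap SE of the between-group mean K2P distance.

    Alignment columns are resampled with replacement ``n_boot`` times; the
    SE is the standard deviation of the replicate means.  Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    arr_a = np.array([list(r) for r in group_a])
    arr_b = np.array([list(r) for r in group_b])
    width = arr_a.shape[1]
    if width < 2:
        raise ValueError("alignment width must be >= 2")
    reps = []
    for _ in range(n_boot):
        cols = rng.integers(0, width, size=width)
        rows_a = ["".join(row) for row in arr_a[:, cols]]
        rows_b = ["".join(row) for row in arr_b[:, cols]]
        try:
            reps.append(between_group_distance(rows_a, rows_b).K_mean)
        except ValueError:
            continue
    if not reps:
        return math.nan
    return float(np.std(reps, ddof=0))


def group_distance_with_se(group_a, group_b, n_boot: int = 500, seed: int = 0) -> GroupDistance:
    base = between_group_distance(group_a, group_b)
    se = bootstrap_se(group_a, group_b, n_boot=n_boot, seed=seed)
    return GroupDistance(base.K_mean, se, base.n_pairs, n_boot, base.n_dropped)


def concatenate_by_name(records) -> str:
    """Concatenate gene sequences in ascending lexicographic gene-id order.

    Accepts SnoRecords or ``(gene_id, sequence)`` pairs.
    """
    items = []
    for rec in records:
        if isinstance(rec, tuple):
            items.append(rec)
        else:
            items.append((rec.gene_id, rec.sequence))
    if not items:
        raise ValueError("no records")
    return "".join(seq for _, seq in sorted(items, key=lambda x: x[0]))


def partitioned_rates(group_a, group_b, column_labels,
                      classes=("STEM", "BOX", "ASE1", "ASE2", "REST"),
                      min_sites: int = 5) -> dict:
    """Between-group K2P distance restricted to each structural class.

    ``column_labels`` gives one class label per alignment column.  Classes
    with fewer than ``min_sites`` valid sites (or saturated) map to None.
    """
    width = len(column_labels)
    for row in list(group_a) + list(group_b):
        if len(row) != width:
            raise ValueError("column label vector does not match alignment width")
    labels = np.asarray(column_labels)
    arr_a = np.array([list(r) for r in group_a])
    arr_b = np.array([list(r) for r in group_b])
    out = {}
    for cls in classes:
        mask = labels == cls
        if mask.sum() < min_sites:
            out[cls] = None
            continue
        rows_a = ["".join(row) for row in arr_a[:, mask]]
        rows_b = ["".join(row) for row in arr_b[:, mask]]
        try:
            gd = between_group_distance(rows_a, rows_b)
        except ValueError:
            out[cls] = None
            continue
        out[cls] = gd.K_mean
    return out


def flank_vs_gene(gene_alignment, upstream_alignment, downstream_alignment,
                  group_a_ids, group_b_ids) -> FlankComparison:
    """Compare substitution rates of genes vs their flanking sequences.

    Each alignment is a list of ``(id, row)`` pairs with matching ids.
    ``K_f`` is the mean of the upstream and downstream between-group K.
    """
    def split(aln):
        rows = dict(aln)
        missing = (set(group_a_ids) | set(group_b_ids)) - set(rows)
        if missing:
            raise KeyError(f"ids missing from alignment: {sorted(missing)}")
        return [rows[i] for i in group_a_ids], [rows[i] for i in group_b_ids]

    ga, gb = split(gene_alignment)
    k_sno = between_group_distance(ga, gb).K_mean
    ua, ub = split(upstream_alignment)
    da, db = split(downstream_alignment)
    k_up = between_group_distance(ua, ub).K_mean
    k_down = between_group_distance(da, db).K_mean
    return FlankComparison(K_sno=k_sno, K_f=(k_up + k_down) / 2.0)


def birth_rate(n_new: int, time_my: float, n_families: int = 1) -> BirthRate:
    """Gene birth rate: newly derived genes per My (and per family).

    The rate is the number of genes gained on a terminal lineage divided by
    the time since that species diverged from its closest relative.
    """
    if time_my <= 0:
        raise ValueError("divergence time must be positive")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rate = n_new / time_my
    return BirthRate(
        n_new=n_new,
        time_my=time_my,
        n_families=n_families,
        rate=rate,
        per_family_rate=rate / n_families,
    )


def rate_ratio(a, b, ndigits: int = 2) -> float:
    """Fold difference between two birth rates, rounded as reported."""
    av = a.per_family_rate if isinstance(a, BirthRate) else float(a)
    bv = b.per_family_rate if isinstance(b, BirthRate) else float(b)
    if bv == 0:
        raise ZeroDivisionError("denominator rate is zero")
    return round(av / bv, ndigits)
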