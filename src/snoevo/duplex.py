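"""snoRNA antisense-element : target-mRNA duplex analysis.

The guide region 5' of the D box base-pairs antiparallel with the target
mRNA; the target nucleotide paired to the 5th snoRNA position upstream of
the D box receives the 2'-O-methylation (the "+5 rule").  "Perfect binding"
here means strict Watson-Crick pairs (A:U, G:C); G:U wobble is excluded by
default and available behind a flag.

Distance convention: ``dist_from_dbox = 0`` means the duplex ends at the
snoRNA position immediately 5' of the D box::

        5'---[ ASE2 ... duplex ]<--dist-->[D box]---3'   (snoRNA)
        3'---[       target    ]---------------------5'  (mRNA, antiparallel)

Position ``i`` in the anchored-duplex report is the i-th snoRNA nucleotide
upstream of the D box (1 = immediately adjacent); it pairs the i-th
nucleotide of the target site read 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from snoevo.seqio import reverse_complement

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = WC | {("G", "T"), ("T", "G")}


@dataclass
class DuplexMatch:
    sno_interval: tuple     # on the snoRNA, 0-based half-open
    target_interval: tuple  # on the mRNA (forward strand coordinates)
    length: int
    dist_from_dbox: int


@dataclass
class AnchoredDuplex:
    pairing: list                 # True/False per position, index 0 = position 1
    mismatch_positions: list      # 1-based distances upstream of the D box
    n_mm_first5: int


@dataclass
class SitePrediction:
    target_index: int | None
    valid: bool


def pairs(a: str, b: str, wobble: bool = False) -> bool:
    return (a, b) in (WOBBLE if wobble else WC)


def scan_perfect_matches(sno_seq: str, dbox_start: int, target: str,
                         min_len: int = 7, wobble: bool = False):
    """All maximal perfect duplexes between the guide region and a target.

    The snoRNA region 5' of the D box is compared against the reverse
    complement of the target; a duplex is a maximal run of strict
    complementarity.  Returns ``(matches, best)`` where ``best`` is the
    longest match, ties broken by smallest distance from the D box then
    smallest target start.  Raises if the D box is not annotated.
    """
    if dbox_start is None or dbox_start <= 0:
        raise ValueError("D box position required for duplex scanning")
    region = sno_seq[:dbox_start]
    rc = reverse_complement(target)
    n, m = len(region), len(rc)
    matches = []
    if wobble:
        def eq(i, j):
            # wobble G:U duplex pair means sno G vs target T -> rc A... handled
            # by comparing against the target base directly
            t = target[len(target) - 1 - j]
            return pairs(region[i], t, wobble=True)
    else:
        def eq(i, j):
            return region[i] == rc[j]
    # diagonal scan for maximal common runs between region and rc(target)
    for diag in range(-(m - 1), n):
        i = max(diag, 0)
        j = i - diag
        run = 0
        while i <= n and j <= m:
            inside = i < n and j < m and eq(i, j)
            if inside:
                run += 1
            elif run:
                if run >= min_len:
                    sno_iv = (i - run, i)
                    # rc[j-run:j] maps to target[m-j : m-j+run]
                    tgt_iv = (m - j, m - j + run)
                    matches.append(
                        DuplexMatch(
                            sno_interval=sno_iv,
                            target_interval=tgt_iv,
                            length=run,
                            dist_from_dbox=dbox_start - sno_iv[1],
                        )
                    )
                run = 0
            if i == n or j == m:
                break
            i += 1
            j += 1
    best = None
    if matches:
        best = min(
            matches,
            key=lambda d: (-d.length, d.dist_from_dbox, d.target_interval[0]),
        )
    return matches, best


def anchored_duplex(ase_window: str, target_site: str,
                    wobble: bool = False) -> AnchoredDuplex:
    """Position-by-position pairing of the D-box-anchored guide window.

    ``ase_window`` is read in genomic orientation (its last base abuts the
    D box); ``target_site`` is the mRNA site 5'->3'.  Both must have equal
    length.
    """
    if len(ase_window) != len(target_site):
        raise ValueError("ASE window and target site must have equal length")
    W = len(ase_window)
    pairing = []
    mismatches = []
    for pos in range(1, W + 1):  # 1 = immediately upstream of the D box
        sno_base = ase_window[W - pos]
        tgt_base = target_site[pos - 1]
        ok = pairs(sno_base, tgt_base, wobble=wobble)
        pairing.append(ok)
        if not ok:
            mismatches.append(pos)
    n_first5 = sum(1 for p in mismatches if p <= 5)
    return AnchoredDuplex(pairing=pairing, mismatch_positions=mismatches,
                          n_mm_first5=n_first5)


def predict_modified_site(anchored: AnchoredDuplex,
                          target_offset: int) -> SitePrediction:
    """Target coordinate paired with snoRNA position 5 upstream of the D box.

    ``target_offset`` is the mRNA coordinate of the 5'-most base of the
    anchored target site; position 5 pairs the site's 5th base, i.e.
    ``target_offset + 4``.  The prediction is invalid when that position is
    unpaired.
    """
    if len(anchored.pairing) < 5:
        return SitePrediction(None, False)
    valid = 5 not in anchored.mismatch_positions
    return SitePrediction(target_offset + 4, valid)


def summarize_binding(per_pair_results) -> pd.DataFrame:
    """Distribution table of best-match (length, distance) per species.

    ``per_pair_results`` is an iterable of ``(species, best_match_or_None)``.
    Returns one row per species with counts and medians; pairs without a
    qualifying match contribute to ``n_no_match`` only.
    """
    rows = {}
    for species, best in per_pair_results:
        entry = rows.setdefault(species, {"lengths": [], "dists": [],
                                          "n_no_match": 0})
        if best is None:
            entry["n_no_match"] += 1
        else:
            entry["lengths"].append(best.length)
            entry["dists"].append(best.dist_from_dbox)
    out = []
    for species, entry in rows.items():
        lengths = entry["lengths"]
        dists = entry["dists"]
        out.append(
            {
                "species": species,
                "n_pairs": len(lengths) + entry["n_no_match"],
                "n_matched": len(lengths),
                "n_no_match": entry["n_no_match"],
                "median_length": float(np.median(lengths)) if lengths else np.nan,
                "median_dist": float(np.median(dists)) if dists else np.nan,
            }
        )
    return pd.DataFrame(out)


def assert_maximal(match: DuplexMatch, sno_seq: str, dbox_start: int,
                   target: str, wobble: bool = False) -> None:
    """Sanity check: extending the match one position either way must break
    complementarity (or leave the searchable region)."""
    region = sno_seq[:dbox_start]
    (a, b) = match.sno_interval
    (ta, tb) = match.target_interval
    # extend toward the D box: sno b pairs target ta-1
    if b < len(region) and ta - 1 >= 0:
        if pairs(region[b], target[ta - 1], wobble):
            raise AssertionError("match extensible toward the D box")
    if a - 1 >= 0 and tb < len(target):
        if pairs(region[a - 1], target[tb], wobble):
            raise AssertionError("match extensible away from the D box")
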