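"""Neutrality and selection tests.

Tajima's D contrasts the mean number of pairwise differences (k-hat) with
Watterson's theta (S/a1); an excess of rare variants (recent expansion or
positive selection) drives D negative.  Significance uses the beta
approximation to the null distribution of D.  Following common practice for
multigene families, the within-genome family members stand in for the
population sample; the statistic is thereby repurposed for paralogs and the
package documents it as such.

Ka/Ks uses the Nei--Gojobori (1986) pathway method with Jukes--Cantor
correction and a one-tailed purifying-selection Z-test whose variance comes
from a codon bootstrap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from snoevo.rates import VALID_BASES

STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _build_codon_table():
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    for codon, aa in table.forward_table.items():
        _CODON_TABLE[codon] = aa
    for codon in table.stop_codons:
        _CODON_TABLE[codon] = "*"


_build_codon_table()


@dataclass
class TajimaDResult:
    n: int
    S: int
    k_hat: float
    theta_W: float
    D: float
    p_value: float
    defined: bool


@dataclass
class KaKsResult:
    Ks: float
    Ka: float
    ratio: float | None   # None mirrors the undefined "-" convention
    p_purifying: float | None
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    defined: bool


def _drop_incomplete_columns(rows):
    arr = np.array([list(r) for r in rows])
    keep = np.all(np.isin(arr, list(VALID_BASES)), axis=0)
    return arr[:, keep]


def tajimas_d(rows) -> TajimaDResult:
    """Tajima's D over an alignment of n >= 4 equal-length sequences.

    Columns containing a gap or N in any row are excluded (complete
    deletion).  Returns ``defined=False`` (not an exception) when n < 4 or
    no site segregates.
    """
    rows = list(rows)
    n = len(rows)
    if n and len({len(r) for r in rows}) != 1:
        raise ValueError("rows must share one alignment length")
    if n < 4:
        return TajimaDResult(n, 0, 0.0, 0.0, math.nan, math.nan, False)
    arr = _drop_incomplete_columns(rows)
    S = int(sum(1 for j in range(arr.shape[1]) if len(set(arr[:, j])) > 1))
    pair_diffs = []
    for i, j in itertools.combinations(range(n), 2):
        pair_diffs.append(int(np.sum(arr[i] != arr[j])))
    k_hat = float(np.mean(pair_diffs)) if pair_diffs else 0.0
    a1 = sum(1.0 / i for i in range(1, n))
    theta_w = S / a1
    if S == 0:
        return TajimaDResult(n, 0, k_hat, 0.0, math.nan, math.nan, False)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    D = (k_hat - theta_w) / math.sqrt(var)

    # beta approximation to the null distribution of D (bounded support)
    d_min = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    d_max = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(e2)
    alpha = -(1.0 + d_min * d_max) * d_max / (d_max - d_min)
    beta = (1.0 + d_min * d_max) * d_min / (d_max - d_min)
    x = (D - d_min) / (d_max - d_min)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return TajimaDResult(n, S, k_hat, theta_w, D, p, True)


# ---------------------------------------------------------------------------
# Nei-Gojobori
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[alt] == aa and alt not in STOP_CODONS:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_differences(c1: str, c2: str) -> tuple:
    """(synonymous, nonsynonymous) differences, averaged over all orderings
    of single-step mutational pathways; pathways through stops excluded
    (all-blocked codon pairs fall back to all pathways)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        sd = nd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:
        valid = []
        for order in itertools.permutations(diff_pos):
            sd = nd = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if cur in _CODON_TABLE and nxt in _CODON_TABLE and \
                        _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            valid.append((sd, nd))
    sds, nds = zip(*valid)
    return float(np.mean(sds)), float(np.mean(nds))


def jukes_cantor(p: float) -> float:
    """JC69 correction d = -3/4 ln(1 - 4p/3); undefined at p >= 3/4."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # normalize -0.0


def _split_codons(seq: str):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def nei_gojobori(seq1: str, seq2: str, n_boot: int = 500, seed: int = 0) -> KaKsResult:
    """Nei-Gojobori Ka/Ks between two aligned coding sequences.

    The ratio is None (the "-" convention) when Ks = 0.  ``p_purifying`` is
    a one-tailed Z-test of dS > dN with the variance of dS - dN estimated by
    ``n_boot`` codon-bootstrap replicates.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned CDSs must have equal length")
    if len(seq1) % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    codons1 = _split_codons(seq1)
    codons2 = _split_codons(seq2)
    # trailing stop codons are allowed and excluded from the computation
    if codons1 and codons1[-1] in STOP_CODONS and codons2[-1] in STOP_CODONS:
        codons1, codons2 = codons1[:-1], codons2[:-1]
    usable = []
    for idx, (c1, c2) in enumerate(zip(codons1, codons2)):
        if any(b not in VALID_BASES for b in c1 + c2):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {idx + 1}")
        usable.append((c1, c2))
    if not usable:
        raise ValueError("no usable codons")

    def compute(pairs):
        S = N = Sd = Nd = 0.0
        for c1, c2 in pairs:
            s1, n1 = _codon_sites(c1)
            s2, n2 = _codon_sites(c2)
            S += (s1 + s2) / 2.0
            N += (n1 + n2) / 2.0
            sd, nd = _codon_differences(c1, c2)
            Sd += sd
            Nd += nd
        ps = Sd / S if S > 0 else 0.0
        pn = Nd / N if N > 0 else 0.0
        return S, N, Sd, Nd, jukes_cantor(ps), jukes_cantor(pn)

    S, N, Sd, Nd, ds, dn = compute(usable)
    defined = not (math.isnan(ds) or math.isnan(dn))
    ratio = None
    if defined and ds > 0:
        ratio = dn / ds
    elif defined and ds == 0 and dn == 0:
        ratio = None  # 0/0, reported "-"
    elif defined and ds == 0:
        ratio = None  # Ka > 0, Ks = 0: undefined by zero division

    p_purifying = None
    if defined:
        rng = np.random.default_rng(seed)
        diffs = []
        n_codons = len(usable)
        for _ in range(n_boot):
            idx = rng.integers(0, n_codons, size=n_codons)
            rep = [usable[i] for i in idx]
            _, _, _, _, rds, rdn = compute(rep)
            if not (math.isnan(rds) or math.isnan(rdn)):
                diffs.append(rds - rdn)
        if diffs:
            se = float(np.std(diffs, ddof=0))
            if se > 0:
                z = (ds - dn) / se
                p_purifying = float(1.0 - stats.norm.cdf(z))

    return KaKsResult(
        Ks=ds,
        Ka=dn,
        ratio=ratio,
        p_purifying=p_purifying,
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        defined=defined,
    )
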