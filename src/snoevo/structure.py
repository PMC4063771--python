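"""C/D box snoRNA structural annotation.

A canonical C/D box snoRNA is laid out, 5' to 3', as::

    [5' stem][C box]...[D' box][C' box]...[ASE2][D box][3' stem]

The 4-5 nt terminal stems fold back on each other and juxtapose the C
(consensus ``RUGAUGA``) and D (consensus ``CUGA``) boxes into the kink-turn
that snoRNP core proteins recognise.  The antisense elements immediately
upstream of the D box (ASE2) and of the internal D' box (ASE1) base-pair
with the target RNA and select the 2'-O-methylation site.

This module locates those features, partitions every gene into five
structural classes (``STEM``, ``BOX``, ``ASE1``, ``ASE2``, ``REST``) used by
the partitioned substitution-rate analysis, and calls pseudogenes from
box-disrupting lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

C_CONSENSUS = "RTGATGA"  # R = A or G
D_CONSENSUS = "CTGA"

IUPAC = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "N": {"A", "C", "G", "T"},
}

# Watson-Crick plus G:T (G:U) wobble, used for the terminal stem only.
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = WC_PAIRS | {("G", "T"), ("T", "G")}

REGION_CLASSES = ("STEM", "BOX", "ASE1", "ASE2", "REST")


@dataclass
class MotifParams:
    """Knobs of the annotation scheme.

    The score is a transparent linear gate over box matches and stem length,
    ``w_C*(7-mmC) + w_D*(4-mmD) + w_stem*stem_len``, accepted at
    ``score >= threshold``.  A canonical gene with perfect boxes and a 5-bp
    stem scores 2*7 + 3*4 + 5 = 31.
    """

    c_allow: int = 1          # mismatches tolerated in the C box
    d_allow: int = 0          # mismatches tolerated in the D box
    cprime_allow: int = 2
    dprime_allow: int = 1
    c_window: int = 25        # C box searched in this many nt after the 5' stem
    d_window: int = 15        # D box searched in this many nt before the 3' stem
    ase_len: int = 18         # ASE length; an 18-nt guide duplex is the functional unit
    w_c: float = 2.0
    w_d: float = 3.0
    w_stem: float = 1.0
    threshold: float = 24.0
    min_len: int = 50         # genes shorter than this are called pseudogenes
    stem_wobble: bool = True  # allow G:U pairs in the terminal stem


@dataclass
class BoxHit:
    kind: str        # C, D, Cprime, Dprime
    start: int
    end: int
    observed: str
    mismatches: int


@dataclass
class StructureAnnotation:
    length: int
    c_box: BoxHit | None
    d_box: BoxHit | None
    c_prime: BoxHit | None = None
    d_prime: BoxHit | None = None
    stem5: tuple | None = None
    stem3: tuple | None = None
    ase1: tuple | None = None
    ase2: tuple | None = None
    remainder: list = field(default_factory=list)
    score: float = 0.0
    accepted: bool = False

    def region_map(self) -> list:
        """Per-position class labels; raises if computed intervals overlap."""
        labels = ["REST"] * self.length
        claimed = [False] * self.length

        def claim(interval, cls):
            if interval is None:
                return
            a, b = interval
            for i in range(a, b):
                if claimed[i]:
                    raise ValueError(
                        f"overlapping structural intervals at position {i}"
                    )
                claimed[i] = True
                labels[i] = cls

        claim(self.stem5, "STEM")
        claim(self.stem3, "STEM")
        for box in (self.c_box, self.d_box, self.c_prime, self.d_prime):
            if box is not None:
                claim((box.start, box.end), "BOX")
        claim(self.ase1, "ASE1")
        claim(self.ase2, "ASE2")
        return labels


@dataclass
class PseudogeneCall:
    is_pseudogene: bool
    reasons: list = field(default_factory=list)


def _mismatches(observed: str, consensus: str) -> int:
    return sum(
        1 for o, c in zip(observed, consensus) if o not in IUPAC.get(c, {c})
    )


def _scan(seq: str, consensus: str, lo: int, hi: int, allow: int):
    """All hits of ``consensus`` in ``seq[lo:hi]`` with <= allow mismatches."""
    k = len(consensus)
    hits = []
    for i in range(lo, min(hi, len(seq)) - k + 1):
        window = seq[i : i + k]
        mm = _mismatches(window, consensus)
        if mm <= allow:
            hits.append(BoxHit("", i, i + k, window, mm))
    return hits


def detect_terminal_stem(seq: str, k_range=(5, 4), wobble: bool = True):
    """Longest k in ``k_range`` such that the terminal k-mers are complementary.

    The first k and last k bases must pair (Watson-Crick, G:U allowed by
    default) when the 3' arm is read in reverse.  Returns
    ``((0, k), (L-k, L))`` or ``None``.
    """
    pairs = WOBBLE_PAIRS if wobble else WC_PAIRS
    L = len(seq)
    for k in sorted(k_range, reverse=True):
        if 2 * k > L:
            continue
        left = seq[:k]
        right = seq[L - k :]
        if all((left[i], right[k - 1 - i]) in pairs for i in range(k)):
            return (0, k), (L - k, L)
    return None


def find_boxes(seq: str, params: MotifParams | None = None) -> dict:
    """Locate C, D and (optionally) internal C'/D' boxes.

    The best C hit (fewest mismatches, ties to the 5'-most position) is
    searched within ``c_window`` nt after the 5' stem; the best D hit (ties
    to the 3'-most position, since the D box abuts the 3' stem) within
    ``d_window`` nt before the 3' stem.  Absence is a value, not an error.
    """
    if params is None:
        params = MotifParams()
    if len(seq) < 40:
        raise ValueError("sequence too short for box search (< 40 nt)")
    stem = detect_terminal_stem(seq, wobble=params.stem_wobble)
    s5_end = stem[0][1] if stem else 0
    s3_start = stem[1][0] if stem else len(seq)

    out = {"C": None, "D": None, "Cprime": None, "Dprime": None, "stem": stem}

    c_hits = _scan(seq, C_CONSENSUS, s5_end, s5_end + params.c_window,
                   params.c_allow)
    if c_hits:
        best = min(c_hits, key=lambda h: (h.mismatches, h.start))
        best.kind = "C"
        out["C"] = best

    d_lo = max(0, s3_start - params.d_window)
    d_hits = _scan(seq, D_CONSENSUS, d_lo, s3_start, params.d_allow)
    if d_hits:
        best = min(d_hits, key=lambda h: (h.mismatches, -h.start))
        best.kind = "D"
        out["D"] = best

    # internal boxes between C end and D start (layout: C .. D' .. C' .. D)
    lo = out["C"].end if out["C"] else s5_end
    hi = out["D"].start if out["D"] else s3_start
    dp_hits = _scan(seq, D_CONSENSUS, lo, hi, params.dprime_allow)
    if dp_hits:
        # prefer the expected location one ASE length downstream of the C box
        anchor = lo + params.ase_len
        best = min(dp_hits, key=lambda h: (h.mismatches, abs(h.start - anchor)))
        best.kind = "Dprime"
        out["Dprime"] = best
        cp_hits = _scan(seq, C_CONSENSUS, best.end, hi, params.cprime_allow)
        if cp_hits:
            bestc = min(cp_hits, key=lambda h: (h.mismatches, h.start))
            bestc.kind = "Cprime"
            out["Cprime"] = bestc
    return out


def annotate_structure(seq: str, params: MotifParams | None = None) -> StructureAnnotation:
    """Full structural annotation of one gene.

    ASE2 is up to ``ase_len`` nt immediately 5' of the D box; ASE1 is up to
    ``ase_len`` nt immediately 5' of the D' box when present, otherwise the
    ``ase_len`` nt following the C box.  Everything unassigned is REST.
    """
    if params is None:
        params = MotifParams()
    L = len(seq)
    boxes = find_boxes(seq, params)
    stem = boxes["stem"]
    ann = StructureAnnotation(
        length=L,
        c_box=boxes["C"],
        d_box=boxes["D"],
        c_prime=boxes["Cprime"],
        d_prime=boxes["Dprime"],
        stem5=stem[0] if stem else None,
        stem3=stem[1] if stem else None,
    )

    occupied_after_c = ann.c_box.end if ann.c_box else (stem[0][1] if stem else 0)
    if ann.d_box is not None:
        floor = occupied_after_c
        for box in (ann.d_prime, ann.c_prime):
            if box is not None:
                floor = max(floor, box.end)
        a2_start = max(ann.d_box.start - params.ase_len, floor)
        if a2_start < ann.d_box.start:
            ann.ase2 = (a2_start, ann.d_box.start)

    if ann.d_prime is not None:
        a1_start = max(ann.d_prime.start - params.ase_len, occupied_after_c)
        if a1_start < ann.d_prime.start:
            ann.ase1 = (a1_start, ann.d_prime.start)
    elif ann.c_box is not None:
        ceiling = L
        for iv in (ann.ase2, (ann.d_box.start, ann.d_box.end) if ann.d_box else None):
            if iv is not None:
                ceiling = min(ceiling, iv[0])
        if stem:
            ceiling = min(ceiling, stem[1][0])
        a1_end = min(ann.c_box.end + params.ase_len, ceiling)
        if ann.c_box.end < a1_end:
            ann.ase1 = (ann.c_box.end, a1_end)

    labels = ann.region_map()  # raises on overlap
    rem = []
    start = None
    for i, lab in enumerate(labels + ["_"]):
        if lab == "REST" and start is None:
            start = i
        elif lab != "REST" and start is not None:
            rem.append((start, i))
            start = None
    ann.remainder = rem

    mm_c = ann.c_box.mismatches if ann.c_box else None
    mm_d = ann.d_box.mismatches if ann.d_box else None
    stem_len = (stem[0][1] - stem[0][0]) if stem else 0
    score = 0.0
    if mm_c is not None:
        score += params.w_c * (len(C_CONSENSUS) - mm_c)
    if mm_d is not None:
        score += params.w_d * (len(D_CONSENSUS) - mm_d)
    score += params.w_stem * stem_len
    ann.score = score
    ann.accepted = (
        ann.c_box is not None and ann.d_box is not None and score >= params.threshold
    )
    return ann


def partition_alignment(alignment, reference_id: str,
                        reference_annotation: StructureAnnotation) -> list:
    """Label every alignment column with the reference row's structural class.

    ``alignment`` is a list of ``(id, row)`` pairs.  Columns where the
    reference row has a gap are labeled REST.
    """
    rows = dict(alignment)
    if reference_id not in rows:
        raise KeyError(f"reference id {reference_id!r} not in alignment")
    ref_row = rows[reference_id]
    pos_labels = reference_annotation.region_map()
    labels = []
    ref_pos = 0
    for col_char in ref_row:
        if col_char == "-":
            labels.append("REST")
        else:
            if ref_pos >= len(pos_labels):
                raise ValueError(
                    "reference row longer than its structural annotation"
                )
            labels.append(pos_labels[ref_pos])
            ref_pos += 1
    if ref_pos != reference_annotation.length:
        raise ValueError("reference row shorter than its structural annotation")
    return labels


def call_pseudogene(annotation: StructureAnnotation,
                    params: MotifParams | None = None) -> PseudogeneCall:
    """Call a gene a pseudogene from box/stem-disrupting lesions.

    A gene is a pseudogene iff the C box is absent or carries more than
    ``c_allow`` mismatches, the D box is absent or carries more than
    ``d_allow`` mismatches, the terminal stem is absent, or the gene is
    shorter than ``min_len``.
    """
    if params is None:
        params = MotifParams()
    reasons = []
    if annotation.c_box is None or annotation.c_box.mismatches > params.c_allow:
        reasons.append("C_box_disrupted")
    if annotation.d_box is None or annotation.d_box.mismatches > params.d_allow:
        reasons.append("D_box_disrupted")
    if annotation.stem5 is None or annotation.stem3 is None:
        reasons.append("no_stem")
    if annotation.length < params.min_len:
        reasons.append("truncated")
    return PseudogeneCall(is_pseudogene=bool(reasons), reasons=reasons)


def pseudogene_ratio(entries):
    """Per-(species, family) pseudogene ratios.

    ``entries`` is an iterable of ``(species, family, is_pseudogene)``
    triples (or objects with those attributes).  Returns a pandas DataFrame
    with columns species, family, n_pseudo, n_total, ratio.
    """
    import pandas as pd

    rows = []
    for e in entries:
        if isinstance(e, tuple):
            species, family, is_pseudo = e
        else:
            species, family, is_pseudo = e.species, e.family, e.is_pseudogene
        rows.append({"species": species, "family": family,
                     "pseudo": bool(is_pseudo)})
    if not rows:
        raise ValueError("no entries")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["species", "family"], as_index=False)
        .agg(n_pseudo=("pseudo", "sum"), n_total=("pseudo", "size"))
    )
    out["ratio"] = out["n_pseudo"] / out["n_total"]
    return out


def group_average_ratio(ratio_table, species_groups: dict):
    """Unweighted mean pseudogene ratio per species group.

    ``species_groups`` maps species name to a group label (e.g. primates /
    rodents / other).  Each species first gets its own mean ratio over
    families, and groups average those species means.
    """
    df = ratio_table.copy()
    df["group"] = df["species"].map(species_groups)
    per_species = df.groupby(["group", "species"])["ratio"].mean().reset_index()
    return per_species.groupby("group")["ratio"].mean().to_dict()
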