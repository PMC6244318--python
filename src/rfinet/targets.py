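"""miRNA target prediction: seed-site scanning and complementarity alignment.

Two lines of evidence are combined, mirroring the classic TargetScan/miRanda
pairing:

* **Seed sites** — exact matches on the 3'UTR (read 5'->3') to the reverse
  complement of the miRNA seed.  Site classes follow the canonical hierarchy:
  ``6mer`` (miRNA positions 2-7), ``7mer-m8`` (positions 2-8), ``7mer-A1``
  (6mer followed by an A opposite position 1) and ``8mer`` (7mer-m8 followed
  by an A).  Every locus is reported once at its most specific class.
* **Alignment hits** — Smith-Waterman-style local complementarity alignment
  of the miRNA (3'->5') against the UTR (5'->3') with G:U wobble pairing,
  affine gaps, and double weight on the seed region (positions 2-8).

A gene is a predicted target of a miRNA (``mode="intersection"``, the
default) when it carries at least one seed site, at least one alignment hit
at or above the score threshold, and is in the expressed-gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def normalize_nt(seq: str) -> str:
    """Uppercase and map RNA U to T; other characters pass through."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    seq = normalize_nt(seq)
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq))


def extract_seed(mirna_sequence: str) -> str:
    """Seed heptamer: miRNA positions 2-8 (1-based, inclusive), U mapped to T."""
    seq = normalize_nt(mirna_sequence)
    if len(seq) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt for seed extraction")
    return seq[1:8]


@dataclass(frozen=True)
class SeedSite:
    """A seed match on a UTR; [start, end) is 0-based on the UTR 5'->3'."""

    start: int
    end: int
    site_type: str  # one of: 8mer, 7mer-m8, 7mer-A1, 6mer


@dataclass(frozen=True)
class AlignmentHit:
    """A local complementarity alignment between a miRNA and a UTR window."""

    score: float
    utr_start: int
    utr_end: int
    mirna_aligned: str
    utr_aligned: str


@dataclass
class AlignmentParams:
    """Scoring scheme for the complementarity alignment (all configurable)."""

    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_weight: float = 2.0  # multiplier on pair scores at miRNA positions 2-8
    score_threshold: float = 80.0


def scan_seed_sites(mirna_sequence: str, utr_sequence: str) -> list[SeedSite]:
    """All seed sites of a miRNA on a UTR, labelled at the most specific class.

    The scan anchors on occurrences of the 6mer core (reverse complement of
    miRNA positions 2-7); presence of the position-8 complement immediately
    5' of the core upgrades to 7mer-m8, an A immediately 3' upgrades to
    7mer-A1, and both together give an 8mer.  Overlapping cores are all
    reported.  Positions with non-ACGTU characters never match and a warning
    is emitted once per UTR if any are present.
    """
    mir = normalize_nt(mirna_sequence)
    if len(mir) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt")
    utr = normalize_nt(utr_sequence)
    if len(utr) < 6:
        raise ValueError("UTR must be at least 6 nt")
    if any(c not in "ACGT" for c in utr):
        warnings.warn("scan_seed_sites: non-ACGTU characters in UTR never match")
    core6 = reverse_complement(mir[1:7])  # revcomp of positions 2-7
    m8_comp = _COMPLEMENT.get(mir[7], "N")  # base pairing miRNA position 8
    sites = []
    start = utr.find(core6)
    while start != -1:
        has_m8 = start >= 1 and utr[start - 1] == m8_comp
        has_a1 = start + 6 < len(utr) and utr[start + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(start - 1, start + 7, "8mer"))
        elif has_m8:
            sites.append(SeedSite(start - 1, start + 6, "7mer-m8"))
        elif has_a1:
            sites.append(SeedSite(start, start + 7, "7mer-A1"))
        else:
            sites.append(SeedSite(start, start + 6, "6mer"))
        start = utr.find(core6, start + 1)
    return sites


# -- complementarity alignment ------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq], dtype=np.int8)


@njit(cache=True)
def _gotoh_matrices(q, d, weights, match, wobble, mismatch, gap_open, gap_extend):
    """Local alignment DP (Gotoh affine gaps) of query q against database d.

    q is the miRNA read 3'->5'; weights holds the per-row seed multiplier.
    Returns H, E, F score matrices with a leading zero row/column.
    """
    n, m = q.shape[0], d.shape[0]
    neg = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap consuming UTR
    F = np.full((n + 1, m + 1), neg)  # gap consuming miRNA
    for i in range(1, n + 1):
        qi = q[i - 1]
        w = weights[i - 1]
        for j in range(1, m + 1):
            dj = d[j - 1]
            if qi < 0 or dj < 0:
                s = mismatch
            elif qi + dj == 3:
                # Watson-Crick complement: A-T (0+3) or C-G (1+2)
                s = match
            elif (qi == 2 and dj == 3) or (qi == 3 and dj == 2):
                s = wobble  # G:U pair in the RNA duplex
            else:
                s = mismatch
            s = s * w
            e = H[i, j - 1] + gap_open
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


def _pair_score(qc: int, dc: int, w: float, p: AlignmentParams) -> float:
    if qc < 0 or dc < 0:
        s = p.mismatch
    elif qc + dc == 3:
        s = p.match
    elif {qc, dc} == {2, 3}:
        s = p.wobble
    else:
        s = p.mismatch
    return s * w


def _traceback(H, E, F, q, d, weights, params, i, j):
    """Recover one local alignment ending at cell (i, j)."""
    qa, da = [], []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            s = _pair_score(q[i - 1], d[j - 1], weights[i - 1], params)
            if np.isclose(H[i, j], H[i - 1, j - 1] + s):
                qa.append(i - 1)
                da.append(j - 1)
                i -= 1
                j -= 1
            elif np.isclose(H[i, j], E[i, j]):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            qa.append(-1)
            da.append(j - 1)
            if np.isclose(E[i, j], E[i, j - 1] + params.gap_extend):
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            qa.append(i - 1)
            da.append(-1)
            if np.isclose(F[i, j], F[i - 1, j] + params.gap_extend):
                i -= 1
            else:
                i -= 1
                state = "H"
    return qa[::-1], da[::-1], j


def align_mirna_utr(
    mirna_sequence: str,
    utr_sequence: str,
    params: AlignmentParams | None = None,
) -> list[AlignmentHit]:
    """Local complementarity alignments of a miRNA against a UTR.

    The miRNA is aligned 3'->5' against the UTR 5'->3' (antiparallel duplex
    geometry); pair scores reward Watson-Crick complementarity and G:U
    wobbles, with the seed region (miRNA positions 2-8) weighted by
    ``seed_weight``.  All non-overlapping local optima scoring at or above
    ``score_threshold`` are returned, best first.
    """
    if params is None:
        params = AlignmentParams()
    mir = normalize_nt(mirna_sequence)
    utr = normalize_nt(utr_sequence)
    if not mir or not utr:
        return []
    q_seq = mir[::-1]  # 3'->5'
    q = _encode(q_seq)
    d = _encode(utr)
    L = len(mir)
    # reversed row r (0-based) holds original 1-based position L - r
    weights = np.array(
        [params.seed_weight if 2 <= L - r <= 8 else 1.0 for r in range(L)]
    )
    H, E, F = _gotoh_matrices(
        q, d, weights, params.match, params.wobble, params.mismatch,
        params.gap_open, params.gap_extend,
    )
    candidates = np.argwhere(H >= params.score_threshold)
    if candidates.size == 0:
        return []
    scores = H[candidates[:, 0], candidates[:, 1]]
    order = np.lexsort((candidates[:, 1], candidates[:, 0], -scores))
    hits: list[AlignmentHit] = []
    taken: list[tuple[int, int]] = []
    for idx in order:
        i, j = int(candidates[idx, 0]), int(candidates[idx, 1])
        qa, da, j0 = _traceback(H, E, F, q, d, weights, params, i, j)
        if not da:
            continue
        utr_start, utr_end = j0, j
        if any(not (utr_end <= a or utr_start >= b) for (a, b) in taken):
            continue
        mir_aln = "".join(q_seq[k] if k >= 0 else "-" for k in qa)
        utr_aln = "".join(utr[k] if k >= 0 else "-" for k in da)
        hits.append(
            AlignmentHit(float(H[i, j]), utr_start, utr_end, mir_aln, utr_aln)
        )
        taken.append((utr_start, utr_end))
    hits.sort(key=lambda h: (-h.score, h.utr_start))
    return hits


# -- combining evidence -------------------------------------------------------

@dataclass
class TargetSet:
    """miRNA -> predicted target genes with the supporting evidence."""

    targets: dict = field(default_factory=dict)  # mirna_id -> sorted list of gene ids
    evidence: pd.DataFrame | None = None

    def genes(self, mirna_id: str) -> list[str]:
        return list(self.targets.get(mirna_id, []))

    def pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, genes in self.targets.items() for g in genes}


def predict_targets(
    seed_sites: dict,
    alignment_hits: dict,
    expressed_genes,
    mode: str = "intersection",
) -> TargetSet:
    """Combine seed and alignment evidence into a per-miRNA target list.

    ``seed_sites`` and ``alignment_hits`` map ``(mirna_id, gene_id)`` to
    nonempty lists of :class:`SeedSite` / :class:`AlignmentHit`.  With
    ``mode="intersection"`` (default) a gene needs both kinds of evidence;
    ``"union"`` accepts either.  Either way the gene must be in
    ``expressed_genes``.
    """
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    expressed = set(expressed_genes)
    seed_pairs = {k for k, v in seed_sites.items() if v}
    align_pairs = {k for k, v in alignment_hits.items() if v}
    kept = seed_pairs & align_pairs if mode == "intersection" else seed_pairs | align_pairs
    kept = {(m, g) for (m, g) in kept if g in expressed}

    targets: dict[str, list[str]] = {}
    rows = []
    for m, g in sorted(kept):
        targets.setdefault(m, []).append(g)
        ss = seed_sites.get((m, g), [])
        ah = alignment_hits.get((m, g), [])
        rows.append(
            {
                "mirna_id": m,
                "gene_id": g,
                "n_seed_sites": len(ss),
                "best_site_type": _best_site_type(ss),
                "best_alignment_score": max((h.score for h in ah), default=np.nan),
            }
        )
    evidence = pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "gene_id", "n_seed_sites", "best_site_type",
            "best_alignment_score",
        ],
    )
    return TargetSet(targets=targets, evidence=evidence)


_SITE_RANK = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}


def _best_site_type(sites) -> str:
    if not sites:
        return ""
    return min((s.site_type for s in sites), key=_SITE_RANK.__getitem__)


def predict_targets_from_sequences(
    mirna_seqs: dict,
    utr_seqs: dict,
    expressed_genes,
    mode: str = "intersection",
    params: AlignmentParams | None = None,
) -> TargetSet:
    """Scan + align every miRNA against every expressed gene's UTR.

    In intersection mode the (expensive) alignment is only run for pairs that
    already carry a seed site, which cannot change the result; union mode
    aligns every pair.
    """
    if params is None:
        params = AlignmentParams()
    expressed = [g for g in utr_seqs if g in set(expressed_genes)]
    seed_sites = {}
    for mid, mseq in mirna_seqs.items():
        for gid in expressed:
            sites = scan_seed_sites(mseq, utr_seqs[gid])
            if sites:
                seed_sites[(mid, gid)] = sites
    align_hits = {}
    pairs = (
        seed_sites.keys()
        if mode == "intersection"
        else [(m, g) for m in mirna_seqs for g in expressed]
    )
    for mid, gid in pairs:
        hits = align_mirna_utr(mirna_seqs[mid], utr_seqs[gid], params)
        if hits:
            align_hits[(mid, gid)] = hits
    return predict_targets(seed_sites, align_hits, expressed, mode=mode)
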