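"""Contact-map alignment, register-shift calls and false-positive filters.

The contact maximum overlap (CMO) between two contact maps is the largest
total weight of contacts matchable under a monotone (order-preserving,
gapped) residue alignment.  Exact CMO is NP-hard, so the aligner here is
a double dynamic-programming heuristic in the spirit of map_align: an
inner similarity matrix scores aligning residue i of one map to residue
k of the other from the overlap of their contact neighbourhoods, an
outer affine-gap DP produces a monotone alignment, and the two are
iterated.  Several diagonal-seeded starts make constant sequence-register
shifts easy to discover.  ``brute_force_cmo`` provides the exhaustive
optimum for small maps and serves as the test oracle.

Stretches where the alignment uses a register different from the model's
own become register-shift calls, which are then screened by three
false-positive filters: predicted-contact density, mean pLDDT, and a
superposition Q-score against the predicted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .structures import ContactMap, StructureChain

__all__ = [
    "CMOAlignment",
    "RegisterShiftCall",
    "SuperpositionResult",
    "align_contact_maps",
    "brute_force_cmo",
    "extract_register_shifts",
    "contact_density_filter",
    "plddt_filter",
    "kabsch_superpose",
    "q_score",
    "qscore_filter",
]

_NEG = -1e18


@dataclass
class CMOAlignment:
    """A monotone mapping between two contact maps.

    ``mapping`` lists (index_a, index_b) pairs, 1-based, strictly
    increasing in both coordinates.  ``score`` is the matched contact
    weight minus affine gap penalties for interior gaps.
    """

    mapping: List[Tuple[int, int]]
    matched_contacts: int
    matched_weight: float
    score: float

    @property
    def offsets(self) -> List[Tuple[int, int]]:
        """(index_a, register offset) per aligned pair."""
        return [(i, j - i) for i, j in self.mapping]


@dataclass
class RegisterShiftCall:
    """A stretch of residues whose contacts are best explained by a
    shifted sequence register."""

    start: int
    end: int
    shift: int
    filter_verdicts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shift == 0:
            raise ValueError("a register-shift call needs a nonzero shift")
        if self.end < self.start:
            raise ValueError("end before start")

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1

    @property
    def proposed_register(self) -> str:
        sign = "+" if self.shift > 0 else ""
        return (f"assign model residues {self.start}-{self.end} to reference "
                f"positions {self.start + self.shift}-{self.end + self.shift} "
                f"(shift {sign}{self.shift})")

    @property
    def passes_filters(self) -> bool:
        return all(v in ("pass", "skipped", "not_run")
                   for v in self.filter_verdicts.values())


@dataclass
class SuperpositionResult:
    """Least-squares rigid superposition of matched coordinates."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_align: int
    q_score: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# affine-gap DP (Gotoh) with free end gaps and an optional diagonal band


def _gotoh(S: np.ndarray, gap_open: float, gap_extend: float,
           band: Optional[Tuple[int, int]] = None) -> List[Tuple[int, int]]:
    """Semi-global monotone alignment maximizing sum of S over matched
    cells plus affine penalties for interior gaps; end gaps are free.

    ``band`` restricts 0-based offsets j - i to [dlo, dhi].  Returns the
    matched (i, j) pairs, 0-based.
    """
    La, Lb = S.shape
    M = np.full((La + 1, Lb + 1), _NEG)
    Ix = np.full((La + 1, Lb + 1), _NEG)
    Iy = np.full((La + 1, Lb + 1), _NEG)
    H = np.full((La + 1, Lb + 1), _NEG)
    H[0, :] = 0.0
    H[:, 0] = 0.0

    def cols(i: int) -> range:
        if band is None:
            return range(1, Lb + 1)
        dlo, dhi = band
        return range(max(1, i + dlo), min(Lb, i + dhi) + 1)

    for i in range(1, La + 1):
        for j in cols(i):
            m = S[i - 1, j - 1] + H[i - 1, j - 1]
            M[i, j] = m
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            H[i, j] = max(M[i, j], Ix[i, j], Iy[i, j])

    # best end on the last row or column (trailing gaps free)
    best, bi, bj = _NEG, La, 0
    for j in cols(La):
        if H[La, j] > best:
            best, bi, bj = H[La, j], La, j
    for i in range(1, La + 1):
        j = Lb
        if band is not None and not (band[0] <= j - i <= band[1]):
            continue
        if H[i, j] > best:
            best, bi, bj = H[i, j], i, j
    if best <= _NEG / 2:
        return []

    pairs: List[Tuple[int, int]] = []
    i, j = bi, bj
    state = "M" if H[i, j] == M[i, j] else ("Ix" if H[i, j] == Ix[i, j] else "Iy")
    while i > 0 and j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            prev = H[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 or j == 0:
                break
            if prev == M[i, j]:
                state = "M"
            elif prev == Ix[i, j]:
                state = "Ix"
            elif prev == Iy[i, j]:
                state = "Iy"
            else:  # started here via the free border
                break
        elif state == "Ix":
            state = "M" if Ix[i, j] == M[i - 1, j] + gap_open else "Ix"
            i -= 1
        else:
            state = "M" if Iy[i, j] == M[i, j - 1] + gap_open else "Iy"
            j -= 1
    pairs.reverse()
    return pairs


# ---------------------------------------------------------------------------
# similarity matrices

_SEP_BINS = np.array([-1e9, -40, -25, -17, -11, -7, -4, 4, 7, 11, 17, 25, 40, 1e9])


def _profile_similarity(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Initial residue-pair similarity from binned contact-separation
    profiles: residues whose partners sit at similar sequence offsets
    look alike even before any alignment exists."""
    def hist(m):
        L = m.shape[0]
        h = np.zeros((L, len(_SEP_BINS) - 1))
        ii, jj = np.nonzero(m)
        d = jj - ii
        b = np.searchsorted(_SEP_BINS, d, side="left") - 1
        np.add.at(h, (ii, b), m[ii, jj])
        return h

    ha, hb = hist(A), hist(B)
    S = np.zeros((A.shape[0], B.shape[0]))
    for b in range(ha.shape[1]):
        S += np.minimum.outer(ha[:, b], hb[:, b])
    return S


def _refine_similarity(A: np.ndarray, B: np.ndarray,
                       pairs: Sequence[Tuple[int, int]]) -> np.ndarray:
    """Similarity of aligning i to k = total weight of contacts (i, j)
    matched with (k, aligned(j)) under the current alignment."""
    pi = np.array([p for p, _ in pairs], dtype=int)
    pj = np.array([q for _, q in pairs], dtype=int)
    return A[:, pi] @ B[pj, :]


def _matched_weight(cm_a: ContactMap, cm_b: ContactMap,
                    mapping: Sequence[Tuple[int, int]]) -> Tuple[float, int]:
    m = dict(mapping)
    total, count = 0.0, 0
    for (p, q), w in cm_a.pairs.items():
        if p in m and q in m:
            wb = cm_b.weight(m[p], m[q])
            if wb > 0:
                total += min(w, wb, 1.0)
                count += 1
    return total, count


def _gap_penalty(mapping: Sequence[Tuple[int, int]],
                 gap_open: float, gap_extend: float) -> float:
    pen = 0.0
    for (i1, j1), (i2, j2) in zip(mapping, mapping[1:]):
        for d in (i2 - i1 - 1, j2 - j1 - 1):
            if d > 0:
                pen += gap_open + (d - 1) * gap_extend
    return pen


def align_contact_maps(cm_a: ContactMap, cm_b: ContactMap,
                       gap_open: float = -3.0, gap_extend: float = -0.1,
                       n_iter: int = 3, max_shift: int = 10,
                       band_pad: int = 4) -> CMOAlignment:
    """Heuristic contact-maximum-overlap alignment of two contact maps.

    Several starting points are tried — a contact-profile similarity with
    a full DP, and diagonal-seeded banded DPs for every register offset
    up to ``max_shift`` — each refined for ``n_iter`` rounds of
    similarity-recompute + realign.  Candidates are ranked by matched
    contact weight (the CMO objective), ties by the gap-penalised score.
    On maps of up to ~20 residues the DP passes run with vanishing gap
    penalties so the heuristic chases the pure CMO.
    """
    La, Lb = cm_a.L, cm_b.L
    if len(cm_a) == 0 or len(cm_b) == 0:
        return CMOAlignment([], 0, 0.0, 0.0)
    A = np.minimum(cm_a.to_matrix(), 1.0)
    B = np.minimum(cm_b.to_matrix(), 1.0)
    S0 = _profile_similarity(A, B)
    small = max(La, Lb) <= 20
    go, ge = (-1e-3, -1e-4) if small else (gap_open, gap_extend)

    shifts = range(-min(max_shift, Lb - 1), min(max_shift, Lb - 1) + 1)
    # (band, initial similarity, pinned anchor) starting points
    candidates: list = [(None, S0, None)]
    candidates += [((min(0, k) - band_pad, max(0, k) + band_pad), S0, None)
                   for k in shifts]
    if small:
        # anchor-seeded starts: pin each residue pairing and let the
        # refinement rounds grow an alignment around it
        deg_a = A.sum(axis=1)
        deg_b = B.sum(axis=1)
        for i0 in np.where(deg_a > 0)[0]:
            for j0 in np.where(deg_b > 0)[0]:
                candidates.append((None, S0, [(int(i0), int(j0))]))
        # contact-pair anchors: directly attempt matching one contact of A
        # to one contact of B by pinning both endpoint pairings
        for (p, q) in cm_a.pairs:
            for (r, s) in cm_b.pairs:
                candidates.append((None, S0,
                                   [(p - 1, r - 1), (q - 1, s - 1)]))
    bonus = S0.sum() + A.sum() + 1.0  # large enough that the DP keeps the anchor

    best = CMOAlignment([], 0, 0.0, 0.0)
    best_key = (-1.0, -np.inf)

    def consider(mapping0: List[Tuple[int, int]]) -> None:
        nonlocal best, best_key
        if not mapping0:
            return
        mapping1 = [(i + 1, j + 1) for i, j in mapping0]
        mw, mc = _matched_weight(cm_a, cm_b, mapping1)
        score = mw + _gap_penalty(mapping1, gap_open, gap_extend)
        key = (round(mw, 9), round(score, 9))
        if key > best_key:
            best_key = key
            best = CMOAlignment(mapping1, mc, mw, score)

    rounds = max(n_iter, 5) if small else max(1, n_iter)
    for band, S, anchors in candidates:
        if anchors:
            S = S.copy()
            for cell in anchors:
                S[cell] += bonus
        mapping: List[Tuple[int, int]] = []
        for it in range(rounds):
            mapping = _gotoh(S, go, ge, band)
            if not mapping:
                break
            if small:
                consider(mapping)  # keep the best round, not just the last
            if it < rounds - 1:
                S = _refine_similarity(A, B, mapping) + 1e-6 * S0
                for cell in (anchors or ()):
                    S[cell] += bonus
        if not small:
            consider(mapping)
    return best


def brute_force_cmo(cm_a: ContactMap, cm_b: ContactMap) -> CMOAlignment:
    """Exact contact maximum overlap by exhaustive enumeration of monotone
    mappings.  Test oracle only: both maps must have at most 12 residues.

    Only contact-bearing residues are enumerated; aligning a residue with
    no contacts can never change the matched weight.
    """
    if cm_a.L > 12 or cm_b.L > 12:
        raise ValueError("brute_force_cmo is limited to maps of <= 12 residues")
    deg_a = cm_a.degrees()
    deg_b = cm_b.degrees()
    ra = [i + 1 for i in range(cm_a.L) if deg_a[i] > 0]
    rb = [j + 1 for j in range(cm_b.L) if deg_b[j] > 0]
    best_w, best_c, best_map = 0.0, 0, []
    kmax = min(len(ra), len(rb))
    for k in range(kmax, 0, -1):
        for sub_a in combinations(ra, k):
            for sub_b in combinations(rb, k):
                mapping = list(zip(sub_a, sub_b))
                w, c = _matched_weight(cm_a, cm_b, mapping)
                if w > best_w + 1e-12:
                    best_w, best_c, best_map = w, c, mapping
    return CMOAlignment(best_map, best_c, best_w, best_w)


# ---------------------------------------------------------------------------
# register-shift extraction


def extract_register_shifts(aln: CMOAlignment, min_len: int = 5,
                            merge_gap: int = 5) -> List[RegisterShiftCall]:
    """Turn constant nonzero register offsets in an alignment into calls.

    Maximal runs of consecutively aligned residues with the same nonzero
    offset and at least ``min_len`` residues become calls; calls with the
    same shift separated by at most ``merge_gap`` residues are merged.
    """
    runs: List[Tuple[int, int, int]] = []  # (start, end, offset)
    for i, j in aln.mapping:
        off = j - i
        if runs and runs[-1][2] == off and i == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], i, off)
        else:
            runs.append((i, i, off))
    calls = [RegisterShiftCall(s, e, o) for s, e, o in runs
             if o != 0 and e - s + 1 >= min_len]
    merged: List[RegisterShiftCall] = []
    for call in calls:
        if (merged and merged[-1].shift == call.shift
                and call.start - merged[-1].end - 1 <= merge_gap):
            merged[-1] = RegisterShiftCall(merged[-1].start, call.end, call.shift)
        else:
            merged.append(call)
    return merged


# ---------------------------------------------------------------------------
# false-positive filters


def contact_density_filter(call: RegisterShiftCall, pred_cm) -> str:
    """Fail a call when predicted contacts are too sparse to trust the
    alignment: mean or median predicted contacts per residue < 2 over the
    affected range."""
    counts = pred_cm.degrees()[call.start - 1: call.end]
    if len(counts) == 0:
        raise ValueError("empty residue range")
    if counts.mean() < 2.0 or np.median(counts) < 2.0:
        return "fail"
    return "pass"


def plddt_filter(call: RegisterShiftCall,
                 predicted_chain: Optional[StructureChain]) -> str:
    """Fail a call whose range has mean predictor confidence (pLDDT)
    below 65; skipped when no pLDDT is available."""
    if predicted_chain is None:
        warnings.warn("no predicted model: pLDDT filter skipped")
        return "skipped"
    plddt = predicted_chain.plddt_array()
    if plddt is None:
        warnings.warn("predicted model carries no pLDDT; filter skipped")
        return "skipped"
    vals = plddt[call.start - 1: call.end]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return "skipped"
    return "fail" if vals.mean() < 65.0 else "pass"


def kabsch_superpose(coords_a, coords_b) -> SuperpositionResult:
    """Least-squares rigid superposition of matched coordinate lists
    (proper rotation enforced), mapping A onto B."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate lists must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 matched pairs")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, s, Vt = np.linalg.svd(H)
    if s[1] <= 1e-9 * max(s[0], 1e-12):
        raise ValueError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_align=n,
                               q_score=q_score(n, rmsd, n, n))


def q_score(n_align: int, rmsd: float, n1: int, n2: int, r0: float = 3.0) -> float:
    """Superposition quality in [0, 1]:
    Q = N_align^2 / ((1 + (rmsd/R0)^2) * N1 * N2), with R0 = 3 Å."""
    if n1 == 0 or n2 == 0:
        return 0.0
    return n_align ** 2 / ((1.0 + (rmsd / r0) ** 2) * n1 * n2)


def qscore_filter(call: RegisterShiftCall, model_chain: StructureChain,
                  predicted_chain: Optional[StructureChain],
                  r0: float = 3.0, threshold: float = 0.5) -> str:
    """Fail a call when the predicted model does not structurally support
    the proposed register.

    The chains are superposed on sequence-identity pairs outside the call
    range (the presumably correct bulk of the model).  Within the range,
    model residue i is paired with predicted residue i + shift — the
    register the call proposes — and the Q-score over those pairs is
    computed with N1/N2 the modelled range lengths in each chain.  Fails
    when Q < 0.5; skipped when no predicted model is given.
    """
    if predicted_chain is None:
        warnings.warn("no predicted model: Q-score filter skipped")
        return "skipped"
    mc = model_chain.coords()
    pc = predicted_chain.coords()
    common = min(model_chain.L, predicted_chain.L)
    in_range = np.zeros(common, dtype=bool)
    in_range[max(0, call.start - 1): call.end] = True
    both = ~np.isnan(mc[:common, 0]) & ~np.isnan(pc[:common, 0])
    anchors = np.where(both & ~in_range)[0]

    pair_i, pair_j = [], []
    for i in range(call.start, call.end + 1):
        j = i + call.shift
        if (1 <= i <= model_chain.L and 1 <= j <= predicted_chain.L
                and not np.isnan(mc[i - 1, 0]) and not np.isnan(pc[j - 1, 0])):
            pair_i.append(i - 1)
            pair_j.append(j - 1)
    n1 = int((~np.isnan(mc[call.start - 1: call.end, 0])).sum())
    lo, hi = max(1, call.start + call.shift), min(predicted_chain.L, call.end + call.shift)
    n2 = int((~np.isnan(pc[lo - 1: hi, 0])).sum()) if hi >= lo else 0
    if not pair_i or n1 == 0 or n2 == 0:
        return "skipped"
    if len(anchors) >= 3:
        sup = kabsch_superpose(mc[anchors], pc[anchors])
    elif len(pair_i) >= 3:
        sup = kabsch_superpose(mc[pair_i], pc[pair_j])
    else:
        return "skipped"
    diff = sup.transform(mc[pair_i]) - pc[pair_j]
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    q = q_score(len(pair_i), rmsd, n1, n2, r0=r0)
    return "fail" if q < threshold - 1e-9 else "pass"
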