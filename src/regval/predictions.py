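"""Predicted inter-residue distance distributions (distograms).

A distogram holds, for every residue pair, a probability distribution over
binned distances, as produced by deep-learning structure predictors.  This
module loads distograms from a small portable JSON/TSV dialect, converts
them to point distance predictions with confidences, derives contact
probabilities (total mass below a cutoff), and selects the top-L/2
predicted contacts used by the validation metrics.  A CASP-RR reader is
provided for contact-only input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .structures import ContactMap

__all__ = [
    "Distogram",
    "DistancePrediction",
    "PredictedContactMap",
    "default_bin_edges",
    "load_distogram",
    "distogram_to_distance",
    "distogram_to_contact_probabilities",
    "select_top_contacts",
    "contact_map_from_probabilities",
    "read_casp_rr",
]


def default_bin_edges() -> np.ndarray:
    """Default distance binning: 2-22 Å in 0.5 Å steps plus an open last bin.

    B bins are described by B+1 edges; the final bin is open-ended from its
    lower edge (the last listed edge is nominal).
    """
    return np.concatenate([np.arange(2.0, 22.0 + 1e-9, 0.5), [22.5]])


class Distogram:
    """Per-pair probability distributions over distance bins.

    ``bin_edges`` has B+1 entries for B bins; bin b spans
    [edges[b], edges[b+1]) except the last, which is open-ended from
    edges[B-1].  ``probs`` is an (L, L, B) array, symmetric in the first
    two axes, with each row summing to 1.
    """

    def __init__(self, bin_edges, probs, sequence: Optional[str] = None,
                 normalize: bool = False):
        self.bin_edges = np.asarray(bin_edges, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 3 or probs.shape[0] != probs.shape[1]:
            raise ValueError("probs must be an L x L x B array")
        if probs.shape[2] != len(self.bin_edges) - 1:
            raise ValueError("probs bin dimension does not match bin_edges")
        sums = probs.sum(axis=2)
        off = np.abs(sums - 1.0)
        if normalize:
            if np.any(off > 1e-3):
                bad = np.unravel_index(np.argmax(off), off.shape)
                raise ValueError(
                    f"pair {tuple(int(x)+1 for x in bad)} has probability sum "
                    f"{sums[bad]:.4f}, not normalizable")
            probs = probs / sums[..., None]
        elif np.any(off > 1e-6):
            raise ValueError("per-pair probabilities do not sum to 1")
        probs = 0.5 * (probs + probs.transpose(1, 0, 2))
        self.probs = probs
        self.sequence = sequence
        if sequence is not None and len(sequence) != probs.shape[0]:
            raise ValueError("sequence length does not match distogram size")

    @property
    def L(self) -> int:
        return self.probs.shape[0]

    @property
    def n_bins(self) -> int:
        return self.probs.shape[2]

    def bin_midpoints(self) -> np.ndarray:
        """Midpoints per bin; the open-ended last bin uses its lower edge
        plus half the previous bin's width."""
        e = self.bin_edges
        mids = 0.5 * (e[:-1] + e[1:])
        mids[-1] = e[-2] + 0.5 * (e[-2] - e[-3])
        return mids


@dataclass
class DistancePrediction:
    """Point distance prediction per pair: the argmax-bin midpoint and the
    probability mass of that bin as confidence.

    ``in_range`` is False where the argmax is the open-ended last bin,
    i.e. where the predictor only asserts "far apart" with no usable
    midpoint.
    """

    pred_dist: np.ndarray
    confidence: np.ndarray
    in_range: np.ndarray

    @property
    def L(self) -> int:
        return self.pred_dist.shape[0]


class PredictedContactMap(ContactMap):
    """Contact map whose weights are contact probabilities, carrying
    per-residue predicted-contact counts for the density filter."""

    @property
    def counts(self) -> np.ndarray:
        return self.degrees()


# ---------------------------------------------------------------------------
# file I/O


def load_distogram(path) -> Distogram:
    """Load a distogram from the JSON or TSV dialect.

    JSON: ``{"sequence": str, "bin_edges": [...], "probs": [...]}`` with
    probs flattened row-major (L*L*B values).  TSV: a header line
    ``#bin_edges: e0,e1,...`` followed by rows ``i<TAB>j<TAB>p1..pB``
    (1-based i, j; missing (j, i) rows are filled by symmetry).
    Rows are renormalized when their sum is within 1e-3 of 1.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        data = json.loads(text)
        seq = data["sequence"]
        edges = np.asarray(data["bin_edges"], dtype=float)
        L = len(seq)
        B = len(edges) - 1
        flat = np.asarray(data["probs"], dtype=float)
        if flat.size != L * L * B:
            raise ValueError(f"probs has {flat.size} values, expected {L * L * B}")
        return Distogram(edges, flat.reshape(L, L, B), sequence=seq, normalize=True)
    return _load_distogram_tsv(text)


def _load_distogram_tsv(text: str) -> Distogram:
    edges = None
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#bin_edges:"):
            edges = np.array([float(x) for x in line.split(":", 1)[1].split(",")])
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        rows.append((int(parts[0]), int(parts[1]),
                     np.array([float(x) for x in parts[2:]], dtype=float)))
    if edges is None:
        raise ValueError("TSV distogram lacks a '#bin_edges:' header")
    B = len(edges) - 1
    L = max(max(i, j) for i, j, _ in rows)
    probs = np.zeros((L, L, B))
    seen = np.zeros((L, L), dtype=bool)
    for i, j, p in rows:
        if len(p) != B:
            raise ValueError(f"row ({i},{j}) has {len(p)} probabilities, expected {B}")
        probs[i - 1, j - 1] = p
        seen[i - 1, j - 1] = True
    # symmetric completion for pairs given in one orientation only
    missing = seen & ~seen.T
    probs = np.where((~seen)[..., None] & seen.T[..., None],
                     probs.transpose(1, 0, 2), probs)
    seen = seen | seen.T
    for d in range(L):
        if not seen[d, d]:
            probs[d, d, 0] = 1.0
    uncovered = ~seen
    np.fill_diagonal(uncovered, False)
    if uncovered.any():
        raise ValueError("TSV distogram does not cover all residue pairs")
    return Distogram(edges, probs, normalize=True)


def write_distogram_json(dist: Distogram, path, sequence: Optional[str] = None) -> None:
    seq = sequence or dist.sequence or "X" * dist.L
    data = {
        "sequence": seq,
        "bin_edges": [float(x) for x in dist.bin_edges],
        "probs": [round(float(x), 6) for x in dist.probs.ravel()],
    }
    Path(path).write_text(json.dumps(data))


# ---------------------------------------------------------------------------
# conversions


def distogram_to_distance(D: Distogram) -> DistancePrediction:
    """Argmax-bin midpoint as predicted distance, its mass as confidence.

    Exact ties between bins resolve to the lower-distance bin.
    """
    amax = np.argmax(D.probs, axis=2)  # first (= lowest-distance) max wins
    mids = D.bin_midpoints()
    pred = mids[amax]
    conf = np.take_along_axis(D.probs, amax[..., None], axis=2)[..., 0]
    in_range = amax < D.n_bins - 1
    np.fill_diagonal(pred, 0.0)
    return DistancePrediction(pred_dist=pred, confidence=conf, in_range=in_range)


def distogram_to_contact_probabilities(D: Distogram, cutoff: float = 8.0) -> np.ndarray:
    """Total probability mass in bins whose upper edge is at most ``cutoff``.

    The cutoff must coincide with a bin edge so that no bin is split.
    """
    edges = D.bin_edges
    hits = np.where(np.isclose(edges, cutoff))[0]
    if len(hits) == 0:
        raise ValueError(f"cutoff {cutoff} Å is not one of the bin edges")
    k = int(hits[0])  # bins 0..k-1 have upper edge <= cutoff
    P = D.probs[:, :, :k].sum(axis=2)
    np.fill_diagonal(P, 0.0)
    return P


def select_top_contacts(P: np.ndarray, L: Optional[int] = None, fraction: float = 0.5,
                        min_sep: int = 5) -> PredictedContactMap:
    """Keep the floor(L * fraction) highest-probability contacts.

    Candidates are pairs i < j with |i - j| >= min_sep; ties break by
    (probability desc, i asc, j asc).  If fewer candidates exist, all are
    returned.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if L is None:
        L = n
    iu, ju = np.triu_indices(n, k=min_sep)
    probs = P[iu, ju]
    order = np.lexsort((ju, iu, -probs))
    keep = order[: int(np.floor(L * fraction))]
    pairs = [(int(iu[k]) + 1, int(ju[k]) + 1, float(probs[k]))
             for k in keep if probs[k] > 0]
    return PredictedContactMap(pairs, L=n)


def contact_map_from_probabilities(P: np.ndarray, threshold: float = 0.5,
                                   min_sep: int = 5) -> PredictedContactMap:
    """All pairs with contact probability >= threshold, weighted by it.

    This denser map (rather than the top-L/2 subset) feeds the contact-map
    alignment, where coverage matters more than ranking.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    iu, ju = np.triu_indices(n, k=min_sep)
    ok = P[iu, ju] >= threshold
    pairs = [(int(i) + 1, int(j) + 1, float(P[i, j]))
             for i, j in zip(iu[ok], ju[ok])]
    return PredictedContactMap(pairs, L=n)


def read_casp_rr(path, L: Optional[int] = None) -> PredictedContactMap:
    """Read a CASP-RR contact file (columns: i j d1 d2 prob)."""
    pairs = []
    max_idx = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.split()[0].upper() in {
                "PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END"}:
            continue
        parts = line.split()
        if len(parts) < 5:
            continue  # sequence lines in some RR files
        try:
            i, j = int(parts[0]), int(parts[1])
            prob = float(parts[4])
        except ValueError:
            continue
        max_idx = max(max_idx, i, j)
        pairs.append((i, j, prob))
    return PredictedContactMap(pairs, L=L if L is not None else max_idx)
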