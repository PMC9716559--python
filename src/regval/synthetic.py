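"""Synthetic structures, distograms and register-error corruptions.

Every other module is testable without downloads: this module builds
self-avoiding toy folds from parametric helix/strand segments, simulates
sharply peaked distograms centred on the true distances (with a
controllable fraction of corrupted pairs), injects sequence-register
shifts with ground-truth labels, and assembles labelled per-residue
feature datasets for classifier training.

The defaults here define the study conditions used throughout the test
suite: 100-residue helix bundles, 0.5 Å distogram sharpness, 5% corrupted
pairs, error segments of 6-40 residues shifted by 1-5 positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classifier import LabelledDataset
from .predictions import Distogram, default_bin_edges
from .structures import Residue, StructureChain, observed_distance_matrix

__all__ = [
    "SyntheticSpec",
    "make_toy_fold",
    "simulate_distogram",
    "inject_register_shift",
    "corrupt_chain",
    "generate_labelled_dataset",
]

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

HELIX_RISE = 1.5        # Å per residue along the axis
HELIX_RADIUS = 2.3      # Å, Cα helix radius
HELIX_TWIST = 100.0     # degrees per residue
STRAND_RISE = 3.3       # Å per residue along a strand


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic chain / dataset."""

    L: int = 100
    topology: str = "helix_bundle"
    distogram_sharpness: float = 0.5   # Å std of mass around the true distance
    distogram_noise: float = 0.05      # fraction of pairs with corrupted argmax
    error_segments: Optional[List[Tuple[int, int, int]]] = None  # (start, end, shift)
    seed: int = 0

    def __post_init__(self):
        if self.distogram_sharpness <= 0:
            raise ValueError("sharpness must be positive")
        if self.error_segments:
            for s, e, k in self.error_segments:
                if k == 0:
                    raise ValueError("shift must be nonzero")
                if not (1 <= s <= e <= self.L):
                    raise ValueError("segment outside chain")


# ---------------------------------------------------------------------------
# toy folds


def _helix_points(n: int, xc: float, yc: float, z0: float, direction: int,
                  phase: float) -> np.ndarray:
    t = np.arange(n)
    ang = np.radians(direction * HELIX_TWIST * t + phase)
    return np.stack([xc + HELIX_RADIUS * np.cos(ang),
                     yc + HELIX_RADIUS * np.sin(ang),
                     z0 + direction * HELIX_RISE * t], axis=1)


def _turn_points(p_from: np.ndarray, p_to: np.ndarray, n: int,
                 bulge: float) -> np.ndarray:
    """n residues connecting two segment endpoints, bulging outward in z."""
    fracs = np.linspace(0.0, 1.0, n + 2)[1:-1]
    pts = p_from[None, :] + fracs[:, None] * (p_to - p_from)[None, :]
    pts[:, 2] += bulge * np.sin(np.pi * fracs)
    return pts


def _build_helix_bundle(L: int, rng) -> Tuple[np.ndarray, List[str]]:
    helix_len, turn_len = 18, 3
    coords, ss = [], []
    h = 0
    zmax = HELIX_RISE * (helix_len - 1)
    prev_end = None
    while len(coords) < L:
        col, parity = h // 2, h % 2
        row = parity if col % 2 == 0 else 1 - parity
        xc, yc = col * 9.0, row * 8.5
        direction = 1 if h % 2 == 0 else -1
        z0 = 0.0 if direction > 0 else zmax
        phase = float(rng.uniform(0, 360))
        pts = _helix_points(helix_len, xc, yc, z0, direction, phase)
        if prev_end is not None:
            need = min(turn_len, L - len(coords))
            outward = 3.0 if prev_end[2] > zmax / 2 else -3.0
            for p in _turn_points(prev_end, pts[0], need, outward):
                coords.append(p)
                ss.append("coil")
        take = min(helix_len, L - len(coords))
        for p in pts[:take]:
            coords.append(p)
            ss.append("helix")
        prev_end = pts[take - 1] if take > 0 else prev_end
        h += 1
    return np.array(coords[:L]), ss[:L]


def _build_sheet_coil(L: int, rng) -> Tuple[np.ndarray, List[str]]:
    strand_len, turn_len = 8, 3
    coords, ss = [], []
    seg = 0
    prev_end = None
    zmax = STRAND_RISE * (strand_len - 1)
    while len(coords) < L:
        is_coil = seg % 3 == 2   # every third segment meanders as coil
        xc = seg * 4.8
        direction = 1 if seg % 2 == 0 else -1
        z0 = 0.0 if direction > 0 else zmax
        n = strand_len
        t = np.arange(n)
        y = 0.6 * (-1.0) ** t + (6.0 if is_coil else 0.0)
        pts = np.stack([np.full(n, xc), y, z0 + direction * STRAND_RISE * t], axis=1)
        if prev_end is not None:
            need = min(turn_len, L - len(coords))
            outward = 4.0 if prev_end[2] > zmax / 2 else -4.0
            for p in _turn_points(prev_end, pts[0], need, outward):
                coords.append(p)
                ss.append("coil")
        take = min(n, L - len(coords))
        for p in pts[:take]:
            coords.append(p)
            ss.append("coil" if is_coil else "sheet")
        prev_end = pts[take - 1] if take > 0 else prev_end
        seg += 1
    return np.array(coords[:L]), ss[:L]


def make_toy_fold(L: int, topology: str = "helix_bundle", seed: int = 0,
                  plddt: float = 90.0) -> StructureChain:
    """Deterministic self-avoiding toy backbone of L representative atoms.

    ``helix_bundle`` packs antiparallel helices on a serpentine 2-row
    grid; ``sheet_coil_mix`` packs antiparallel strands with interleaved
    coil segments.  Coordinates carry a small seeded jitter.
    """
    if L < 10:
        raise ValueError("L must be at least 10")
    builders = {"helix_bundle": _build_helix_bundle,
                "sheet_coil_mix": _build_sheet_coil}
    if topology not in builders:
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)
    for _ in range(8):
        coords, ss = builders[topology](L, rng)
        coords = coords + rng.normal(0.0, 0.15, size=coords.shape)
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        sep = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
        if d[sep >= 2].min() > 2.0:
            break
    else:
        raise RuntimeError("could not build a self-avoiding fold")
    aa = rng.choice(_AA20, size=L)
    residues = [Residue(i + 1, str(aa[i]), coords[i], plddt=plddt, ss_class=ss[i])
                for i in range(L)]
    chain = StructureChain(residues, chain_id="A", L=L)
    from .structures import _neighbour_acc

    acc = _neighbour_acc(chain)
    for i, r in enumerate(chain.residues):
        r.acc = float(acc[i])
    return chain


# ---------------------------------------------------------------------------
# distograms


def simulate_distogram(chain: StructureChain, sharpness: float = 0.5,
                       noise: float = 0.0, seed: int = 0,
                       bin_edges=None) -> Distogram:
    """Distogram whose per-pair mass is a discretized Gaussian centred on
    the true distance (std = ``sharpness``); with probability ``noise``
    a pair's centre is displaced by a random offset of at least 4 Å.
    """
    from scipy.special import ndtr

    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, float)
    if not chain.modelled_mask.all():
        raise ValueError("simulate_distogram needs a fully modelled chain")
    rng = np.random.default_rng(seed)
    L = chain.L
    D = observed_distance_matrix(chain).values.copy()
    if noise > 0:
        iu, ju = np.triu_indices(L, k=1)
        hit = rng.random(len(iu)) < noise
        offs = rng.uniform(4.0, 10.0, size=len(iu)) * rng.choice([-1.0, 1.0], size=len(iu))
        newd = np.maximum(0.5, D[iu, ju] + np.where(hit, offs, 0.0))
        D[iu, ju] = newd
        D[ju, iu] = newd
    B = len(edges) - 1
    # cdf at the B "real" boundaries e0..e_{B-1}; the last bin is open-ended
    c = ndtr((edges[:B][None, None, :] - D[:, :, None]) / sharpness)
    probs = np.empty((L, L, B))
    probs[:, :, : B - 1] = np.diff(c, axis=2)
    probs[:, :, B - 1] = 1.0 - c[:, :, B - 1]
    probs[:, :, 0] += c[:, :, 0]       # sub-range mass folds into the first bin
    di = np.arange(L)
    probs[di, di, :] = 0.0
    probs[di, di, 0] = 1.0
    return Distogram(edges, probs, sequence=chain.sequence().replace("-", "X"),
                     normalize=True)


# ---------------------------------------------------------------------------
# register-shift corruption


def inject_register_shift(chain: StructureChain, start: int, end: int,
                          shift: int) -> Tuple[StructureChain, np.ndarray]:
    """Corrupt a chain with a sequence-register error.

    Residues start..end take the coordinates (and geometry-derived
    annotation) of the residue ``shift`` positions downstream: the
    backbone is kept but the sequence register is wrong, which is
    precisely a register error's signature.  Coordinates outside
    [start, end] are untouched.  Returns the corrupted chain and binary
    per-residue labels (1 inside the segment).
    """
    if shift == 0:
        raise ValueError("shift must be nonzero")
    if not (1 <= start <= end <= chain.L):
        raise ValueError("segment outside chain")
    if not (1 <= start + shift and end + shift <= chain.L):
        raise ValueError("shifted segment falls outside the chain")
    out = chain.copy()
    src = chain  # read from the pristine chain, not the partly written copy
    for i in range(start, end + 1):
        donor = src[i + shift]
        target = out[i]
        target.rep_coord = None if donor.rep_coord is None else np.array(donor.rep_coord)
        target.ss_class = donor.ss_class
        target.acc = donor.acc
    labels = np.zeros(chain.L, dtype=int)
    labels[start - 1: end] = 1
    return out, labels


def corrupt_chain(chain: StructureChain, segments: Sequence[Tuple[int, int, int]],
                  occlude_overlap: bool = True) -> Tuple[StructureChain, np.ndarray]:
    """Apply register-shift corruptions, optionally masking the residues
    whose coordinates the shifted segment now occupies.

    A literal shift duplicates geometry: residues just past the segment
    end share coordinates with the segment's tail.  Real register errors
    have no such duplication — the compensating residues are simply
    absent from the model — so by default those out-of-segment residues
    are marked unmodelled.
    """
    out = chain
    labels = np.zeros(chain.L, dtype=int)
    for start, end, shift in segments:
        out, lab = inject_register_shift(out, start, end, shift)
        labels |= lab
        if occlude_overlap:
            if shift > 0:
                occl = range(end + 1, min(chain.L, end + shift) + 1)
            else:
                occl = range(max(1, start + shift), start)
            for i in occl:
                if labels[i - 1] == 0:
                    out[i].rep_coord = None
    return out, labels


def _random_segments(rng, L: int, max_segments: int = 2,
                     min_len: int = 6, max_len: int = 40,
                     max_shift: int = 5) -> List[Tuple[int, int, int]]:
    """0..max_segments non-overlapping error segments with safety margins
    so occlusion zones never collide."""
    n = int(rng.integers(0, max_segments + 1))
    segments: List[Tuple[int, int, int]] = []
    for _ in range(n):
        for _attempt in range(20):
            length = int(rng.integers(min_len, max_len + 1))
            shift = int(rng.integers(1, max_shift + 1)) * (1 if rng.random() < 0.5 else -1)
            lo = max(1, 1 - shift)
            hi = L - length + 1 - max(shift, 0)
            if hi < lo:
                continue
            start = int(rng.integers(lo, hi + 1))
            end = start + length - 1
            margin = abs(shift) + 6
            if all(end + margin < s0 or e0 + margin < start
                   for s0, e0, _ in segments):
                segments.append((start, end, shift))
                break
    return sorted(segments)


# ---------------------------------------------------------------------------
# labelled datasets


def generate_labelled_dataset(n_chains: int = 40,
                              spec: Optional[SyntheticSpec] = None,
                              seed: int = 1) -> LabelledDataset:
    """Per-residue features + labels from ``n_chains`` corrupted toy folds.

    Each chain gets 0-2 random register-error segments (6-40 residues,
    |shift| 1-5); features are the classifier's 11-column set computed
    from the corrupted chain against a distogram simulated from the
    pristine chain.  The group id is the source chain, enabling
    leakage-aware splits.  Deterministic under ``seed``.
    """
    from .report import compute_features

    spec = spec if spec is not None else SyntheticSpec()
    rng = np.random.default_rng(seed)
    frames, labels_all, groups_all = [], [], []
    for c in range(n_chains):
        chain = make_toy_fold(spec.L, spec.topology, seed=int(rng.integers(2 ** 31)))
        dist = simulate_distogram(chain, spec.distogram_sharpness,
                                  spec.distogram_noise,
                                  seed=int(rng.integers(2 ** 31)))
        segments = (spec.error_segments if spec.error_segments is not None
                    else _random_segments(rng, spec.L))
        corrupted, labels = corrupt_chain(chain, segments)
        feats, table = compute_features(corrupted, dist)
        keep = table["mask"].to_numpy()
        frames.append(feats.iloc[keep].reset_index(drop=True))
        labels_all.append(labels[keep])
        groups_all.append(np.full(int(keep.sum()), c))
    X = pd.concat(frames, ignore_index=True)
    return LabelledDataset(X, np.concatenate(labels_all), np.concatenate(groups_all))
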