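"""Benchmark harnesses over the synthetic study conditions.

These routines regenerate the package's headline numbers from scratch:
agreement of the heuristic contact-map aligner with the exhaustive
optimum, recovery of injected register shifts, classifier hold-out
performance and feature importance, recall as a function of the
consecutive-residue threshold, and the false-positive control on clean
chains.  Problem sizes are chosen so a full run finishes in minutes on a
single core; every routine is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .classifier import (FEATURE_NAMES, TrainedClassifier, flag_error_runs,
                         make_balanced_split, score_residues,
                         train_error_classifier)
from .cmo import align_contact_maps, brute_force_cmo, extract_register_shifts
from .predictions import (contact_map_from_probabilities,
                          distogram_to_contact_probabilities)
from .report import compute_features
from .structures import ContactMap, observed_contact_map
from .synthetic import (SyntheticSpec, corrupt_chain, generate_labelled_dataset,
                        make_toy_fold, simulate_distogram)

__all__ = [
    "random_contact_map",
    "cmo_oracle_agreement",
    "register_shift_recovery",
    "classifier_benchmark",
    "permutation_importance",
    "recall_vs_min_run",
    "false_positive_control",
]


def random_contact_map(L: int, n_contacts: int, rng, min_sep: int = 2) -> ContactMap:
    """A random contact map: ``n_contacts`` distinct pairs with
    |i - j| >= min_sep, unit weights."""
    candidates = [(i, j) for i in range(1, L + 1) for j in range(i + min_sep, L + 1)]
    idx = rng.choice(len(candidates), size=min(n_contacts, len(candidates)),
                     replace=False)
    return ContactMap([candidates[k] for k in idx], L=L)


def cmo_oracle_agreement(n_instances: int = 100, L: int = 8,
                         seed: int = 0) -> Dict[str, float]:
    """Heuristic aligner vs exhaustive optimum on random small map pairs.

    Returns the number of instances where the heuristic attains the
    optimal matched weight, and whether it ever exceeded it (it must
    not — the oracle is exhaustive).
    """
    rng = np.random.default_rng(seed)
    agree, exceed = 0, 0
    for _ in range(n_instances):
        na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 7))
        cm_a = random_contact_map(L, na, rng)
        cm_b = random_contact_map(L, nb, rng)
        oracle = brute_force_cmo(cm_a, cm_b)
        heur = align_contact_maps(cm_a, cm_b)
        if heur.matched_weight > oracle.score + 1e-9:
            exceed += 1
        if abs(heur.matched_weight - oracle.score) <= 1e-9:
            agree += 1
    return {"n": n_instances, "agree": agree, "exceed": exceed,
            "agreement_rate": agree / n_instances}


@dataclass
class RecoveryTrial:
    start: int
    end: int
    shift: int
    recovered: bool
    calls: list


def register_shift_recovery(n_trials: int = 100, L: int = 100,
                            min_seg: int = 20, max_seg: int = 40,
                            sharpness: float = 0.3, seed: int = 0,
                            endpoint_tol: int = 2) -> Dict[str, object]:
    """Inject one register shift (k = 1..5 cycling) into a toy fold and
    check that contact-map alignment recovers the exact shift with
    endpoints within ``endpoint_tol`` residues."""
    rng = np.random.default_rng(seed)
    trials: List[RecoveryTrial] = []
    for t in range(n_trials):
        k = t % 5 + 1
        chain = make_toy_fold(L, "helix_bundle", seed=int(rng.integers(2 ** 31)))
        dist = simulate_distogram(chain, sharpness=sharpness, noise=0.0,
                                  seed=int(rng.integers(2 ** 31)))
        length = int(rng.integers(min_seg, max_seg + 1))
        start = int(rng.integers(1, L - length - k + 2))
        end = start + length - 1
        corrupted, _ = corrupt_chain(chain, [(start, end, k)])
        P = distogram_to_contact_probabilities(dist)
        pred_cm = contact_map_from_probabilities(P, min_sep=3)
        obs_cm = observed_contact_map(corrupted, min_sep=3)
        aln = align_contact_maps(obs_cm, pred_cm)
        calls = extract_register_shifts(aln)
        ok = any(c.shift == k and abs(c.start - start) <= endpoint_tol
                 and abs(c.end - end) <= endpoint_tol for c in calls)
        trials.append(RecoveryTrial(start, end, k, ok,
                                    [(c.start, c.end, c.shift) for c in calls]))
    n_ok = sum(t.recovered for t in trials)
    return {"n": n_trials, "recovered": n_ok, "recovery_rate": n_ok / n_trials,
            "trials": trials}


def classifier_benchmark(seed: int = 1, n_chains: int = 40, n_iter: int = 200
                         ) -> Dict[str, object]:
    """Train on the default synthetic labelled dataset with a group-aware
    balanced split; report hold-out accuracy and AUC and the trained
    classifier itself."""
    from sklearn.metrics import accuracy_score, roc_auc_score

    ds = generate_labelled_dataset(n_chains=n_chains, seed=seed)
    train, test = make_balanced_split(ds, seed=seed, by_group=True)
    clf = train_error_classifier(train, n_iter=n_iter, seed=seed)
    probs = score_residues(clf, test.X)
    auc = float(roc_auc_score(test.y, probs))
    acc = float(accuracy_score(test.y, probs >= 0.5))
    return {"classifier": clf, "auc": auc, "accuracy": acc,
            "n_train": len(train), "n_test": len(test),
            "test": test}


def permutation_importance(clf: TrainedClassifier, test, n_repeats: int = 20,
                           seed: int = 0) -> Dict[str, float]:
    """Mean accuracy drop on the hold-out set after shuffling one feature
    at a time (each shuffle repeated ``n_repeats`` times)."""
    from sklearn.metrics import accuracy_score

    rng = np.random.default_rng(seed)
    X = test.X[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = test.y
    base = accuracy_score(y, clf.predict_proba(X) >= 0.5)
    drops = {}
    for f, name in enumerate(FEATURE_NAMES):
        acc = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, f] = rng.permutation(Xp[:, f])
            acc.append(accuracy_score(y, clf.predict_proba(Xp) >= 0.5))
        drops[name] = float(base - np.mean(acc))
    return drops


def recall_vs_min_run(clf: TrainedClassifier, n_chains: int = 12,
                      threshold: float = 0.9, min_runs=range(1, 21),
                      seed: int = 7, L: int = 100) -> Dict[int, float]:
    """Residue-level recall of flagged error runs as the consecutive-
    residue threshold grows, on freshly generated corrupted chains."""
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(L=L)
    score_rows, label_rows = [], []
    for _ in range(n_chains):
        chain = make_toy_fold(L, spec.topology, seed=int(rng.integers(2 ** 31)))
        dist = simulate_distogram(chain, spec.distogram_sharpness,
                                  spec.distogram_noise, seed=int(rng.integers(2 ** 31)))
        from .synthetic import _random_segments

        segments = _random_segments(rng, L)
        corrupted, labels = corrupt_chain(chain, segments)
        feats, table = compute_features(corrupted, dist)
        scores = score_residues(clf, feats)
        keep = table["mask"].to_numpy()
        score_rows.append((scores, keep))
        label_rows.append(labels)
    out = {}
    for m in min_runs:
        tp = fn = 0
        for (scores, keep), labels in zip(score_rows, label_rows):
            flagged = np.zeros(len(scores), dtype=bool)
            for call in flag_error_runs(scores, min_run=m, threshold=threshold):
                flagged[call.start - 1: call.end] = True
            pos = (labels == 1) & keep
            tp += int((flagged & pos).sum())
            fn += int((~flagged & pos).sum())
        out[int(m)] = tp / (tp + fn) if tp + fn else 0.0
    return out


def false_positive_control(clf: TrainedClassifier, n_seeds: int = 50,
                           L: int = 100, seed: int = 0,
                           min_run: int = 6, threshold: float = 0.9
                           ) -> Dict[str, int]:
    """Uncorrupted, noise-free chains through the full pipeline: counts
    classifier error calls and register-shift calls (both should be 0)."""
    rng = np.random.default_rng(seed)
    n_error_calls = n_shift_calls = 0
    for _ in range(n_seeds):
        chain = make_toy_fold(L, "helix_bundle", seed=int(rng.integers(2 ** 31)))
        dist = simulate_distogram(chain, sharpness=0.3, noise=0.0,
                                  seed=int(rng.integers(2 ** 31)))
        feats, _ = compute_features(chain, dist)
        scores = score_residues(clf, feats)
        n_error_calls += len(flag_error_runs(scores, min_run=min_run,
                                             threshold=threshold))
        P = distogram_to_contact_probabilities(dist)
        aln = align_contact_maps(observed_contact_map(chain, min_sep=3),
                                 contact_map_from_probabilities(P, min_sep=3))
        n_shift_calls += len(extract_register_shifts(aln))
    return {"n_seeds": n_seeds, "error_calls": n_error_calls,
            "register_shift_calls": n_shift_calls}
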