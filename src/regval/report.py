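"""End-to-end validation: classifier scores + register-shift calls.

``run_validate`` chains the whole pipeline — read model, load distogram,
compute per-residue metrics, score residues with the trained classifier,
align the observed and predicted contact maps, extract register-shift
calls and screen them with the false-positive filters — and returns a
``ValidationReport`` covering every reference position.  Reports are
written as a per-residue TSV plus a JSON file with the full call objects
and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _version
from .classifier import (ErrorCall, TrainedClassifier, build_feature_matrix,
                         flag_error_runs, load_default_classifier, score_residues)
from .cmo import (RegisterShiftCall, align_contact_maps, contact_density_filter,
                  extract_register_shifts, plddt_filter, qscore_filter)
from .metrics import build_metric_table, smooth_profile
from .predictions import (Distogram, contact_map_from_probabilities,
                          distogram_to_contact_probabilities,
                          distogram_to_distance, load_distogram,
                          select_top_contacts)
from .structures import (StructureChain, assign_ss_and_acc, observed_contact_map,
                         read_model, renumber_to_reference)

__all__ = ["ValidationReport", "compute_features", "run_validate", "write_report"]


def compute_features(chain: StructureChain, distogram: Distogram,
                     min_sep: int = 5, contact_cutoff: float = 8.0
                     ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Metric table + 11-column classifier feature matrix for one chain.

    The predicted contact map is the top-L/2 subset of the distogram's
    contact probabilities.  Returns (features, metric_table).
    """
    if chain.L != distogram.L:
        raise ValueError(f"chain has {chain.L} reference positions but the "
                         f"distogram covers {distogram.L}")
    pred = distogram_to_distance(distogram)
    P = distogram_to_contact_probabilities(distogram, cutoff=contact_cutoff)
    pred_cm = select_top_contacts(P, L=chain.L, fraction=0.5, min_sep=min_sep)
    table = build_metric_table(chain, pred, pred_cm, min_sep=min_sep,
                               contact_cutoff=contact_cutoff)
    feats = build_feature_matrix(table, chain)
    return feats, table


@dataclass
class ValidationReport:
    """Per-residue validation verdicts for one chain.

    ``residue_table`` has one row per reference position: index, amino
    acid, raw and display-smoothed (five-residue rolling average)
    classifier scores, an above-0.5 flag, the register status under the
    contact-map alignment (native / shifted / unaligned) and the local
    shift.  Display smoothing never alters the stored raw scores.
    """

    residue_table: pd.DataFrame
    error_calls: List[ErrorCall]
    register_calls: List[RegisterShiftCall]
    provenance: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return len(self.residue_table)

    def to_json_dict(self) -> dict:
        return {
            "format": "regval-report",
            "version": 1,
            "provenance": self.provenance,
            "residues": {
                "index": self.residue_table.index.tolist(),
                **{c: self.residue_table[c].tolist()
                   for c in self.residue_table.columns},
            },
            "error_calls": [
                {"start": c.start, "end": c.end, "mean_score": round(c.mean_score, 6),
                 "n_residues": c.n_residues}
                for c in self.error_calls
            ],
            "register_shifts": [
                {"start": c.start, "end": c.end, "shift": c.shift,
                 "n_residues": c.n_residues,
                 "proposed_register": c.proposed_register,
                 "filter_verdicts": dict(c.filter_verdicts),
                 "passes_filters": c.passes_filters}
                for c in self.register_calls
            ],
        }

    @classmethod
    def from_json(cls, path) -> "ValidationReport":
        data = json.loads(Path(path).read_text())
        if data.get("format") != "regval-report":
            raise ValueError("not a regval report")
        res = data["residues"]
        idx = res.pop("index")
        table = pd.DataFrame(res, index=pd.Index(idx, name="residue"))
        errors = [ErrorCall(d["start"], d["end"], d["mean_score"])
                  for d in data["error_calls"]]
        shifts = []
        for d in data["register_shifts"]:
            call = RegisterShiftCall(d["start"], d["end"], d["shift"],
                                     filter_verdicts=d.get("filter_verdicts", {}))
            shifts.append(call)
        return cls(table, errors, shifts, data.get("provenance", {}))


def run_validate(model, distogram, chain_id: str = "A",
                 classifier: Optional[TrainedClassifier] = None,
                 predicted_model=None, dssp_path=None, ref_seq: Optional[str] = None,
                 min_run: int = 6, score_threshold: float = 0.9,
                 min_shift_len: int = 5, min_sep: int = 5, cmo_min_sep: int = 3,
                 contact_cutoff: float = 8.0, contact_prob_threshold: float = 0.5,
                 apply_filters: bool = True, seed: int = 0) -> ValidationReport:
    """Validate one chain against a distance prediction.

    ``model`` and ``distogram`` may be paths or already-loaded objects;
    ``predicted_model`` (path or chain) enables the pLDDT and Q-score
    filters.  Defaults flag stretches of >= 6 consecutive residues with a
    score >= 0.9 and register shifts of >= 5 aligned residues.
    Deterministic for fixed inputs and classifier.
    """
    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"validation stage {name!r} failed: {exc}") from exc

    if isinstance(model, (str, Path)):
        chain = stage("read_model", read_model, model, chain_id)
    else:
        chain = model
    if ref_seq is not None:
        chain = stage("renumber", renumber_to_reference, chain, ref_seq)
    if dssp_path is not None or any(r.ss_class is None for r in chain.residues
                                    if r.modelled):
        chain = stage("annotate", assign_ss_and_acc, chain, dssp_path)
    if isinstance(distogram, (str, Path)):
        distogram = stage("load_distogram", load_distogram, distogram)
    if classifier is None:
        classifier = load_default_classifier()
    pred_chain = predicted_model
    if isinstance(predicted_model, (str, Path)):
        pred_chain = stage("read_predicted_model", read_model, predicted_model, chain_id)

    feats, table = stage("metrics", compute_features, chain, distogram,
                         min_sep=min_sep, contact_cutoff=contact_cutoff)
    scores = stage("classifier", score_residues, classifier, feats)
    error_calls = flag_error_runs(scores, min_run=min_run, threshold=score_threshold)

    # the alignment uses a denser map (smaller sequence separation) than the
    # confusion metrics: local contacts pin the register at segment boundaries
    P = distogram_to_contact_probabilities(distogram, cutoff=contact_cutoff)
    pred_cm_dense = contact_map_from_probabilities(P, threshold=contact_prob_threshold,
                                                   min_sep=cmo_min_sep)
    obs_cm = observed_contact_map(chain, cutoff=contact_cutoff, min_sep=cmo_min_sep)
    aln = stage("cmo", align_contact_maps, obs_cm, pred_cm_dense)
    register_calls = extract_register_shifts(aln, min_len=min_shift_len)
    for call in register_calls:
        if apply_filters:
            call.filter_verdicts["contact_density"] = contact_density_filter(
                call, pred_cm_dense)
            call.filter_verdicts["plddt"] = plddt_filter(call, pred_chain)
            call.filter_verdicts["qscore"] = qscore_filter(call, chain, pred_chain)
        else:
            call.filter_verdicts = {"contact_density": "not_run",
                                    "plddt": "not_run", "qscore": "not_run"}

    offsets = {i: j - i for i, j in aln.mapping}
    status, shift_col = [], []
    for i in range(1, chain.L + 1):
        off = offsets.get(i)
        if off is None:
            status.append("unaligned")
            shift_col.append(0)
        elif off == 0:
            status.append("native")
            shift_col.append(0)
        else:
            status.append("shifted")
            shift_col.append(off)
    residue_table = pd.DataFrame({
        "aa": list(chain.sequence()),
        "score": np.round(scores, 6),
        "smooth_score": np.round(smooth_profile(scores, window=5), 6),
        "above_0.5": scores >= 0.5,
        "cmo_status": status,
        "cmo_shift": shift_col,
    }, index=pd.RangeIndex(1, chain.L + 1, name="residue"))

    provenance = {
        "regval_version": _version,
        "chain_id": chain.chain_id,
        "L": chain.L,
        "seed": int(seed),
        "thresholds": {"min_run": min_run, "score_threshold": score_threshold,
                       "min_shift_len": min_shift_len, "min_sep": min_sep,
                       "contact_cutoff": contact_cutoff,
                       "contact_prob_threshold": contact_prob_threshold,
                       "cmo_min_sep": cmo_min_sep},
        "classifier": classifier.metadata,
        "filters_applied": bool(apply_filters),
    }
    return ValidationReport(residue_table, error_calls, register_calls, provenance)


def write_report(report: ValidationReport, tsv_path=None, json_path=None) -> None:
    """Write the per-residue TSV and/or the full JSON report."""
    if tsv_path is not None:
        report.residue_table.to_csv(tsv_path, sep="\t")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.to_json_dict(), indent=1))


def plot_report(report: ValidationReport, path) -> None:
    """Score trace + register-status bars, in the style of a per-chain
    validation figure.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = report.residue_table.index.to_numpy()
    fig, (ax, axb) = plt.subplots(2, 1, figsize=(10, 4), sharex=True,
                                  gridspec_kw={"height_ratios": [4, 1]})
    ax.plot(idx, report.residue_table["smooth_score"], color="teal",
            label="classifier score (5-residue average)")
    ax.axhline(0.5, color="red", ls=":", lw=1)
    ax.set_ylim(-0.02, 1.02)
    ax.set_ylabel("error probability")
    ax.legend(loc="upper right", fontsize=8)
    above = report.residue_table["above_0.5"].to_numpy()
    shifted = (report.residue_table["cmo_status"] == "shifted").to_numpy()
    axb.imshow(np.vstack([above, shifted]), aspect="auto", cmap="coolwarm",
               extent=(idx[0] - 0.5, idx[-1] + 0.5, -0.5, 1.5))
    axb.set_yticks([0, 1], ["CMO shifted", "score > 0.5"])
    axb.set_xlabel("residue")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
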