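"""Ensemble benchmarking: per-complex metrics, threshold curves, subsampling.

For each generated frame the protein conformation is scored by TM-score
against the reference Calpha trace and the binding pose by L-rms (ligand
heavy-atom RMSD after protein alignment). Per-complex summaries are the
median and best over the ensemble; cohort-level curves report, per
threshold, the fraction of complexes whose best frame passes (above the
threshold for TM-score, below for L-rms). ``subsample_performance``
measures how that success fraction grows with the number of generative
samples by averaging over random subsets.

All statistics are pure functions of the per-frame metric lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CoordinateFrame, ligand_rms, tm_score
from .sampling import StructureEnsemble

__all__ = ["EnsembleMetrics", "score_ensemble", "threshold_curve",
           "subsample_performance", "stratified_success"]

DEFAULT_LRMS_CUTOFFS = (2.0, 5.0)


@dataclass
class EnsembleMetrics:
    """Per-frame metric lists and their summaries for one complex."""

    system_id: str
    tm_scores: np.ndarray
    l_rms: np.ndarray

    def __post_init__(self) -> None:
        self.tm_scores = np.asarray(self.tm_scores, dtype=np.float64)
        self.l_rms = np.asarray(self.l_rms, dtype=np.float64)
        if len(self.tm_scores) != len(self.l_rms):
            raise ValueError("metric lists must have equal length")
        if np.any((self.tm_scores <= 0) | (self.tm_scores > 1)):
            raise ValueError("TM-scores must lie in (0, 1]")
        if np.any(self.l_rms < 0):
            raise ValueError("L-rms must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.tm_scores)

    @property
    def median_tm(self) -> float:
        return float(np.median(self.tm_scores))

    @property
    def best_tm(self) -> float:
        return float(self.tm_scores.max())

    @property
    def median_lrms(self) -> float:
        return float(np.median(self.l_rms))

    @property
    def best_lrms(self) -> float:
        return float(self.l_rms.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_id": np.arange(1, self.n_frames + 1),
            "tm_score": self.tm_scores,
            "l_rms": self.l_rms,
        })


def score_ensemble(ensemble: StructureEnsemble, reference: CoordinateFrame,
                   system_id: str = "complex") -> EnsembleMetrics:
    """TM-score and L-rms of every frame against the reference structure."""
    ref_roles = reference.atom_roles
    tm, lr = [], []
    for frame in ensemble.frames:
        if not np.array_equal(frame.atom_roles, ref_roles):
            raise ValueError("frame and reference atom roles differ")
        tm.append(tm_score(frame.protein_coords(), reference.protein_coords()))
        lr.append(ligand_rms(frame, reference))
    return EnsembleMetrics(system_id=system_id, tm_scores=np.array(tm),
                           l_rms=np.array(lr))


def threshold_curve(metrics_list: list[EnsembleMetrics], metric: str,
                    thresholds: np.ndarray) -> np.ndarray:
    """Fraction of complexes whose best frame passes each threshold.

    ``metric`` is ``"tm"`` (best TM-score above the threshold) or ``"lrms"``
    (best L-rms below the threshold). The curve is monotone across a sorted
    grid: non-increasing for TM, non-decreasing for L-rms.
    """
    if not metrics_list:
        raise ValueError("at least one complex required")
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if metric == "tm":
        best = np.array([m.best_tm for m in metrics_list])
        passes = best[:, None] > thresholds[None, :]
    elif metric == "lrms":
        best = np.array([m.best_lrms for m in metrics_list])
        passes = best[:, None] < thresholds[None, :]
    else:
        raise ValueError("metric must be 'tm' or 'lrms'")
    return passes.mean(axis=0)


def subsample_performance(metrics_list: list[EnsembleMetrics], k: int,
                          n_reps: int, rng: np.random.Generator | int,
                          cutoffs=DEFAULT_LRMS_CUTOFFS) -> dict[float, float]:
    """Success fraction with k-sample ensembles at the given L-rms cutoffs.

    For each repetition, a random size-k subset of frames (without
    replacement, independently per complex) stands in for a smaller
    generative run; a complex succeeds when any subset frame falls under the
    cutoff. Returns the mean success fraction per cutoff over ``n_reps``
    repetitions. ``k`` equal to the full ensemble reproduces the
    full-ensemble fraction exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if not metrics_list:
        raise ValueError("at least one complex required")
    for m in metrics_list:
        if k > m.n_frames:
            raise ValueError("k exceeds the ensemble size")
    if k < 1 or n_reps < 1:
        raise ValueError("k and n_reps must be >= 1")
    results = {float(c): 0.0 for c in cutoffs}
    for _ in range(n_reps):
        for cutoff in cutoffs:
            hits = 0
            for m in metrics_list:
                idx = rng.choice(m.n_frames, size=k, replace=False)
                if np.any(m.l_rms[idx] < cutoff):
                    hits += 1
            results[float(cutoff)] += hits / len(metrics_list)
    return {c: v / n_reps for c, v in results.items()}


def stratified_success(metrics_list: list[EnsembleMetrics],
                       annotations: dict[str, object], cutoff: float = 2.0) -> pd.DataFrame:
    """Success fraction grouped by a per-complex annotation.

    ``annotations`` maps system_id to a group label (e.g. a rotatable-bond
    count bin or a related-training-data bin). Returns one row per group
    with the number of complexes and the fraction whose best L-rms is under
    ``cutoff``.
    """
    rows = [
        {"group": annotations[m.system_id],
         "success": m.best_lrms < cutoff}
        for m in metrics_list
    ]
    df = pd.DataFrame(rows)
    out = df.groupby("group", sort=True)["success"].agg(["count", "mean"])
    return out.rename(columns={"count": "n_complexes", "mean": "fraction"}).reset_index()
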