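"""Trajectory-level analysis of per-residue reactivity descriptors.

Assembles per-frame residue descriptors into a frames × residues matrix
ordered along the folding coordinate, subtracts the folded reference
(the frame of lowest RMSD-Cα) to obtain Δη, locates the frame where
per-residue fluctuations stabilize (a single least-squares change point
on the mean |Δη| series), and summarizes values by physicochemical
residue group and by residue type.

The classifier operationalizes the qualitative picture of folding
trajectories in which a residue's local hardness fluctuates above and
below its final native value while the chain is non-native, then
settles once a native-like topology forms: the segment with the lower
mean instability score is labeled native-like regardless of whether the
trajectory is ordered folding→unfolded or the reverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cdft_local import ResidueField

__all__ = [
    "TrajectoryDescriptorMatrix",
    "FoldingClassification",
    "RESIDUE_GROUPS",
    "build_matrix",
    "normalize_center",
    "delta_eta",
    "stability_changepoint",
    "group_region_averages",
    "residue_type_profile",
    "correlate_global",
]

#: Five physicochemical residue groups (3-letter codes).  CYS is left
#: unassigned deliberately.
RESIDUE_GROUPS: dict[int, tuple[str, ...]] = {
    1: ("ALA", "GLY", "ILE", "LEU", "MET", "PRO", "VAL"),   # nonpolar aliphatic
    2: ("PHE", "TRP", "TYR"),                               # aromatic
    3: ("ASN", "GLN", "SER", "THR"),                        # uncharged polar
    4: ("ARG", "HIS", "LYS"),                               # positively charged
    5: ("ASP", "GLU"),                                      # negatively charged
}

GROUP_LABELS = {
    1: "nonpolar aliphatic",
    2: "aromatic",
    3: "uncharged polar",
    4: "positively charged",
    5: "negatively charged",
}


@dataclass
class TrajectoryDescriptorMatrix:
    """Frames × residues values of one descriptor along the folding
    coordinate."""

    name: str
    frame_ids: list
    residue_labels: list[str]
    residue_names: list[str]
    values: np.ndarray               # (n_frames, n_residues)
    reference_frame: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.frame_ids),
                                 len(self.residue_labels)):
            raise ValueError("matrix shape does not match frame/residue "
                             "labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing cells in descriptor matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.frame_ids,
                            columns=self.residue_labels)


@dataclass
class FoldingClassification:
    """Two-segment labeling of a trajectory by fluctuation stabilization."""

    changepoint: int                  # first frame of the second segment
    labels: list[str]                 # per frame: non-native | native-like
    scores: np.ndarray                # per-frame instability score
    no_evidence: bool = False
    params: dict = field(default_factory=dict)


def build_matrix(residue_fields: list[ResidueField],
                 frame_order: list | None = None,
                 name: str | None = None) -> TrajectoryDescriptorMatrix:
    """Assemble per-frame residue fields into a matrix, in frame order."""
    if not residue_fields:
        raise ValueError("no residue fields")
    ref = residue_fields[0]
    for f in residue_fields:
        if f.residue_labels != ref.residue_labels:
            missing = set(ref.residue_labels) ^ set(f.residue_labels)
            raise ValueError(
                f"residue sets differ across frames: {sorted(missing)}")
    if frame_order is None:
        fields = list(residue_fields)
    else:
        by_id = {f.frame_id: f for f in residue_fields}
        try:
            fields = [by_id[i] for i in frame_order]
        except KeyError as exc:
            raise ValueError(f"missing frame {exc.args[0]!r}") from exc
    return TrajectoryDescriptorMatrix(
        name=name or ref.name,
        frame_ids=[f.frame_id for f in fields],
        residue_labels=list(ref.residue_labels),
        residue_names=list(ref.residue_names),
        values=np.array([f.values for f in fields]),
    )


def normalize_center(matrix: TrajectoryDescriptorMatrix
                     ) -> TrajectoryDescriptorMatrix:
    """Global normalization: subtract the matrix mean, divide by the
    maximum absolute deviation.  Result lies in [−1, 1] with mean 0.

    Normalization is matrix-global rather than per-residue so the
    ordering of residues by descriptor magnitude survives.
    """
    v = matrix.values
    centered = v - v.mean()
    scale = np.abs(centered).max()
    if scale < 1e-15:
        raise ValueError("zero variance: constant matrix cannot be "
                         "normalized")
    return TrajectoryDescriptorMatrix(
        matrix.name, list(matrix.frame_ids), list(matrix.residue_labels),
        list(matrix.residue_names), centered / scale,
        matrix.reference_frame)


def delta_eta(matrix: TrajectoryDescriptorMatrix,
              rmsd_series: np.ndarray) -> TrajectoryDescriptorMatrix:
    """Per-residue deviation from the folded reference frame.

    The reference is the frame of minimum RMSD-Cα (first occurrence on
    ties, with a warning); every cell becomes value − reference value,
    so the reference row is exactly zero and positive cells mean
    "harder than the same residue in the folded reference".
    """
    rmsd = np.asarray(rmsd_series, dtype=float)
    if len(rmsd) != len(matrix.frame_ids):
        raise ValueError("rmsd series not aligned with frames")
    ref = int(np.argmin(rmsd))
    if np.sum(rmsd == rmsd[ref]) > 1:
        warnings.warn("tie in minimum RMSD; using first occurrence",
                      stacklevel=2)
    return TrajectoryDescriptorMatrix(
        f"delta_{matrix.name}", list(matrix.frame_ids),
        list(matrix.residue_labels), list(matrix.residue_names),
        matrix.values - matrix.values[ref], reference_frame=ref)


def stability_changepoint(matrix: TrajectoryDescriptorMatrix,
                          min_segment: int = 5,
                          score: str = "abs") -> FoldingClassification:
    """Single least-squares change point on the instability score.

    The per-frame score is the mean over residues of |Δη| (or a
    centered rolling SD with ``score="rolling_sd"``).  The change point
    is the split minimizing the pooled within-segment sum of squared
    deviations, each segment at least ``min_segment`` frames; the
    segment with the lower mean score is labeled native-like.  If the
    two segment means are equal within tolerance the split carries no
    information and ``no_evidence`` is set.
    """
    F = len(matrix.frame_ids)
    if F < 2 * min_segment:
        raise ValueError(f"need at least {2 * min_segment} frames")
    if score == "abs":
        s = np.mean(np.abs(matrix.values), axis=1)
    elif score == "rolling_sd":
        w = max(3, min_segment)
        s = pd.Series(np.std(matrix.values, axis=1)).rolling(
            w, center=True, min_periods=1).std().bfill().ffill().to_numpy()
    else:
        raise ValueError(f"unknown score {score!r}")

    csum = np.concatenate([[0.0], np.cumsum(s)])
    csq = np.concatenate([[0.0], np.cumsum(s * s)])

    def sse(a, b):  # frames [a, b)
        n = b - a
        tot, tot2 = csum[b] - csum[a], csq[b] - csq[a]
        return tot2 - tot * tot / n

    splits = range(min_segment, F - min_segment + 1)
    costs = np.array([sse(0, k) + sse(k, F) for k in splits])
    k = int(np.argmin(costs)) + min_segment

    mean1, mean2 = s[:k].mean(), s[k:].mean()
    tol = 1e-8 * (abs(s.mean()) + 1.0)
    no_evidence = bool(abs(mean1 - mean2) <= tol)
    first, second = (("non-native", "native-like") if mean1 >= mean2
                     else ("native-like", "non-native"))
    labels = [first] * k + [second] * (F - k)
    return FoldingClassification(
        changepoint=k, labels=labels, scores=s, no_evidence=no_evidence,
        params={"min_segment": min_segment, "score": score})


def group_region_averages(matrix: TrajectoryDescriptorMatrix,
                          classification: FoldingClassification,
                          groups: dict[int, tuple[str, ...]] | None = None
                          ) -> pd.DataFrame:
    """Mean and SD per residue group × region (non-native / native-like).

    Cells are pooled over all frames of the region and all residues
    whose 3-letter code belongs to the group; a group with no member
    residues present is omitted with a warning.
    """
    if len(classification.labels) != len(matrix.frame_ids):
        raise ValueError("classification not aligned with matrix")
    groups = RESIDUE_GROUPS if groups is None else groups
    labels = np.array(classification.labels)
    rows = []
    for gid, members in groups.items():
        cols = [j for j, rn in enumerate(matrix.residue_names)
                if rn in members]
        if not cols:
            warnings.warn(f"group {gid} has no member residues present",
                          stacklevel=2)
            continue
        for region in ("non-native", "native-like"):
            sel = matrix.values[np.ix_(labels == region, cols)]
            if sel.size == 0:
                continue
            rows.append({
                "group": gid,
                "group_label": GROUP_LABELS.get(gid, str(gid)),
                "region": region,
                "mean": float(sel.mean()),
                "sd": float(sel.std(ddof=0)),
                "n_cells": int(sel.size),
            })
    return pd.DataFrame(rows)


def residue_type_profile(matrices: list[TrajectoryDescriptorMatrix]
                         ) -> pd.DataFrame:
    """Pooled distribution summary per residue 3-letter code.

    Values from all frames of all matrices are pooled by residue type;
    the summary gives median, quartiles and extrema, comparable across
    proteins when the matrices were normalized consistently.
    """
    if not matrices:
        raise ValueError("no matrices")
    pooled: dict[str, list[np.ndarray]] = {}
    for m in matrices:
        for j, rn in enumerate(m.residue_names):
            pooled.setdefault(rn, []).append(m.values[:, j])
    rows = []
    for rn in sorted(pooled):
        v = np.concatenate(pooled[rn])
        rows.append({
            "residue": rn,
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "min": float(v.min()),
            "max": float(v.max()),
            "n": int(v.size),
        })
    return pd.DataFrame(rows)


def correlate_global(global_series: pd.DataFrame,
                     structural_series: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of global descriptors vs structural metrics.

    Returns the full symmetric pairwise R table over all columns of
    both inputs (aligned by position); zero-variance columns get NaN
    against every partner.
    """
    if len(global_series) != len(structural_series):
        raise ValueError("series not aligned")
    if len(global_series) < 3:
        raise ValueError("need at least 3 frames")
    joined = pd.concat(
        [global_series.reset_index(drop=True),
         structural_series.reset_index(drop=True)], axis=1)
    corr = joined.corr(method="pearson")
    np.fill_diagonal(corr.values,
                     np.where(joined.std().to_numpy() > 0, 1.0, np.nan))
    return corr
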