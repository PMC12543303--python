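"""Structure-function coupling statistics at every analysis level.

Coupling is always a Pearson correlation between matched SC and FC
quantities; what varies is the unit of correlation:

* subject-overall -- within one participant, across edges (whole
  connectome, within one network, or within the DMN);
* group-average -- across edges of the group-averaged SC and FC matrices;
* edge-wise -- across participants of one group, separately per edge;
* node-wise -- across participants of one group, separately per node,
  using nodal strengths (signed sum of incident edge weights).

Only direct connections enter any coupling: an FC edge with no structural
counterpart is dropped from edge-level couplings.  FC nodal strength, by
contrast, sums *all* functional edges of a node, not only those with SC
support, so that the functional strength is not truncated by the sparser
structural mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome_model import (
    AtlasDefinition,
    ConnectomeMatrix,
    SubjectRecord,
    vectorize,
)

#: Minimum (SC, FC) pairs for any reported correlation.
MIN_PAIRS = 3
#: Minimum subjects contributing to an edge-wise or node-wise correlation.
MIN_SUBJECTS = 10

_VAR_EPS = 1e-14


@dataclass
class CouplingResult:
    """Coupling correlations at one analysis level, with their sample sizes."""

    level: str  # subject_overall | group_average | edge | node
    modality: str
    scope: str = "whole"
    fc_sign_filter: str = "all"
    values: Mapping = field(default_factory=dict)
    n_pairs: Mapping = field(default_factory=dict)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson r; NaN if degenerate (zero variance or <MIN_PAIRS)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < MIN_PAIRS:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx <= _VAR_EPS or vy <= _VAR_EPS:
        return float("nan")
    return float(np.clip((xc @ yc) / np.sqrt(vx * vy), -1.0, 1.0))


def edge_scope_mask(atlas: AtlasDefinition, scope) -> np.ndarray:
    """Boolean mask over the N(N-1)/2 edge vector selecting a scope.

    ``scope`` is ``"whole"``, ``"dmn"`` (edges with both endpoints in the
    DMN), ``"network:<name>"`` (both endpoints in that network), or a
    custom boolean array of edge length.
    """
    iu, ju = np.triu_indices(atlas.n_nodes, k=1)
    if isinstance(scope, np.ndarray):
        if scope.shape != iu.shape:
            raise ValueError("custom scope mask has wrong length")
        return scope.astype(bool)
    if scope == "whole":
        return np.ones(iu.size, dtype=bool)
    if scope == "dmn":
        node_mask = np.asarray(atlas.is_dmn, dtype=bool)
    elif isinstance(scope, str) and scope.startswith("network:"):
        name = scope.split(":", 1)[1]
        node_mask = np.zeros(atlas.n_nodes, dtype=bool)
        node_mask[atlas.nodes_in_network(name)] = True
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return node_mask[iu] & node_mask[ju]


def _sign_mask(fc_values: np.ndarray, fc_sign_filter: str) -> np.ndarray:
    if fc_sign_filter == "all":
        return np.ones_like(fc_values, dtype=bool)
    if fc_sign_filter == "positive":
        return fc_values > 0
    if fc_sign_filter == "negative":
        return fc_values < 0
    raise ValueError(f"unknown fc_sign_filter {fc_sign_filter!r}")


def subject_coupling(
    subj: SubjectRecord,
    modality: str,
    scope="whole",
    fc_sign_filter: str = "all",
    atlas: AtlasDefinition | None = None,
) -> float:
    """Within-subject Pearson r between matched SC and FC edge weights.

    Pairs are edges that are structurally present, inside ``scope``, and
    (optionally) whose FC weight has the requested sign; FC edges that are
    exactly zero are excluded from the positive-only and negative-only
    variants.  Fewer than three usable pairs yields NaN with a warning.
    """
    sc = vectorize(subj.matrices[modality])
    fc = vectorize(subj.matrices["FC"])
    mask = sc.present & fc.present
    if scope != "whole" or isinstance(scope, np.ndarray):
        if atlas is None:
            raise ValueError("atlas is required for non-whole scopes")
        mask &= edge_scope_mask(atlas, scope)
    fc_vals = np.where(fc.present, fc.values, np.nan)
    mask &= _sign_mask(np.nan_to_num(fc_vals), fc_sign_filter)
    if mask.sum() < MIN_PAIRS:
        warnings.warn(
            f"subject {subj.subject_id}: only {int(mask.sum())} usable "
            f"(SC, FC) pairs; coupling undefined",
            stacklevel=2,
        )
        return float("nan")
    return _pearson(sc.values[mask], fc.values[mask])


def cohort_subject_coupling(
    subjects: Sequence[SubjectRecord],
    modality: str,
    scope="whole",
    fc_sign_filter: str = "all",
    atlas: AtlasDefinition | None = None,
) -> pd.Series:
    """Subject-overall coupling for every subject, indexed by subject_id."""
    return pd.Series(
        {
            s.subject_id: subject_coupling(s, modality, scope, fc_sign_filter, atlas)
            for s in subjects
        },
        name=f"{modality}_coupling",
    )


def stack_edges(subjects: Sequence[SubjectRecord], modality: str):
    """Stack SC and FC edge vectors into (n_subjects, n_edges) arrays.

    Absent edges are NaN.  This is the workhorse layout for edge-wise
    coupling and its permutation nulls.
    """
    sc_rows, fc_rows = [], []
    for s in subjects:
        sc = vectorize(s.matrices[modality])
        fc = vectorize(s.matrices["FC"])
        sc_rows.append(np.where(sc.present, sc.values, np.nan))
        fc_rows.append(np.where(fc.present, fc.values, np.nan))
    return np.asarray(sc_rows), np.asarray(fc_rows)


def nan_pearson_columns(
    x: np.ndarray, y: np.ndarray, min_n: int = MIN_SUBJECTS
) -> np.ndarray:
    """Column-wise Pearson r between x and y over rows where both are finite.

    Columns with fewer than ``min_n`` complete rows, or with zero variance
    in either variable, are NaN.  Vectorized over columns via moment sums.
    """
    m = np.isfinite(x) & np.isfinite(y)
    n = m.sum(axis=0)
    xf = np.where(m, x, 0.0)
    yf = np.where(m, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = xf.sum(axis=0)
        sy = yf.sum(axis=0)
        cov = (xf * yf).sum(axis=0) - sx * sy / n
        vx = (xf * xf).sum(axis=0) - sx * sx / n
        vy = (yf * yf).sum(axis=0) - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    bad = (n < max(min_n, MIN_PAIRS)) | (vx <= _VAR_EPS) | (vy <= _VAR_EPS)
    r = np.where(bad, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def group_average_coupling(
    subjects: Sequence[SubjectRecord],
    group: str,
    modality: str,
    scope="whole",
    atlas: AtlasDefinition | None = None,
):
    """Coupling of the group-averaged matrices: one Pearson r per group.

    Each SC and FC edge is first averaged over the group's participants
    (missing subjects ignored per edge), and the two mean edge vectors are
    then correlated over edges with at least one SC contributor.

    Returns ``(r, n_edges)``; ``n_edges`` is the number of edge pairs that
    entered the correlation (the effective n for a Fisher r-to-Z
    comparison of group-average couplings).
    """
    members = [s for s in subjects if s.group == group]
    if not members:
        raise ValueError(f"group {group!r} is empty")
    sc_stack, fc_stack = stack_edges(members, modality)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        sc_mean = np.nanmean(sc_stack, axis=0)
        fc_mean = np.nanmean(fc_stack, axis=0)
    mask = np.isfinite(sc_mean) & np.isfinite(fc_mean)
    if scope != "whole" or isinstance(scope, np.ndarray):
        if atlas is None:
            raise ValueError("atlas is required for non-whole scopes")
        mask &= edge_scope_mask(atlas, scope)
    return _pearson(sc_mean[mask], fc_mean[mask]), int(mask.sum())


def edge_wise_coupling(
    subjects: Sequence[SubjectRecord],
    group: str,
    modality: str,
    min_subjects: int = MIN_SUBJECTS,
) -> np.ndarray:
    """Per-edge Pearson r of SC vs FC across one group's participants.

    Each participant contributes one (SC, FC) value per edge; edges with
    fewer than ``min_subjects`` participants having the SC edge, or with
    zero cross-subject variance, are NaN.
    """
    members = [s for s in subjects if s.group == group]
    if not members:
        raise ValueError(f"group {group!r} is empty")
    sc_stack, fc_stack = stack_edges(members, modality)
    return nan_pearson_columns(sc_stack, fc_stack, min_n=min_subjects)


def node_strength(m: ConnectomeMatrix, node: int | None = None):
    """Signed sum of present incident edge weights (negative FC kept as-is).

    With ``node=None`` returns the full strength vector; nodes with no
    present incident edges are NaN.
    """
    filled = np.where(m.present, m.weights, 0.0)
    strengths = filled.sum(axis=1)
    isolated = ~m.present.any(axis=1)
    strengths = np.where(isolated, np.nan, strengths)
    if node is None:
        return strengths
    return float(strengths[node])


def stack_strengths(subjects: Sequence[SubjectRecord], modality: str):
    """(n_subjects, n_nodes) arrays of SC and FC nodal strengths.

    FC strength uses every functional edge of the node, not only those
    with a structural counterpart.
    """
    sc_rows = [node_strength(s.matrices[modality]) for s in subjects]
    fc_rows = [node_strength(s.matrices["FC"]) for s in subjects]
    return np.asarray(sc_rows), np.asarray(fc_rows)


def node_wise_coupling(
    subjects: Sequence[SubjectRecord],
    group: str,
    modality: str,
    min_subjects: int = MIN_SUBJECTS,
) -> np.ndarray:
    """Per-node Pearson r of SC vs FC nodal strength across one group."""
    members = [s for s in subjects if s.group == group]
    if not members:
        raise ValueError(f"group {group!r} is empty")
    sc_s, fc_s = stack_strengths(members, modality)
    return nan_pearson_columns(sc_s, fc_s, min_n=min_subjects)


def subject_dmn_coupling(
    subj: SubjectRecord, atlas: AtlasDefinition, modality: str
):
    """Per-subject DMN couplings: (within-DMN edge r, DMN node-strength r).

    The edge part correlates SC and FC weights over within-DMN edges with
    SC support.  The node part correlates SC and FC nodal strengths over
    the DMN nodes, where each strength sums *all* of the node's incident
    edges (whole-brain, not DMN-restricted) -- internetwork connections of
    DMN nodes therefore contribute to the nodal coupling.
    """
    edge_r = subject_coupling(subj, modality, scope="dmn", atlas=atlas)
    dmn = atlas.dmn_nodes
    sc_s = node_strength(subj.matrices[modality])[dmn]
    fc_s = node_strength(subj.matrices["FC"])[dmn]
    ok = np.isfinite(sc_s) & np.isfinite(fc_s)
    if ok.sum() < MIN_PAIRS:
        warnings.warn(
            f"subject {subj.subject_id}: fewer than {MIN_PAIRS} DMN nodes "
            "with defined strength",
            stacklevel=2,
        )
        node_r = float("nan")
    else:
        node_r = _pearson(sc_s[ok], fc_s[ok])
    return edge_r, node_r
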