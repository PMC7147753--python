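"""Temporal regulatory cascade construction.

The method identifies stage-specific regulators in a time series by
correlating each regulator's expression profile against a library of
*template peak patterns* (TPPs) — one-hot references that are 100% at one
time point and zero elsewhere — and assembles the survivors into a
stage-ordered cascade graph:

1. build one TPP per time point;
2. score every regulator's replicate-mean profile against every TPP
   (Pearson correlation) and assign it to its best stage if that
   correlation clears ``minC``, keeping at most ``maxS`` genes per stage;
3. map regulatory interactions *within* each stage column from the
   background network;
4. map interactions from each column to the next non-empty column,
   linking the stages into a cascade.

Genes whose expression never exceeds ``minE`` in any replicate or time
point of the raw matrix are dropped before scoring, so lowly expressed
genes cannot enter the cascade even with a perfectly peaked shape.

Because a TPP is one-hot, its Pearson correlation with a profile ``x``
over ``T`` time points has the closed form

    r_s = (x_s - mean(x)) / (sd_pop(x) * sqrt(T - 1))

which also yields the conservation law ``sum_s r_s**2 = T/(T-1)`` for any
non-constant profile: a gene cannot be strongly peak-correlated at many
stages at once, which is what makes single-peak templates stage-selective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TemplatePeakPattern",
    "TrcParameters",
    "StageAssignment",
    "TemporalCascade",
    "collapse_replicates",
    "build_tpp_library",
    "correlate_to_tpp",
    "tpp_correlation_matrix",
    "assign_stages",
    "build_cascade",
    "classify_interactions",
    "build_trc",
]

PEAK_LEVEL = 100.0  # template peak height, percent of maximum


@dataclass(frozen=True)
class TemplatePeakPattern:
    """One-hot reference profile: 100 at ``stage``, 0 at every other point."""

    stage: int
    n_timepoints: int

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("a TPP needs >= 2 time points")
        if not (0 <= self.stage < self.n_timepoints):
            raise ValueError(
                f"stage {self.stage} out of range for T={self.n_timepoints}"
            )

    @property
    def vector(self) -> np.ndarray:
        v = np.zeros(self.n_timepoints)
        v[self.stage] = PEAK_LEVEL
        return v


def build_tpp_library(n_timepoints: int) -> list[TemplatePeakPattern]:
    """One TPP per time point; T < 2 is rejected (correlation undefined)."""
    if n_timepoints < 2:
        raise ValueError(
            f"TPP library needs >= 2 time points, got {n_timepoints}"
        )
    return [TemplatePeakPattern(s, n_timepoints) for s in range(n_timepoints)]


@dataclass(frozen=True)
class TrcParameters:
    """The three cascade tuning parameters.

    minE
        Expression floor, in the matrix's own units.  A gene must exceed
        this value *strictly* in at least one replicate/time point of the
        raw matrix to take part at all.
    minC
        Minimum Pearson correlation to a stage's TPP for a gene to be
        associated with that stage.
    maxS
        Cap on the number of genes per stage column; the best-correlated
        genes are kept.  The cascade can hence never exceed maxS * T nodes.
    """

    minE: float = 4.0
    minC: float = 0.6
    maxS: int = 10

    def __post_init__(self) -> None:
        if self.minE < 0:
            raise ValueError(f"minE must be >= 0, got {self.minE}")
        if not (-1.0 <= self.minC <= 1.0):
            raise ValueError(f"minC must be in [-1, 1], got {self.minC}")
        if self.maxS < 1:
            raise ValueError(f"maxS must be >= 1, got {self.maxS}")


def collapse_replicates(ds: ExpressionDataset) -> pd.DataFrame:
    """Replicate-mean gene x time-point matrix, columns in time order."""
    return ds.collapse()


def correlate_to_tpp(profile: np.ndarray, tpp: TemplatePeakPattern) -> float:
    """Pearson correlation between a profile and a one-hot template.

    Returns NaN for zero-variance profiles, which are excluded from all
    downstream ranking (a flat gene has no peak stage).
    """
    x = np.asarray(profile, dtype=float)
    if x.shape != (tpp.n_timepoints,):
        raise ValueError(
            f"profile length {x.shape} does not match T={tpp.n_timepoints}"
        )
    sd = x.std()  # population sd
    if sd == 0:
        return float("nan")
    t = tpp.n_timepoints
    return float((x[tpp.stage] - x.mean()) / (sd * np.sqrt(t - 1)))


def tpp_correlation_matrix(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Correlation of every gene profile to every TPP, genes x stages.

    Uses the closed form of Pearson correlation against a one-hot vector;
    zero-variance rows come back as NaN.
    """
    x = collapsed.to_numpy(dtype=float)
    t = x.shape[1]
    if t < 2:
        raise ValueError("need >= 2 time points")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x - mean) / (sd * np.sqrt(t - 1))
    r[np.repeat(sd == 0, t, axis=1)] = np.nan
    return pd.DataFrame(r, index=collapsed.index, columns=range(t))


@dataclass(frozen=True)
class StageAssignment:
    """Stage-specific regulators: per time point, (gene, r) sorted by r desc.

    A gene belongs to at most one stage (its best-correlated one); stages
    with no qualifying gene carry no entry.
    """

    stages: tuple[tuple[int, tuple[tuple[str, float], ...]], ...]
    n_timepoints: int

    @classmethod
    def from_dict(
        cls, stages: dict[int, list[tuple[str, float]]], n_timepoints: int
    ) -> "StageAssignment":
        cols = tuple(
            (s, tuple(stages[s])) for s in sorted(stages) if stages[s]
        )
        return cls(cols, n_timepoints)

    def column(self, stage: int) -> list[tuple[str, float]]:
        for s, col in self.stages:
            if s == stage:
                return list(col)
        return []

    def genes(self, stage: int | None = None) -> list[str]:
        if stage is not None:
            return [g for g, _ in self.column(stage)]
        return [g for _, col in self.stages for g, _ in col]

    def stage_of(self) -> dict[str, int]:
        return {g: s for s, col in self.stages for g, _ in col}

    @property
    def stage_indices(self) -> list[int]:
        return [s for s, _ in self.stages]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s, "rank": i, "gene": g, "correlation": r}
            for s, col in self.stages
            for i, (g, r) in enumerate(col)
        ]
        return pd.DataFrame(rows, columns=["stage", "rank", "gene", "correlation"])


def assign_stages(
    ds: ExpressionDataset,
    regulators: Iterable[str],
    params: TrcParameters,
) -> StageAssignment:
    """Assign stage-specific regulators by TPP correlation.

    Filtering order: (i) the minE floor is applied to the *raw* matrix
    (a gene needs one strictly-greater value in any replicate or time
    point); (ii) only genes in the regulator universe are eligible;
    (iii) each survivor goes to its single best-correlated stage, kept
    only when that correlation reaches ``minC`` (ties between stages go
    to the earlier one); (iv) per stage the best ``maxS`` genes by
    correlation are retained (ties break by gene symbol for determinism).
    """
    regulators = {g for g in regulators}
    if not regulators:
        raise ValueError(
            "empty regulator universe — check the background network "
            "(its edge sources define who may enter the cascade)"
        )
    passes_min_e = ds.max_per_gene() > params.minE
    n_failed = int((~passes_min_e).sum())
    eligible = [g for g in ds.genes if passes_min_e[g] and g in regulators]
    logger.info(
        "minE=%g dropped %d/%d genes; %d eligible regulators remain",
        params.minE, n_failed, ds.n_genes, len(eligible),
    )
    collapsed = ds.collapse().loc[eligible]
    corr = tpp_correlation_matrix(collapsed)
    n_flat = int(corr.isna().all(axis=1).sum())
    if n_flat:
        logger.info("%d zero-variance profiles excluded", n_flat)

    stages: dict[int, list[tuple[str, float]]] = {}
    arr = corr.to_numpy()
    for i, gene in enumerate(corr.index):
        row = arr[i]
        if np.isnan(row).all():
            continue
        best = int(np.nanargmax(row))  # ties -> earlier stage
        r = float(row[best])
        if r >= params.minC:
            stages.setdefault(best, []).append((gene, r))
    for s in stages:
        stages[s].sort(key=lambda gr: (-gr[1], gr[0]))
        stages[s] = stages[s][: params.maxS]
        logger.debug("stage %d: %d regulators kept", s, len(stages[s]))
    return StageAssignment.from_dict(stages, ds.n_timepoints)


@dataclass(frozen=True)
class TemporalCascade:
    """The method's output: stage columns plus typed regulatory edges.

    ``stages`` holds the non-empty columns in time order; ``edges`` holds
    (source, source_stage, target, target_stage, type) tuples where type
    is ``within`` (same column) or ``cross`` (to the next non-empty
    column).  Node in/out degrees are computed on the cascade graph only.
    """

    stages: tuple[tuple[int, tuple[tuple[str, float], ...]], ...]
    edges: frozenset[tuple[str, int, str, int, str]] = field(
        default_factory=frozenset
    )

    @property
    def n_nodes(self) -> int:
        return sum(len(col) for _, col in self.stages)

    @property
    def stage_indices(self) -> list[int]:
        return [s for s, _ in self.stages]

    def genes(self) -> list[str]:
        return [g for _, col in self.stages for g, _ in col]

    def stage_of(self) -> dict[str, int]:
        return {g: s for s, col in self.stages for g, _ in col}

    def node_metrics(self) -> pd.DataFrame:
        """Per-node indegree/outdegree within the cascade graph."""
        indeg = {g: 0 for g in self.genes()}
        outdeg = {g: 0 for g in self.genes()}
        for src, _, tgt, _, _ in self.edges:
            outdeg[src] += 1
            indeg[tgt] += 1
        stage = self.stage_of()
        return pd.DataFrame(
            {
                "gene": list(indeg),
                "stage": [stage[g] for g in indeg],
                "indegree": list(indeg.values()),
                "outdegree": [outdeg[g] for g in indeg],
            }
        ).set_index("gene")


def build_cascade(
    assignment: StageAssignment, net: RegulatoryNetwork
) -> TemporalCascade:
    """Map within-stage and consecutive-stage edges from the network.

    Empty stages are skipped entirely: cross edges bridge each column to
    the *next non-empty* column, so a missing time point does not break
    the cascade's connectivity.
    """
    cols = assignment.stages
    edges: set[tuple[str, int, str, int, str]] = set()
    for idx, (s, col) in enumerate(cols):
        genes = [g for g, _ in col]
        for u, v in net.subnetwork(genes, genes):
            edges.add((u, s, v, s, "within"))
        if idx + 1 < len(cols):
            s_next, col_next = cols[idx + 1]
            next_genes = [g for g, _ in col_next]
            for u, v in net.subnetwork(genes, next_genes):
                edges.add((u, s, v, s_next, "cross"))
    return TemporalCascade(stages=cols, edges=frozenset(edges))


def classify_interactions(
    cascade: TemporalCascade,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label cascade edges and score candidate master regulators.

    Edge labels: a within-stage edge is ``one-way`` unless its reverse
    also exists (then both are ``reciprocal``); every cross-stage edge is
    labelled ``cross-stage``.  The node table reports each regulator's
    same-stage and next-stage out-fan — a node activating many same-stage
    or next-stage regulators is a candidate master regulator of that
    transition — ranked by fan size.
    """
    edge_set = cascade.edges
    rows = []
    for src, s_stage, tgt, t_stage, kind in sorted(edge_set):
        if kind == "within":
            reciprocal = (tgt, t_stage, src, s_stage, "within") in edge_set
            label = "reciprocal" if reciprocal else "one-way"
        else:
            label = "cross-stage"
        rows.append(
            {
                "source": src, "source_stage": s_stage,
                "target": tgt, "target_stage": t_stage,
                "type": kind, "pattern": label,
            }
        )
    edge_table = pd.DataFrame(
        rows,
        columns=["source", "source_stage", "target", "target_stage",
                 "type", "pattern"],
    )

    within_fan = {g: 0 for g in cascade.genes()}
    cross_fan = {g: 0 for g in cascade.genes()}
    for src, _, tgt, _, kind in edge_set:
        if src == tgt:
            continue
        if kind == "within":
            within_fan[src] += 1
        else:
            cross_fan[src] += 1
    stage = cascade.stage_of()
    node_table = pd.DataFrame(
        {
            "gene": list(within_fan),
            "stage": [stage[g] for g in within_fan],
            "same_stage_fan": list(within_fan.values()),
            "next_stage_fan": [cross_fan[g] for g in within_fan],
        }
    )
    node_table = node_table.sort_values(
        ["same_stage_fan", "next_stage_fan", "gene"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    return edge_table, node_table


def build_trc(
    ds: ExpressionDataset,
    net: RegulatoryNetwork,
    params: TrcParameters | None = None,
    restrict_to_regulators: bool = True,
) -> tuple[TemporalCascade, StageAssignment]:
    """Run the full construction: staging plus cascade edge mapping.

    With ``restrict_to_regulators=False`` every dataset gene is eligible
    for a stage column (the ablation control); edges are still drawn from
    the background network.
    """
    params = params or TrcParameters()
    eligible = net.regulators if restrict_to_regulators else set(ds.genes)
    assignment = assign_stages(ds, eligible, params)
    return build_cascade(assignment, net), assignment
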