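"""Synthetic benchmark fixtures with planted stage-specific regulators.

The generator emulates the structure of a differentiation time course:
a minority of regulator genes peak sharply at one time point (one-hot
profile plus truncated Gaussian noise) while background genes sit on
flat log-normal baselines, so the minE expression floor has realistic
bite.  A matched toy network plants within-stage and stage-to-next-stage
edges among the peaking regulators (plus random decoy edges), and a
matched annotation map gives each stage's planted set a dedicated term —
so every pipeline step has a ground truth to recover.

It is not a realistic RNA-seq count simulator: there is no library-size
or dispersion modelling, and noise is additive, not count-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import StageAssignment
from .dataset import ExpressionDataset
from .io import AnnotationMap, write_expression
from .network import RegulatoryNetwork

__all__ = ["PlantedDesign", "generate_planted", "write_fixture"]


@dataclass(frozen=True)
class PlantedDesign:
    """Parameters of the planted fixture.

    Defaults sketch a small differentiation course: 5 time points with
    duplicates, 8 planted peaking regulators per stage against 800
    background genes, a peak of 100 expression units over a baseline of
    1, additive Gaussian noise with sd 5 (5% of peak height, truncated
    at zero), and a 0.3 chance for each plantable within-/cross-stage
    regulator pair to carry a network edge.

    Half of the background genes act as decoy regulators (network
    sources with random targets), so the regulator universe is an order
    of magnitude larger than a stage column — as in real TF networks,
    where hundreds of TFs compete for a handful of column slots.  Each
    stage's dedicated annotation term holds its planted regulators plus
    ``n_term_downstream`` non-regulator background genes, mirroring GO
    terms that mix the controlling TFs with their downstream program.
    """

    n_timepoints: int = 5
    n_replicates: int = 2
    n_planted_per_stage: int = 8
    n_background: int = 800
    peak_height: float = 100.0
    baseline: float = 1.0
    noise_sd: float = 5.0
    network_density: float = 0.3
    n_term_downstream: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("need >= 2 time points")
        if self.n_replicates < 1 or self.n_planted_per_stage < 0 \
                or self.n_background < 0:
            raise ValueError("counts must be non-negative (replicates >= 1)")
        if not (self.peak_height > self.baseline >= 0):
            raise ValueError("need peak_height > baseline >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.network_density <= 1):
            raise ValueError("network_density must be in [0, 1]")
        if self.n_term_downstream < 0:
            raise ValueError("n_term_downstream must be >= 0")


def generate_planted(
    design: PlantedDesign,
) -> tuple[ExpressionDataset, RegulatoryNetwork, AnnotationMap, StageAssignment]:
    """Generate (dataset, network, annotations, truth) for one design.

    The truth is the planted stage assignment: which regulators peak at
    which time point.  With ``noise_sd=0`` every planted profile is an
    exact affine image of its stage's template, so its correlation is 1.
    """
    rng = np.random.default_rng(design.seed)
    t, r = design.n_timepoints, design.n_replicates

    planted: dict[int, list[str]] = {
        s: [f"TF{s}_{i:02d}" for i in range(design.n_planted_per_stage)]
        for s in range(t)
    }
    planted_genes = [g for s in range(t) for g in planted[s]]
    background = [f"GENE{i:04d}" for i in range(design.n_background)]
    genes = planted_genes + background

    samples = [f"T{tp}_r{rep + 1}" for tp in range(t) for rep in range(r)]
    time_index = np.repeat(np.arange(t), r)

    profiles = np.empty((len(genes), t))
    for row, s in enumerate(np.repeat(np.arange(t), design.n_planted_per_stage)):
        profiles[row] = design.baseline
        profiles[row, s] = design.peak_height
    # flat log-normal baselines for background genes
    base = rng.lognormal(mean=3.0, sigma=1.0, size=len(background))
    profiles[len(planted_genes):] = base[:, None]

    values = profiles[:, time_index]
    if design.noise_sd > 0:
        values = values + rng.normal(0.0, design.noise_sd, size=values.shape)
        values = np.clip(values, 0.0, None)
    vdf = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                       columns=samples)
    ds_design = pd.DataFrame(
        {
            "time": time_index.astype(float),
            "time_index": time_index,
            "replicate": np.tile(np.arange(r), t),
        },
        index=pd.Index(samples, name="sample"),
    )
    ds = ExpressionDataset(vdf, ds_design)

    # --- network: planted within/cross edges plus random decoys ------
    edges: set[tuple[str, str]] = set()
    for s in range(t):
        col = planted[s]
        for u in col:
            for v in col:
                if u != v and rng.random() < design.network_density:
                    edges.add((u, v))
        if s + 1 < t:
            for u in col:
                for v in planted[s + 1]:
                    if rng.random() < design.network_density:
                        edges.add((u, v))
    # every planted gene must be a network source (a regulator), or the
    # pipeline could never recover it
    for s in range(t):
        for u in planted[s]:
            if not any(e[0] == u for e in edges):
                peers = [g for g in planted[s] if g != u] or background or [u]
                edges.add((u, peers[int(rng.integers(len(peers)))]))
    # decoy regulators: half the background genes source random edges, so
    # the regulator universe dwarfs the stage columns (as real TF sets do)
    n_decoy = design.n_background // 2
    decoys = list(rng.choice(background, size=n_decoy, replace=False)) \
        if n_decoy else []
    for u in decoys:
        for _ in range(int(rng.poisson(3)) + 1):
            edges.add((str(u), genes[int(rng.integers(len(genes)))]))
    net = RegulatoryNetwork(frozenset(edges))

    # --- annotations: one dedicated term per planted stage + noise ----
    # a stage term holds its planted regulators plus downstream
    # non-regulator genes, like a GO process term mixing TFs and effectors
    non_regulators = [g for g in background if g not in set(decoys)]
    term_to_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for s in range(t):
        if not planted[s]:
            continue
        downstream = rng.choice(
            non_regulators,
            size=min(design.n_term_downstream, len(non_regulators)),
            replace=False,
        ) if non_regulators else []
        term_to_genes[f"GO:STAGE{s}"] = set(planted[s]) | set(map(str, downstream))
        term_names[f"GO:STAGE{s}"] = f"planted stage {s} program"
    term_to_genes["GO:ALL"] = set(genes)
    term_names["GO:ALL"] = "all fixture genes"
    for i in range(30):
        term_to_genes[f"GO:RAND{i:02d}"] = set(
            rng.choice(genes, size=min(15, len(genes)), replace=False)
        )
        term_names[f"GO:RAND{i:02d}"] = f"random control set {i}"
    annotations = AnnotationMap(term_to_genes, term_names)

    truth = StageAssignment.from_dict(
        {s: [(g, 1.0) for g in sorted(planted[s])] for s in range(t)
         if planted[s]},
        n_timepoints=t,
    )
    return ds, net, annotations, truth


def write_fixture(design: PlantedDesign, outdir) -> dict[str, Path]:
    """Materialize a fixture on disk in the package's standard formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, net, annotations, truth = generate_planted(design)
    paths = {
        "expression": outdir / "expression.csv",
        "network": outdir / "network.tsv",
        "annotations": outdir / "annotations.gmt",
        "truth": outdir / "planted_truth.csv",
    }
    write_expression(ds, paths["expression"])
    with open(paths["network"], "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
    with open(paths["annotations"], "w") as fh:
        for term in sorted(annotations.term_to_genes):
            genes = "\t".join(sorted(annotations.term_to_genes[term]))
            fh.write(f"{term}\t{annotations.name(term)}\t{genes}\n")
    truth.to_frame().to_csv(paths["truth"], index=False)
    return paths
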