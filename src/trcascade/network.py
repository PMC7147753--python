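"""Background regulatory network and its construction from binding scores.

The background network is a directed regulator -> target graph, built
independently of any expression dataset.  It can be supplied directly as
an edge list, or derived from a table of scored binding-site predictions
(e.g. PWM scan scores over promoters): for each PWM the best-scoring
fraction of its predicted sites is retained, and each retained
(PWM, target) site becomes an edge from every TF gene the PWM maps to.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .dataset import normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "build_network",
    "retained_count",
    "read_predictions",
    "read_pwm_map",
]


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Directed regulator -> target graph (deduplicated edge set)."""

    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @classmethod
    def from_edge_list(cls, edges: Iterable[tuple[str, str]]) -> "RegulatoryNetwork":
        return cls(frozenset(
            (normalize_symbol(u), normalize_symbol(v)) for u, v in edges
        ))

    @property
    def regulators(self) -> frozenset[str]:
        """The regulator universe: every gene appearing as an edge source."""
        return frozenset(u for u, _ in self.edges)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(v for _, v in self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def subnetwork(
        self, sources: Iterable[str], sinks: Iterable[str]
    ) -> set[tuple[str, str]]:
        """Edges running from ``sources`` into ``sinks``."""
        src = set(sources)
        snk = set(sinks)
        return {(u, v) for u, v in self.edges if u in src and v in snk}


def retained_count(n_sites: int, top_fraction: float) -> int:
    """Number of sites kept for a PWM with ``n_sites`` ranked predictions.

    The best ``top_fraction`` of each PWM's sites are kept, rounded up,
    with a floor of one so that every scored PWM contributes at least its
    single best site.
    """
    return min(n_sites, max(1, math.ceil(top_fraction * n_sites)))


def build_network(
    predictions: pd.DataFrame,
    pwm_map: Mapping[str, Iterable[str]],
    top_fraction: float = 0.05,
) -> RegulatoryNetwork:
    """Build the background network from scored binding predictions.

    Parameters
    ----------
    predictions
        DataFrame with columns ``pwm_id``, ``target``, ``score``; one row
        per predicted binding site.  A (pwm, target) pair may repeat when
        several sites were predicted for the same promoter.
    pwm_map
        Map from PWM id to the TF gene symbol(s) it represents.  PWMs
        shared within a TF family may map to several genes; each retained
        site fans out to an edge for every mapped gene.
    top_fraction
        Fraction of each PWM's sites to keep, ranked by score descending
        (default 0.05, i.e. the best 5% per PWM).

    Ties at the score cutoff break by (score desc, target asc, input
    order) so that results are deterministic.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if not pwm_map:
        raise ValueError("empty PWM -> gene map")
    required = {"pwm_id", "target", "score"}
    if not required.issubset(predictions.columns):
        raise ValueError(f"predictions table needs columns {sorted(required)}")
    pwm_map = {
        str(p): frozenset(normalize_symbol(g) for g in gs)
        for p, gs in pwm_map.items()
    }
    edges: set[tuple[str, str]] = set()
    n_skipped = 0
    df = predictions.assign(
        _order=range(len(predictions)),
        target=[normalize_symbol(t) for t in predictions["target"]],
    )
    for pwm, grp in df.groupby("pwm_id", sort=True):
        genes = pwm_map.get(str(pwm))
        if not genes:
            n_skipped += 1
            continue
        ranked = grp.sort_values(
            ["score", "target", "_order"], ascending=[False, True, True]
        )
        keep = ranked.head(retained_count(len(ranked), top_fraction))
        for target in keep["target"]:
            for g in genes:
                edges.add((g, target))
    if n_skipped:
        logger.info("%d PWM(s) absent from the PWM->gene map; skipped", n_skipped)
    return RegulatoryNetwork(frozenset(edges))


def read_predictions(path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited binding-prediction table (pwm_id, target, score)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        df = df.rename(
            columns={cols["pwm_id"]: "pwm_id", cols["target"]: "target",
                     cols["score"]: "score"}
        )
    except KeyError:
        if df.shape[1] != 3:
            raise ValueError(
                f"{path}: expected columns pwm_id, target, score"
            ) from None
        df.columns = ["pwm_id", "target", "score"]
    df["score"] = pd.to_numeric(df["score"])
    if not df["score"].map(math.isfinite).all():
        raise ValueError(f"{path}: non-finite score in prediction table")
    return df[["pwm_id", "target", "score"]]


def read_pwm_map(path, sep: str | None = None) -> dict[str, frozenset[str]]:
    """Read a two-column PWM-id -> TF-gene map (one pair per line)."""
    out: dict[str, set[str]] = {}
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in (line.split(sep) if sep else line.replace(
                ",", "\t").replace(";", "\t").split("\t")) if f.strip()]
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            gene = normalize_symbol(fields[1])
            if not gene:
                raise ValueError(f"{path}:{lineno}: empty gene symbol")
            out.setdefault(fields[0].strip(), set()).add(gene)
    return {p: frozenset(g) for p, g in out.items()}
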