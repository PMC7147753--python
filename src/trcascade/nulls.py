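"""Dataset randomizations used as null-model controls.

Three randomizations probe whether stage-specific enrichment could arise
by chance: re-assigning gene labels to other expression profiles (all
genes, or regulators only), permuting every cell of the matrix, and
replacing the matrix with random values.  All are explicitly seeded; the
first two conserve the value multiset exactly.  A fourth control drops
the regulator restriction to show that non-regulatory genes dilute the
stage sets.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .core import TemporalCascade, TrcParameters, build_trc
from .dataset import ExpressionDataset
from .network import RegulatoryNetwork

__all__ = [
    "shuffle_profile_assignment",
    "permute_matrix",
    "random_dataset",
    "unrestricted_cascade",
]


def shuffle_profile_assignment(
    ds: ExpressionDataset,
    seed: int,
    scope: str = "all-genes",
    regulators: Iterable[str] | None = None,
) -> ExpressionDataset:
    """Re-assign gene labels to other expression profiles.

    ``scope='all-genes'`` permutes every row label; ``'regulators-only'``
    permutes labels within the supplied regulator set and leaves all
    other rows untouched.  Each profile stays bit-identical to some
    original row; only which gene owns it changes.
    """
    if scope not in {"all-genes", "regulators-only"}:
        raise ValueError(f"unknown scope {scope!r}")
    rng = np.random.default_rng(seed)
    values = ds.values.copy()
    if scope == "all-genes":
        pool = list(values.index)
    else:
        if regulators is None:
            raise ValueError("regulators-only scope needs a regulator set")
        reg = set(regulators)
        pool = [g for g in values.index if g in reg]
    if len(pool) < 2:
        raise ValueError(
            f"profile shuffle needs >= 2 genes in scope, got {len(pool)}"
        )
    perm = rng.permutation(len(pool))
    shuffled = values.loc[pool].to_numpy()[perm]
    values.loc[pool] = shuffled
    return ds.replace_values(values)


def permute_matrix(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Uniformly permute all cells across rows and columns.

    Destroys both profile shapes and gene identities while conserving the
    multiset of values exactly.
    """
    rng = np.random.default_rng(seed)
    arr = ds.values.to_numpy(dtype=float)
    flat = rng.permutation(arr.ravel())
    values = pd.DataFrame(
        flat.reshape(arr.shape), index=ds.values.index, columns=ds.values.columns
    )
    return ds.replace_values(values)


def random_dataset(
    template: ExpressionDataset,
    seed: int,
    distribution: Callable[[np.random.Generator, tuple[int, int]], np.ndarray]
    | None = None,
) -> ExpressionDataset:
    """Fresh random values on the template's genes, samples and design.

    By default values are i.i.d. uniform on [0, max(template)]; pass a
    callable ``(rng, shape) -> array`` for a different sampling rule.
    """
    rng = np.random.default_rng(seed)
    shape = template.values.shape
    if distribution is None:
        hi = float(template.values.to_numpy().max())
        arr = rng.uniform(0.0, hi, size=shape)
    else:
        arr = np.asarray(distribution(rng, shape), dtype=float)
        if arr.shape != shape:
            raise ValueError(
                f"distribution returned shape {arr.shape}, expected {shape}"
            )
    values = pd.DataFrame(
        arr, index=template.values.index, columns=template.values.columns
    )
    return template.replace_values(values)


def unrestricted_cascade(
    ds: ExpressionDataset,
    net: RegulatoryNetwork,
    params: TrcParameters | None = None,
) -> TemporalCascade:
    """Ablation: stage sets drawn from *all* dataset genes, not regulators.

    Edges still come from the background network, so non-regulator nodes
    typically sit disconnected — the control shows how non-regulatory
    genes crowd out the small stage-specific regulator sets.
    """
    cascade, _ = build_trc(ds, net, params, restrict_to_regulators=False)
    return cascade
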