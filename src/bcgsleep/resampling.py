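"""SMOTE oversampling of minority sleep stages.

New minority samples are convex interpolations X_i + lambda (X_i^NN - X_i)
with lambda ~ U(0,1) and X_i^NN one of the k nearest same-class neighbours
(Euclidean distance on z-scored features).  Original rows are preserved
verbatim; by default every class is raised to the majority count.  Meant
for training folds only — never for validation or test rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .selection import split_features_labels, zscore


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    strategy: dict[str, int] | None = None  # target count per class; None = full balance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote_resample(
    table: pd.DataFrame,
    config: SmoteConfig | None = None,
    return_provenance: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Oversample minority classes; returns (table, synthetic_row_mask).

    The returned table holds all original rows first (verbatim), then the
    synthetic rows; the boolean mask flags the synthetic ones.  With
    ``return_provenance`` a third element lists, per synthetic row, the
    original-row indices of its two parents and the interpolation lambda.
    """
    config = config or SmoteConfig()
    X_df, y = split_features_labels(table)
    X = X_df.to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    targets = config.strategy or {c: int(counts.max()) for c in classes}
    rng = np.random.default_rng(config.seed)
    Xz = zscore(X)

    new_rows, new_labels, provenance = [], [], []
    for c in classes:
        target = targets.get(c, 0)
        sel = np.nonzero(y == c)[0]
        deficit = target - len(sel)
        if deficit <= 0:
            continue
        if len(sel) <= config.k_neighbors:
            raise ValueError(
                f"class {c!r} has {len(sel)} samples; needs > k={config.k_neighbors}"
            )
        nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(Xz[sel])
        _, idx = nn.kneighbors(Xz[sel])
        neigh = idx[:, 1:]  # drop self
        anchors = rng.integers(0, len(sel), size=deficit)
        picks = neigh[anchors, rng.integers(0, config.k_neighbors, size=deficit)]
        lam = rng.uniform(0.0, 1.0, size=deficit)[:, None]
        xi = X[sel[anchors]]
        xnn = X[sel[picks]]
        new_rows.append(xi + lam * (xnn - xi))
        new_labels.extend([c] * deficit)
        provenance.extend(
            zip(sel[anchors].tolist(), sel[picks].tolist(), lam[:, 0].tolist())
        )

    if not new_rows:
        empty = (table.copy(), np.zeros(len(table), dtype=bool))
        return (*empty, []) if return_provenance else empty
    synth = pd.DataFrame(np.vstack(new_rows), columns=X_df.columns)
    synth["stage"] = new_labels
    out = pd.concat([table.reset_index(drop=True), synth], ignore_index=True)
    mask = np.zeros(len(out), dtype=bool)
    mask[len(table):] = True
    if return_provenance:
        return out, mask, provenance
    return out, mask


def interpolate(xi: np.ndarray, xnn: np.ndarray, lam: float) -> np.ndarray:
    """The SMOTE interpolation rule: xi + lam (xnn - xi)."""
    xi = np.asarray(xi, dtype=float)
    return xi + lam * (np.asarray(xnn, dtype=float) - xi)
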