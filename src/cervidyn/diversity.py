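"""Alpha diversity (Chao1, Simpson's evenness, Faith's PD) and Bray-Curtis.

Computations delegate to scikit-bio, fixed to the conventions used
throughout this package:

- Chao1 uses the bias-corrected estimator
  ``S_obs + F1*(F1-1)/(2*(F2+1))`` so samples without doubletons are defined.
- Simpson's evenness is inverse-Simpson divided by observed richness,
  ``E = (1 / sum p_i^2) / S_obs``, in (0, 1].
- Faith's PD sums the branch lengths of the minimal subtree connecting the
  present taxa, including the path to the root.
- Bray-Curtis is computed on relative abundances (an option allows raw
  counts for parity with count-based workflows).
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .io import RelAbundanceTable, TaxaCountTable


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate from an integer count vector."""
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.all(np.mod(counts, 1) == 0):
        raise ValueError("counts must be non-negative integers")
    if counts.sum() == 0:
        raise ValueError("zero-depth sample")
    return float(_skbio_chao1(counts.astype(np.int64), bias_corrected=True))


def simpson_evenness(rel) -> float:
    """Inverse-Simpson evenness E = (1 / sum p_i^2) / S_obs, in (0, 1]."""
    rel = np.asarray(rel, dtype=float)
    total = rel.sum()
    if total <= 0 or np.any(rel < 0):
        raise ValueError("empty sample")
    p = rel / total
    s_obs = int((p > 0).sum())
    return float(1.0 / np.sum(p**2) / s_obs)


def faith_pd(present_taxa: Iterable[str], tree: TreeNode) -> float:
    """Total branch length of the minimal rooted subtree spanning the taxa.

    The path from the spanning subtree up to the root is included. Raises if
    any requested taxon is not a leaf of the tree.
    """
    present = list(dict.fromkeys(present_taxa))
    if not present:
        return 0.0
    tips = [t.name for t in tree.tips()]
    missing = set(present) - set(tips)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    indicator = np.array([1 if t in present else 0 for t in tips])
    return float(_skbio_faith_pd(indicator, tips, tree))


def bray_curtis_matrix(rel: RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities over all valid samples."""
    ids, values = rel.valid_subset()
    if len(ids) < 2:
        raise ValueError("need at least two valid samples")
    return beta_diversity("braycurtis", values, ids=ids)


def bray_curtis_from_counts(table: TaxaCountTable) -> DistanceMatrix:
    """Bray-Curtis on raw counts (count-based convention)."""
    depths = table.counts.sum(axis=1)
    keep = depths > 0
    ids = [s for s, ok in zip(table.sample_ids, keep) if ok]
    return beta_diversity("braycurtis", table.counts[keep], ids=ids)


def alpha_diversity_table(
    table: TaxaCountTable, tree: Optional[TreeNode] = None
) -> pd.DataFrame:
    """Per-sample alpha-diversity summary.

    Columns: sample_id, observed_richness, chao1, simpson_evenness,
    faith_pd (NaN when no tree is supplied), valid (False for zero-depth
    samples, whose metric columns are NaN).
    """
    rows = []
    for sid, counts in zip(table.sample_ids, table.counts):
        depth = counts.sum()
        if depth == 0:
            rows.append(
                {
                    "sample_id": sid,
                    "observed_richness": 0,
                    "chao1": np.nan,
                    "simpson_evenness": np.nan,
                    "faith_pd": np.nan,
                    "valid": False,
                }
            )
            continue
        present = [t for t, c in zip(table.taxon_names, counts) if c > 0]
        rows.append(
            {
                "sample_id": sid,
                "observed_richness": len(present),
                "chao1": chao1(counts),
                "simpson_evenness": simpson_evenness(counts),
                "faith_pd": faith_pd(present, tree) if tree is not None else np.nan,
                "valid": True,
            }
        )
    return pd.DataFrame(rows)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )
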