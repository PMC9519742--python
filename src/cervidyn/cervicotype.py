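"""Rule-based cervicotype (CT) assignment.

A sample's relative-abundance vector is mapped to one of four community
classes:

- **CT1** — at least half of the community is non-*iners* *Lactobacillus*
  (typically *L. crispatus*); the rule sums over all *Lactobacillus* taxa
  except *L. iners*, including genus-level *Lactobacillus* reads without a
  species call.
- **CT2** — *Lactobacillus iners* holds the plurality of reads.
- **CT3** — *Gardnerella vaginalis* holds the plurality.
- **CT4** — mixed community with no single dominant taxon from the rules
  above (anaerobe-rich, BV-associated).

The rules are total and exclusive: every positive-depth sample receives
exactly one label. Degenerate exact ties at the maximum are resolved by the
fixed precedence CT2 > CT3 > CT4 (ties have measure zero in real data).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .io import RelAbundanceTable

CERVICOTYPES = ("CT1", "CT2", "CT3", "CT4")
LACTO_CTS = ("CT1", "CT2")
BV_CTS = ("CT3", "CT4")

L_INERS = "Lactobacillus iners"
G_VAGINALIS = "Gardnerella vaginalis"


def is_lactobacillus(name: str) -> bool:
    return name.strip().casefold().startswith("lactobacillus")


@lru_cache(maxsize=64)
def _masks(taxon_names: tuple[str, ...]):
    """Precomputed index structures for a taxon panel."""
    folded = [t.strip().casefold() for t in taxon_names]
    noniners = np.array(
        [is_lactobacillus(t) and f != L_INERS.casefold() for t, f in zip(taxon_names, folded)]
    )
    iners_idx = folded.index(L_INERS.casefold()) if L_INERS.casefold() in folded else -1
    gvag_idx = folded.index(G_VAGINALIS.casefold()) if G_VAGINALIS.casefold() in folded else -1
    return noniners, iners_idx, gvag_idx


def _as_simplex(rel: np.ndarray) -> np.ndarray:
    rel = np.asarray(rel, dtype=float)
    total = rel.sum()
    if not np.isfinite(total) or total <= 0 or np.any(rel < 0):
        raise ValueError("invalid sample: abundances must be non-negative with positive sum")
    return rel / total


def noniners_lactobacillus_fraction(rel: Sequence[float], taxon_names: Sequence[str]) -> float:
    """Summed relative abundance of all *Lactobacillus* taxa except *L. iners*."""
    rel = _as_simplex(np.asarray(rel))
    noniners, _, _ = _masks(tuple(taxon_names))
    return float(rel[noniners].sum())


def assign_cervicotype(rel: Sequence[float], taxon_names: Sequence[str]) -> str:
    """Assign one cervicotype to a relative-abundance (or count) vector.

    Counts are accepted and normalized internally, so assignment is
    scale-invariant.
    """
    rel = _as_simplex(np.asarray(rel))
    noniners, iners_idx, gvag_idx = _masks(tuple(taxon_names))
    if rel[noniners].sum() >= 0.5:
        return "CT1"
    top = rel.max()
    if iners_idx >= 0 and rel[iners_idx] == top:
        return "CT2"
    if gvag_idx >= 0 and rel[gvag_idx] == top:
        return "CT3"
    return "CT4"


def assign_all(rel: RelAbundanceTable) -> dict[str, str]:
    """One label per valid sample; zero-depth samples are omitted."""
    taxa = tuple(rel.taxon_names)
    return {
        sid: assign_cervicotype(rel.values[i], taxa)
        for i, sid in enumerate(rel.sample_ids)
        if rel.valid[i]
    }


def assignment_table(rel: RelAbundanceTable):
    """Per-sample assignment detail for export.

    Columns: sample_id, cervicotype, noniners_lacto_fraction, argmax_taxon.
    """
    import pandas as pd

    taxa = tuple(rel.taxon_names)
    rows = []
    for i, sid in enumerate(rel.sample_ids):
        if not rel.valid[i]:
            continue
        vec = rel.values[i]
        rows.append(
            {
                "sample_id": sid,
                "cervicotype": assign_cervicotype(vec, taxa),
                "noniners_lacto_fraction": noniners_lactobacillus_fraction(vec, taxa),
                "argmax_taxon": taxa[int(np.argmax(vec))],
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "cervicotype", "noniners_lacto_fraction", "argmax_taxon"])


def ct_frequencies(labels: Mapping[str, str]) -> dict[str, float]:
    """Empirical cervicotype frequencies of a label map."""
    n = len(labels)
    if n == 0:
        return {ct: float("nan") for ct in CERVICOTYPES}
    return {ct: sum(1 for v in labels.values() if v == ct) / n for ct in CERVICOTYPES}
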