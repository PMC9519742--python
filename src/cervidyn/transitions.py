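"""Stratified cervicotype transition counts and probabilities.

For every subject and every pair of consecutive visits with both endpoints
observed, one transition is tallied into the 4x4 count matrix of that
interval's stratum (by default the study group crossed with antibiotic use
at the interval's starting visit — treatment dispensed at a visit acts
during the following interval). Gaps are never bridged: a subject missing
month 3 contributes no baseline-to-month-6 transition. Probabilities are
raw row proportions with no pseudocounts; rows with no observations carry
NaN with an explicit ``row_defined`` marker rather than a fake
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cervicotype import CERVICOTYPES
from .io import MISSING, VISITS, SampleRecord

STRATIFIERS = ("group", "antibiotic_use", "interval")

_CT_INDEX = {ct: i for i, ct in enumerate(CERVICOTYPES)}


@dataclass(frozen=True)
class CTSequence:
    """A subject's ordered visit labels; ``None`` marks a missing visit."""

    subject_id: str
    labels: tuple[Optional[str], ...]

    def n_observed(self) -> int:
        return sum(1 for l in self.labels if l is not None)


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-stratum 4x4 transition counts and optional row-normalized probs."""

    stratum: tuple[tuple[str, object], ...]  # sorted (covariate, value) pairs
    counts: np.ndarray
    probs: Optional[np.ndarray] = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (4, 4) or np.any(counts < 0):
            raise ValueError("counts must be a non-negative 4x4 matrix")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if self.probs is not None:
            probs = np.asarray(self.probs, dtype=float)
            row_sums = np.nansum(probs, axis=1)
            defined = ~np.isnan(probs).all(axis=1)
            if np.any(np.abs(row_sums[defined] - 1.0) > 1e-9):
                raise ValueError("defined probability rows must sum to 1")
            object.__setattr__(self, "probs", probs)

    @property
    def stratum_dict(self) -> dict:
        return dict(self.stratum)

    @property
    def row_defined(self) -> np.ndarray:
        return self.counts.sum(axis=1) > 0

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


def build_ct_sequences(
    labels: Mapping[tuple[str, str], str],
    metadata: Sequence[SampleRecord],
    visits: Sequence[str] = VISITS,
) -> list[CTSequence]:
    """One ordered label sequence per subject; missing visits become gaps."""
    subjects = sorted({r.subject_id for r in metadata})
    known = set(subjects)
    for subj, _ in labels:
        if subj not in known:
            raise ValueError(f"label for unknown subject {subj!r}")
    return [
        CTSequence(subj, tuple(labels.get((subj, v)) for v in visits))
        for subj in subjects
    ]


def build_transition_counts(
    seqs: Sequence[CTSequence],
    metadata: Sequence[SampleRecord],
    stratify_by: Sequence[str] = ("group", "antibiotic_use"),
    visits: Sequence[str] = VISITS,
) -> list[TransitionMatrix]:
    """Tally transitions over consecutive observed visit pairs, per stratum.

    ``stratify_by`` may contain any of ``group``, ``antibiotic_use`` and
    ``interval``; an empty list pools everything into one matrix. A missing
    antibiotic flag at the starting visit becomes the stratum value ``"NA"``
    so that pooled counts always equal the sum over strata.
    """
    unknown = set(stratify_by) - set(STRATIFIERS)
    if unknown:
        raise ValueError(f"unknown covariate(s): {sorted(unknown)}")
    meta = {(r.subject_id, r.visit): r for r in metadata}
    strata: dict[tuple, np.ndarray] = {}
    for seq in seqs:
        for i in range(len(visits) - 1):
            a, b = seq.labels[i], seq.labels[i + 1]
            if a is None or b is None:
                continue
            rec = meta.get((seq.subject_id, visits[i]))
            values = {}
            if "group" in stratify_by:
                values["group"] = rec.group if rec else MISSING
            if "antibiotic_use" in stratify_by:
                flag = rec.antibiotic_use if rec else None
                values["antibiotic_use"] = MISSING if flag is None else flag
            if "interval" in stratify_by:
                values["interval"] = f"{visits[i]}->{visits[i + 1]}"
            key = tuple(sorted(values.items(), key=lambda kv: kv[0]))
            mat = strata.setdefault(key, np.zeros((4, 4), dtype=np.int64))
            mat[_CT_INDEX[a], _CT_INDEX[b]] += 1
    return [
        TransitionMatrix(key, strata[key])
        for key in sorted(strata, key=lambda k: tuple(map(str, k)))
    ]


def normalize_transitions(tm: TransitionMatrix) -> TransitionMatrix:
    """Populate raw row-proportion probabilities; empty rows stay NaN."""
    counts = tm.counts
    row_sums = counts.sum(axis=1)
    probs = np.full((4, 4), np.nan)
    for i in range(4):
        if row_sums[i] > 0:
            probs[i] = counts[i] / row_sums[i]
    return replace(tm, probs=probs)


def transition_edge_list(
    tms: Sequence[TransitionMatrix], min_prob: float = 0.0
) -> pd.DataFrame:
    """Flatten matrices into a deterministic (stratum, from, to) edge table."""
    rows = []
    for tm in tms:
        if tm.probs is None:
            raise ValueError("normalize_transitions must be applied first")
        stratum_label = ";".join(f"{k}={v}" for k, v in tm.stratum) or "all"
        for i, src in enumerate(CERVICOTYPES):
            for j, dst in enumerate(CERVICOTYPES):
                p = tm.probs[i, j]
                if np.isnan(p) or p < min_prob:
                    continue
                rows.append(
                    {
                        "stratum": stratum_label,
                        "from": src,
                        "to": dst,
                        "count": int(tm.counts[i, j]),
                        "prob": p,
                    }
                )
    df = pd.DataFrame(rows, columns=["stratum", "from", "to", "count", "prob"])
    return df.sort_values(["stratum", "from", "to"], kind="stable").reset_index(drop=True)


def write_transition_tables(tms: Sequence[TransitionMatrix], counts_path, probs_path) -> None:
    """Write stacked per-stratum counts and probs TSVs (deterministic order)."""
    count_rows, prob_rows = [], []
    for tm in tms:
        stratum_label = ";".join(f"{k}={v}" for k, v in tm.stratum) or "all"
        for i, src in enumerate(CERVICOTYPES):
            crow = {"stratum": stratum_label, "from": src}
            crow.update({dst: int(tm.counts[i, j]) for j, dst in enumerate(CERVICOTYPES)})
            count_rows.append(crow)
            if tm.probs is not None:
                prow = {"stratum": stratum_label, "from": src}
                prow.update(
                    {
                        dst: (MISSING if np.isnan(tm.probs[i, j]) else f"{tm.probs[i, j]:.6f}")
                        for j, dst in enumerate(CERVICOTYPES)
                    }
                )
                prob_rows.append(prow)
    pd.DataFrame(count_rows).to_csv(counts_path, sep="\t", index=False)
    if prob_rows:
        pd.DataFrame(prob_rows).to_csv(probs_path, sep="\t", index=False)
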