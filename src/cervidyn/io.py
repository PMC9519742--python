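"""Core table types and TSV/Newick readers and writers.

The pipeline's primary input is a samples x taxa count table of 16S read
counts at species (where resolvable) or genus level, plus a per-sample
clinical metadata table covering a three-visit longitudinal design
(baseline, month 3, month 6) with PrEP group membership, antibiotic use,
Nugent score, STI status and vaginal pH. All on-disk formats are plain
tab-separated UTF-8 with ``NA`` as the missing-value sentinel; trees are
Newick.

This module also packages the transition counts and cross-tabulations
printed for the 100-woman cohort the pipeline was designed around, so the
worked examples can be recomputed without any sequence data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

MISSING = "NA"

#: Ordered study visits.
VISITS = ("baseline", "month3", "month6")

#: Study arms.
GROUPS = ("PrEP", "nonPrEP")

#: Abbreviation -> canonical taxon name, applied (case-insensitively) when
#: reading taxa tables. The cervicotype rules key on exact names, so common
#: shorthand must be folded onto the controlled vocabulary at the door.
TAXON_ALIASES = {
    "g. vaginalis": "Gardnerella vaginalis",
    "gardnerella": "Gardnerella vaginalis",
    "l. crispatus": "Lactobacillus crispatus",
    "l. iners": "Lactobacillus iners",
    "l. jensenii": "Lactobacillus jensenii",
    "l. gasseri": "Lactobacillus gasseri",
    "l. vaginalis": "Lactobacillus vaginalis",
    "a. vaginae": "Atopobium vaginae",
    "p. bivia": "Prevotella bivia",
    "s. amnii": "Sneathia amnii",
}


def normalize_taxon_name(name: str) -> str:
    """Trim whitespace and resolve known abbreviations to canonical names."""
    clean = " ".join(str(name).split())
    return TAXON_ALIASES.get(clean.casefold(), clean)


# ---------------------------------------------------------------------------
# Count and relative-abundance tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxaCountTable:
    """Samples x taxa table of non-negative integer read counts."""

    sample_ids: tuple[str, ...]
    taxon_names: tuple[str, ...]
    counts: np.ndarray  # shape (n_samples, n_taxa), integer

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.taxon_names)):
            raise ValueError("counts shape does not match sample/taxon axes")
        if len(self.taxon_names) == 0:
            raise ValueError("table must have at least one taxon column")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.mod(counts, 1) == 0):
                raise ValueError("non-integer count")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("negative count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise ValueError("duplicate taxon names")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_names", tuple(str(t) for t in self.taxon_names))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.taxon_names)
        )


@dataclass(frozen=True)
class RelAbundanceTable:
    """Samples x taxa proportions; zero-depth rows are flagged, not zeroed.

    ``values`` rows for invalid (zero-depth) samples are NaN so they can
    never be mistaken for real compositions.
    """

    sample_ids: tuple[str, ...]
    taxon_names: tuple[str, ...]
    values: np.ndarray  # shape (n_samples, n_taxa), floats
    valid: np.ndarray  # shape (n_samples,), bool

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if values.shape != (len(self.sample_ids), len(self.taxon_names)):
            raise ValueError("values shape does not match sample/taxon axes")
        if valid.shape != (len(self.sample_ids),):
            raise ValueError("valid flag shape mismatch")
        sums = values[valid].sum(axis=1) if valid.any() else np.empty(0)
        if sums.size and np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("valid rows must sum to 1 within 1e-9")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)

    @property
    def valid_sample_ids(self) -> tuple[str, ...]:
        return tuple(s for s, ok in zip(self.sample_ids, self.valid) if ok)

    def row(self, sample_id: str) -> np.ndarray:
        i = self.sample_ids.index(sample_id)
        if not self.valid[i]:
            raise ValueError(f"sample {sample_id!r} has zero depth")
        return self.values[i]

    def valid_subset(self) -> tuple[list[str], np.ndarray]:
        """IDs and value matrix restricted to valid rows (order preserved)."""
        ids = [s for s, ok in zip(self.sample_ids, self.valid) if ok]
        return ids, self.values[self.valid]


def to_relative_abundance(table: TaxaCountTable) -> RelAbundanceTable:
    """Row-normalize counts; rows with zero depth are flagged invalid."""
    depths = table.counts.sum(axis=1)
    valid = depths > 0
    values = np.full(table.counts.shape, np.nan)
    if valid.any():
        values[valid] = table.counts[valid] / depths[valid, None]
    return RelAbundanceTable(table.sample_ids, table.taxon_names, values, valid)


def read_taxa_table(path) -> TaxaCountTable:
    """Read a TSV with sample IDs in the first column and taxa as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("empty table")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample IDs")
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric count: {exc}") from None
    if np.any(~np.isfinite(counts)) or np.any(np.mod(counts, 1) != 0):
        raise ValueError("non-integer count")
    if np.any(counts < 0):
        raise ValueError("negative count")
    taxa = tuple(normalize_taxon_name(c) for c in df.columns)
    return TaxaCountTable(tuple(df.index.astype(str)), taxa, counts.astype(np.int64))


def write_taxa_table(table: TaxaCountTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """Clinical and longitudinal covariates for one sample (one visit)."""

    sample_id: str
    subject_id: str
    visit: str
    group: str
    antibiotic_use: Optional[bool] = None
    nugent_score: Optional[int] = None
    sti_positive: Optional[bool] = None
    vaginal_ph: Optional[float] = None

    def __post_init__(self):
        if self.visit not in VISITS:
            raise ValueError(f"unknown visit level {self.visit!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group level {self.group!r}")
        if self.nugent_score is not None and not 0 <= self.nugent_score <= 10:
            raise ValueError(f"Nugent score {self.nugent_score} outside 0-10")
        if self.vaginal_ph is not None and self.vaginal_ph <= 0:
            raise ValueError("vaginal pH must be positive")


METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "visit",
    "group",
    "antibiotic_use",
    "nugent_score",
    "sti_positive",
    "vaginal_ph",
)


def _parse_bool(token: str) -> Optional[bool]:
    if token == MISSING:
        return None
    if token in ("True", "TRUE", "true", "1", "yes"):
        return True
    if token in ("False", "FALSE", "false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {token!r}")


def read_metadata(path) -> list[SampleRecord]:
    """Parse the metadata TSV into validated records.

    Raises on duplicated (subject, visit) pairs, unknown visit/group levels,
    or out-of-range Nugent scores.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS[:4]) - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing metadata columns: {sorted(missing_cols)}")
    records = []
    for _, row in df.iterrows():
        nugent = row.get("nugent_score", MISSING)
        ph = row.get("vaginal_ph", MISSING)
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                subject_id=row["subject_id"],
                visit=row["visit"],
                group=row["group"],
                antibiotic_use=_parse_bool(row.get("antibiotic_use", MISSING)),
                nugent_score=None if nugent == MISSING else int(nugent),
                sti_positive=_parse_bool(row.get("sti_positive", MISSING)),
                vaginal_ph=None if ph == MISSING else float(ph),
            )
        )
    keys = [(r.subject_id, r.visit) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicated (subject, visit) pair")
    if len({r.sample_id for r in records}) != len(records):
        raise ValueError("duplicate sample IDs in metadata")
    return records


def _format_value(v) -> str:
    if v is None:
        return MISSING
    if isinstance(v, bool):
        return "TRUE" if v else "FALSE"
    return str(v)


def write_metadata(records: Sequence[SampleRecord], path) -> None:
    rows = [
        {col: _format_value(getattr(r, col)) for col in METADATA_COLUMNS}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees (Faith's PD support)
# ---------------------------------------------------------------------------


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; negative branch lengths are rejected."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Packaged worked-example fixtures
# ---------------------------------------------------------------------------

#: Aggregate community classes used where only pooled moves were recorded.
BV_CLASS = "BV"  # BV-associated cervicotypes (CT3 + CT4 pooled)
LACTO_CLASS = "Lacto"  # Lactobacillus-dominated cervicotypes (CT1 + CT2 pooled)


@dataclass(frozen=True)
class InPaperTransitionFixture:
    """Transcribed per-stratum cervicotype transition counts.

    Rows carry (group, interval, from_state, to_state, count). Where only a
    pooled move was recorded (BV-associated -> Lactobacillus-dominated) the
    class labels ``BV``/``Lacto`` are used instead of individual CTs; they
    are deliberately never expanded into per-CT guesses.
    """

    rows: pd.DataFrame = field(repr=False)

    def row_total(self, group: str, interval: str, from_state: str) -> int:
        sel = self._select(group, interval, from_state)
        return int(sel["count"].sum())

    def count(self, group: str, interval: str, from_state: str, to_state: str) -> int:
        sel = self._select(group, interval, from_state)
        sel = sel[sel["to_state"] == to_state]
        return int(sel["count"].sum())

    def prob(self, group: str, interval: str, from_state: str, to_state: str) -> float:
        """Row-normalized transition proportion, exactly as printed counts imply."""
        total = self.row_total(group, interval, from_state)
        if total == 0:
            raise ValueError("undefined transition probability: empty row")
        return self.count(group, interval, from_state, to_state) / total

    def _select(self, group, interval, from_state) -> pd.DataFrame:
        r = self.rows
        return r[
            (r["group"] == group)
            & (r["interval"] == interval)
            & (r["from_state"] == from_state)
        ]


def _load_packaged_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("cervidyn").joinpath("data", name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype={"count": int})


def load_inpaper_fixture() -> InPaperTransitionFixture:
    """Load the packaged transition-count fixture (``transitions_inpaper.tsv``)."""
    rows = _load_packaged_tsv("transitions_inpaper.tsv")
    if (rows["count"] < 0).any():
        raise ValueError("fixture contains a negative count")
    return InPaperTransitionFixture(rows)


def load_inpaper_crosstabs() -> dict[str, pd.DataFrame]:
    """Packaged cross-tabulation counts for the baseline cohort.

    Returns pivoted count tables keyed by name:

    - ``ct_by_bv``: cervicotype x Nugent >= 4 (yes/no), denominators as printed
      over the full 100-woman cohort;
    - ``ct_by_sti``: cervicotype x STI-positive (yes/no);
    - ``nugent_by_group``: Nugent category (0-3 / 4-6 / 7-10) x study group at
      baseline (denominators 61 PrEP / 36 non-PrEP after missing results).
    """
    raw = _load_packaged_tsv("crosstabs_inpaper.tsv")
    out = {}
    for name, sub in raw.groupby("table"):
        out[name] = sub.pivot(index="row", columns="col", values="count").fillna(0).astype(int)
    return out
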