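"""End-to-end run orchestration and figure-style data exports.

``run_pipeline`` chains simulation (or file loading), cervicotype
assignment, stratified transition estimation, alpha/beta diversity,
per-timepoint NMDS and PERMANOVA (PrEP vs non-PrEP), and cross-tabulations
of cervicotype against clinical labels, writing every stage as TSV plus a
machine-readable ``report.json``. Reruns with identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cervicotype import CERVICOTYPES, assign_all, assignment_table, ct_frequencies
from .diversity import alpha_diversity_table, bray_curtis_matrix, write_distance_matrix
from .io import (
    MISSING,
    VISITS,
    SampleRecord,
    TaxaCountTable,
    read_metadata,
    read_taxa_table,
    read_tree,
    to_relative_abundance,
    write_metadata,
    write_taxa_table,
    write_tree,
)
from .simulate import SimulationConfig, generate_cohort
from .stats import chi_square_rxc, fisher_exact_2x2, nmds, permanova
from .transitions import (
    build_ct_sequences,
    build_transition_counts,
    normalize_transitions,
    transition_edge_list,
    write_transition_tables,
)

NUGENT_BINS = ("0-3", "4-6", "7-10")


def nugent_category(score: Optional[int]) -> Optional[str]:
    """Map a 0-10 Nugent score onto the no-BV / intermediate / BV bins."""
    if score is None:
        return None
    if not 0 <= score <= 10:
        raise ValueError(f"Nugent score {score} outside 0-10")
    if score <= 3:
        return "0-3"
    if score <= 6:
        return "4-6"
    return "7-10"


def crosstab_ct_clinical(
    cts: Mapping[str, str],
    metadata: Sequence[SampleRecord],
    variable: str,
    visit: str = "baseline",
):
    """Cervicotype x clinical-category counts at one visit, with a test.

    ``variable`` is ``nugent_category`` or ``sti``. 2x2 tables get Fisher's
    exact test; larger tables a Pearson chi-square (flagged when any
    expected cell is below 5). Samples lacking either a label or the
    clinical value are dropped.
    """
    if variable not in ("nugent_category", "sti"):
        raise ValueError(f"unknown variable {variable!r}")
    pairs = []
    for rec in metadata:
        if rec.visit != visit or rec.sample_id not in cts:
            continue
        if variable == "nugent_category":
            value = nugent_category(rec.nugent_score)
        else:
            value = None if rec.sti_positive is None else ("pos" if rec.sti_positive else "neg")
        if value is not None:
            pairs.append((cts[rec.sample_id], value))
    if not pairs:
        raise ValueError("no overlap between labels and metadata")
    df = pd.DataFrame(pairs, columns=["cervicotype", variable])
    table = pd.crosstab(df["cervicotype"], df[variable])
    table = table.reindex(index=[ct for ct in CERVICOTYPES if ct in table.index])
    test: dict = {"test": None, "statistic": None, "df": None, "p_value": None, "warning": None}
    nonzero = table.loc[table.sum(axis=1) > 0, table.columns[table.sum(axis=0) > 0]]
    if nonzero.shape[0] >= 2 and nonzero.shape[1] >= 2:
        if nonzero.shape == (2, 2):
            test.update(test="fisher_exact", p_value=fisher_exact_2x2(nonzero.to_numpy()))
        else:
            stat, dof = chi_square_rxc(nonzero.to_numpy())
            expected = np.outer(nonzero.sum(axis=1), nonzero.sum(axis=0)) / nonzero.to_numpy().sum()
            test.update(test="chi_square", statistic=stat, df=dof)
            from scipy.stats import chi2

            test["p_value"] = float(chi2.sf(stat, dof))
            if (expected < 5).any():
                test["warning"] = "expected cell count < 5"
    else:
        test["warning"] = "degenerate table: test undefined"
    return table, test


def export_heatmap_matrix(rel, cts: Mapping[str, str], top_n: int = 15) -> pd.DataFrame:
    """Samples ordered by cervicotype then dominant-taxon abundance, top taxa.

    Mirrors a community heat map: rows grouped CT1..CT4, within each block
    sorted by descending abundance of the sample's dominant taxon; columns
    are the ``top_n`` taxa by mean relative abundance across valid samples.
    """
    ids, values = rel.valid_subset()
    order_cols = np.argsort(-values.mean(axis=0), kind="stable")[: min(top_n, values.shape[1])]
    taxa = [rel.taxon_names[i] for i in order_cols]
    rows = []
    for sid, vec in zip(ids, values):
        if sid not in cts:
            continue
        rows.append((cts[sid], -vec.max(), sid, vec[order_cols]))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return pd.DataFrame(
        [r[3] for r in rows],
        index=[r[2] for r in rows],
        columns=taxa,
    )


def export_ct_timelines(seqs) -> pd.DataFrame:
    """Per-subject visit x cervicotype table; gaps encoded as ``NA``."""
    return pd.DataFrame(
        [
            {"subject_id": s.subject_id, **{v: (l if l is not None else MISSING) for v, l in zip(VISITS, s.labels)}}
            for s in seqs
        ],
        columns=["subject_id", *VISITS],
    )


@dataclasses.dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    version: str
    seed: Optional[int]
    n_permutations: int
    config: Optional[dict]
    ct_frequencies_by_visit: dict
    crosstabs: dict
    transition_matrices: list
    permanova_by_visit: dict
    nmds_by_visit: dict
    excluded_samples: list

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunReport":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def run_pipeline(
    out_dir,
    config: Optional[SimulationConfig] = None,
    taxa_path=None,
    metadata_path=None,
    tree_path=None,
    n_permutations: int = 9999,
    stratify_by: Sequence[str] = ("group", "antibiotic_use"),
    nmds_restarts: int = 20,
    seed: Optional[int] = None,
) -> RunReport:
    """Run every stage and write all outputs under ``out_dir``.

    Either a :class:`SimulationConfig` (self-contained synthetic run) or
    paths to taxa/metadata(/tree) TSVs must be provided. ``seed`` drives the
    stochastic statistics (PERMANOVA permutations, NMDS restarts); for
    simulated runs it defaults to the config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is not None:
        cohort = generate_cohort(config)
        table, metadata, tree = cohort.taxa_table, list(cohort.metadata), cohort.tree
        write_taxa_table(table, out / "taxa_counts.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        write_tree(tree, out / "tree.nwk")
        config_echo = config.to_dict()
        if seed is None:
            seed = config.seed
    elif taxa_path is not None and metadata_path is not None:
        table = read_taxa_table(taxa_path)
        metadata = read_metadata(metadata_path)
        tree = read_tree(tree_path) if tree_path else None
        config_echo = None
        if seed is None:
            seed = 0
    else:
        raise ValueError("provide either a SimulationConfig or taxa + metadata paths")

    rel = to_relative_abundance(table)
    excluded = [s for s, ok in zip(rel.sample_ids, rel.valid) if not ok]
    cts = assign_all(rel)
    assignment_table(rel).to_csv(out / "cervicotypes.tsv", sep="\t", index=False)

    meta_by_sample = {r.sample_id: r for r in metadata}
    labels = {
        (meta_by_sample[s].subject_id, meta_by_sample[s].visit): ct
        for s, ct in cts.items()
        if s in meta_by_sample
    }
    seqs = build_ct_sequences(labels, metadata)
    export_ct_timelines(seqs).to_csv(out / "ct_timelines.tsv", sep="\t", index=False)

    tms = [normalize_transitions(tm) for tm in build_transition_counts(seqs, metadata, stratify_by)]
    write_transition_tables(tms, out / "transition_counts.tsv", out / "transition_probs.tsv")
    transition_edge_list(tms).to_csv(out / "transition_edges.tsv", sep="\t", index=False)

    alpha_diversity_table(table, tree).to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
    export_heatmap_matrix(rel, cts).to_csv(out / "heatmap_matrix.tsv", sep="\t", index_label="sample_id")

    ct_freqs, permanova_res, nmds_res = {}, {}, {}
    rng = np.random.default_rng(seed)
    for visit in VISITS:
        visit_samples = [
            r.sample_id for r in metadata if r.visit == visit and r.sample_id in cts
        ]
        ct_freqs[visit] = ct_frequencies({s: cts[s] for s in visit_samples})
        if len(visit_samples) < 3:
            continue
        sub = _subset_rel(rel, visit_samples)
        dm = bray_curtis_matrix(sub)
        write_distance_matrix(dm, out / f"braycurtis_{visit}.tsv")
        groups = [meta_by_sample[s].group for s in dm.ids]
        if len(set(groups)) == 2 and min(groups.count(g) for g in set(groups)) >= 2:
            res = permanova(dm, groups, n_permutations=n_permutations, seed=int(rng.integers(2**31)))
            permanova_res[visit] = {
                "pseudo_F": res.pseudo_f,
                "R2": res.r_squared,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        ord_res = nmds(dm, n_restarts=nmds_restarts, seed=int(rng.integers(2**31)))
        pd.DataFrame(
            ord_res.coordinates, index=dm.ids, columns=[f"NMDS{i + 1}" for i in range(ord_res.coordinates.shape[1])]
        ).to_csv(out / f"nmds_{visit}.tsv", sep="\t", index_label="sample_id")
        nmds_res[visit] = {"stress": ord_res.stress, "converged": ord_res.converged}

    crosstabs = {}
    for variable in ("nugent_category", "sti"):
        try:
            tab, test = crosstab_ct_clinical(cts, metadata, variable)
        except ValueError:
            continue
        crosstabs[variable] = {"counts": {str(i): {str(c): int(v) for c, v in row.items()} for i, row in tab.iterrows()}, "test": test}

    report = RunReport(
        version=__version__,
        seed=seed,
        n_permutations=n_permutations,
        config=config_echo,
        ct_frequencies_by_visit=ct_freqs,
        crosstabs=crosstabs,
        transition_matrices=[
            {
                "stratum": {k: v for k, v in tm.stratum},
                "counts": tm.counts.tolist(),
                "probs": [[None if np.isnan(p) else p for p in row] for row in tm.probs],
            }
            for tm in tms
        ],
        permanova_by_visit=permanova_res,
        nmds_by_visit=nmds_res,
        excluded_samples=excluded,
    )
    report.to_json(out / "report.json")
    return report


def _subset_rel(rel, sample_ids):
    from .io import RelAbundanceTable

    idx = [rel.sample_ids.index(s) for s in sample_ids]
    return RelAbundanceTable(
        tuple(sample_ids), rel.taxon_names, rel.values[idx], rel.valid[idx]
    )
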