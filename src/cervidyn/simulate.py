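"""Seeded synthetic longitudinal cohort generator.

Emulates a 100-subject, three-visit cohort: each subject is assigned to the
PrEP or non-PrEP arm, her baseline cervicotype is drawn from the observed
baseline distribution, and subsequent states follow a Markov chain whose
row-stochastic matrix depends on (group, antibiotic use at the preceding
visit). Antibiotic use is itself drawn per visit conditional on the current
cervicotype (mirroring metronidazole treatment of high-Nugent women).
Compositions are drawn from cervicotype-specific Dirichlet distributions
and rejection-sampled until the rule-based classifier agrees with the
intended label, so the simulated ground truth is exact by construction.
Read counts are multinomial at a negative-binomial depth; Nugent category,
STI flag and vaginal pH are drawn from cervicotype-conditional label
models. A random rooted binary tree over the taxon panel supports Faith's
PD.

Default parameters reproduce the observed cohort's marginal structure:
baseline cervicotype distribution (0.11, 0.47, 0.26, 0.16), group split
0.64/0.36, per-cervicotype Nugent >= 4 rates (0.18, 0.36, 0.73, 0.88) and
STI rates (0.10, 0.13, 0.23, 0.25), and stratum transition matrices
assembled from the reported transition-diagram entries with remaining
probability mass spread uniformly over unreported destinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from skbio import TreeNode

from .cervicotype import CERVICOTYPES, assign_cervicotype
from .io import GROUPS, VISITS, SampleRecord, TaxaCountTable

#: Desk-scale taxon panel covering the key community members the
#: classification rules reference plus common BV-associated anaerobes.
TAXON_PANEL = (
    "Lactobacillus crispatus",
    "Lactobacillus iners",
    "Lactobacillus jensenii",
    "Lactobacillus gasseri",
    "Lactobacillus vaginalis",
    "Lactobacillus sp.",
    "Gardnerella vaginalis",
    "Prevotella bivia",
    "Prevotella amnii",
    "Prevotella timonensis",
    "Sneathia amnii",
    "Sneathia sanguinegens",
    "Atopobium vaginae",
    "Megasphaera sp.",
    "Mobiluncus curtisii",
    "Mobiluncus mulieris",
    "Dialister sp.",
    "Aerococcus christensenii",
    "Peptoniphilus sp.",
    "Anaerococcus tetradius",
)

NUGENT_CATEGORIES = ("0-3", "4-6", "7-10")
_NUGENT_RANGES = {"0-3": (0, 3), "4-6": (4, 6), "7-10": (7, 10)}

_CT_INDEX = {ct: i for i, ct in enumerate(CERVICOTYPES)}


def _row(pinned: Mapping[int, float]) -> np.ndarray:
    """Build a stochastic row from pinned entries, rest uniform."""
    row = np.full(4, np.nan)
    for j, p in pinned.items():
        row[j] = p
    free = np.isnan(row)
    rest = 1.0 - np.nansum(row)
    if free.any():
        row[free] = rest / free.sum()
    return row


def default_transition_matrices() -> dict[tuple[str, bool], np.ndarray]:
    """Stratum matrices assembled from the reported diagram entries.

    Keys are (group, antibiotic_use). Reported entries: PrEP CT1 self 0.5;
    CT2 self 0.62 in both groups; PrEP/no-abx CT3 self 0.47 and CT4 self
    1.00; PrEP/abx CT3 -> CT2 0.55 and CT4 self 0.56; non-PrEP CT1 -> CT2
    0.6 and CT4 -> CT2 0.38. Unreported mass is spread uniformly.
    """
    prep_noabx = np.vstack([_row({0: 0.5}), _row({1: 0.62}), _row({2: 0.47}), _row({3: 1.0})])
    prep_abx = np.vstack([_row({0: 0.5}), _row({1: 0.62}), _row({1: 0.55}), _row({3: 0.56})])
    nonprep = np.vstack([_row({1: 0.6}), _row({1: 0.62}), _row({}), _row({1: 0.38})])
    return {
        ("PrEP", False): prep_noabx,
        ("PrEP", True): prep_abx,
        ("nonPrEP", False): nonprep,
        ("nonPrEP", True): nonprep.copy(),
    }


def default_dirichlet_params() -> dict[str, np.ndarray]:
    """Dirichlet concentrations over :data:`TAXON_PANEL`, one per cervicotype."""
    base = np.full(len(TAXON_PANEL), 0.15)
    idx = {t: i for i, t in enumerate(TAXON_PANEL)}

    ct1 = base.copy()
    ct1[idx["Lactobacillus crispatus"]] = 24.0
    ct1[idx["Lactobacillus jensenii"]] = 2.0
    ct1[idx["Lactobacillus gasseri"]] = 1.5
    ct1[idx["Lactobacillus vaginalis"]] = 0.5
    ct1[idx["Lactobacillus sp."]] = 0.5
    ct1[idx["Lactobacillus iners"]] = 2.0
    ct1[idx["Gardnerella vaginalis"]] = 0.8

    ct2 = base.copy()
    ct2[idx["Lactobacillus iners"]] = 25.0
    ct2[idx["Lactobacillus crispatus"]] = 1.0
    ct2[idx["Gardnerella vaginalis"]] = 2.0
    ct2[idx["Prevotella bivia"]] = 1.0

    ct3 = base.copy()
    ct3[idx["Gardnerella vaginalis"]] = 22.0
    ct3[idx["Lactobacillus iners"]] = 2.0
    ct3[idx["Prevotella bivia"]] = 2.0
    ct3[idx["Atopobium vaginae"]] = 2.0
    ct3[idx["Sneathia amnii"]] = 1.0

    ct4 = base.copy()
    for t, c in {
        "Gardnerella vaginalis": 3.0,
        "Lactobacillus iners": 3.0,
        "Prevotella bivia": 4.0,
        "Prevotella amnii": 3.0,
        "Prevotella timonensis": 2.0,
        "Sneathia amnii": 4.0,
        "Sneathia sanguinegens": 2.0,
        "Atopobium vaginae": 4.0,
        "Megasphaera sp.": 3.0,
        "Mobiluncus curtisii": 1.5,
        "Mobiluncus mulieris": 1.5,
        "Dialister sp.": 2.0,
        "Aerococcus christensenii": 1.5,
        "Peptoniphilus sp.": 1.5,
        "Anaerococcus tetradius": 1.5,
    }.items():
        ct4[idx[t]] = c
    return {"CT1": ct1, "CT2": ct2, "CT3": ct3, "CT4": ct4}


@dataclass
class SimulationConfig:
    """All generative parameters of the synthetic cohort.

    ``depth_dispersion`` is the negative-binomial shape; ``None`` makes the
    read depth deterministic at ``depth_mean``. Antibiotic probabilities
    track the per-cervicotype Nugent >= 4 rates, since high-Nugent visits
    trigger metronidazole treatment.
    """

    seed: int = 0
    n_subjects: int = 100
    visits: tuple[str, ...] = VISITS
    group_probs: dict = field(default_factory=lambda: {"PrEP": 0.64, "nonPrEP": 0.36})
    baseline_ct_probs: tuple[float, ...] = (0.11, 0.47, 0.26, 0.16)
    transition_matrices: dict = field(default_factory=default_transition_matrices)
    antibiotic_prob_given_ct: dict = field(
        default_factory=lambda: {"CT1": 0.18, "CT2": 0.36, "CT3": 0.73, "CT4": 0.88}
    )
    dirichlet_params: dict = field(default_factory=default_dirichlet_params)
    taxon_names: tuple[str, ...] = TAXON_PANEL
    depth_mean: float = 10000.0
    depth_dispersion: Optional[float] = 10.0
    nugent_probs_given_ct: dict = field(
        default_factory=lambda: {
            "CT1": (0.82, 0.108, 0.072),
            "CT2": (0.64, 0.216, 0.144),
            "CT3": (0.27, 0.438, 0.292),
            "CT4": (0.12, 0.528, 0.352),
        }
    )
    sti_prob_given_ct: dict = field(
        default_factory=lambda: {"CT1": 0.10, "CT2": 0.13, "CT3": 0.23, "CT4": 0.25}
    )
    rejection_cap: int = 1000

    def validate(self) -> None:
        pi = np.asarray(self.baseline_ct_probs, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
            raise ValueError("baseline_ct_probs must be a probability vector")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        gp = np.array([self.group_probs.get(g, 0.0) for g in GROUPS], dtype=float)
        if abs(gp.sum() - 1.0) > 1e-9 or np.any(gp < 0):
            raise ValueError("group_probs must sum to 1 over the study arms")
        for key, mat in self.transition_matrices.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (4, 4) or np.any(mat < 0):
                raise ValueError(f"transition matrix {key}: must be non-negative 4x4")
            if np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"transition matrix {key}: non-stochastic row")
        for ct, alpha in self.dirichlet_params.items():
            if np.any(np.asarray(alpha, dtype=float) <= 0):
                raise ValueError(f"Dirichlet concentrations for {ct} must be > 0")
            if len(alpha) != len(self.taxon_names):
                raise ValueError(f"Dirichlet parameter length mismatch for {ct}")
        if self.depth_mean <= 0:
            raise ValueError("non-positive mean depth")
        for mapping in (self.antibiotic_prob_given_ct, self.sti_prob_given_ct):
            for ct, p in mapping.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability for {ct} outside [0, 1]")
        for ct, probs in self.nugent_probs_given_ct.items():
            probs = np.asarray(probs, dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
                raise ValueError(f"Nugent category probabilities for {ct} must sum to 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "visits": list(self.visits),
            "group_probs": dict(self.group_probs),
            "baseline_ct_probs": list(self.baseline_ct_probs),
            "transition_matrices": {
                f"{g}|abx={int(bool(a))}": np.asarray(m).tolist()
                for (g, a), m in self.transition_matrices.items()
            },
            "antibiotic_prob_given_ct": dict(self.antibiotic_prob_given_ct),
            "dirichlet_params": {k: np.asarray(v).tolist() for k, v in self.dirichlet_params.items()},
            "taxon_names": list(self.taxon_names),
            "depth_mean": self.depth_mean,
            "depth_dispersion": self.depth_dispersion,
            "nugent_probs_given_ct": {k: list(v) for k, v in self.nugent_probs_given_ct.items()},
            "sti_prob_given_ct": dict(self.sti_prob_given_ct),
            "rejection_cap": self.rejection_cap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        tms = {}
        for key, mat in d.get("transition_matrices", {}).items():
            group, abx = key.split("|abx=")
            tms[(group, bool(int(abx)))] = np.asarray(mat, dtype=float)
        d["transition_matrices"] = tms or default_transition_matrices()
        d["visits"] = tuple(d.get("visits", VISITS))
        d["baseline_ct_probs"] = tuple(d.get("baseline_ct_probs", (0.11, 0.47, 0.26, 0.16)))
        d["taxon_names"] = tuple(d.get("taxon_names", TAXON_PANEL))
        if "dirichlet_params" in d:
            d["dirichlet_params"] = {k: np.asarray(v, dtype=float) for k, v in d["dirichlet_params"].items()}
        if "nugent_probs_given_ct" in d:
            d["nugent_probs_given_ct"] = {k: tuple(v) for k, v in d["nugent_probs_given_ct"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TrajectorySet:
    """Ground-truth cervicotype trajectories with their stratum covariates."""

    labels: dict  # (subject_id, visit) -> CT
    groups: dict  # subject_id -> group
    antibiotics: dict  # (subject_id, visit) -> bool


@dataclass(frozen=True)
class SyntheticCohort:
    taxa_table: TaxaCountTable
    metadata: tuple[SampleRecord, ...]
    tree: TreeNode
    true_ct_labels: dict  # (subject_id, visit) -> CT
    config: SimulationConfig


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _subject_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def simulate_ct_trajectories(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> TrajectorySet:
    """Draw per-subject cervicotype trajectories under the stratum chains.

    Baseline states come from the baseline distribution; each later state is
    drawn from the row of the subject's (group, antibiotic-at-previous-visit)
    matrix indexed by the previous state. Antibiotic use at each visit is
    drawn conditional on the current cervicotype.
    """
    config.validate()
    if rng is None:
        rng = _child_rngs(config.seed, 5)[0]
    groups_arr = rng.choice(
        GROUPS, size=config.n_subjects, p=[config.group_probs.get(g, 0.0) for g in GROUPS]
    )
    labels, groups, antibiotics = {}, {}, {}
    pi = np.asarray(config.baseline_ct_probs, dtype=float)
    for sid, group in zip(_subject_ids(config.n_subjects), groups_arr):
        groups[sid] = str(group)
        state = int(rng.choice(4, p=pi))
        for v, visit in enumerate(config.visits):
            if v > 0:
                matrix = np.asarray(config.transition_matrices[(groups[sid], prev_abx)], dtype=float)
                state = int(rng.choice(4, p=matrix[state]))
            ct = CERVICOTYPES[state]
            labels[(sid, visit)] = ct
            abx = bool(rng.random() < config.antibiotic_prob_given_ct.get(ct, 0.0))
            antibiotics[(sid, visit)] = abx
            prev_abx = abx
    return TrajectorySet(labels, groups, antibiotics)


def simulate_composition(ct: str, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw rejection-sampled until the classifier returns ``ct``."""
    alpha = np.asarray(config.dirichlet_params[ct], dtype=float)
    taxa = tuple(config.taxon_names)
    for _ in range(config.rejection_cap):
        vec = rng.dirichlet(alpha)
        if assign_cervicotype(vec, taxa) == ct:
            return vec
    raise RuntimeError(
        f"rejection sampling failed for {ct} after {config.rejection_cap} attempts; "
        "Dirichlet concentrations are inconsistent with the classification rules"
    )


def simulate_counts(rel: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Multinomial read counts at a negative-binomial depth."""
    if config.depth_mean <= 0:
        raise ValueError("non-positive mean depth")
    rel = np.asarray(rel, dtype=float)
    if config.depth_dispersion is None:
        depth = int(round(config.depth_mean))
    else:
        k = config.depth_dispersion
        p = k / (k + config.depth_mean)
        depth = 0
        while depth == 0:
            depth = int(rng.negative_binomial(k, p))
    return rng.multinomial(depth, rel)


def _draw_nugent(ct: str, config: SimulationConfig, rng: np.random.Generator) -> int:
    cat = NUGENT_CATEGORIES[int(rng.choice(3, p=np.asarray(config.nugent_probs_given_ct[ct])))]
    lo, hi = _NUGENT_RANGES[cat]
    return int(rng.integers(lo, hi + 1))


def simulate_clinical(
    ct_labels: Mapping[tuple[str, str], str],
    config: SimulationConfig,
    rng: np.random.Generator,
    antibiotics: Optional[Mapping[tuple[str, str], bool]] = None,
) -> dict:
    """Draw Nugent score, STI flag, pH (and antibiotic flag if not given).

    When trajectories were simulated, their antibiotic flags should be
    passed through so the clinical record matches the stratum that actually
    drove the transitions.
    """
    out = {}
    for key in sorted(ct_labels):
        ct = ct_labels[key]
        nugent = _draw_nugent(ct, config, rng)
        sti = bool(rng.random() < config.sti_prob_given_ct.get(ct, 0.0))
        if antibiotics is not None:
            abx = bool(antibiotics[key])
        else:
            abx = bool(rng.random() < config.antibiotic_prob_given_ct.get(ct, 0.0))
        ph = float(np.round(3.8 + 0.18 * nugent + rng.normal(0, 0.25), 2))
        out[key] = {"nugent_score": nugent, "sti_positive": sti, "antibiotic_use": abx, "vaginal_ph": max(ph, 3.0)}
    return out


def simulate_tree(taxon_names: Sequence[str], seed: int) -> TreeNode:
    """Random rooted binary tree with exponential branch lengths."""
    names = list(taxon_names)
    if len(names) < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=n, length=float(rng.exponential(0.1))) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort: trajectories -> compositions -> counts -> labels -> tree."""
    config.validate()
    rng_traj, rng_comp, rng_depth, rng_clin, _ = _child_rngs(config.seed, 5)
    traj = simulate_ct_trajectories(config, rng_traj)
    clinical = simulate_clinical(traj.labels, config, rng_clin, antibiotics=traj.antibiotics)
    sample_keys = sorted(traj.labels)
    counts = np.zeros((len(sample_keys), len(config.taxon_names)), dtype=np.int64)
    records = []
    for row, (sid, visit) in enumerate(sample_keys):
        rel = simulate_composition(traj.labels[(sid, visit)], config, rng_comp)
        counts[row] = simulate_counts(rel, config, rng_depth)
        clin = clinical[(sid, visit)]
        records.append(
            SampleRecord(
                sample_id=f"{sid}-{visit}",
                subject_id=sid,
                visit=visit,
                group=traj.groups[sid],
                antibiotic_use=clin["antibiotic_use"],
                nugent_score=clin["nugent_score"],
                sti_positive=clin["sti_positive"],
                vaginal_ph=clin["vaginal_ph"],
            )
        )
    table = TaxaCountTable(
        tuple(f"{sid}-{visit}" for sid, visit in sample_keys),
        tuple(config.taxon_names),
        counts,
    )
    tree = simulate_tree(config.taxon_names, seed=config.seed + 977)
    return SyntheticCohort(table, tuple(records), tree, dict(traj.labels), config)
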