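"""Synthetic case-control cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes: independent biallelic SNPs in Hardy-Weinberg proportions, a
prospective logistic disease model with small per-allele main effects,
dosage-product pairwise interactions, an optional planted Boolean risk rule
over dominant/recessive covariates, a BMI covariate mildly associated with
case status, and genotype calls missing completely at random.  Cases and
controls are accrued by rejection sampling from the prospective model until
the requested counts are reached exactly, so planted odds ratios remain
interpretable as population ORs (logistic ORs are invariant under
case-control sampling of the outcome).

Default configuration emulates a breast-cancer candidate-SNP panel:
2,718 cases and 4,496 controls typed at 17 SNPs, with two planted pairwise
interactions (ORs 1.16 and 1.33) and a planted 4-leaf Boolean risk rule
(group OR 1.18).  Per-SNP minor-allele frequencies are plausible
placeholders (the study's true panel frequencies are not published in the
text this package draws on); the four SNPs in the planted rule get MAFs that
reproduce the reported carrier-frequency pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MISSING, CohortDataset, SNPMeta
from .logic import AND, OR, Leaf, LogicTree, Node
from .risk_groups import RiskGroupTable, group_odds_ratios

# The 17-SNP candidate panel (gene labels as reported for the study design).
PANEL: list[tuple[str, str]] = [
    ("rs13250873", "8q24.11"),
    ("rs1556459", "10q26.3"),
    ("rs2297381", "RPAP1"),
    ("rs7614", "MBD2"),
    ("rs4041245", "MBD2"),
    ("rs8094493", "MBD2"),
    ("rs1136410", "PARP1"),
    ("rs1799977", "MLH1"),
    ("rs184967", "MSH3"),
    ("rs26279", "MSH3"),
    ("rs2228528", "ERCC6"),
    ("rs769412", "MDM2"),
    ("rs1799943", "BRCA2"),
    ("rs17655", "ERCC5"),
    ("rs1130409", "APEX1"),
    ("rs1799796", "XRCC3"),
    ("rs25487", "XRCC1"),
]

_PANEL_IDS = [s for s, _ in PANEL]

# Placeholder MAFs in [0.06, 0.45]; the four SNPs of the planted Boolean rule
# (rs4041245, rs1799977, rs769412, rs1799943) are set so that the implied
# carrier/homozygote frequencies match the reported risk-group pattern
# (e.g. major-homozygote ~88% for rs769412, minor-carrier ~45% for rs1799943).
_DEFAULT_MAFS: dict[str, float] = {
    "rs13250873": 0.20, "rs1556459": 0.25, "rs2297381": 0.35, "rs7614": 0.30,
    "rs4041245": 0.43, "rs8094493": 0.40, "rs1136410": 0.17, "rs1799977": 0.31,
    "rs184967": 0.22, "rs26279": 0.27, "rs2228528": 0.33, "rs769412": 0.06,
    "rs1799943": 0.26, "rs17655": 0.28, "rs1130409": 0.45, "rs1799796": 0.24,
    "rs25487": 0.36,
}

# Small single-locus per-allele ORs in [0.85, 1.20]; SNPs reported with known
# marginal effects keep those values, the rest sit near the null.
_DEFAULT_MAIN_OR: dict[str, float] = {
    "rs13250873": 0.85, "rs1556459": 0.86, "rs2297381": 1.07, "rs7614": 0.90,
    "rs4041245": 1.13, "rs8094493": 0.92, "rs1136410": 1.05, "rs1799977": 0.94,
    "rs184967": 1.02, "rs26279": 0.98, "rs2228528": 1.04, "rs769412": 0.86,
    "rs1799943": 1.13, "rs17655": 0.95, "rs1130409": 1.01, "rs1799796": 1.08,
    "rs25487": 1.10,
}


def default_planted_tree() -> LogicTree:
    """The default 4-leaf planted risk rule over dominant/recessive covariates.

    In the covariate ordering of :func:`epilogic.logic.binarize_genotypes`
    (dom, rec per SNP in panel order):

        (NOT dom(rs4041245) OR NOT dom(rs1799977))
            AND NOT dom(rs769412) AND dom(rs1799943)

    i.e. major-homozygote indicators at the first three SNPs and a
    minor-allele carrier indicator at the fourth — common genotypes, so the
    risk group is a sizeable fraction of the cohort.
    """
    dom = {sid: 2 * _PANEL_IDS.index(sid) for sid in _PANEL_IDS}
    return LogicTree(
        Node(AND,
             Node(AND,
                  Node(OR,
                       Leaf(dom["rs4041245"], negate=True),
                       Leaf(dom["rs1799977"], negate=True)),
                  Leaf(dom["rs769412"], negate=True)),
             Leaf(dom["rs1799943"])))


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort."""

    n_cases: int = 2_718
    n_controls: int = 4_496
    snp_ids: list[str] = field(default_factory=lambda: list(_PANEL_IDS))
    gene_labels: dict[str, str] = field(default_factory=lambda: dict(PANEL))
    mafs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MAFS))
    main_effects: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MAIN_OR))
    pair_effects: list[tuple[str, str, float]] = field(default_factory=lambda: [
        ("rs1130409", "rs2297381", 1.16),
        ("rs1799977", "rs769412", 1.33),
    ])
    planted_logic: tuple[LogicTree, float] | None = field(
        default_factory=lambda: (default_planted_tree(), 1.18))
    baseline_prevalence: float = 0.10
    bmi_mean: float = 26.0
    bmi_sd: float = 4.5
    bmi_or_per_unit: float = 1.02
    bmi_bounds: tuple[float, float] = (15.0, 62.0)
    missing_rate: float = 0.00125  # per-call; ~2.1% incomplete subjects over 17 SNPs
    seed: int | None = None

    def __post_init__(self) -> None:
        for sid in self.snp_ids:
            q = self.mafs.get(sid)
            if q is None or not 0 <= q < 0.5:
                raise ValueError(f"{sid}: MAF must be in [0, 0.5)")
            if self.main_effects.get(sid, 1.0) <= 0:
                raise ValueError(f"{sid}: main-effect OR must be positive")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def simulate_genotypes(n: int, mafs, seed=None) -> np.ndarray:
    """Draw (n, len(mafs)) dosages under Hardy-Weinberg proportions.

    Per SNP with minor-allele frequency q, genotype probabilities are
    ((1-q)^2, 2q(1-q), q^2), independent across SNPs and subjects.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = np.asarray(list(mafs), dtype=float)
    # dosage = sum of two independent allele draws
    return (rng.random((n, q.size)) < q).astype(np.int8) + (
        rng.random((n, q.size)) < q
    ).astype(np.int8)


def _tree_indicator(tree: LogicTree, dosages: np.ndarray) -> np.ndarray:
    """Evaluate a planted tree on the dom/rec covariates implied by dosages."""
    n, p = dosages.shape
    X = np.empty((n, 2 * p), dtype=bool)
    X[:, 0::2] = dosages >= 1
    X[:, 1::2] = dosages == 2
    return tree.evaluate(X)


def simulate_cohort(config: SimConfig | None = None,
                    seed: int | np.random.Generator | None = None) -> CohortDataset:
    """Accrue an exact-count case-control cohort from the prospective model.

    Disease status for each drawn subject follows

        logit P = logit(baseline) + sum log(OR_j) d_j
                  + sum log(OR_ab) d_a d_b + log(OR_group) 1[tree true]
                  + log(OR_bmi) (BMI - bmi_mean)

    and subjects are banked as cases or controls until both quotas are met
    exactly; missingness is then applied completely at random.  ``seed``
    overrides ``config.seed`` when given.
    """
    cfg = config or SimConfig()
    if seed is None:
        seed = cfg.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sids = cfg.snp_ids
    q = [cfg.mafs[s] for s in sids]
    log_main = np.log([cfg.main_effects.get(s, 1.0) for s in sids])
    pair_idx = [(sids.index(a), sids.index(b), np.log(orr))
                for a, b, orr in cfg.pair_effects]
    b0 = np.log(cfg.baseline_prevalence / (1 - cfg.baseline_prevalence))
    log_bmi = np.log(cfg.bmi_or_per_unit)

    n_want_cases, n_want_controls = cfg.n_cases, cfg.n_controls
    case_geno, ctrl_geno = [], []
    case_bmi, ctrl_bmi = [], []
    batch = max(4 * (n_want_cases + n_want_controls), 1000)
    max_draws = 200 * (n_want_cases + n_want_controls) + 100_000
    drawn = 0
    while (sum(len(g) for g in case_geno) < n_want_cases
           or sum(len(g) for g in ctrl_geno) < n_want_controls):
        if drawn >= max_draws:
            raise RuntimeError(
                "could not accrue the requested case/control counts; "
                "check prevalence and effect settings"
            )
        g = simulate_genotypes(batch, q, rng)
        bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=batch)
        lo, hi = cfg.bmi_bounds
        out = (bmi < lo) | (bmi > hi)
        while out.any():  # truncated normal by redraw
            bmi[out] = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=int(out.sum()))
            out = (bmi < lo) | (bmi > hi)
        eta = b0 + g @ log_main + log_bmi * (bmi - cfg.bmi_mean)
        for ia, ib, lab in pair_idx:
            eta += lab * g[:, ia] * g[:, ib]
        if cfg.planted_logic is not None:
            tree, group_or = cfg.planted_logic
            eta += np.log(group_or) * _tree_indicator(tree, g)
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        drawn += batch
        case_geno.append(g[y])
        case_bmi.append(bmi[y])
        ctrl_geno.append(g[~y])
        ctrl_bmi.append(bmi[~y])

    cg = np.concatenate(case_geno)[:n_want_cases]
    cb = np.concatenate(case_bmi)[:n_want_cases]
    tg = np.concatenate(ctrl_geno)[:n_want_controls]
    tb = np.concatenate(ctrl_bmi)[:n_want_controls]
    genotypes = np.concatenate([cg, tg]).astype(np.int8)
    bmi_all = np.concatenate([cb, tb])
    phenotype = np.concatenate([
        np.ones(n_want_cases, dtype=np.int8),
        np.zeros(n_want_controls, dtype=np.int8),
    ])
    if cfg.missing_rate > 0:
        mask = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes[mask] = MISSING

    # interleave-free deterministic ordering: cases then controls; shuffle for
    # realism while keeping reproducibility
    order = rng.permutation(genotypes.shape[0])
    genotypes, phenotype, bmi_all = genotypes[order], phenotype[order], bmi_all[order]

    subjects = [f"S{i + 1:06d}" for i in range(genotypes.shape[0])]
    snps = [SNPMeta(snp_id=s, gene_label=cfg.gene_labels.get(s),
                    alleles=("A", "G")) for s in sids]
    covariates = pd.DataFrame({"BMI": bmi_all})
    return CohortDataset(subjects=subjects, phenotype=phenotype,
                         genotypes=genotypes, snps=snps, covariates=covariates)


def published_risk_group_counts() -> RiskGroupTable:
    """The published logic-based risk-group counts as a test fixture.

    Four groups from two logic trees (2,662 complete cases, 4,395 controls);
    the reference group is (Logic1=Yes, Logic2=No).
    """
    labels = [(False, False), (True, False), (False, True), (True, True)]
    cases = np.array([527, 829, 500, 806])
    controls = np.array([1076, 1329, 895, 1095])
    return group_odds_ratios(cases, controls, labels, reference=(True, False))
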