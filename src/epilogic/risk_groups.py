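"""Risk-group cross-classification from fitted logic trees.

Subjects are grouped by the tuple of their logic-tree outputs (2^t groups
for t trees, empty groups kept with zero counts); each group's odds ratio is
the raw cross-tabulation odds against a chosen reference group, which by
construction has OR = 1.00.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datasets import MISSING, CohortDataset


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as used for display."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RiskGroupTable:
    """Cross-classification of subjects by tree outputs with counts and ORs."""

    labels: list[tuple[bool, ...]]
    cases: np.ndarray
    controls: np.ndarray
    reference: tuple[bool, ...]
    odds_ratios: np.ndarray
    zero_cell_corrected: bool = False

    @property
    def n_cases(self) -> int:
        return int(self.cases.sum())

    @property
    def n_controls(self) -> int:
        return int(self.controls.sum())

    def label_strings(self, tree_names: list[str] | None = None) -> list[str]:
        t = len(self.labels[0])
        names = tree_names or [f"Logic {i + 1}" for i in range(t)]
        return [" ".join(f"{nm} = {'Yes' if b else 'No'}" for nm, b in zip(names, lab))
                for lab in self.labels]

    def to_dataframe(self, decimals: int = 2) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.label_strings(),
            "n_cases": self.cases,
            "n_controls": self.controls,
            "odds_ratio": [round_half_up(o, decimals) if np.isfinite(o) else np.nan
                           for o in self.odds_ratios],
            "odds_ratio_full": self.odds_ratios,
        })


def assign_groups(tree_outputs: list[np.ndarray]) -> tuple[np.ndarray, list[tuple[bool, ...]]]:
    """Map each subject to the tuple of its tree outcomes.

    Returns (group index per subject, ordered list of all 2^t labels);
    labels are ordered with the first tree varying slowest, No before Yes.
    """
    outs = [np.asarray(o, dtype=bool) for o in tree_outputs]
    n = outs[0].size
    if any(o.size != n for o in outs):
        raise ValueError("tree output vectors differ in length")
    t = len(outs)
    labels: list[tuple[bool, ...]] = []
    for code in range(2**t):
        labels.append(tuple(bool((code >> (t - 1 - i)) & 1) for i in range(t)))
    idx = np.zeros(n, dtype=int)
    for i, o in enumerate(outs):
        idx |= o.astype(int) << (t - 1 - i)
    return idx, labels


def group_odds_ratios(
    cases: np.ndarray,
    controls: np.ndarray,
    labels: list[tuple[bool, ...]],
    reference: tuple[bool, ...],
) -> RiskGroupTable:
    """Raw cross-tabulation odds ratios against the reference group.

    OR(g) = (cases_g / controls_g) / (cases_ref / controls_ref); the
    reference must have at least one case and one control.  Zero cells in
    non-reference groups get the Haldane-Anscombe 0.5 correction (flagged).
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if reference not in labels:
        raise ValueError(f"reference label {reference} not among groups")
    ref = labels.index(reference)
    if cases[ref] < 1 or controls[ref] < 1:
        raise ValueError("reference group needs at least one case and one control")
    ref_odds = cases[ref] / controls[ref]
    ors = np.empty(len(labels))
    corrected = False
    for g in range(len(labels)):
        a, b = cases[g], controls[g]
        if g != ref and (a == 0 or b == 0):
            a, b = a + 0.5, b + 0.5
            corrected = True
        ors[g] = (a / b) / ref_odds if b > 0 else np.nan
    ors[ref] = 1.0
    return RiskGroupTable(labels=list(labels), cases=cases.astype(int),
                          controls=controls.astype(int), reference=reference,
                          odds_ratios=ors, zero_cell_corrected=corrected)


def risk_group_table(
    y: np.ndarray,
    tree_outputs: list[np.ndarray],
    reference: tuple[bool, ...] | None = None,
) -> RiskGroupTable:
    """Build the full risk-group table from labels and tree outputs.

    The default reference is (Yes, No, No, ...): first tree positive, all
    others negative.
    """
    idx, labels = assign_groups(tree_outputs)
    y = np.asarray(y)
    ncell = len(labels)
    cases = np.bincount(idx[y == 1], minlength=ncell)
    controls = np.bincount(idx[y == 0], minlength=ncell)
    if reference is None:
        t = len(labels[0])
        reference = tuple([True] + [False] * (t - 1))
    return group_odds_ratios(cases, controls, labels, reference)


def group_or_confidence(table: RiskGroupTable, alpha: float = 0.05) -> pd.DataFrame:
    """Woolf CIs for the per-group odds ratios."""
    from scipy import stats

    z = stats.norm.ppf(1 - alpha / 2)
    ref = table.labels.index(table.reference)
    a0, b0 = table.cases[ref], table.controls[ref]
    rows = []
    for g, (a, b) in enumerate(zip(table.cases, table.controls)):
        if g == ref:
            rows.append((1.0, 1.0, 1.0))
            continue
        aa, bb = (a + 0.5, b + 0.5) if (a == 0 or b == 0) else (a, b)
        se = np.sqrt(1 / aa + 1 / bb + 1 / a0 + 1 / b0)
        lo = table.odds_ratios[g] * np.exp(-z * se)
        hi = table.odds_ratios[g] * np.exp(z * se)
        rows.append((table.odds_ratios[g], lo, hi))
    return pd.DataFrame(rows, columns=["OR", "OR_lo", "OR_hi"])


def genotype_frequency_report(
    data: CohortDataset, indicators: list[tuple[str, set[int]]]
) -> pd.DataFrame:
    """Count and percentage of cases/controls carrying given genotypes.

    ``indicators`` are (snp_id, dosage set) pairs, e.g. (rs_id, {0}) for the
    major-allele homozygote or (rs_id, {0, 1}) for non-carriers of two minor
    alleles.  Percentages are over subjects with complete genotypes at the
    indicated SNPs.
    """
    cols = [data.snp_index(s) for s, _ in indicators]
    complete = ~(data.genotypes[:, cols] == MISSING).any(axis=1)
    rows = []
    for (snp_id, dosages), j in zip(indicators, cols):
        col = data.genotypes[complete, j]
        y = data.phenotype[complete]
        hit = np.isin(col, list(dosages))
        for cls, name in ((1, "cases"), (0, "controls")):
            m = y == cls
            n_cls, n_hit = int(m.sum()), int((hit & m).sum())
            rows.append({
                "snp_id": snp_id,
                "dosages": "/".join(map(str, sorted(dosages))),
                "class": name, "n": n_cls, "count": n_hit,
                "pct": round_half_up(100.0 * n_hit / n_cls, 2) if n_cls else np.nan,
            })
    return pd.DataFrame(rows)
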