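"""End-to-end orchestration: QC -> single-locus -> pair scan -> logic regression -> risk groups."""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .datasets import CohortDataset, QCThresholds, complete_case_filter, read_genotype_table
from .epistasis import pairs_to_dataframe, scan_all_pairs
from .logic import (AnnealSchedule, anneal_fit, binarize_genotypes, covariate_matrix,
                    cross_validate, permutation_test)
from .qc import qc_report, single_locus_table
from .risk_groups import group_or_confidence, risk_group_table

log = logging.getLogger("epilogic")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    input_path: str
    out_dir: str
    seed: int = 0
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    covariate_names: list[str] = field(default_factory=list)
    tree_range: tuple[int, ...] = (1, 2)
    leaf_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    cv_folds: int = 10
    n_permutations: int = 10_000
    anneal_iterations: int = 50_000
    reference_group: tuple[bool, ...] | None = None
    log_level: str = "INFO"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stage-name hashed), below 2^31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _write_tsv(df, path: Path, provenance: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in provenance.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, data: CohortDataset | None = None) -> dict:
    """Execute every stage and return the run manifest.

    Stage order: QC -> single-locus tests -> pairwise interaction scan
    (pairwise complete-case) -> complete-case filter -> logic regression
    (CV size selection, final fit, permutation test) -> risk groups.
    Any stage error aborts with the stage name; outputs written so far are
    retained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    prov = {"epilogic": __version__, "seed": config.seed}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                info = fn()
            except Exception as e:
                manifest["stages"][name] = {"error": str(e)}
                with open(out / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=2, default=str)
                raise RuntimeError(f"pipeline aborted at stage {name!r}: {e}") from e
            info["wall_s"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
            log.info("stage %s: %.2fs %s", name, info["wall_s"],
                     {k: v for k, v in info.items() if k != "wall_s"})
            return info
        return deco

    if data is None:
        data = read_genotype_table(config.input_path)
    manifest["n_subjects_in"] = data.n_subjects
    manifest["n_snps_in"] = data.n_snps

    @stage("qc")
    def _qc():
        records = qc_report(data, config.thresholds)
        import pandas as pd

        df = pd.DataFrame([vars(r) for r in records])
        _write_tsv(df, out / "qc_report.tsv", prov)
        passed = [r.snp_id for r in records if r.passed]
        if not passed:
            raise ValueError("no SNP passed QC thresholds")
        return {"n_snps_in": data.n_snps, "n_snps_pass": len(passed), "passed": passed}

    passed = manifest["stages"]["qc"]["passed"]
    data_qc = data.subset_snps(passed)

    @stage("single_locus")
    def _sl():
        df = single_locus_table(data_qc, config.covariate_names or None)
        _write_tsv(df, out / "single_locus.tsv", prov)
        return {"n_snps": len(df)}

    @stage("pair_scan")
    def _scan():
        if data_qc.n_snps < 2:
            raise ValueError("fewer than 2 SNPs survived QC; cannot scan pairs")
        results = scan_all_pairs(data_qc)
        _write_tsv(pairs_to_dataframe(results), out / "pairs.tsv", prov)
        return {"n_pairs": len(results)}

    @stage("complete_case")
    def _cc():
        filtered, n_excluded = complete_case_filter(data_qc)
        return {"n_excluded": n_excluded, "n_subjects": filtered.n_subjects,
                "_data": filtered}

    cc = manifest["stages"]["complete_case"].pop("_data")

    @stage("logic_regression")
    def _logic():
        covs = binarize_genotypes(cc)
        X, names = covariate_matrix(covs)
        y = cc.phenotype.astype(float)
        sched = AnnealSchedule(n_iterations=config.anneal_iterations)
        cv = cross_validate(X, y, config.tree_range, config.leaf_range,
                            k=config.cv_folds,
                            seed=stage_seed(config.seed, "cv"), schedule=sched)
        import pandas as pd

        cv_df = pd.DataFrame([{"n_trees": t, "max_leaves": L, "mean_heldout_deviance": d}
                              for (t, L), d in sorted(cv.grid.items())])
        _write_tsv(cv_df, out / "cv_grid.tsv", prov)
        t_sel, l_sel = cv.selected
        model = anneal_fit(X, y, n_trees=t_sel, max_total_leaves=l_sel,
                           schedule=sched, seed=stage_seed(config.seed, "final_fit"))
        with open(out / "logic_model.json", "w") as fh:
            json.dump({
                "intercept": model.intercept,
                "coefficients": list(model.coefficients),
                "trees": [t.to_string(names) for t in model.trees],
                "deviance": model.score,
                "selected_size": [t_sel, l_sel],
            }, fh, indent=2)
        perm = permutation_test(X, y, (t_sel, l_sel),
                                n_perm=config.n_permutations,
                                seed=stage_seed(config.seed, "permutation"),
                                schedule=sched, observed_score=model.score)
        perm_df = pd.DataFrame({"permuted_score": perm.permuted_scores})
        _write_tsv(perm_df, out / "permutation.tsv",
                   dict(prov, observed_score=perm.observed_score, p=perm.p))
        return {"selected_size": [t_sel, l_sel], "deviance": model.score,
                "permutation_p": perm.p, "_model": model, "_X": X}

    model = manifest["stages"]["logic_regression"].pop("_model")
    X = manifest["stages"]["logic_regression"].pop("_X")

    @stage("risk_groups")
    def _groups():
        outs = [t.evaluate(X) for t in model.trees]
        table = risk_group_table(cc.phenotype, outs, reference=config.reference_group)
        df = table.to_dataframe()
        ci = group_or_confidence(table)
        df["OR_lo"], df["OR_hi"] = ci["OR_lo"], ci["OR_hi"]
        _write_tsv(df, out / "risk_groups.tsv", prov)
        return {"n_groups": len(table.labels), "n_cases": table.n_cases,
                "n_controls": table.n_controls}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
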