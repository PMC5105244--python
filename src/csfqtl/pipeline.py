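"""End-to-end pipeline: simulate/load -> QC -> PCA -> GWAS -> adjust -> compare.

A single YAML config drives the run; the seed is mandatory and expanded into
per-stage substreams.  Every stage writes a TSV, and a manifest records the
config snapshot, seed, library versions, SHA-256 digests of all outputs, the
top variant with its effect and delta R-squared, and the final correlation
comparison — so a rerun with the same config reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .adjust import genetic_adjust, log_standardize, variance_explained
from .association import (
    GENOME_WIDE_P,
    classify_significance,
    conditional_analysis,
    genomic_inflation,
    run_gwas,
)
from .casecontrol import test_status_association
from .correlation import compare_adjusted
from .qc import detect_duplicates, filter_variants, pca_population_structure
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["RunManifest", "run_pipeline", "manhattan_table", "build_covariate_design"]

logger = logging.getLogger("csfqtl")


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    top_variant: dict = field(default_factory=dict)
    lambda_gc: float = float("nan")
    comparisons: list = field(default_factory=list)
    status_tests: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _setup_logging(outdir: str) -> None:
    fmt = logging.Formatter("ts=%(asctime)s stage=%(name)s level=%(levelname)s %(message)s")
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, (logging.StreamHandler,))]
    sh = logging.StreamHandler(sys.stderr)
    fh = logging.FileHandler(os.path.join(outdir, "run.log"))
    for h in (sh, fh):
        h.setFormatter(fmt)
        logger.addHandler(h)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _emit(manifest: RunManifest, outdir: str, name: str, writer) -> str:
    """Write a stage output atomically and record its digest."""
    path = os.path.join(outdir, name)
    tmp = path + ".partial"
    writer(tmp)
    os.replace(tmp, path)
    manifest.outputs[name] = _sha256(path)
    return path


def build_covariate_design(pheno: pd.DataFrame, covariate_cols, pcs=None) -> tuple[np.ndarray, list]:
    """Assemble the covariate matrix: numeric columns, batch as indicators,
    optional principal-component scores appended."""
    arrays, names = [], []
    for c in covariate_cols:
        v = pheno[c].to_numpy(dtype=float)
        if c == "batch":
            levels = np.unique(v[np.isfinite(v)])
            for lv in levels[1:]:
                arrays.append((v == lv).astype(float))
                names.append(f"batch_{int(lv)}")
        else:
            arrays.append(v)
            names.append(c)
    if pcs is not None:
        for k in range(pcs.shape[1]):
            arrays.append(pcs[:, k])
            names.append(f"PC{k + 1}")
    return np.column_stack(arrays), names


def manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """CHR, POS, -log10 p, CLASS plus a cumulative genome coordinate."""
    if assoc.empty:
        raise ValueError("empty association table")
    tab = assoc.loc[np.isfinite(assoc["P"].to_numpy(dtype=float))].copy()
    tab["NEGLOG10P"] = -np.log10(tab["P"].to_numpy(dtype=float))
    offset, offsets = 0, {}
    key = tab["CHR"].astype(str)
    for c in dict.fromkeys(key):
        sel = key == c
        offsets[c] = offset
        offset += int(tab.loc[sel, "POS"].max()) + 1
    tab["CUMPOS"] = tab["POS"].to_numpy() + np.array([offsets[c] for c in key])
    return tab[["CHR", "POS", "ID", "NEGLOG10P", "CLASS", "CUMPOS"]].reset_index(drop=True)


def load_config(config_path: str) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in cfg:
        raise ValueError("config must set a seed")
    return cfg


def run_pipeline(config_path: str, outdir: str | None = None, force_adjust: bool = False) -> RunManifest:
    """Execute all stages in order and return the manifest (also written as JSON)."""
    cfg = load_config(config_path)
    seed = int(cfg["seed"])
    outdir = outdir or cfg.get("outdir", "csfqtl_run")
    os.makedirs(outdir, exist_ok=True)
    _setup_logging(outdir)

    versions = {
        "csfqtl": __import__("csfqtl").__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    manifest = RunManifest(config=cfg, seed=seed, versions=versions)
    analysis = cfg.get("analysis", {})
    biomarker = analysis.get("biomarker", "ykl40")
    targets = analysis.get("targets", ["ptau181", "tau", "abeta42", "tau_abeta_ratio"])
    covariate_cols = analysis.get("covariates", ["age", "gender", "batch"])
    n_pcs = int(analysis.get("n_pcs", 2))
    qc_cfg = cfg.get("qc", {})
    force_adjust = force_adjust or bool(cfg.get("force_adjust", False))

    def stage(name):
        t0 = time.time()
        logger.info("event=start stage=%s", name)
        return lambda **kw: logger.info(
            "event=done stage=%s elapsed=%.2fs %s",
            name, time.time() - t0, " ".join(f"{k}={v}" for k, v in kw.items()),
        )

    try:
        # --- stage 1: simulate or load ----------------------------------
        done = stage("input")
        if "simulate" in cfg:
            sim_cfg = SimulationConfig(seed=seed, **cfg["simulate"])
            G, pheno = simulate_cohort(sim_cfg)
        else:
            inputs = cfg["inputs"]
            geno_path = inputs["genotypes"]
            G = qio.read_vcf(geno_path) if geno_path.endswith(".vcf") else qio.read_counts_tsv(geno_path)
            pheno = qio.read_phenotypes(inputs["phenotypes"])
        _emit(manifest, outdir, "genotypes.vcf", lambda p: qio.write_vcf(G, p))
        _emit(manifest, outdir, "phenotypes.tsv", lambda p: qio.write_phenotypes(pheno, p))
        done(n_samples=G.n_samples, n_variants=G.n_variants)

        # --- stage 2: QC -------------------------------------------------
        done = stage("qc")
        Gq, report = filter_variants(
            G,
            call_rate_min=qc_cfg.get("call_rate_min", 0.98),
            maf_min=qc_cfg.get("maf_min", 0.02),
            hwe_alpha=qc_cfg.get("hwe_alpha", 1e-6),
        )
        report.duplicate_pairs = detect_duplicates(Gq, qc_cfg.get("dup_sharing_min", 0.95))
        if report.duplicate_pairs:
            manifest.warnings.append(f"duplicate sample pairs flagged: {report.duplicate_pairs}")
        _emit(manifest, outdir, "qc_variants.tsv", lambda p: qio.write_table(report.variant_table, p))
        _emit(manifest, outdir, "qc_samples.tsv", lambda p: qio.write_table(report.sample_table, p))
        pheno = pheno.set_index("sample_id").loc[Gq.sample_ids].reset_index()
        done(
            variants_kept=Gq.n_variants,
            variants_dropped=G.n_variants - Gq.n_variants,
            samples_kept=Gq.n_samples,
        )

        # --- stage 3: PCA ------------------------------------------------
        done = stage("pca")
        pcs = pca_population_structure(Gq, k=n_pcs)
        pc_df = pd.DataFrame(
            pcs.scores, columns=[f"PC{k + 1}" for k in range(n_pcs)]
        ).assign(sample_id=pcs.sample_ids)
        _emit(manifest, outdir, "pcs.tsv", lambda p: qio.write_table(pc_df, p))
        done(k=n_pcs, eigenvalues=np.round(pcs.eigenvalues, 3).tolist())

        # --- stage 4: GWAS -----------------------------------------------
        done = stage("gwas")
        y = log_standardize(pheno[biomarker].to_numpy(dtype=float))
        covars_gwas, _ = build_covariate_design(pheno, covariate_cols, pcs.scores)
        assoc = run_gwas(Gq, y, covars_gwas)
        valid_p = assoc["P"].to_numpy(dtype=float)
        manifest.lambda_gc = genomic_inflation(valid_p[np.isfinite(valid_p)])
        _emit(manifest, outdir, "association.tsv", lambda p: qio.write_table(assoc, p))
        _emit(manifest, outdir, "manhattan.tsv", lambda p: qio.write_table(manhattan_table(assoc), p))
        done(n_variants=len(assoc), lambda_gc=round(manifest.lambda_gc, 3))

        # --- stage 5: top variant + conditional --------------------------
        done = stage("top_variant")
        finite = assoc.loc[np.isfinite(assoc["P"].to_numpy(dtype=float))]
        top = finite.sort_values(["P", "CHR", "POS"], kind="mergesort").iloc[0]
        top_id = str(top["ID"])
        genome_wide = top["P"] < GENOME_WIDE_P
        if not genome_wide:
            msg = f"no genome-wide hit (top variant {top_id}, p={top['P']:.3g})"
            logger.warning(msg)
            manifest.warnings.append(msg)
        cond = conditional_analysis(Gq, y, covars_gwas, top_id)
        _emit(manifest, outdir, "conditional.tsv", lambda p: qio.write_table(cond, p))
        manifest.top_variant = {
            "id": top_id,
            "beta": float(top["BETA"]),
            "se": float(top["SE"]),
            "p": float(top["P"]),
            "class": str(top["CLASS"]),
        }
        done(top=top_id, p=f"{top['P']:.3g}")

        # --- stage 6-8: delta R2, adjustment, comparisons ----------------
        if genome_wide or force_adjust:
            done = stage("adjust")
            if not genome_wide:
                logger.warning("force-adjust: adjusting on non-genome-wide top variant %s", top_id)
            g_top = Gq.counts[:, Gq.variant_index(top_id)]
            covars_r2, _ = build_covariate_design(pheno, covariate_cols)
            r2_cov, r2_var = variance_explained(y, g_top, covars_r2)
            adj = genetic_adjust(
                y, g_top, sample_ids=Gq.sample_ids, variant_id=top_id,
                covariates=covars_r2, raw=pheno[biomarker].to_numpy(dtype=float),
            )
            manifest.top_variant.update(r2_covariates=r2_cov, r2_variant=r2_var)
            adj_col = f"{biomarker}_adj_{top_id}"
            pheno[adj_col] = adj.adjusted
            pheno[f"{biomarker}_logstd"] = y
            _emit(manifest, outdir, "phenotypes_adjusted.tsv", lambda p: qio.write_phenotypes(pheno, p))
            done(r2_covariates=round(r2_cov, 4), r2_variant=round(r2_var, 4))

            done = stage("compare")
            rows = []
            for target in targets:
                cc = compare_adjusted(pheno, f"{biomarker}_logstd", adj_col, target)
                rows.append(
                    {
                        "target": target, "r_jk": cc.r_jk, "r_jh": cc.r_jh, "r_kh": cc.r_kh,
                        "n": cc.n, "Z": cc.Z, "p": cc.p, "ci_low": cc.ci_low,
                        "ci_high": cc.ci_high, "decision": cc.decision,
                    }
                )
            comp_df = pd.DataFrame(rows)
            manifest.comparisons = rows
            _emit(manifest, outdir, "comparisons.tsv", lambda p: qio.write_table(comp_df, p))
            done(n_targets=len(rows))

            done = stage("status_test")
            st_rows = []
            for col, lg in ((biomarker, True), (adj_col, False)):
                fit = test_status_association(pheno, col, covariate_cols, log_std=lg)
                st_rows.append(
                    {
                        "analyte": col, "beta": fit.beta[1], "se": fit.se[1],
                        "z": fit.z[1], "p": fit.p[1], "n": fit.n,
                    }
                )
            manifest.status_tests = st_rows
            _emit(manifest, outdir, "status_tests.tsv", lambda p: qio.write_table(pd.DataFrame(st_rows), p))
            done(n_tests=len(st_rows))
        else:
            manifest.warnings.append("adjustment skipped: no genome-wide hit (use force_adjust)")

        _emit(manifest, outdir, "manifest.json", lambda p: open(p, "w").write(manifest.to_json()))
    except Exception as exc:
        logger.error("event=abort error=%r", exc)
        raise
    return manifest
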