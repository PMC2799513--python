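"""End-to-end orchestration: damage -> DE -> GSA -> consensus -> EPIG -> clinical.

Runs the stages in dependency order on a directory of input files (as produced
by the synthetic-cohort generator or supplied by the user), writes each
stage's artifacts to the output directory, and keeps a run log with record
counts in and out of every stage.  Reruns with the same config and seed
reproduce all stochastic outputs exactly; each run writes a ``run_info.json``
with the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import diffexpr, epig, geneset, io, qpcr_damage

logger = logging.getLogger(__name__)


class RunLog:
    """Timestamped stage log with in/out record counts."""

    def __init__(self) -> None:
        self.entries: list[dict] = []

    def add(self, stage: str, message: str, level: str = "INFO", **counts) -> None:
        entry = {"time": time.time(), "level": level, "stage": stage,
                 "message": message, **counts}
        self.entries.append(entry)
        logger.log(getattr(logging, level), "[%s] %s %s", stage, message,
                   {k: v for k, v in counts.items()} or "")

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2))


def _config_hash(config: io.PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: io.PipelineConfig, in_dir: str | Path, out_dir: str | Path) -> RunLog:
    """Run every applicable stage on the inputs found in ``in_dir``.

    Expected inputs (a stage is skipped, with a log entry, when its input file
    is absent): ``expression.tsv`` + ``metadata.tsv``, ``qpcr.csv``,
    ``gene_sets.gmt``, ``clinical.tsv``.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    run_info = {"seed": config.seed, "config_hash": _config_hash(config)}
    io.write_json(run_info, out_dir / "run_info.json")

    # --- stage: DNA damage quantification -------------------------------
    qpcr_path = in_dir / "qpcr.csv"
    lesions = None
    if qpcr_path.exists():
        log.add("damage", "start")
        table = io.read_qpcr_table(qpcr_path)
        lesions = qpcr_damage.estimate_lesions(table, config.amplicons)
        lesions["damage_class"] = [
            qpcr_damage.classify_damage(v, config.damage_threshold_per_10kb)
            for v in lesions["lesions_per_10kb"]
        ]
        lesions.to_csv(out_dir / "lesions.tsv", sep="\t", index=False)
        io.write_json(qpcr_damage.damage_group_stats(lesions), out_dir / "damage_stats.json")
        log.add("damage", "end", n_in=len(table), n_out=len(lesions))
    else:
        log.add("damage", f"skipped: {qpcr_path} absent")

    # --- stage: differential expression ----------------------------------
    expr_path, meta_path = in_dir / "expression.tsv", in_dir / "metadata.tsv"
    matrix = labels = scores = de_list = None
    if expr_path.exists():
        if not meta_path.exists():
            raise io.ParseError(f"stage 'de': expression present but {meta_path} missing")
        log.add("de", "start")
        matrix = io.read_expression_matrix(expr_path)
        meta = io.read_metadata(meta_path)
        labels = meta.loc[matrix.columns, "group"]
        fdr_table = diffexpr.permutation_fdr(matrix, labels, config.n_perm, config.seed)
        x, mask2 = diffexpr._group_arrays(matrix, labels)
        numer, s, _ = diffexpr._sam_d(x, mask2, 0.0)
        s0 = diffexpr.estimate_s0(s, numer)
        scores = diffexpr.sam_statistic(matrix, labels, s0)
        scores.to_frame().to_csv(out_dir / "sam_scores.tsv", sep="\t")
        fdr_table.fdr_percent().to_csv(out_dir / "fdr_table.tsv", sep="\t", index=False)
        de_list = diffexpr.call_genes(scores, fdr_table, config.fdr_threshold_percent)
        de_list.to_csv(out_dir / "de_genes.tsv", sep="\t")
        log.add("de", "end", n_genes=len(matrix), n_called=len(de_list))
    else:
        log.add("de", f"skipped: {expr_path} absent")

    # --- stage: gene-set analysis + consensus -----------------------------
    gmt_path = in_dir / "gene_sets.gmt"
    if gmt_path.exists() and matrix is not None:
        log.add("gsa", "start")
        catalog = geneset.GeneSetCatalog(io.read_gmt(gmt_path))
        results = geneset.gsa(catalog, matrix, labels, n_perm=config.n_perm,
                              seed=config.seed, p_significant=config.gsa_p_threshold)
        results.to_csv(out_dir / "gsa_results.tsv", sep="\t")
        log.add("gsa", "end", n_sets=len(results),
                n_significant=int(results["significant"].sum()))

        significant = {name: catalog.sets[name]
                       for name in results.index[results["significant"]]}
        if significant:
            log.add("consensus", "start")
            signature = geneset.consensus_signature(significant, config.consensus_fraction)
            signature.to_csv(out_dir / "consensus_signature.tsv", sep="\t")
            io.write_json({"min_count": signature.attrs["min_count"],
                           "n_sets": signature.attrs["n_sets_total"],
                           "n_members": len(signature)},
                          out_dir / "consensus_info.json")
            log.add("consensus", "end", n_sets=len(significant), n_members=len(signature))
        else:
            log.add("consensus", "skipped: no significant sets")
    else:
        log.add("gsa", "skipped: gene sets or expression absent")

    # --- stage: EPIG pattern extraction ----------------------------------
    clin_path = in_dir / "clinical.tsv"
    if matrix is not None:
        log.add("epig", "start")
        patterns = epig.extract_patterns(matrix, config.epig, labels)
        if patterns:
            assignment = epig.assign_genes(matrix, patterns, config.epig.r_assign)
            assignment.to_csv(out_dir / "pattern_assignment.tsv", sep="\t")
            profiles = pd.DataFrame(
                {p.id: p.representative_profile for p in patterns}, index=matrix.columns
            )
            profiles.rename_axis("sample_id").to_csv(out_dir / "pattern_profiles.tsv", sep="\t")
            if clin_path.exists():
                clin_table = io.read_metadata(clin_path)
                covariates = [c for c in clin_table.columns
                              if c != "group" and pd.api.types.is_numeric_dtype(clin_table[c])]
                common = [s for s in matrix.columns if s in clin_table.index]
                correlations = {}
                for p in patterns:
                    prof = pd.Series(p.representative_profile, index=matrix.columns)[common]
                    correlations[p.id] = {}
                    for cov in covariates:
                        vals = clin_table.loc[common, cov].to_numpy(dtype=float)
                        keep = np.isfinite(vals)
                        if keep.sum() < 3 or np.ptp(vals[keep]) == 0:
                            continue
                        r, pv = epig.correlate_pattern_covariate(
                            prof.to_numpy()[keep], vals[keep])
                        correlations[p.id][cov] = {"r": r, "p": pv}
                io.write_json(correlations, out_dir / "pattern_covariates.json")
        log.add("epig", "end", n_patterns=len(patterns))

    # --- stage: clinical correlation --------------------------------------
    if clin_path.exists():
        log.add("clinical", "start")
        clin_table = io.read_metadata(clin_path)
        outputs: dict = {}
        if "ddct" in clin_table.columns:
            strata = clin.stratify_expressers(
                clin_table["ddct"].dropna(), config.stratify_threshold_ddct)
            outputs["expresser_counts"] = {
                "high": int((strata == "high").sum()),
                "low": int((strata == "low").sum()),
                "threshold": config.stratify_threshold_ddct,
            }
            fits = {}
            for cov in ("age_of_onset", "icars", "gaa_short", "gaa_long"):
                if cov in clin_table.columns:
                    sub = clin_table[["ddct", cov]].dropna()
                    if len(sub) >= 3:
                        fits[cov] = clin.univariate_fit(sub["ddct"], sub[cov])
            if fits:
                qs = clin.qvalues([f["p"] for f in fits.values()])
                for (cov, fit), q in zip(fits.items(), qs):
                    fit["q"] = float(q)
            outputs["ddct_fits"] = fits
        io.write_json(outputs, out_dir / "clinical_stats.json")

        if matrix is not None and "icars" in clin_table.columns:
            common = [s for s in matrix.columns if s in clin_table.index]
            icars = clin_table.loc[common, "icars"]
            keep = icars.notna()
            if keep.sum() >= 3:
                passers = clin.supervised_correlation(
                    matrix[list(icars.index[keep])], icars[keep].to_numpy(), 0.01)
                passers.to_csv(out_dir / "icars_correlated_genes.tsv", sep="\t")
                log.add("clinical", "supervised ICARS correlation",
                        n_passers=len(passers))
        log.add("clinical", "end")
    else:
        log.add("clinical", f"skipped: {clin_path} absent")

    log.write(out_dir / "run_log.json")
    return log
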