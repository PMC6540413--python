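"""End-to-end orchestration: simulate or load a cohort, normalize, score,
test associations, cluster, and run the morphology statistics, emitting
plain-text artifacts plus a structured JSON run report.

Stage order follows the analysis design: background floor -> positive-control
normalize -> log2 + quantile normalize -> signature scoring (cell types,
categories, Teff, Teff/Treg) -> Z standardization -> per-signature mean-Z
difference and Wilcoxon tests -> moderated-t DEG with BH FDR and fold-change
filter -> gene-wise Z + response-category restriction + hierarchical
clustering -> TIL aggregation, dichotomization, odds ratios, chi-square,
logistic regression and VIF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import expression_processing as xp
from . import morphology_stats as morph
from . import signatures as sigs
from . import synthetic_data as synth

logger = logging.getLogger("rccimmune")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    mode 'simulate' generates a synthetic cohort (see ``simulation`` for
    generator overrides); 'rcc_dir' loads per-sample RCC files; 'tsv' loads
    a combined count TSV. Load modes need ``gmt_path`` and
    ``annotation_path``.
    """

    mode: str = "simulate"
    rcc_dir: str | None = None
    counts_tsv: str | None = None
    gmt_path: str | None = None
    annotation_path: str | None = None
    platform: str = sigs.PLATFORM_NANOSTRING
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.3
    exact_cutoff: int = assoc.EXACT_CUTOFF
    vif_flag_level: float = morph.VIF_FLAG_LEVEL
    scheme: str = "cut2"
    cluster_method: str = "complete"
    cluster_metric: str = "euclidean"
    n_flat_clusters: int = 2
    outdir: str = "rccimmune_out"
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("simulate", "rcc_dir", "tsv"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "rcc_dir":
            self._need_paths(rcc_dir=self.rcc_dir, gmt_path=self.gmt_path,
                             annotation_path=self.annotation_path)
        if self.mode == "tsv":
            self._need_paths(counts_tsv=self.counts_tsv, gmt_path=self.gmt_path,
                             annotation_path=self.annotation_path)
        if not (0 < self.fdr_threshold <= 1) or self.fc_threshold <= 0:
            raise ValueError("thresholds out of range")
        if self.scheme not in morph.SCHEMES:
            raise ValueError(f"scheme must be one of {morph.SCHEMES}")

    @staticmethod
    def _need_paths(**paths: str | None) -> None:
        for name, path in paths.items():
            if path is None:
                raise ValueError(f"mode requires {name}")
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stage_order: list[str]
    outputs: dict[str, str]
    summaries: dict
    timings: dict[str, float]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage; any stage error aborts with the stage name and
    cause, leaving partial outputs plus a FAILED marker in the output dir."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    outputs: dict[str, str] = {}
    summaries: dict = {}
    timings: dict[str, float] = {}
    stage_order: list[str] = []
    chash = config.hash()
    prov = {"config_hash": chash, "seed": config.seed}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                marker = os.path.join(config.outdir, "FAILED")
                with open(marker, "w") as fh:
                    fh.write(f"stage: {name}\ncause: {exc}\n")
                raise PipelineError(name, exc) from exc
            timings[name] = time.perf_counter() - t0
            stage_order.append(name)
            logger.info("[%s] done in %.3fs", name, timings[name])
            return result
        return wrap

    def emit(key: str, fname: str) -> str:
        path = os.path.join(config.outdir, fname)
        outputs[key] = path
        return path

    # ---- load / simulate -------------------------------------------------
    def _load():
        if config.mode == "simulate":
            sim_cfg = synth.SimulationConfig(seed=config.seed, **config.simulation)
            panel, cohort = synth.simulate_cohort(sim_cfg)
            return cohort.raw_counts, panel.signatures, cohort.annotation
        if config.mode == "rcc_dir":
            raw = xp.read_rcc_dir(config.rcc_dir)
        else:
            raw = xp.read_counts_tsv(config.counts_tsv)
        registry = sigs.SignatureRegistry.from_gmt(config.gmt_path)
        annotation = morph.read_annotation_csv(config.annotation_path)
        return raw, registry, annotation

    raw, registry, annotation = stage("load")(_load)
    labels = annotation["recurrence"].astype(str)
    labels = labels[labels.index.intersection(raw.samples)]

    # ---- expression processing ------------------------------------------
    floored = stage("background_floor")(lambda: xp.background_floor(raw))
    normalized_raw, factors = stage("positive_control_normalize")(
        lambda: xp.positive_control_normalize(floored)
    )
    log2mat = stage("log2_quantile_normalize")(
        lambda: xp.log2_quantile_normalize(normalized_raw)
    )
    xp.write_matrix_tsv(log2mat.values, emit("normalized", "normalized_log2.tsv"),
                        {**prov, **log2mat.provenance})

    # ---- signature scoring ----------------------------------------------
    def _score():
        table = sigs.score_signatures(log2mat, registry,
                                      kinds=(sigs.KIND_CELL_TYPE, sigs.KIND_CATEGORY))
        teff_sigs = registry.of_kind(sigs.KIND_TEFF)
        ratio = None
        if teff_sigs and "Treg" in registry:
            teff = sigs.teff_score(log2mat, teff_sigs[0])
            treg = sigs.score_signature(log2mat, registry["Treg"])
            ratio = sigs.teff_treg_ratio(teff, treg, config.platform)
        return table, ratio

    score_table, teff_treg = stage("score_signatures")(_score)
    score_table.to_tsv(emit("scores", "signature_scores.tsv"))

    ztable = stage("standardize_scores")(lambda: sigs.standardize_scores(score_table))

    # ---- association -----------------------------------------------------
    def _associate():
        report = assoc.associate_signatures(ztable, labels)
        if teff_treg is not None:
            rec, non = assoc.split_groups(teff_treg.ratio.dropna(), labels)
            w, p_one = assoc.wilcoxon_rank_sum(rec, non, "less", config.exact_cutoff)
            _, p_two = assoc.wilcoxon_rank_sum(rec, non, "two_sided", config.exact_cutoff)
            report.loc["Teff/Treg"] = {
                "delta_z": np.nan, "W": w, "p": p_two, "q": np.nan,
            }
            summaries["teff_treg"] = {
                "platform": teff_treg.platform,
                "one_sided_p_recurrent_lower": p_one,
                "two_sided_p": p_two,
            }
        return report

    sig_report = stage("signature_association")(_associate)
    sig_report.to_csv(emit("associations", "signature_associations.tsv"), sep="\t")
    summaries["signatures"] = {
        "n_tested": int(sig_report.shape[0]),
        "delta_z": sig_report["delta_z"].dropna().round(4).to_dict(),
        "p": sig_report["p"].round(6).to_dict(),
    }

    deg = stage("deg_analysis")(
        lambda: assoc.deg_table(log2mat.values, labels,
                                config.fc_threshold, config.fdr_threshold)
    )
    deg.to_csv(emit("deg", "deg_table.tsv"), sep="\t")
    summaries["deg"] = {
        "n_genes": int(deg.shape[0]),
        "n_reported": int(deg["reported"].sum()),
        "reported_genes": sorted(deg.index[deg["reported"]]),
    }

    # ---- clustering ------------------------------------------------------
    def _cluster():
        genes = assoc.category_gene_set(registry)
        present = [g for g in genes if g in log2mat.values.index]
        sub = log2mat.values.loc[present]
        sub = sub[sub.std(axis=1, ddof=1) > 0]
        zmat = assoc.gene_zscore(sub)
        return assoc.hierarchical_cluster(
            zmat, config.n_flat_clusters, config.cluster_metric, config.cluster_method
        )

    cluster = stage("hierarchical_cluster")(_cluster)
    with open(emit("cluster", "cluster_result.json"), "w") as fh:
        json.dump({**prov, **cluster.to_json_dict()}, fh)
    summaries["cluster"] = {
        "n_genes": len(cluster.row_order),
        "n_samples": len(cluster.col_order),
    }

    # ---- morphology ------------------------------------------------------
    def _morphology():
        out: dict = {}
        if "til_score" not in annotation.columns:
            logger.warning("annotation lacks til_score; skipping morphology stage")
            return out
        table = morph.recurrence_table(annotation, "til_score", "high", config.scheme)
        try:
            orres = morph.odds_ratio(table)
        except morph.MorphologyError:
            orres = morph.odds_ratio(table, haldane=True)
        out["til_or"] = {
            "scheme": config.scheme,
            "odds_ratio": orres.odds_ratio,
            "ci": [orres.ci_low, orres.ci_high],
            "method": orres.method,
            "chi2": orres.chi2,
            "p": orres.p,
        }
        design = pd.DataFrame(
            {
                "til_high": annotation["til_score"].map(
                    lambda s: float(morph.dichotomize(int(s), config.scheme) == "high")
                ),
                "grade_high": (annotation["grade"].astype(str) == "3-4").astype(float),
                "necrosis": (annotation["necrosis"].astype(str) == "yes").astype(float),
                "stage_high": (annotation["stage"].astype(str) == ">T1").astype(float),
            },
            index=annotation.index,
        )
        y = (annotation["recurrence"].astype(str) == "recurrent").astype(float)
        import statsmodels.api as sm

        try:
            fit = morph.logistic_fit(sm.add_constant(design), y)
            out["logistic"] = {
                "odds_ratios": fit.odds_ratios.round(4).to_dict(),
                "iterations": fit.iterations,
            }
        except morph.MorphologyError as exc:
            out["logistic"] = {"error": str(exc)}
        out["vif"] = morph.vif(design, config.vif_flag_level)["vif"].round(3).to_dict()
        return out

    summaries["morphology"] = stage("morphology_stats")(_morphology)

    report = RunReport(chash, config.seed, stage_order, outputs, summaries, timings)
    report.to_json(os.path.join(config.outdir, "run_report.json"))
    outputs["report"] = os.path.join(config.outdir, "run_report.json")
    return report


def run_signature_association(sim_config: "synth.SimulationConfig") -> pd.DataFrame:
    """Simulate a cohort and run the expression -> scoring -> association
    chain, returning the per-signature report (delta_z, W, p, q).

    This is the in-memory core of the pipeline without the DEG, clustering
    and morphology stages; power and calibration studies loop over it.
    """
    panel, cohort = synth.simulate_cohort(sim_config)
    floored = xp.background_floor(cohort.raw_counts)
    normed, _ = xp.positive_control_normalize(floored)
    log2mat = xp.log2_quantile_normalize(normed)
    table = sigs.score_signatures(
        log2mat, panel.signatures, kinds=(sigs.KIND_CELL_TYPE, sigs.KIND_CATEGORY)
    )
    ztable = sigs.standardize_scores(table)
    return assoc.associate_signatures(ztable, cohort.truth.labels)


# ---------------------------------------------------------------------------
# published-table validation
# ---------------------------------------------------------------------------

#: the reproducible univariate odds-ratio targets: (cohort, table, scheme)
REPRODUCIBLE_OR_TARGETS = (
    ("FCCC", "til", "cut2"),
    ("FCCC", "til", "cut3"),
    ("UAB", "necrosis", None),
)


def _printed_tolerance(printed: float) -> float:
    """One unit in the last printed decimal place (accepts either rounding
    or truncation of the underlying value)."""
    text = f"{printed}"
    decimals = len(text.split(".")[1]) if "." in text else 0
    return 10.0 ** (-decimals)


def validate_tables(tables: dict | None = None, targets=REPRODUCIBLE_OR_TARGETS) -> list[dict]:
    """Recompute the published univariate odds ratios from the bundled
    cross-tabulation counts and compare each with its printed value at
    printed precision. Failures are listed, not raised."""
    tables = tables if tables is not None else morph.COHORT_TABLES
    results = []
    for cohort, name, scheme in targets:
        if name == "til":
            strata = tables[cohort]["til"]
            cut = 2 if scheme == "cut2" else 3
            n_hi = sum(n for s, (n, _) in strata.items() if s >= cut)
            r_hi = sum(r for s, (_, r) in strata.items() if s >= cut)
            n_lo = sum(n for s, (n, _) in strata.items() if s < cut)
            r_lo = sum(r for s, (_, r) in strata.items() if s < cut)
            table = morph.ContingencyTable2x2.from_margins(r_hi, n_hi, r_lo, n_lo)
            printed = tables[cohort]["printed_or"][f"til_{scheme}"]
            label = f"{cohort}_til_{scheme}"
        else:
            strata = tables[cohort][name]
            (hi, (n_hi, r_hi)), (lo, (n_lo, r_lo)) = strata.items()
            table = morph.ContingencyTable2x2.from_margins(r_hi, n_hi, r_lo, n_lo)
            printed = tables[cohort]["printed_or"][name]
            label = f"{cohort}_{name}"
        computed = morph.odds_ratio(table).odds_ratio
        tol = _printed_tolerance(printed)
        results.append(
            {
                "target": label,
                "computed": round(computed, 6),
                "printed": printed,
                "tolerance": tol,
                "passed": bool(abs(computed - printed) <= tol),
            }
        )
    return results
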