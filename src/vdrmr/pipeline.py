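"""End-to-end orchestration: simulate/load -> ASB -> GIV -> models -> meta.

A run is driven by a :class:`RunConfig` (loadable from YAML).  Cohorts are
either simulated or read from the interchange formats; instruments for
VDR binding come from a weights file, from the cohort simulation's own
binding effects, or from an in-run ChIP-exo simulation whose sites map
onto the cohorts' binding variants and are pushed through the ASB caller.
Each study is QC-filtered, mean-imputed, scored, and fitted with the main
and interaction logistic models; per-instrument results are pooled by
DerSimonian-Laird meta-analysis and BH-corrected within families.  Every
stage logs record counts to a manifest and all randomness derives from the
configured seed, so reruns are byte-identical.

The module also provides the power / type-I-error study of the
interaction-based pleiotropy test: under pure pleiotropy (the binding
variant affects disease only outside the binding path) the b3 product
term should reject at the nominal rate, while a genuine binding-by-25(OH)D
interaction should be detected with power growing in the effect size.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import asb as asb_mod
from . import io as io_mod
from .assoc import AssocResult, fit_interaction_model, fit_main_model
from .giv import (QcThresholds, VariantWeight, compute_giv_25ohd,
                  compute_giv_vdr, mean_impute, qc_filter)
from .meta import dl_meta, meta_analyze_family
from .simulate import (CohortData, SimAsbParams, SimCohortParams,
                       simulate_chipexo, simulate_cohort)

__all__ = ["RunConfig", "PowerScenario", "run_pipeline", "power_study",
           "PipelineStageError", "PipelineResult"]


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and offending item."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[stage: {stage}] {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``cohorts`` is a list of dicts, each with a ``study_label`` and either
    ``sim`` (SimCohortParams fields) or ``files`` (``prefix`` of the TSV
    trio, or ``vcf`` + ``covariates``).  ``vdr_instruments`` /
    ``ohd_instruments`` select the weight source: ``{"mode":
    "from_cohort_sim"}``, ``{"mode": "file", "path": ...}`` or (VDR only)
    ``{"mode": "asb_sim", ...SimAsbParams fields...}``.
    """

    cohorts: list = field(default_factory=list)
    vdr_instruments: dict = field(default_factory=lambda: {"mode": "from_cohort_sim"})
    ohd_instruments: dict = field(default_factory=lambda: {"mode": "from_cohort_sim"})
    standardize_25ohd: bool = False
    alpha: float = 0.05
    qc: dict = field(default_factory=dict)
    target_fdr: float = 0.02
    n_null_sims: int = 20
    seed: int = 0
    out_dir: str = "vdrmr_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not self.cohorts:
            raise ValueError("config must list at least one cohort")
        for spec in self.cohorts:
            if "sim" not in spec and "files" not in spec:
                raise ValueError("each cohort needs 'sim' or 'files'")
            if "files" in spec:
                f = spec["files"]
                for key in ("prefix", "vcf", "covariates"):
                    if key in f and not Path(
                            f[key] if key != "prefix"
                            else str(f[key]) + ".dosages.tsv").exists():
                        raise FileNotFoundError(
                            f"cohort input does not exist: {f[key]}")


@dataclass
class PipelineResult:
    """Tables and paths produced by one run."""

    out_dir: Path
    per_study: pd.DataFrame
    interaction_per_study: pd.DataFrame
    meta_tables: dict[str, pd.DataFrame]
    manifest: dict


@dataclass
class PowerScenario:
    """One cell of the power / type-I-error study of the b3 test."""

    label: str
    params: SimCohortParams
    n_cohorts: int = 4
    n_replicates: int = 100
    alpha: float = 0.05


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _load_cohorts(config: RunConfig, seeds: list[int], manifest: dict
                  ) -> list[CohortData]:
    cohorts = []
    for i, spec in enumerate(config.cohorts):
        label = spec.get("study_label", f"STUDY{i + 1}")
        try:
            if "sim" in spec:
                params = SimCohortParams(**{**spec["sim"],
                                            "study_label": label,
                                            "seed": seeds[i]})
                cohort = simulate_cohort(params)
            else:
                f = spec["files"]
                if "vcf" in f:
                    cohort = io_mod.read_cohort_vcf(
                        f["vcf"], f["covariates"], study_label=label)
                else:
                    cohort = io_mod.read_cohort_tsv(f["prefix"],
                                                    study_label=label)
        except Exception as exc:
            raise PipelineStageError("load_cohorts",
                                     f"cohort {label}: {exc}") from exc
        cohorts.append(cohort)
        manifest["cohorts"].append({
            "study": label, "n_cases": cohort.n_cases,
            "n_controls": cohort.n_controls,
            "n_variants": cohort.dosages.shape[1],
            "seed": cohort.attrs.get("seed"),
            "pool_case_fraction": cohort.attrs.get("pool_case_fraction"),
        })
    return cohorts


def _qc_stage(cohorts: list[CohortData], config: RunConfig, manifest: dict
              ) -> list[CohortData]:
    thresholds = QcThresholds(**config.qc) if config.qc else QcThresholds()
    out = []
    for cohort in cohorts:
        try:
            filtered = mean_impute(qc_filter(cohort, thresholds))
        except Exception as exc:
            raise PipelineStageError(
                "qc", f"cohort {cohort.study_label}: {exc}") from exc
        n_in = cohort.dosages.shape[1]
        n_kept = filtered.dosages.shape[1]
        manifest["qc"].append({
            "study": cohort.study_label,
            "variants_in": n_in,
            "variants_dropped": n_in - n_kept,
            "variants_retained": n_kept,
            "samples_dropped": filtered.attrs.get("qc_samples_dropped", 0),
            "dosages_imputed": filtered.attrs.get("n_imputed_dosages", 0),
        })
        out.append(filtered)
    return out


def _sim_weights_from_cohort(cohort: CohortData, which: str
                             ) -> list[VariantWeight]:
    key = "vdr_binding_betas" if which == "vdr" else "score_snp_betas"
    betas = cohort.attrs.get(key)
    if betas is None:
        raise PipelineStageError(
            "instruments", f"cohort {cohort.study_label} carries no "
            f"simulated {which} weights; use a weights file")
    out = []
    for rsid, beta in betas.items():
        if rsid not in cohort.variant_meta.index:
            continue
        meta = cohort.variant_meta.loc[rsid]
        out.append(VariantWeight(
            rsID=rsid, effect_allele=str(meta["effect_allele"]),
            other_allele=str(meta["other_allele"]), beta=float(beta),
            chrom=str(meta["chrom"]), pos=int(meta["pos"])))
    return out


def _vdr_instruments(config: RunConfig, cohorts: list[CohortData],
                     seed: int, out_dir: Path, manifest: dict
                     ) -> list[VariantWeight]:
    mode = config.vdr_instruments.get("mode", "from_cohort_sim")
    if mode == "file":
        weights = io_mod.read_weights_tsv(config.vdr_instruments["path"])
    elif mode == "from_cohort_sim":
        weights = _sim_weights_from_cohort(cohorts[0], "vdr")
    elif mode == "asb_sim":
        kw = {k: v for k, v in config.vdr_instruments.items()
              if k not in ("mode",)}
        vdr_ids = cohorts[0].vdr_variant_ids()
        params = SimAsbParams(**{"seed": seed, **kw})
        if params.n_sites < len(vdr_ids):
            raise PipelineStageError(
                "instruments", "asb_sim n_sites is smaller than the "
                "number of cohort VDR binding variants")
        dataset = simulate_chipexo(params)
        # map the first sites onto the cohorts' binding variants so called
        # sites become usable instruments
        mapping = dict(zip(dataset.sites.index[:len(vdr_ids)], vdr_ids))
        dataset.counts["site_id"] = dataset.counts["site_id"].map(
            lambda s: mapping.get(s, s))
        dataset.sites.index = [mapping.get(s, s)
                               for s in dataset.sites.index]
        if dataset.truth is not None:
            dataset.truth.index = [mapping.get(s, s)
                                   for s in dataset.truth.index]
        catalog = asb_mod.call_vdr_bvs(dataset, target_fdr=config.target_fdr,
                                       n_null_sims=config.n_null_sims,
                                       seed=seed)
        io_mod.write_catalog_tsv(catalog, out_dir / "vdr_bv_catalog.tsv")
        manifest["asb"] = {
            "sites_in": params.n_sites,
            "sites_called": len(catalog.calls),
            "fdr_cutoff_p": catalog.fdr_threshold_p,
        }
        weights = []
        meta0 = cohorts[0].variant_meta
        for call in catalog.calls:
            if call.site_id not in meta0.index:
                continue
            vm = meta0.loc[call.site_id]
            weights.append(VariantWeight(
                rsID=call.site_id, effect_allele=str(vm["effect_allele"]),
                other_allele=str(vm["other_allele"]),
                beta=float(call.effect_beta), p_value=call.p_value,
                chrom=str(vm["chrom"]), pos=int(vm["pos"])))
    else:
        raise PipelineStageError("instruments",
                                 f"unknown VDR instrument mode {mode!r}")
    if not weights:
        raise PipelineStageError("instruments",
                                 "no usable VDR instruments")
    manifest["instruments"]["vdr"] = {
        "mode": mode, "n": len(weights),
        "rsids": [w.rsID for w in weights]}
    return weights


def _ohd_instruments(config: RunConfig, cohorts: list[CohortData],
                     manifest: dict) -> list[VariantWeight]:
    mode = config.ohd_instruments.get("mode", "from_cohort_sim")
    if mode == "file":
        weights = io_mod.read_weights_tsv(config.ohd_instruments["path"])
    elif mode == "from_cohort_sim":
        weights = _sim_weights_from_cohort(cohorts[0], "ohd")
    else:
        raise PipelineStageError("instruments",
                                 f"unknown 25(OH)D instrument mode {mode!r}")
    if not weights:
        raise PipelineStageError("instruments",
                                 "no usable 25(OH)D instruments")
    manifest["instruments"]["ohd"] = {"mode": mode, "n": len(weights)}
    return weights


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute a configured run and write its results bundle.

    Products under ``config.out_dir``: per-study main-effect and
    interaction TSVs, per-family meta TSVs (with BH ``p_fdr``), a JSON
    manifest with the config echo, seeds and per-stage record counts, and
    a plain-text report.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": _config_echo(config), "cohorts": [],
                      "qc": [], "instruments": {}, "stages": []}

    seeds = _child_seeds(config.seed, len(config.cohorts) + 2)
    cohort_seeds, asb_seed = seeds[:-2], seeds[-2]

    def stage(name, fn, *args, **kw):
        t = time.time()
        out = fn(*args, **kw)
        manifest["stages"].append({"stage": name,
                                   "seconds": round(time.time() - t, 3)})
        return out

    cohorts = stage("load_cohorts", _load_cohorts, config, cohort_seeds,
                    manifest)
    cohorts = stage("qc", _qc_stage, cohorts, config, manifest)
    vdr_weights = stage("vdr_instruments", _vdr_instruments, config, cohorts,
                        asb_seed, out_dir, manifest)
    ohd_weights = stage("ohd_instruments", _ohd_instruments, config, cohorts,
                        manifest)

    # per-study models
    main_rows: list[AssocResult] = []
    main_instr: list[str] = []
    int_rows: list[AssocResult] = []
    int_instr: list[str] = []
    vdr_family: dict[str, list[AssocResult]] = {w.rsID: [] for w in vdr_weights}
    ohd_family: dict[str, list[AssocResult]] = {"giv_25ohd": []}
    interaction_family: dict[str, list[AssocResult]] = {
        w.rsID: [] for w in vdr_weights}

    t_model = time.time()
    for cohort in cohorts:
        try:
            ohd_score = compute_giv_25ohd(cohort, ohd_weights)["score"]
            r = fit_main_model(cohort, ohd_score, term="giv_25ohd",
                               standardize_25ohd=config.standardize_25ohd)
            main_rows.append(r)
            main_instr.append("giv_25ohd")
            ohd_family["giv_25ohd"].append(r)
            for w in vdr_weights:
                giv = compute_giv_vdr(cohort, w)
                r = fit_main_model(cohort, giv, term="giv_vdr")
                main_rows.append(r)
                main_instr.append(w.rsID)
                vdr_family[w.rsID].append(r)
                inter = fit_interaction_model(
                    cohort, giv, ohd_score,
                    standardize_25ohd=config.standardize_25ohd)
                b3 = inter["giv_vdr:giv_25ohd"]
                int_rows.append(b3)
                int_instr.append(w.rsID)
                interaction_family[w.rsID].append(b3)
        except Exception as exc:
            raise PipelineStageError(
                "associate",
                f"cohort {cohort.study_label}: {exc}") from exc
    manifest["stages"].append({"stage": "associate",
                               "seconds": round(time.time() - t_model, 3),
                               "n_fits": len(main_rows) + len(int_rows)})

    t_meta = time.time()
    meta_tables = {
        "vdr_main": meta_analyze_family(vdr_family, family="vdr_main"),
        "ohd_main": meta_analyze_family(ohd_family, family="ohd_main"),
        "interaction": meta_analyze_family(interaction_family,
                                           family="interaction"),
    }
    manifest["stages"].append({"stage": "meta",
                               "seconds": round(time.time() - t_meta, 3)})

    io_mod.write_assoc_tsv(main_rows, out_dir / "per_study_main.tsv",
                           instrument=main_instr)
    io_mod.write_assoc_tsv(int_rows, out_dir / "per_study_interaction.tsv",
                           instrument=int_instr)
    for name, table in meta_tables.items():
        table.to_csv(out_dir / f"meta_{name}.tsv", sep="\t", index=False)
    manifest["total_seconds"] = round(time.time() - t0, 3)
    manifest["n_significant"] = {
        name: int((tab["p"] < config.alpha).sum())
        for name, tab in meta_tables.items()}
    manifest["n_significant_fdr"] = {
        name: int((tab["p_fdr"] < config.alpha).sum())
        for name, tab in meta_tables.items()}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    _write_report(out_dir, config, meta_tables)
    return PipelineResult(out_dir=out_dir,
                          per_study=pd.read_csv(
                              out_dir / "per_study_main.tsv", sep="\t"),
                          interaction_per_study=pd.read_csv(
                              out_dir / "per_study_interaction.tsv", sep="\t"),
                          meta_tables=meta_tables, manifest=manifest)


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["cohorts"] = [
        {k: (v if not isinstance(v, dict) else dict(v))
         for k, v in spec.items()} for spec in config.cohorts]
    return echo


def _write_report(out_dir: Path, config: RunConfig,
                  meta_tables: dict[str, pd.DataFrame]) -> None:
    lines = ["VDR binding / 25(OH)D Mendelian randomization run", ""]
    for name, title in [("ohd_main", "25(OH)D genetic score, main effect"),
                        ("vdr_main", "VDR binding variants, main effects"),
                        ("interaction",
                         "VDR x 25(OH)D interaction (pleiotropy test)")]:
        tab = meta_tables[name]
        lines.append(f"== {title} ==")
        cols = ["instrument", "k", "pooled_or", "ci_low", "ci_high", "p",
                "tau2", "Q", "p_Q", "I2_percent", "p_fdr"]
        lines.append(tab[cols].to_string(
            index=False, float_format=lambda v: f"{v:.4g}"))
        n_sig = int((tab["p"] < config.alpha).sum())
        n_fdr = int((tab["p_fdr"] < config.alpha).sum())
        lines.append(f"significant at p<{config.alpha}: {n_sig}; "
                     f"after BH correction: {n_fdr}")
        lines.append("")
    (out_dir / "report.txt").write_text("\n".join(lines))


# -- power / type-I-error study -------------------------------------------

def _beta3_meta_p(params: SimCohortParams, n_cohorts: int,
                  seeds: Sequence[int],
                  standardize_25ohd: bool = False) -> float:
    """Meta-analyzed Wald p of the b3 term over freshly simulated cohorts."""
    results = []
    for c in range(n_cohorts):
        cohort = simulate_cohort(replace(params, seed=seeds[c],
                                         study_label=f"S{c + 1}"))
        vdr_id = cohort.vdr_variant_ids()[0]
        binding = cohort.attrs["vdr_binding_betas"][vdr_id]
        giv_vdr = cohort.dosages[vdr_id] * binding
        score_betas = cohort.attrs["score_snp_betas"]
        giv_ohd = cohort.dosages[list(score_betas)].to_numpy() @ np.asarray(
            list(score_betas.values()))
        inter = fit_interaction_model(cohort, giv_vdr,
                                      pd.Series(giv_ohd,
                                                index=cohort.dosages.index),
                                      standardize_25ohd=standardize_25ohd)
        results.append(inter["giv_vdr:giv_25ohd"])
    mr = dl_meta([r.log_or for r in results], [r.se for r in results])
    return mr.p_value


def power_study(scenarios: Sequence[PowerScenario], seed: int = 0
                ) -> pd.DataFrame:
    """Rejection rate of the b3 pleiotropy test per scenario.

    Each replicate simulates ``n_cohorts`` fresh studies under the
    scenario parameters, fits the interaction model in each, pools the b3
    terms by DerSimonian-Laird, and rejects when the pooled Wald p falls
    below alpha.  Scenarios with ``beta_interaction = 0`` estimate type-I
    error; the rest estimate power.  Replicate-level model failures are
    counted in ``n_failed`` rather than silently dropped.
    """
    rows = []
    scen_seeds = _child_seeds(seed, len(scenarios))
    for scen, s0 in zip(scenarios, scen_seeds):
        rep_seed_blocks = np.random.SeedSequence(s0).spawn(scen.n_replicates)
        n_reject = n_failed = 0
        for block in rep_seed_blocks:
            seeds = [int(x % (2**31 - 1)) for x in
                     block.generate_state(scen.n_cohorts)]
            try:
                p = _beta3_meta_p(scen.params, scen.n_cohorts, seeds)
            except Exception:
                n_failed += 1
                continue
            if p < scen.alpha:
                n_reject += 1
        n_ok = scen.n_replicates - n_failed
        rate = n_reject / n_ok if n_ok else np.nan
        se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else np.nan
        rows.append({
            "scenario": scen.label,
            "beta_vdr": float(np.mean(np.atleast_1d(scen.params.beta_vdr))),
            "beta_pleio": float(np.mean(np.atleast_1d(scen.params.beta_pleio))),
            "beta_interaction": float(np.mean(
                np.atleast_1d(scen.params.beta_interaction))),
            "n_cohorts": scen.n_cohorts, "alpha": scen.alpha,
            "n_replicates": scen.n_replicates, "n_failed": n_failed,
            "n_reject": n_reject, "rejection_rate": rate,
            "binomial_se": se,
        })
    return pd.DataFrame(rows)
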