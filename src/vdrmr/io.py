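"""Readers and writers for the interchange formats.

Cohorts travel either as a trio of TSVs (wide dosage matrix, variant
metadata, covariates-plus-status) or as a VCF with a per-sample ``DS``
dosage FORMAT field (effect allele stored as ALT) plus the covariate TSV.
Instrument weights, allele-specific count tables, called-catalog tables,
per-individual scores and association/meta results each have a flat TSV
form.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .asb import VdrBvCatalog
from .assoc import AssocResult
from .giv import VariantWeight
from .simulate import AsbDataset, CohortData

__all__ = [
    "write_cohort_tsv", "read_cohort_tsv",
    "write_cohort_vcf", "read_cohort_vcf",
    "write_covariates_tsv", "read_covariates_tsv",
    "read_weights_tsv", "write_weights_tsv",
    "write_asb_tsv", "read_asb_tsv",
    "write_catalog_tsv",
    "write_scores_tsv",
    "write_assoc_tsv",
]


# -- cohort: TSV trio ------------------------------------------------------

def write_covariates_tsv(cohort: CohortData, path) -> None:
    out = cohort.covariates.copy()
    out.insert(0, "sample_id", cohort.covariates.index)
    out["status"] = cohort.status.to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    t = t.set_index("sample_id")
    status = t.pop("status").astype(int)
    return t, status


def write_cohort_tsv(cohort: CohortData, prefix) -> dict[str, Path]:
    """Write <prefix>.dosages.tsv / .variants.tsv / .covariates.tsv."""
    prefix = Path(prefix)
    paths = {
        "dosages": prefix.with_suffix(".dosages.tsv"),
        "variants": prefix.with_suffix(".variants.tsv"),
        "covariates": prefix.with_suffix(".covariates.tsv"),
    }
    d = cohort.dosages.copy()
    d.insert(0, "sample_id", cohort.dosages.index)
    d.to_csv(paths["dosages"], sep="\t", index=False, na_rep="NA")
    vm = cohort.variant_meta.copy()
    vm.insert(0, "rsID", cohort.variant_meta.index)
    vm.to_csv(paths["variants"], sep="\t", index=False)
    write_covariates_tsv(cohort, paths["covariates"])
    return paths


def read_cohort_tsv(prefix, study_label: str | None = None) -> CohortData:
    prefix = Path(prefix)
    d = pd.read_csv(prefix.with_suffix(".dosages.tsv"), sep="\t",
                    na_values=["NA"], dtype={"sample_id": str})
    d = d.set_index("sample_id")
    d.index.name = None
    vm = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t",
                     dtype={"rsID": str, "chrom": str}).set_index("rsID")
    cov, status = read_covariates_tsv(prefix.with_suffix(".covariates.tsv"))
    cohort = CohortData(
        study_label=study_label or prefix.name,
        dosages=d, variant_meta=vm, covariates=cov.loc[d.index],
        status=status.loc[d.index])
    cohort.validate()
    return cohort


# -- cohort: VCF -----------------------------------------------------------

def write_cohort_vcf(cohort: CohortData, path) -> None:
    """Dosage VCF: one record per variant, effect allele as ALT, per-sample
    DS field carrying the effect-allele dosage (missing where NA)."""
    header = pysam.VariantHeader()
    for chrom in pd.unique(cohort.variant_meta["chrom"].astype(str)):
        header.contigs.add(chrom)
    header.formats.add("DS", 1, "Float", "Effect-allele dosage")
    header.info.add("EAF", 1, "Float", "Effect-allele frequency")
    header.info.add("IMPINFO", 1, "Float", "Imputation info score")
    for s in cohort.dosages.index:
        header.add_sample(str(s))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rsid, meta in cohort.variant_meta.iterrows():
            rec = vcf.new_record(
                contig=str(meta["chrom"]), start=int(meta["pos"]) - 1,
                alleles=(str(meta["other_allele"]), str(meta["effect_allele"])),
                id=str(rsid))
            rec.info["EAF"] = float(meta["eaf"])
            rec.info["IMPINFO"] = float(meta["info"])
            col = cohort.dosages[rsid]
            for s in cohort.dosages.index:
                v = col.loc[s]
                if not np.isnan(v):
                    rec.samples[str(s)]["DS"] = float(v)
            vcf.write(rec)


def read_cohort_vcf(path, covariates_path, study_label: str = "VCF",
                    vdr_prefix: str = "rsVDR") -> CohortData:
    """Read a dosage VCF plus its covariate TSV back into a cohort.

    Variants whose IDs start with ``vdr_prefix`` are flagged as VDR
    binding variants.
    """
    rows, meta_rows, rsids = [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            rsids.append(rec.id)
            meta_rows.append({
                "chrom": rec.chrom, "pos": rec.pos,
                "effect_allele": rec.alts[0], "other_allele": rec.ref,
                "eaf": float(rec.info.get("EAF", np.nan)),
                "info": float(rec.info.get("IMPINFO", 1.0)),
                "is_vdr_bv": str(rec.id).startswith(vdr_prefix),
            })
            vals = []
            for s in samples:
                ds = rec.samples[s].get("DS")
                vals.append(np.nan if ds is None else float(ds))
            rows.append(vals)
    dosages = pd.DataFrame(np.asarray(rows).T, index=pd.Index(samples),
                           columns=rsids)
    vm = pd.DataFrame(meta_rows, index=pd.Index(rsids, name="rsID"))
    cov, status = read_covariates_tsv(covariates_path)
    cohort = CohortData(study_label=study_label, dosages=dosages,
                        variant_meta=vm, covariates=cov.loc[dosages.index],
                        status=status.loc[dosages.index])
    cohort.validate()
    return cohort


# -- instrument weights ----------------------------------------------------

def write_weights_tsv(weights: Sequence[VariantWeight], path) -> None:
    pd.DataFrame([{
        "rsID": w.rsID, "chrom": w.chrom, "pos": w.pos,
        "effect_allele": w.effect_allele,
        "other_allele": w.other_allele if w.other_allele else ".",
        "beta": w.beta, "p": w.p_value,
    } for w in weights]).to_csv(path, sep="\t", index=False)


def read_weights_tsv(path) -> list[VariantWeight]:
    t = pd.read_csv(path, sep="\t", dtype={"rsID": str, "chrom": str})
    out = []
    for _, r in t.iterrows():
        other = r.get("other_allele", ".")
        out.append(VariantWeight(
            rsID=r["rsID"], effect_allele=str(r["effect_allele"]),
            beta=float(r["beta"]), p_value=float(r.get("p", 1.0)),
            chrom=str(r.get("chrom", ".")), pos=int(r.get("pos", 0)),
            other_allele=None if other in (".", None) or pd.isna(other)
            else str(other)))
    return out


# -- allele-specific counts and calls --------------------------------------

def write_asb_tsv(dataset: AsbDataset, path) -> None:
    cols = ["site_id", "chrom", "pos", "sample_id", "ref_reads", "alt_reads"]
    dataset.counts[cols].to_csv(path, sep="\t", index=False)


def read_asb_tsv(path, ref_allele: str = "C", alt_allele: str = "T"
                 ) -> AsbDataset:
    counts = pd.read_csv(path, sep="\t",
                         dtype={"site_id": str, "chrom": str,
                                "sample_id": str})
    sites = (counts[["site_id", "chrom", "pos"]]
             .drop_duplicates("site_id").set_index("site_id"))
    sites["ref"] = ref_allele
    sites["alt"] = alt_allele
    return AsbDataset(counts=counts, sites=sites, truth=None)


def write_catalog_tsv(catalog: VdrBvCatalog, path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


# -- scores and results ----------------------------------------------------

def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    out.insert(0, "sample_id", scores.index)
    out.to_csv(path, sep="\t", index=False)


def write_assoc_tsv(results: Sequence[AssocResult], path,
                    instrument: Sequence[str] | None = None) -> None:
    rows = []
    for i, r in enumerate(results):
        rows.append({
            "study": r.study_label,
            "instrument": instrument[i] if instrument else r.term,
            "term": r.term, "log_or": r.log_or, "se": r.se,
            "or": r.odds_ratio, "ci_low": r.or_ci95[0],
            "ci_high": r.or_ci95[1], "p": r.p_value,
            "n_cases": r.n_cases, "n_controls": r.n_controls,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
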