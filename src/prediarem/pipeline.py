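"""End-to-end analysis: phenotyping -> classification -> statistics.

``run_pipeline`` consumes the delimited tables written by the simulator (or
supplied by a user in the same layout), computes the per-visit OGTT index
panel and deconvolved secretion rates, labels responders within the
non-weight-loss stratum, fits the group x time mixed models with
Benjamini-Hochberg correction across the family, runs the progression
analysis (risk ratio, Kaplan-Meier, log-rank), scores and adjusts the VAT
polygenic score, and emits a machine-readable report bundle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import classify, cpeptide, ogtt, prs, stats
from .units import TimedSeries, fraction_pct

__all__ = ["load_ogtt_records", "run_pipeline"]

MODEL_OUTCOMES = [
    "ogis",
    "matsuda",
    "hepatic_ir",
    "secretion_index",
    "adaptation_index",
    "insulin_clearance",
    "vat_l",
    "scat_l",
    "scat_vat_ratio",
    "liver_fat_pct",
]
SECRETION_OUTCOMES = {"secretion_index", "adaptation_index"}
COVARIATES = ["age", "sex", "bmi_baseline", "risk_stratum", "intensity"]


def load_ogtt_records(ogtt_df: pd.DataFrame, subjects: pd.DataFrame) -> dict:
    """Assemble OGTTRecord objects from the long-format table.

    Returns ``{(subject_id, visit): OGTTRecord}``; HbA1c and fasting NEFA
    are joined in from the subjects table.
    """
    subj = subjects.set_index("subject_id")
    records = {}
    for (sid, visit), block in ogtt_df.groupby(["subject_id", "visit"]):
        series = {}
        for analyte, sub in block.groupby("analyte"):
            sub = sub.sort_values("time_min")
            series[analyte] = TimedSeries(
                sub["time_min"].to_numpy(float),
                sub["value"].to_numpy(float),
                str(sub["unit"].iloc[0]),
            )
        if "glucose" not in series or "insulin" not in series:
            raise ValueError(f"subject {sid} visit {visit}: glucose/insulin missing")
        hba1c = subj.loc[sid, f"hba1c_{visit}"]
        nefa = subj.loc[sid].get("fasting_nefa", np.nan)
        records[(sid, visit)] = ogtt.OGTTRecord(
            subject_id=str(sid),
            visit=str(visit),
            glucose=series["glucose"],
            insulin=series["insulin"],
            c_peptide=series.get("c_peptide"),
            glp1=series.get("glp1"),
            gip=series.get("gip"),
            glucagon=series.get("glucagon"),
            fasting_nefa=None if pd.isna(nefa) else float(nefa),
            hba1c=float(hba1c),
        )
    return records


def _classify_visits(records: dict) -> pd.DataFrame:
    rows = []
    for (sid, visit), rec in records.items():
        inputs = classify.GlycemicInputs(
            fpg=rec.glucose.value_at(0.0),
            hba1c=rec.hba1c,
            g120=rec.glucose.value_at(120.0),
            g60=rec.glucose.value_at(60.0) if rec.glucose.has_times([60.0]) else None,
        )
        rows.append(
            {
                "subject_id": sid,
                "visit": visit,
                "status": classify.classify_status(inputs).value,
            }
        )
    return pd.DataFrame(rows)


def _panels(records: dict, subjects: pd.DataFrame) -> pd.DataFrame:
    subj = subjects.set_index("subject_id")
    rows = []
    for (sid, visit), rec in records.items():
        weight = subj.loc[sid, f"weight_{visit}"]
        bsa = ogtt.bsa_dubois(float(weight), float(subj.loc[sid, "height_m"]))
        panel = ogtt.compute_panel(rec, bsa).as_dict()
        panel["group"] = subj.loc[sid, "group"]
        rows.append(panel)
    return pd.DataFrame(rows)


def _isr_tables(records: dict, subjects: pd.DataFrame):
    subj = subjects.set_index("subject_id")
    isr_rows, sens_rows = [], []
    for (sid, visit), rec in records.items():
        if rec.c_peptide is None:
            continue
        weight = float(subj.loc[sid, f"weight_{visit}"])
        params = cpeptide.vancauter_params(
            float(subj.loc[sid, "age"]),
            str(subj.loc[sid, "sex"]),
            float(subj.loc[sid, "height_m"]),
            weight,
            "prediabetes",
        )
        profile = cpeptide.deconvolve_isr(rec.c_peptide, params)
        for t, v in zip(profile.times, profile.isr):
            isr_rows.append(
                {"subject_id": sid, "visit": visit, "time_min": t, "isr_pmol_min": v}
            )
        if rec.glp1 is not None:
            iauc_isr, iauc_glp1, ratio = cpeptide.beta_cell_glp1_sensitivity(
                profile, rec.glp1
            )
            sens_rows.append(
                {
                    "subject_id": sid,
                    "visit": visit,
                    "iauc_isr": iauc_isr,
                    "iauc_glp1": iauc_glp1,
                    "ratio": ratio,
                    "isr_auc_0_120": profile.auc(0.0, 120.0),
                }
            )
    return pd.DataFrame(isr_rows), pd.DataFrame(sens_rows)


def _long_table(panels, imaging, subjects):
    subj = subjects[
        ["subject_id", "group", "age", "sex", "bmi_baseline", "risk_stratum", "intensity"]
    ]
    img = imaging.copy()
    img["scat_vat_ratio"] = img["scat_l"] / img["vat_l"]
    merged = panels.drop(columns=["group"]).merge(
        img, on=["subject_id", "visit"], how="outer"
    )
    merged = merged.merge(subj, on="subject_id", how="left")
    merged = merged.rename(columns={"visit": "time"})
    return merged


def _fit_models(long_df: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    results = []
    for outcome in MODEL_OUTCOMES:
        if outcome not in long_df.columns or long_df[outcome].dropna().empty:
            continue
        extra = ["insulin_sensitivity"] if outcome in SECRETION_OUTCOMES else []
        tab = long_df.rename(columns={outcome: "value"})[
            ["subject_id", "group", "time", "value"] + COVARIATES + extra
        ]
        res = stats.fit_group_time_model(
            tab,
            outcome=outcome,
            covariates=COVARIATES,
            adjust_for_sensitivity=outcome in SECRETION_OUTCOMES,
        )
        results.append(res)
    pvals = [r.p_interaction for r in results]
    adjusted = stats.bh_adjust(pvals)
    for r, p in zip(results, adjusted):
        r.p_adjusted = float(p)
    return pd.DataFrame([r.as_dict() for r in results]), results


def _progression(survival: pd.DataFrame) -> dict:
    grp = survival.groupby("group")
    a = int(grp.get_group("R")["event"].sum())
    b = int((1 - grp.get_group("R")["event"]).sum())
    c = int(grp.get_group("NR")["event"].sum())
    d = int((1 - grp.get_group("NR")["event"]).sum())
    rr = stats.relative_risk(a, b, c, d)
    chi2, p_lr = stats.log_rank(
        survival["time_years"], survival["event"].astype(bool), survival["group"]
    )
    km = {}
    for g, block in grp:
        timeline, surv = stats.km_estimate(
            block["time_years"], block["event"].astype(bool)
        )
        km[g] = {"time": timeline.tolist(), "survival": surv.tolist()}
    return {
        "events": {"R": a, "NR": c},
        "at_risk": {"R": a + b, "NR": c + d},
        "relative_risk": rr.rr,
        "rr_ci": [rr.ci_low, rr.ci_high],
        "p_fisher": rr.p_fisher,
        "log_rank_chi2": chi2,
        "log_rank_p": p_lr,
        "km": km,
    }


def _prs_section(genotypes, snp_meta, weights, subjects) -> dict:
    retained, report = prs.snp_qc(genotypes)
    if not retained:
        return {"available": False, "reason": "no SNP passed QC"}
    scores = prs.compute_prs(genotypes[retained], weights, snp_meta.loc[retained])
    subj = subjects.set_index("subject_id").loc[scores.index]
    cov = pd.DataFrame(
        {
            "age": subj["age"].astype(float),
            "sex": (subj["sex"] == "F").astype(float),
            "bmi": subj["bmi_baseline"].astype(float),
        }
    )
    adjusted = prs.adjust_prs(scores, cov)
    r_mask = subj["group"] == "R"
    raw_p = sps.mannwhitneyu(scores[r_mask], scores[~r_mask]).pvalue
    adj_p = sps.mannwhitneyu(adjusted[r_mask], adjusted[~r_mask]).pvalue
    return {
        "available": True,
        "n_snps_input": int(genotypes.shape[1]),
        "n_snps_retained": len(retained),
        "group_medians_raw": {
            "R": float(scores[r_mask].median()),
            "NR": float(scores[~r_mask].median()),
        },
        "p_raw": float(raw_p),
        "p_adjusted_score": float(adj_p),
        "scores": pd.DataFrame(
            {"raw_score": scores, "adjusted_score": adjusted}
        ),
        "qc_report": report,
    }


def _incretin_section(records: dict, subjects: pd.DataFrame) -> dict:
    subj = subjects.set_index("subject_id")
    rows = []
    for (sid, visit), rec in records.items():
        if rec.glp1 is None and rec.gip is None and rec.glucagon is None:
            continue
        entry = {"subject_id": sid, "visit": visit, "group": subj.loc[sid, "group"]}
        entry.update(cpeptide.hormone_aucs(rec))
        if rec.glucagon is not None and rec.glucagon.has_times([0.0, 30.0]):
            entry["glucagon_suppression_pct"] = cpeptide.glucagon_suppression(
                rec.glucagon
            )
        rows.append(entry)
    if not rows:
        return {"available": False}
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["group", "visit"])
        .mean(numeric_only=True)
        .round(6)
        .reset_index()
        .to_dict(orient="records")
    )
    return {"available": True, "summary": summary}


def run_pipeline(input_dir, out_dir=None, seed: int = 0) -> dict:
    """Execute the full analysis on a directory of input tables.

    Expects ``subjects.csv``, ``ogtt.csv``, ``imaging.csv``,
    ``survival.csv`` and optionally ``genotypes.tsv`` / ``snps.tsv`` /
    ``weights.tsv``.  Writes ``report.json`` plus per-stage CSVs when
    ``out_dir`` is given, and returns the report dictionary.
    """
    input_dir = Path(input_dir)
    subjects = pd.read_csv(input_dir / "subjects.csv")
    ogtt_df = pd.read_csv(input_dir / "ogtt.csv")
    imaging = pd.read_csv(input_dir / "imaging.csv")
    survival = pd.read_csv(input_dir / "survival.csv")

    impute_vars = [
        v for v in ("liver_fat_pct", "scat_l", "vat_l") if imaging[v].isna().any()
    ]
    imputation_note = "none required"
    if impute_vars:
        completed = stats.impute_missing(imaging, impute_vars, m=5, seed=seed)
        imaging = completed[0].copy()
        for v in impute_vars:  # average the chained-equation draws
            imaging[v] = np.mean([c[v].to_numpy(float) for c in completed], axis=0)
        imputation_note = f"chained-equation imputation (m=5) for {impute_vars}"

    records = load_ogtt_records(ogtt_df, subjects)
    status = _classify_visits(records)
    wide_status = status.pivot(index="subject_id", columns="visit", values="status")

    labels = []
    subj_idx = subjects.set_index("subject_id")
    for sid, row in wide_status.iterrows():
        w0 = float(subj_idx.loc[sid, "weight_baseline"])
        w12 = float(subj_idx.loc[sid, "weight_month12"])
        if not classify.non_weight_loss_filter(w0, w12):
            continue
        lab = classify.label_response(
            classify.GlycemicStatus(row["month12"]), weight_change=w12 - w0
        )
        labels.append(
            {
                "subject_id": sid,
                "status_baseline": row["baseline"],
                "status_month12": row["month12"],
                "response_label": lab.label,
                "weight_change_kg": lab.weight_change,
                "criterion": "standard",
            }
        )
    labels = pd.DataFrame(labels)

    panels = _panels(records, subjects)
    isr_df, glp1_sens = _isr_tables(records, subjects)
    long_df = _long_table(panels, imaging, subjects)
    long_df["insulin_sensitivity"] = long_df["ogis"]
    models_df, model_results = _fit_models(long_df)
    trans = classify.transition_table(
        wide_status["baseline"], wide_status["month12"]
    )

    n_r = int((labels["response_label"] == "R").sum())
    n_nr = int((labels["response_label"] == "NR").sum())
    n = n_r + n_nr
    report = {
        "seed": seed,
        "cohort": {
            "n_non_weight_loss": n,
            "n_responders": n_r,
            "n_nonresponders": n_nr,
            "pct_responders": fraction_pct(n_r, n) if n else float("nan"),
            "pct_nonresponders": fraction_pct(n_nr, n) if n else float("nan"),
        },
        "imputation": imputation_note,
        "transitions": {
            "from": trans.index.tolist(),
            "counts": trans.to_numpy().tolist(),
        },
        "models": models_df.to_dict(orient="records"),
        "incretins": _incretin_section(records, subjects),
        "progression": _progression(
            survival.merge(labels[["subject_id"]], on="subject_id", how="inner")
        ),
    }

    prs_scores = None
    geno_path = input_dir / "genotypes.tsv"
    if geno_path.exists():
        genotypes = pd.read_csv(geno_path, sep="\t", index_col=0)
        snp_meta = pd.read_csv(input_dir / "snps.tsv", sep="\t", index_col=0)
        weights = pd.read_csv(input_dir / "weights.tsv", sep="\t", index_col=0)
        section = _prs_section(genotypes, snp_meta, weights, subjects)
        if section.get("available"):
            prs_scores = section.pop("scores")
            section.pop("qc_report")
        report["prs"] = section
    else:
        report["prs"] = {"available": False, "reason": "no genotype table"}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        panels.to_csv(out / "index_panel.csv", index=False)
        labels.to_csv(out / "labels.csv", index=False)
        if not isr_df.empty:
            isr_df.to_csv(out / "isr.csv", index=False)
        if not glp1_sens.empty:
            glp1_sens.to_csv(out / "glp1_sens.csv", index=False)
        models_df.to_csv(out / "models.csv", index=False)
        if prs_scores is not None:
            prs_scores.rename_axis("subject_id").to_csv(out / "prs.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
    return report
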