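"""Synthetic lifestyle-intervention cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes: a non-weight-loss stratum of two groups — responders (R), who reach
normal glucose regulation at month 12, and nonresponders (NR), who do not —
with similar weight gain but diverging fat-depot redistribution (VAT rises
in NR, subcutaneous fat in R), an R-confined improvement in insulin
sensitivity and early-phase secretion, incretin/glucagon profiles, genotype
dosages with known-truth QC failures, and exponential time-to-diabetes
outcomes whose per-group cumulative incidences give a responder risk ratio
of about 0.29 over the 10-year horizon.

Group sizes and the group x visit means default to the published cohort
summaries used as calibration targets; dispersions quoted as 95% CIs of
means are converted to SDs as ``ci_half_width * sqrt(n) / 1.96``.  C-peptide
is never sampled directly: each subject's secretion-rate profile is drawn
and plasma C-peptide produced through the forward two-compartment model, so
deconvolution has a ground truth by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import GlycemicStatus, GlycemicInputs, classify_status
from .cpeptide import ISRProfile, forward_cpeptide, vancauter_params
from .ogtt import OGTTRecord
from .units import TimedSeries

__all__ = [
    "CohortConfig",
    "SubjectCourse",
    "Cohort",
    "default_config",
    "generate_cohort",
    "generate_ogtt_curve",
    "generate_fat_depots",
    "generate_survival",
    "generate_genotypes",
]

GRID = np.array([0.0, 30.0, 60.0, 90.0, 120.0])

_SD = {"R": math.sqrt(51) / 1.96, "NR": math.sqrt(183) / 1.96}


def _sd(group: str, ci_half_width: float, n: float | None = None) -> float:
    """Back-compute an SD from a 95% CI half-width of a mean."""
    if n is not None:
        return ci_half_width * math.sqrt(n) / 1.96
    return ci_half_width * _SD[group]


@dataclass
class CohortConfig:
    """All generator parameters.

    ``continuous`` maps variable -> group -> (mean0, mean12, sd0, sd12);
    ``curves`` maps analyte -> (group, visit) -> 5-point mean profile on the
    0/30/60/90/120 min grid.  ``incidence`` holds per-group cumulative
    T2D probabilities over ``follow_up_years``.
    """

    n_responders: int = 51
    n_nonresponders: int = 183
    follow_up_years: float = 10.0
    incidence: dict = field(default_factory=lambda: {"R": 0.0725, "NR": 0.25})
    censoring_rate: float = 0.15
    rho: float = 0.7  # within-subject baseline <-> month-12 correlation
    scat_vat_corr: float = 0.5  # cross-sectional SCAT <-> VAT correlation
    age: dict = field(default_factory=lambda: {"R": (54.4, 8.5), "NR": (59.4, 8.0)})
    female_frac: dict = field(default_factory=lambda: {"R": 0.745, "NR": 0.601})
    continuous: dict = field(default_factory=dict)
    weight_gain: dict = field(default_factory=lambda: {"R": (2.8, 2.0), "NR": (2.2, 2.0)})
    curves: dict = field(default_factory=dict)
    glucose_subject_sd: float = 0.4  # mmol/l, whole-curve shift
    glucose_point_sd: float = 0.25  # mmol/l, per-time-point
    insulin_subject_logsd: float = 0.25
    insulin_point_logsd: float = 0.08
    isr_subject_logsd: float = 0.2
    cpep_noise_cv: float = 0.02
    cpep_fasting: dict = field(
        default_factory=lambda: {
            ("R", "baseline"): 700.0,
            ("R", "month12"): 680.0,
            ("NR", "baseline"): 800.0,
            ("NR", "month12"): 810.0,
        }
    )
    isr_amplitude: dict = field(
        default_factory=lambda: {
            ("R", "baseline"): 450.0,
            ("R", "month12"): 560.0,
            ("NR", "baseline"): 480.0,
            ("NR", "month12"): 485.0,
        }
    )
    isr_shape: tuple = (0.0, 1.0, 0.9, 0.6, 0.3)
    hba1c_slope: float = 6.0  # mmol/mol per mmol/l fasting glucose
    hba1c_sd: float = 1.5
    nefa_log_mean: float = math.log(550.0)  # µmol/l
    nefa_log_sd: float = 0.35
    n_snps: int = 205
    maf_range: tuple = (0.05, 0.5)
    n_fail_missingness: int = 7
    n_fail_maf: int = 6
    n_fail_hwe: int = 6
    max_rejection_draws: int = 500

    def group_sizes(self) -> dict:
        return {"R": self.n_responders, "NR": self.n_nonresponders}

    def to_yaml(self, path) -> None:
        def plain(v):
            if isinstance(v, (tuple, list, np.ndarray)):
                return [plain(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        d = asdict(self)
        for key in ("cpep_fasting", "isr_amplitude"):
            d[key] = {"|".join(k): plain(v) for k, v in d[key].items()}
        d["curves"] = {
            analyte: {"|".join(k): plain(v) for k, v in per.items()}
            for analyte, per in d["curves"].items()
        }
        d["continuous"] = {
            var: {g: plain(t) for g, t in per.items()}
            for var, per in d["continuous"].items()
        }
        for key in ("age", "weight_gain", "incidence", "female_frac"):
            d[key] = {g: plain(v) for g, v in d[key].items()}
        for key in ("isr_shape", "maf_range"):
            d[key] = plain(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("cpep_fasting", "isr_amplitude"):
            if key in d:
                d[key] = {tuple(k.split("|")): float(v) for k, v in d[key].items()}
        if "curves" in d:
            d["curves"] = {
                analyte: {tuple(k.split("|")): tuple(v) for k, v in per.items()}
                for analyte, per in d["curves"].items()
            }
        if "continuous" in d:
            d["continuous"] = {
                var: {g: tuple(t) for g, t in per.items()}
                for var, per in d["continuous"].items()
            }
        for key in ("age", "weight_gain"):
            if key in d:
                d[key] = {g: tuple(v) for g, v in d[key].items()}
        for key in ("isr_shape", "maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _default_continuous() -> dict:
    # variable -> group -> (mean0, mean12, sd0, sd12); SDs from CI half-widths
    spec = {
        "weight": {"R": (84.0, 86.8, 6.2, 6.5), "NR": (88.4, 90.6, 2.9, 2.9)},
        "lean_mass": {"R": (56.2, 56.2, 4.4, 4.7), "NR": (59.6, 59.5, 2.7, 2.3)},
        "fat_mass": {"R": (30.7, 32.5, 4.1, 4.5), "NR": (31.7, 32.5, 2.0, 1.9)},
        "vat_l": {"R": (4.31, 4.24, 0.69, 0.69), "NR": (4.99, 5.41, 0.32, 0.36)},
        "scat_l": {"R": (14.41, 15.7, 2.39, 2.06), "NR": (14.97, 14.66, 1.06, 0.98)},
        "liver_fat_pct": {"R": (5.08, 5.9, 1.71, 1.74), "NR": (7.65, 8.13, 1.14, 1.18)},
        "muscle_fat_pct": {"R": (5.85, 6.15, 1.24, 1.49), "NR": (6.4, 6.76, 1.45, 1.49)},
        "leptin": {"R": (37.25, 43.63, 11.81, 11.68), "NR": (40.68, 47.26, 6.24, 6.49)},
        "adiponectin": {
            "R": (3096.48, 3371.57, 535.75, 596.55),
            "NR": (2412.3, 2337.2, 207.49, 217.24),
        },
    }
    # muscle fat was measured in small subgroups (n = 16 R / 27 NR)
    subgroup_n = {"muscle_fat_pct": {"R": 16, "NR": 27}}
    out: dict = {}
    for var, per in spec.items():
        out[var] = {}
        for g, (m0, m1, c0, c1) in per.items():
            n = subgroup_n.get(var, {}).get(g)
            out[var][g] = (m0, m1, _sd(g, c0, n), _sd(g, c1, n))
    return out


def _default_curves() -> dict:
    return {
        "glucose": {  # mmol/l
            ("R", "baseline"): (5.8, 8.8, 9.6, 8.6, 8.1),
            ("R", "month12"): (5.1, 7.8, 8.2, 7.0, 6.3),
            ("NR", "baseline"): (6.0, 9.2, 10.2, 9.4, 8.7),
            ("NR", "month12"): (6.0, 9.3, 10.3, 9.5, 8.8),
        },
        "insulin": {  # pmol/l
            ("R", "baseline"): (60.0, 330.0, 420.0, 390.0, 300.0),
            ("R", "month12"): (55.0, 380.0, 500.0, 380.0, 270.0),
            ("NR", "baseline"): (80.0, 380.0, 520.0, 510.0, 430.0),
            ("NR", "month12"): (82.0, 385.0, 525.0, 515.0, 440.0),
        },
        "glp1": {  # pmol/l; AUC rises in NR, stable in R
            ("R", "baseline"): (15.0, 35.0, 30.0, 25.0, 20.0),
            ("R", "month12"): (15.0, 34.0, 30.0, 25.0, 20.0),
            ("NR", "baseline"): (17.0, 38.0, 33.0, 27.0, 22.0),
            ("NR", "month12"): (17.0, 42.0, 37.0, 30.0, 24.0),
        },
        "gip": {  # pmol/l; similar in both groups, elevated at 120 min
            ("R", "baseline"): (12.0, 55.0, 60.0, 55.0, 45.0),
            ("R", "month12"): (12.0, 55.0, 60.0, 55.0, 45.0),
            ("NR", "baseline"): (13.0, 57.0, 62.0, 57.0, 47.0),
            ("NR", "month12"): (13.0, 58.0, 62.0, 57.0, 47.0),
        },
        "glucagon": {  # pmol/l; early suppression improves in R only
            ("R", "baseline"): (18.0, 15.0, 12.0, 10.0, 9.0),
            ("R", "month12"): (17.0, 11.0, 9.0, 8.0, 8.0),
            ("NR", "baseline"): (20.0, 17.0, 14.0, 12.0, 11.0),
            ("NR", "month12"): (21.0, 18.0, 15.0, 13.0, 12.0),
        },
    }


def default_config() -> CohortConfig:
    cfg = CohortConfig()
    cfg.continuous = _default_continuous()
    cfg.curves = _default_curves()
    return cfg


@dataclass
class SubjectCourse:
    """One synthetic subject across baseline and month 12 plus follow-up."""

    subject_id: str
    group: str
    age: float
    sex: str
    height_m: float
    weight0: float
    weight12: float
    risk_stratum: str
    intensity: str
    phenotypes: dict  # variable -> (baseline, month12)
    fasting_nefa: float
    ogtt: dict  # visit -> OGTTRecord
    isr_true: dict  # visit -> ISRProfile (generator ground truth)
    event_time: float
    event: bool

    @property
    def weight_change(self) -> float:
        return self.weight12 - self.weight0

    def bsa(self, visit: str = "baseline") -> float:
        from .ogtt import bsa_dubois

        w = self.weight0 if visit == "baseline" else self.weight12
        return bsa_dubois(w, self.height_m)


@dataclass
class Cohort:
    subjects: list
    genotypes: pd.DataFrame
    snp_meta: pd.DataFrame
    weights: pd.DataFrame
    config: CohortConfig

    def to_tables(self) -> dict:
        """Flatten to the delimited tables the analysis pipeline reads."""
        subj_rows, imaging_rows, ogtt_rows, surv_rows = [], [], [], []
        for s in self.subjects:
            subj_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "age": s.age,
                    "sex": s.sex,
                    "height_m": s.height_m,
                    "weight_baseline": s.weight0,
                    "weight_month12": s.weight12,
                    "bmi_baseline": s.weight0 / s.height_m**2,
                    "bmi_month12": s.weight12 / s.height_m**2,
                    "risk_stratum": s.risk_stratum,
                    "intensity": s.intensity,
                    "fasting_nefa": s.fasting_nefa,
                    "hba1c_baseline": s.ogtt["baseline"].hba1c,
                    "hba1c_month12": s.ogtt["month12"].hba1c,
                    "leptin_baseline": s.phenotypes["leptin"][0],
                    "leptin_month12": s.phenotypes["leptin"][1],
                    "adiponectin_baseline": s.phenotypes["adiponectin"][0],
                    "adiponectin_month12": s.phenotypes["adiponectin"][1],
                    "lean_mass_baseline": s.phenotypes["lean_mass"][0],
                    "lean_mass_month12": s.phenotypes["lean_mass"][1],
                    "fat_mass_baseline": s.phenotypes["fat_mass"][0],
                    "fat_mass_month12": s.phenotypes["fat_mass"][1],
                }
            )
            for vi, visit in enumerate(("baseline", "month12")):
                imaging_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "visit": visit,
                        "vat_l": s.phenotypes["vat_l"][vi],
                        "scat_l": s.phenotypes["scat_l"][vi],
                        "liver_fat_pct": s.phenotypes["liver_fat_pct"][vi],
                        "muscle_fat_pct": s.phenotypes["muscle_fat_pct"][vi],
                    }
                )
                rec = s.ogtt[visit]
                series = {
                    "glucose": (rec.glucose, "mmol/l"),
                    "insulin": (rec.insulin, "pmol/l"),
                    "c_peptide": (rec.c_peptide, "pmol/l"),
                    "glp1": (rec.glp1, "pmol/l"),
                    "gip": (rec.gip, "pmol/l"),
                    "glucagon": (rec.glucagon, "pmol/l"),
                }
                for analyte, (ts, unit) in series.items():
                    if ts is None:
                        continue
                    for t, v in zip(ts.times, ts.values):
                        ogtt_rows.append(
                            {
                                "subject_id": s.subject_id,
                                "visit": visit,
                                "time_min": t,
                                "analyte": analyte,
                                "value": v,
                                "unit": unit,
                            }
                        )
            surv_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "time_years": s.event_time,
                    "event": int(s.event),
                }
            )
        return {
            "subjects": pd.DataFrame(subj_rows),
            "imaging": pd.DataFrame(imaging_rows),
            "ogtt": pd.DataFrame(ogtt_rows),
            "survival": pd.DataFrame(surv_rows),
            "genotypes": self.genotypes,
            "snp_meta": self.snp_meta,
            "weights": self.weights,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = self.to_tables()
        tables["subjects"].to_csv(out / "subjects.csv", index=False)
        tables["imaging"].to_csv(out / "imaging.csv", index=False)
        tables["ogtt"].to_csv(out / "ogtt.csv", index=False)
        tables["survival"].to_csv(out / "survival.csv", index=False)
        tables["genotypes"].to_csv(out / "genotypes.tsv", sep="\t")
        tables["snp_meta"].to_csv(out / "snps.tsv", sep="\t")
        tables["weights"].to_csv(out / "weights.tsv", sep="\t")


def _bivariate(rng, mean0, mean1, sd0, sd1, rho, size, lo=None):
    """Correlated (baseline, month-12) pairs, clipped at a physiological
    floor.  Clipping (rather than rejection) keeps the group means close to
    the configured targets — rejection of joint draws would shift every
    correlated margin upward."""
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=size
    )
    a = mean0 + sd0 * z[:, 0]
    b = mean1 + sd1 * z[:, 1]
    if lo is not None:
        a, b = np.maximum(a, lo), np.maximum(b, lo)
    return a, b


def generate_fat_depots(n: int, group: str, config: CohortConfig, rng) -> pd.DataFrame:
    """Correlated baseline/month-12 draws of all continuous phenotypes.

    SCAT and VAT are drawn jointly (cross-correlation ``scat_vat_corr`` on
    top of the within-subject correlation ``rho``), since the two depots
    co-vary with overall adiposity and their ratio would otherwise be far
    noisier than real imaging trajectories; both carry physiological floors.
    """
    cols = {}
    rho, r = config.rho, config.scat_vat_corr
    # (vat0, vat12, scat0, scat12): Kronecker structure depot x time
    corr = np.array(
        [
            [1.0, rho, r, r * rho],
            [rho, 1.0, r * rho, r],
            [r, r * rho, 1.0, rho],
            [r * rho, r, rho, 1.0],
        ]
    )
    mv0, mv1, sv0, sv1 = config.continuous["vat_l"][group]
    ms0, ms1, ss0, ss1 = config.continuous["scat_l"][group]
    means = np.array([mv0, mv1, ms0, ms1])
    sds = np.array([sv0, sv1, ss0, ss1])
    floors = np.array([1.0, 1.0, 3.0, 3.0])
    z = rng.multivariate_normal(np.zeros(4), corr, size=n)
    draw = np.maximum(means + sds * z, floors)
    cols["vat_l_baseline"], cols["vat_l_month12"] = draw[:, 0], draw[:, 1]
    cols["scat_l_baseline"], cols["scat_l_month12"] = draw[:, 2], draw[:, 3]
    for var, per in config.continuous.items():
        if var in ("vat_l", "scat_l"):
            continue
        m0, m1, s0, s1 = per[group]
        lo = 0.1 if var.endswith(("_l", "_pct")) else 1.0
        a, b = _bivariate(rng, m0, m1, s0, s1, rho, n, lo=lo)
        cols[f"{var}_baseline"] = a
        cols[f"{var}_month12"] = b
    return pd.DataFrame(cols)


def generate_survival(group: str, n: int, config: CohortConfig, rng):
    """Exponential event times calibrated to the group cumulative incidence.

    The rate solves ``1 - exp(-rate * horizon) = incidence``; censoring is an
    independent uniform time on (0, horizon) applied to a ``censoring_rate``
    fraction, with administrative censoring at the horizon otherwise.
    Returns (observed time, event indicator).
    """
    p = config.incidence[group]
    horizon = config.follow_up_years
    if not 0.0 <= p < 1.0:
        raise ValueError("cumulative incidence must lie in [0, 1)")
    if p == 0.0:
        t_event = np.full(n, np.inf)
    else:
        rate = -math.log1p(-p) / horizon
        t_event = rng.exponential(1.0 / rate, size=n)
    t_cens = np.full(n, horizon)
    is_c = rng.random(n) < config.censoring_rate
    t_cens[is_c] = rng.uniform(0.0, horizon, size=int(is_c.sum()))
    observed = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    observed = np.maximum(observed, 1e-6)
    return observed, event


def generate_genotypes(
    n_subjects: int,
    n_snps: int,
    maf_range: tuple,
    rng,
    n_fail_missingness: int = 0,
    n_fail_maf: int = 0,
    n_fail_hwe: int = 0,
    subject_ids=None,
):
    """HWE-consistent dosage matrix plus weights, with injected QC failures.

    The first ``n_fail_missingness`` SNPs have ~8% missing calls, the next
    ``n_fail_maf`` are near-monomorphic (MAF 0.2%), the next ``n_fail_hwe``
    carry strong excess homozygosity; the remainder are clean binomial
    draws.  Returns (genotypes, snp_meta, weights, truth) where ``truth``
    labels each SNP's intended QC fate.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    n_bad = n_fail_missingness + n_fail_maf + n_fail_hwe
    if n_bad > n_snps:
        raise ValueError("more injected failures than SNPs")
    ids = [f"rs{100000 + i}" for i in range(n_snps)]
    data = np.empty((n_subjects, n_snps))
    truth = []
    mafs = rng.uniform(lo, hi, size=n_snps)
    for j in range(n_snps):
        p = mafs[j]
        if j < n_fail_missingness:
            g = rng.binomial(2, p, size=n_subjects).astype(float)
            drop = rng.random(n_subjects) < 0.08
            g[drop] = np.nan
            truth.append("fail_missingness")
        elif j < n_fail_missingness + n_fail_maf:
            g = rng.binomial(2, 0.002, size=n_subjects).astype(float)
            truth.append("fail_maf")
        elif j < n_bad:
            inbred = rng.random(n_subjects) < 0.9
            g = np.where(
                inbred,
                2.0 * rng.binomial(1, p, size=n_subjects),
                rng.binomial(2, p, size=n_subjects),
            ).astype(float)
            truth.append("fail_hwe")
        else:
            g = rng.binomial(2, p, size=n_subjects).astype(float)
            truth.append("pass")
        data[:, j] = g
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(n_subjects)]
    genotypes = pd.DataFrame(data, index=subject_ids, columns=ids)
    genotypes.index.name = "subject_id"
    # non-ambiguous allele codings; a handful flipped to exercise harmonization
    meta = pd.DataFrame(
        {"effect_allele": "A", "other_allele": "G"}, index=pd.Index(ids, name="snp")
    )
    weights = pd.DataFrame(
        {
            "effect_allele": ["A"] * n_snps,
            "beta": rng.normal(0.0, 0.05, size=n_snps),
        },
        index=pd.Index(ids, name="snp"),
    )
    flip = rng.random(n_snps) < 0.1
    weights.loc[flip, "effect_allele"] = "G"
    weights.loc[flip, "beta"] *= -1.0  # same effect stated for the other allele
    truth = pd.Series(truth, index=ids, name="qc_truth")
    return genotypes, meta, weights, truth


def _kinetic_params(state: dict):
    return vancauter_params(
        state["age"], state["sex"], state["height_m"], state["weight"], "prediabetes"
    )


def generate_ogtt_curve(
    state: dict, group: str, visit: str, config: CohortConfig, rng
) -> tuple[OGTTRecord, ISRProfile]:
    """Draw one subject-visit OGTT record.

    ``state`` carries the subject's anthropometry, fasting set-point
    perturbations (``glucose_shift``, ``insulin_factor``, ``isr_factor``,
    correlated across visits) and fasting NEFA.  Glucose is the group x
    visit mean curve plus the subject shift and per-point noise; insulin is
    the mean curve scaled log-normally; the secretion-rate profile is basal
    (tied to fasting C-peptide through the kinetic steady state) plus a
    scaled early bump, and plasma C-peptide comes from the forward
    two-compartment model with multiplicative assay noise.
    """
    curves = config.curves
    g_mean = np.asarray(curves["glucose"][(group, visit)], dtype=float)
    glucose = (
        g_mean
        + state["glucose_shift"]
        + rng.normal(0.0, config.glucose_point_sd, size=len(GRID))
    )
    glucose = np.maximum(glucose, 2.5)
    i_mean = np.asarray(curves["insulin"][(group, visit)], dtype=float)
    insulin = (
        i_mean
        * state["insulin_factor"]
        * np.exp(rng.normal(0.0, config.insulin_point_logsd, size=len(GRID)))
    )
    params = _kinetic_params(state)
    c_fast = config.cpep_fasting[(group, visit)] * state["isr_factor"]
    basal_isr = c_fast * params.volume * params.k01
    amp = config.isr_amplitude[(group, visit)] * state["isr_factor"]
    isr_true = ISRProfile(GRID, basal_isr + amp * np.asarray(config.isr_shape))
    cpep_clean = forward_cpeptide(isr_true, params, c0=c_fast)
    cpep = cpep_clean.values * np.exp(
        rng.normal(0.0, config.cpep_noise_cv, size=len(GRID))
    )
    hba1c = (
        39.0
        + config.hba1c_slope * (glucose[0] - 5.6)
        + rng.normal(0.0, config.hba1c_sd)
    )
    hba1c = float(np.clip(hba1c, 20.0, 150.0))

    def _hormone(name):
        mean = np.asarray(curves[name][(group, visit)], dtype=float)
        vals = mean * np.exp(rng.normal(0.0, 0.1, size=len(GRID)))
        return TimedSeries(GRID, np.maximum(vals, 0.1), "pmol/l")

    record = OGTTRecord(
        subject_id=state["subject_id"],
        visit=visit,
        glucose=TimedSeries(GRID, glucose, "mmol/l"),
        insulin=TimedSeries(GRID, np.maximum(insulin, 1.0), "pmol/l"),
        c_peptide=TimedSeries(GRID, np.maximum(cpep, 1.0), "pmol/l"),
        glp1=_hormone("glp1"),
        gip=_hormone("gip"),
        glucagon=_hormone("glucagon"),
        fasting_nefa=state["fasting_nefa"],
        hba1c=hba1c,
    )
    return record, isr_true


def _status(record: OGTTRecord) -> GlycemicStatus:
    return classify_status(
        GlycemicInputs(
            fpg=record.glucose.value_at(0.0),
            hba1c=record.hba1c,
            g120=record.glucose.value_at(120.0),
            g60=record.glucose.value_at(60.0),
        )
    )


def _draw_visit(state, group, visit, config, rng, want, n_draws=50):
    """Rejection-sample a visit until its glycemic status satisfies ``want``."""
    for _ in range(n_draws):
        record, isr = generate_ogtt_curve(state, group, visit, config, rng)
        if want(_status(record)):
            return record, isr
    return None


def _draw_subject_visits(base_state, weight0, weight12, group, config, rng):
    """Draw both visits, redrawing the subject's glycemic set-point when a
    perturbation makes the required statuses unreachable (e.g. a strongly
    negative fasting shift that never classifies as prediabetes)."""
    if group == "R":
        want12 = lambda s: s == GlycemicStatus.NGR
    else:
        want12 = lambda s: s != GlycemicStatus.NGR
    state = dict(base_state)
    for attempt in range(config.max_rejection_draws // 25):
        out0 = _draw_visit(
            dict(state, weight=weight0), group, "baseline", config, rng,
            want=lambda s: s == GlycemicStatus.PREDIABETES,
        )
        out12 = (
            _draw_visit(dict(state, weight=weight12), group, "month12", config, rng, want12)
            if out0 is not None
            else None
        )
        if out0 is not None and out12 is not None:
            return out0, out12, state
        state = dict(base_state, glucose_shift=rng.normal(0.0, config.glucose_subject_sd))
    raise RuntimeError(
        f"infeasible config: could not draw {group} visits with the required "
        "glycemic statuses — curve means conflict with the thresholds"
    )


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Generate a full synthetic cohort; bit-reproducible for a given seed."""
    config = config or default_config()
    rng = np.random.default_rng(seed)
    subjects = []
    counter = 0
    all_ids = []
    for group in ("R", "NR"):
        n = config.group_sizes()[group]
        pheno = generate_fat_depots(n, group, config, rng)
        ages = np.clip(rng.normal(*config.age[group], size=n), 25.0, 80.0)
        female = rng.random(n) < config.female_frac[group]
        heights = np.where(
            female, rng.normal(1.66, 0.06, size=n), rng.normal(1.78, 0.07, size=n)
        )
        w_mean, _, w_sd, _ = config.continuous["weight"][group]
        weights0 = np.clip(rng.normal(w_mean, w_sd, size=n), 50.0, 170.0)
        gain_mean, gain_sd = config.weight_gain[group]
        gains = np.abs(rng.normal(gain_mean, gain_sd, size=n))  # non-weight-loss stratum
        etimes, events = generate_survival(group, n, config, rng)
        strata = np.where(rng.random(n) < 0.5, "high", "low")
        intensity = rng.choice(
            ["control", "conventional", "intensified"], size=n, p=[0.15, 0.5, 0.35]
        )
        for i in range(n):
            sid = f"S{counter:04d}"
            counter += 1
            all_ids.append(sid)
            # subject-level set-point perturbations shared across visits
            shift = rng.normal(0.0, config.glucose_subject_sd)
            ifac = float(np.exp(rng.normal(0.0, config.insulin_subject_logsd)))
            sfac = float(np.exp(rng.normal(0.0, config.isr_subject_logsd)))
            nefa = float(np.exp(rng.normal(config.nefa_log_mean, config.nefa_log_sd)))
            base_state = {
                "subject_id": sid,
                "age": float(ages[i]),
                "sex": "F" if female[i] else "M",
                "height_m": float(heights[i]),
                "glucose_shift": shift,
                "insulin_factor": ifac,
                "isr_factor": sfac,
                "fasting_nefa": nefa,
            }
            (rec0, isr0), (rec12, isr12), _ = _draw_subject_visits(
                base_state, float(weights0[i]), float(weights0[i] + gains[i]),
                group, config, rng,
            )
            subjects.append(
                SubjectCourse(
                    subject_id=sid,
                    group=group,
                    age=float(ages[i]),
                    sex="F" if female[i] else "M",
                    height_m=float(heights[i]),
                    weight0=float(weights0[i]),
                    weight12=float(weights0[i] + gains[i]),
                    risk_stratum=str(strata[i]),
                    intensity=str(intensity[i]),
                    phenotypes={
                        var: (
                            float(pheno[f"{var}_baseline"].iloc[i]),
                            float(pheno[f"{var}_month12"].iloc[i]),
                        )
                        for var in config.continuous
                    },
                    fasting_nefa=nefa,
                    ogtt={"baseline": rec0, "month12": rec12},
                    isr_true={"baseline": isr0, "month12": isr12},
                    event_time=float(etimes[i]),
                    event=bool(events[i]),
                )
            )
    genotypes, meta, weights, truth = generate_genotypes(
        len(subjects),
        config.n_snps,
        config.maf_range,
        rng,
        config.n_fail_missingness,
        config.n_fail_maf,
        config.n_fail_hwe,
        subject_ids=all_ids,
    )
    return Cohort(
        subjects=subjects,
        genotypes=genotypes,
        snp_meta=meta,
        weights=weights,
        config=config,
    )
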