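import numpy as np
import pytest

import prediarem as pr


def make_series(values, times=(0, 30, 60, 90, 120), unit=""):
    return pr.TimedSeries(np.asarray(times, float), np.asarray(values, float), unit)


def make_record(
    glucose_mmol,
    insulin_pmol,
    c_peptide_pmol=None,
    times=(0, 30, 60, 90, 120),
    **kwargs,
):
    cpep = make_series(c_peptide_pmol, times, "pmol/l") if c_peptide_pmol is not None else None
    return pr.OGTTRecord(
        subject_id=kwargs.pop("subject_id", "s1"),
        visit=kwargs.pop("visit", "baseline"),
        glucose=make_series(glucose_mmol, times, "mmol/l"),
        insulin=make_series(insulin_pmol, times, "pmol/l"),
        c_peptide=cpep,
        **kwargs,
    )


@pytest.fixture(scope="session")
def kinetics():
    """Population kinetic parameters for a typical overweight adult."""
    return pr.vancauter_params(55.0, "F", 1.68, 84.0, "prediabetes")


def small_config(n_r=12, n_nr=24):
    cfg = pr.default_config()
    cfg.n_responders = n_r
    cfg.n_nonresponders = n_nr
    cfg.n_snps = 40
    cfg.n_fail_missingness = 2
    cfg.n_fail_maf = 2
    cfg.n_fail_hwe = 2
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    return pr.generate_cohort(small_config(), seed=7)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    small_cohort.write(d)
    return d
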