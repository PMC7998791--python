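"""Reported case:control plasma effect sizes used as simulator defaults.

GM1T2:HC fold-changes of mean 1H NMR resonance intensities for the
25-metabolite targeted panel, on the constant-sum-normalized basis and on
the isoleucine-normalized basis (intensities expressed relative to the
Ile-CH3 doublet at 0.997 ppm, a metabolite with no significant
between-group difference).  These are the planted effect sizes the
synthetic cohort generator emulates by default.
"""

#: CS-normalized GM1T2:HC fold-changes of the targeted panel.
FOLD_CHANGES_CS: dict[str, float] = {
    "Total TAGs": 0.75,
    "Isoleucine": 1.04,
    "Leucine": 1.37,
    "Valine": 2.10,
    "3-AIB": 1.21,
    "Alanine": 0.87,
    "Acetate": 0.96,
    "APG-I": 0.91,
    "APG-II": 0.93,
    "Glutamine": 1.20,
    "Glutamate": 1.14,
    "Citrate": 1.16,
    "HDL-PLs": 1.03,
    "Glucose": 1.14,
    "Taurine": 1.13,
    "Cr/PCr": 1.48,
    "Creatinine": 2.65,
    "Lactate": 4.19,
    "Threonine": 1.16,
    "Urea": 1.66,
    "Tyrosine": 1.62,
    "Phenylalanine": 1.52,
    "Histidine": 1.91,
    "PAAR": 1.96,
    "Formate": 1.54,
}

#: Isoleucine-normalized GM1T2:HC fold-changes (no Ile entry: it is the
#: reference and is 1 by construction).
FOLD_CHANGES_ILE: dict[str, float] = {
    "Total TAGs": 0.74,
    "Leucine": 1.32,
    "Valine": 2.00,
    "3-AIB": 1.18,
    "Alanine": 0.86,
    "Acetate": 0.92,
    "APG-I": 0.88,
    "APG-II": 0.89,
    "Glutamine": 1.16,
    "Glutamate": 1.11,
    "Citrate": 1.12,
    "HDL-PLs": 1.01,
    "Glucose": 1.06,
    "Taurine": 1.08,
    "Cr/PCr": 2.59,
    "Creatinine": 2.50,
    "Lactate": 3.98,
    "Threonine": 1.11,
    "Urea": 1.54,
    "Tyrosine": 1.53,
    "Phenylalanine": 1.43,
    "Histidine": 1.78,
    "PAAR": 2.11,
}


def study_cohort_spec(seed: int = 0, n_outliers: int = 1, **overrides):
    """Default study-condition cohort: 28 controls, 10 cases (one an
    inflated outlier profile), CV 0.15, full panel of planted effects."""
    from .synth import CohortSpec

    kw = dict(
        n_control=28,
        n_case=10,
        fold_changes=dict(FOLD_CHANGES_CS),
        within_group_cv=0.15,
        n_outliers=n_outliers,
        seed=seed,
    )
    kw.update(overrides)
    return CohortSpec(**kw)
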