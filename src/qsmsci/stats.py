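"""Per-lesion ROI summaries and the group-level statistical comparisons.

The analysis unit is the lesion: each record carries the mean chi and R2*
inside the SCI mask and inside its mirrored contralateral NAWM mask on the
GRE grid, plus the subject covariates. Lesion-vs-NAWM comparisons use
paired t-tests and Bland-Altman agreement (bias and 1.96-SD limits of
agreement); group effects use Student's t / one-way ANOVA with Tukey HSD;
the multi-factor ANOVA uses sequential (type-I) sums of squares in the
fixed order ln(age), group, lobe, ln(volume). Values can be age-corrected
by residualizing on ln(age) and restoring the grand mean. Lesions within a
subject are treated as independent units and excluded lesions never enter
any statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .segmentation import LesionPair, depth_fractions


@dataclass
class RoiRecord:
    subject_id: str
    lesion_id: int
    definition: str
    group: str = "SCA"
    age_years: float = np.nan
    lobe: str = "other"
    depth: dict = field(default_factory=dict)
    volume_mm3: float = np.nan
    n_voxels: int = 0
    mean_chi_sci: float = np.nan
    mean_chi_nawm: float = np.nan
    mean_r2s_sci: float = np.nan
    mean_r2s_nawm: float = np.nan

    def to_dict(self) -> dict:
        d = asdict(self)
        depth = d.pop("depth")
        for name in ("juxtacortical", "periventricular", "deep"):
            d[f"frac_{name}"] = depth.get(name, 0.0)
        return d


def roi_means(
    pair: LesionPair,
    chi_map: np.ndarray | None = None,
    r2star_map: np.ndarray | None = None,
    depth_map=None,
    voxel_size=(1.0, 1.0, 1.0),
    subject_id: str = "",
    group: str = "SCA",
    age_years: float = np.nan,
    lobe: str | None = None,
) -> tuple[RoiRecord, list[dict]]:
    """Mean chi/R2* inside the SCI and NAWM masks of one lesion pair.

    Returns the lesion record plus per-depth-class sub-rows when the lesion
    spans several white-matter depth classes.
    """
    sci, nawm = pair.sci.mask, pair.nawm.mask
    if not sci.any() or not nawm.any():
        raise ValueError("lesion pair contains an empty mask")
    vs = np.asarray(voxel_size, dtype=float)
    rec = RoiRecord(
        subject_id=subject_id or pair.sci.subject_id,
        lesion_id=pair.sci.lesion_id,
        definition=pair.sci.definition,
        group=group,
        age_years=age_years,
        lobe=lobe if lobe is not None else pair.sci.lobe,
        volume_mm3=float(np.count_nonzero(sci) * vs.prod()),
        n_voxels=int(np.count_nonzero(sci)),
    )
    for name, vol in (("chi", chi_map), ("r2s", r2star_map)):
        if vol is None:
            continue
        vol = np.asarray(vol, dtype=float)
        setattr(rec, f"mean_{name}_sci", float(vol[sci].mean()))
        setattr(rec, f"mean_{name}_nawm", float(vol[nawm].mean()))

    depth_rows: list[dict] = []
    if depth_map is not None:
        rec.depth = depth_fractions(sci, depth_map)
        if len(rec.depth) > 1:
            for cls in rec.depth:
                sel = sci & (depth_map.labels == _depth_code(cls))
                row = {"subject_id": rec.subject_id, "lesion_id": rec.lesion_id,
                       "depth_class": cls, "n_voxels": int(sel.sum())}
                for name, vol in (("chi", chi_map), ("r2s", r2star_map)):
                    if vol is not None:
                        row[f"mean_{name}_sci"] = float(np.asarray(vol)[sel].mean())
                depth_rows.append(row)
    return rec, depth_rows


def _depth_code(name: str) -> int:
    from .segmentation import DEPTH_NAMES
    return {v: k for k, v in DEPTH_NAMES.items()}[name]


def records_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def paired_delta(values_sci, values_nawm) -> dict:
    """Mean SCI-NAWM difference with the classical paired t-test."""
    a = np.asarray(values_sci, dtype=float)
    b = np.asarray(values_nawm, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    delta = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return {"delta": delta, "t": np.nan, "p": np.nan, "n": n,
                "undefined": True}
    t, p = sps.ttest_rel(a, b)
    return {"delta": delta, "t": float(t), "p": float(p), "n": n,
            "undefined": False}


def bland_altman(a, b) -> dict:
    """Bias and 1.96-SD limits of agreement of paired measurements."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need paired vectors with n >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "sd": sd,
            "loa_lower": bias - 1.96 * sd, "loa_upper": bias + 1.96 * sd,
            "mean": (a + b) / 2.0, "diff": d}


def age_correct(values, ages) -> np.ndarray:
    """Residualize on ln(age) and restore the grand mean."""
    v = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    ln_age = np.log(ages)
    if np.allclose(ln_age, ln_age[0]):
        warnings.warn("constant ages: age correction is the identity")
        return v.copy()
    x = sm.add_constant(ln_age)
    fit = sm.OLS(v, x).fit()
    return np.asarray(fit.resid) + float(v.mean())


def anova_effects(records: pd.DataFrame, response: str,
                  factors=None, typ: int = 1) -> pd.DataFrame:
    """Sequential ANOVA of a response on ln(age), group, lobe and ln(volume).

    ``factors`` is an ordered list of (label, patsy term, is_categorical);
    the default reproduces the standard factor order. Type-II sums of
    squares are available via ``typ=2``.
    """
    if factors is None:
        factors = [("ln_age", "np.log(age_years)", False),
                   ("group", "C(group)", True),
                   ("lobe", "C(lobe)", True),
                   ("ln_volume", "np.log(volume_mm3)", False)]
    for label, term, cat in factors:
        if cat:
            col = term[2:-1] if term.startswith("C(") else term
            if records[col].nunique() < 2:
                raise ValueError(f"factor '{label}' has fewer than 2 levels")
    formula = f"{response} ~ " + " + ".join(t for _, t, _ in factors)
    full = smf.ols(formula, data=records).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("rank-deficient design: aliased factors in " +
                         ", ".join(l for l, _, _ in factors))
    if typ != 1:
        table = anova_lm(full, typ=typ)
        return table.rename(index={t: l for l, t, _ in factors})
    # sequential SS in the *stated* factor order via nested model fits
    # (formula interfaces reorder categorical terms, which would silently
    # change the type-I decomposition)
    mse = full.ssr / full.df_resid
    rows, prev = [], smf.ols(f"{response} ~ 1", data=records).fit()
    terms = []
    for label, term, _ in factors:
        terms.append(term)
        fit = smf.ols(f"{response} ~ " + " + ".join(terms), data=records).fit()
        ss = prev.ssr - fit.ssr
        df_f = fit.df_model - prev.df_model
        f_stat = (ss / df_f) / mse
        rows.append({"factor": label, "df": df_f, "sum_sq": ss, "F": f_stat,
                     "PR(>F)": float(sps.f.sf(f_stat, df_f, full.df_resid))})
        prev = fit
    rows.append({"factor": "Residual", "df": full.df_resid, "sum_sq": full.ssr,
                 "F": np.nan, "PR(>F)": np.nan})
    return pd.DataFrame(rows).set_index("factor")


def group_compare(records: pd.DataFrame, by: str, response: str) -> dict:
    """Two groups: Student's t; more: one-way ANOVA plus Tukey HSD."""
    df = records[[by, response]].dropna()
    sizes = df.groupby(by)[response].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping groups with n < 2: {small}")
        df = df[~df[by].isin(small)]
    groups = {k: g[response].to_numpy() for k, g in df.groupby(by)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    means = {k: float(v.mean()) for k, v in groups.items()}
    out = {"means": means, "n": {k: int(v.size) for k, v in groups.items()}}
    vals = list(groups.values())
    if len(groups) == 2:
        t, p = sps.ttest_ind(vals[0], vals[1], equal_var=True)
        out.update(test="student-t", stat=float(t), p=float(p))
    else:
        f, p = sps.f_oneway(*vals)
        tk = pairwise_tukeyhsd(df[response].to_numpy(), df[by].to_numpy())
        out.update(test="anova+tukey", stat=float(f), p=float(p),
                   tukey=pd.DataFrame(tk.summary().data[1:],
                                      columns=tk.summary().data[0]))
    return out


@dataclass
class SubjectSummary:
    subject_id: str
    group: str
    age_years: float
    mean_delta_chi: float
    mean_delta_r2s: float
    n_lesions: int
    fsiq: float = np.nan
    wmi: float = np.nan
    psi: float = np.nan


def summarize_subjects(records: pd.DataFrame, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject means of the lesion-vs-NAWM differences."""
    df = records.copy()
    df["delta_chi"] = df["mean_chi_sci"] - df["mean_chi_nawm"]
    df["delta_r2s"] = df["mean_r2s_sci"] - df["mean_r2s_nawm"]
    agg = df.groupby("subject_id").agg(
        group=("group", "first"), age_years=("age_years", "first"),
        mean_delta_chi=("delta_chi", "mean"), mean_delta_r2s=("delta_r2s", "mean"),
        n_lesions=("lesion_id", "size")).reset_index()
    if covariates is not None:
        agg = agg.merge(covariates, on="subject_id", how="left")
    return agg


def _pearson(x, y) -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}


def cognition_correlate(summaries: pd.DataFrame, measure: str,
                        response: str = "mean_delta_chi") -> dict:
    """Pearson correlation of per-subject lesion means with a cognition score."""
    if measure.lower() not in ("fsiq", "wmi", "psi"):
        raise ValueError("measure must be one of FSIQ, WMI, PSI")
    return _pearson(summaries[response], summaries[measure.lower()])


def correlate_paired(sci_means, nawm_means) -> dict:
    """Pearson correlation between SCI and paired NAWM means."""
    return _pearson(sci_means, nawm_means)
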