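"""Field-level quantification: surface/total reporter ratios,
abundance proxies, colocalisation coefficients and group statistics.

The dual-tagged reporter carries an exofacial HA epitope (stained only
when surface-exposed) and a GFP moiety (reports total reporter), so the
per-field HA/GFP intensity ratio is proportional to the surface-exposed
fraction.  Ratios are normalised so the unstimulated (basal) condition
equals 1, either within each treatment group or against the control
group's basal, matching the two screen-readout conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

from .simulate import FieldImage, FieldImageSet

__all__ = [
    "FieldMeasurement",
    "ColocResult",
    "measure_fields",
    "ha_gfp_ratio",
    "gfp_dapi_ratio",
    "coloc",
    "compare_groups",
]


@dataclass
class FieldMeasurement:
    """Mean channel intensities of one field of view."""

    field_id: str
    treatment: str
    stimulation: str
    mean_HA: float = np.nan
    mean_GFP: float = np.nan
    mean_DAPI: float = np.nan
    mean_marker: float = np.nan


@dataclass
class ColocResult:
    """Pearson and Manders colocalisation coefficients.

    ``manders_m1`` is the fraction of channel-1 intensity in pixels
    where channel 2 exceeds its threshold; ``manders_m2`` is symmetric.
    ``pearson_r`` is NaN (and ``flagged`` True) for a constant channel.
    """

    pearson_r: float
    manders_m1: float
    manders_m2: float
    threshold1: float
    threshold2: float
    flagged: bool = False


def measure_fields(fields: FieldImageSet) -> list[FieldMeasurement]:
    """Whole-field mean intensity of every channel of every field."""
    out = []
    for f in fields:
        m = FieldMeasurement(field_id=f.field_id, treatment=f.treatment,
                             stimulation=f.stimulation)
        for name, img in f.channels.items():
            attr = f"mean_{name}" if name in ("HA", "GFP", "DAPI") else "mean_marker"
            setattr(m, attr, float(np.mean(img)))
        out.append(m)
    return out


def _ratio_frame(fields, num: str, den: str) -> tuple[pd.DataFrame, list[dict]]:
    rows, errors = [], []
    for f in fields:
        d = getattr(f, f"mean_{den}")
        n = getattr(f, f"mean_{num}")
        if not np.isfinite(d) or d <= 0:
            errors.append({"field_id": f.field_id,
                           "reason": f"mean_{den} is zero or missing"})
            continue
        rows.append({"field_id": f.field_id, "treatment": f.treatment,
                     "stimulation": f.stimulation, "ratio": n / d})
    return pd.DataFrame(rows), errors


def _normalise(df: pd.DataFrame, control: str | None) -> pd.DataFrame:
    df = df.copy()
    if control is None:
        # per-treatment convention: each group's basal mean set to 1
        basal = df[df["stimulation"] == "basal"].groupby("treatment")["ratio"].mean()
        missing = set(df["treatment"]) - set(basal.index)
        if missing:
            raise ValueError(f"no basal fields for treatment(s) {sorted(missing)}")
        df["normalized_ratio"] = df.apply(
            lambda r: r["ratio"] / basal[r["treatment"]], axis=1)
    else:
        # cross-group convention: everything relative to the control basal
        sel = (df["treatment"] == control) & (df["stimulation"] == "basal")
        if not sel.any():
            raise ValueError(f"no basal fields for control treatment {control!r}")
        ref = df.loc[sel, "ratio"].mean()
        df["normalized_ratio"] = df["ratio"] / ref
    return df


def ha_gfp_ratio(
    fields: list[FieldMeasurement],
    normalise_to: str | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-field HA/GFP ratio, basal-normalised.

    With ``normalise_to=None`` each treatment group's basal mean is set
    to 1 (per-group convention); with ``normalise_to='control'`` (or any
    treatment label) all groups are divided by that group's basal mean
    (cross-group convention).  Fields with zero GFP are excluded and
    reported in the returned error list.
    """
    df, errors = _ratio_frame(fields, "HA", "GFP")
    if df.empty:
        raise ValueError("no measurable fields")
    return _normalise(df, normalise_to), errors


def gfp_dapi_ratio(
    fields: list[FieldMeasurement],
    normalise_to: str | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-field GFP/DAPI ratio (total reporter per nuclear content).

    Same conventions and error handling as :func:`ha_gfp_ratio`.
    """
    df, errors = _ratio_frame(fields, "GFP", "DAPI")
    if df.empty:
        raise ValueError("no measurable fields")
    return _normalise(df, normalise_to), errors


def coloc(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray | None = None,
    thresholds: tuple[float, float] | None = None,
) -> ColocResult:
    """Pearson correlation and Manders overlap coefficients.

    Thresholds default to per-channel Otsu.  ``manders_m1 =
    sum(ch1 [ch2 > thr2]) / sum(ch1)``; swapping the channels swaps M1
    and M2 and leaves Pearson's r unchanged.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must be co-registered (equal shape)")
    if mask is None:
        mask = np.ones(ch1.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != ch1.shape:
            raise ValueError("mask shape mismatch")
    a, b = ch1[mask], ch2[mask]
    if thresholds is None:
        t1 = float(threshold_otsu(a)) if np.ptp(a) > 0 else float(a.max())
        t2 = float(threshold_otsu(b)) if np.ptp(b) > 0 else float(b.max())
    else:
        t1, t2 = float(thresholds[0]), float(thresholds[1])

    flagged = False
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = float("nan")
        flagged = True
    else:
        r = float(stats.pearsonr(a, b).statistic)

    s1, s2 = a.sum(), b.sum()
    m1 = float(a[b > t2].sum() / s1) if s1 > 0 else float("nan")
    m2 = float(b[a > t1].sum() / s2) if s2 > 0 else float("nan")
    return ColocResult(pearson_r=r, manders_m1=m1, manders_m2=m2,
                       threshold1=t1, threshold2=t2, flagged=flagged)


def compare_groups(
    values_by_group: dict[str, np.ndarray] | pd.DataFrame,
    design: str = "pairwise",
    factors: tuple[str, str] | None = None,
    response: str = "value",
) -> dict:
    """Group comparison statistics.

    ``design='pairwise'`` runs Welch's two-sample t-test on a dict of
    exactly two groups and returns ``{'statistic', 'dof', 'p',
    'flagged'}``.  ``design='two_way'`` expects a tidy DataFrame with
    the two factor columns named in ``factors`` plus a response column,
    and returns the two-way ANOVA (with interaction) table quantities
    per term.
    """
    if design == "pairwise":
        if not isinstance(values_by_group, dict) or len(values_by_group) != 2:
            raise ValueError("pairwise design needs a dict of exactly two groups")
        (na, a), (nb, b) = [(k, np.asarray(v, float))
                            for k, v in values_by_group.items()]
        flagged = (a.size < 2 or b.size < 2
                   or (np.var(a) == 0 and np.var(b) == 0))
        if a.size < 2 or b.size < 2:
            return {"groups": (na, nb), "statistic": float("nan"),
                    "dof": float("nan"), "p": float("nan"), "flagged": True}
        res = stats.ttest_ind(a, b, equal_var=False)
        return {"groups": (na, nb), "statistic": float(res.statistic),
                "dof": float(res.df), "p": float(res.pvalue),
                "flagged": bool(flagged or not np.isfinite(res.statistic))}
    if design == "two_way":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        if factors is None or len(factors) != 2:
            raise ValueError("two_way design needs two factor names")
        df = pd.DataFrame(values_by_group)
        fa, fb = factors
        for col in (fa, fb, response):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        model = smf.ols(f"{response} ~ C({fa}) * C({fb})", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        out = {"flagged": False}
        for term in table.index:
            if term == "Residual":
                continue
            clean = term.replace(f"C({fa})", fa).replace(f"C({fb})", fb)
            out[clean] = {"F": float(table.loc[term, "F"]),
                          "dof": float(table.loc[term, "df"]),
                          "p": float(table.loc[term, "PR(>F)"])}
        return out
    raise ValueError(f"unknown design {design!r}")
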