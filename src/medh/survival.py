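"""Survival association battery for regional deformation-heterogeneity features.

Per tumor-hemisphere group and survival stratum: per-region Spearman rank
correlation of MEDH with survival days, the same adjusted for age and total
tumor volume (partial Spearman on ranks), univariate Cox concordance for
significant regions, and a multivariate Cox model over all significant
regions.  Survival stratification uses fixed cutoffs: short <= 7 months,
long > 18 months, medium in between (1 month = 30.4375 days).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DAYS_PER_MONTH",
    "SHORT_CUTOFF_MONTHS",
    "LONG_CUTOFF_MONTHS",
    "stratify_survival",
    "spearman",
    "partial_spearman",
    "concordance_index",
    "fit_cox",
    "dice",
    "significance_marker",
    "run_association_analysis",
    "AssociationReport",
]

DAYS_PER_MONTH = 30.4375
SHORT_CUTOFF_MONTHS = 7.0
LONG_CUTOFF_MONTHS = 18.0

SUBJECT_COLUMNS = ["subject_id", "survival_days", "age_years", "kps",
                   "tumor_hemisphere", "tumor_volume_ml"]


def stratify_survival(survival_days: float) -> str:
    """Short (<= 7 months), long (> 18 months), else medium."""
    if survival_days <= 0:
        raise ValueError("survival_days must be positive")
    months = survival_days / DAYS_PER_MONTH
    if months <= SHORT_CUTOFF_MONTHS:
        return "short"
    if months > LONG_CUTOFF_MONTHS:
        return "long"
    return "medium"


def significance_marker(p: float) -> str:
    """Marker convention: '**' for p < 0.05, '*' for p < 0.1, else ''."""
    if not np.isfinite(p):
        return ""
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

def _spearman_p_exact(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided permutation p over all n! orderings (n <= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_c = (ry - ry.mean()) / ry.std()
    rs = (perms_take(ry_c, perms) @ rx) / n
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


def perms_take(values: np.ndarray, perms: np.ndarray) -> np.ndarray:
    return values[perms]


def spearman(x: Sequence[float], y: Sequence[float],
             p_method: str = "auto") -> tuple[float, float]:
    """Spearman rho (average ranks) with a two-sided p-value.

    ``p_method``: 'auto' uses exact permutation for n <= 9 and the
    t-approximation otherwise; 'asymptotic' or 'exact' force one path.
    Constant input yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.spearmanr(x, y)
    if p_method == "exact" or (p_method == "auto" and len(x) <= 9):
        p = _spearman_p_exact(x, y, r)
    return float(r), float(p)


def partial_spearman(x: Sequence[float], y: Sequence[float],
                     confounders) -> tuple[float, float]:
    """Confounder-adjusted Spearman: Pearson correlation of rank residuals.

    Ranks of x, y and each confounder are taken (average ranks); x-ranks and
    y-ranks are each regressed on the rank-transformed confounders plus an
    intercept, and the partial correlation is the Pearson correlation of the
    two residual vectors.  p is two-sided from a t distribution with
    n - 2 - k degrees of freedom.  Constant confounder columns drop out,
    reducing to the plain Spearman correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(confounders, dtype=np.float64)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != x.size and z.shape[1] == x.size:
        z = z.T
    n = x.size
    if z.shape[0] != n:
        raise ValueError("confounder matrix must have one row per observation")
    keep = [j for j in range(z.shape[1]) if np.ptp(z[:, j]) > 0]
    z = z[:, keep]
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_confounders + 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: partial Spearman undefined")
        return float("nan"), float("nan")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(n)] + [stats.rankdata(z[:, j])
                                             for j in range(k)])
    if k > 0 and np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear confounders")
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom <= 1e-12:
        # one variable is fully explained by the confounders: nothing remains
        # to correlate, so the partial association is null by convention
        warnings.warn("degenerate residuals in partial Spearman; returning 0")
        return 0.0, 1.0
    r = float((ex * ey).sum() / denom)
    df = n - 2 - k
    r_clip = min(max(r, -0.999999999999), 0.999999999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# Concordance and Cox models
# ---------------------------------------------------------------------------

def concordance_index(risk_scores: Sequence[float], survival_days: Sequence[float],
                      event_indicator: Optional[Sequence[int]] = None) -> float:
    """Harrell's C over comparable pairs; tied risks count 1/2.

    A pair is comparable when the shorter-surviving subject had the event.
    The pair is concordant when that subject carries the higher risk score.
    1.0 is perfect ranking, 0.5 chance level.
    """
    risk = np.asarray(risk_scores, dtype=np.float64)
    time = np.asarray(survival_days, dtype=np.float64)
    if risk.shape != time.shape or risk.ndim != 1:
        raise ValueError("risk and survival arrays must be equal-length 1D")
    if len(risk) < 2:
        raise ValueError("need at least two subjects")
    if not np.isfinite(risk).all():
        raise ValueError("risk scores must be finite")
    event = (np.ones_like(time, dtype=bool) if event_indicator is None
             else np.asarray(event_indicator).astype(bool))

    t_i = time[:, None]
    t_j = time[None, :]
    e_i = event[:, None]
    # pair (i, j): i strictly shorter and i had the event -> comparable
    comparable = (t_i < t_j) & e_i
    r_i = risk[:, None]
    r_j = risk[None, :]
    concordant = comparable & (r_i > r_j)
    tied = comparable & (r_i == r_j)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def fit_cox(features, survival_days, events=None,
            alpha: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Cox proportional-hazards fit (Breslow ties); returns (coef, risk).

    ``risk`` is the per-subject linear predictor X @ coef, the score fed to
    :func:`concordance_index`.
    """
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[0] != np.size(survival_days):
        X = X.T
    time = np.asarray(survival_days, dtype=np.float64)
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("need n > n_features + 2")
    if any(np.ptp(X[:, j]) == 0 for j in range(k)):
        raise ValueError("constant feature column")
    event = (np.ones(n, dtype=bool) if events is None
             else np.asarray(events).astype(bool))
    y = np.empty(n, dtype=[("event", bool), ("time", float)])
    y["event"] = event
    y["time"] = time
    # standardize internally for optimizer stability; coefficients are
    # returned on the original feature scale
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Xs = (X - mu) / sd
    last_exc = None
    # a perfectly separating feature makes the partial likelihood monotone;
    # fall back to a light ridge penalty, which leaves the risk ranking intact
    for a in (alpha, 0.1, 1.0):
        model = CoxPHSurvivalAnalysis(alpha=a, ties="breslow")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xs, y)
        except Exception as exc:  # noqa: BLE001 - retried with regularization
            last_exc = exc
            continue
        coef_s = np.asarray(model.coef_, dtype=np.float64)
        if not np.isfinite(coef_s).all():
            last_exc = RuntimeError("non-finite coefficients")
            continue
        return coef_s / sd, Xs @ coef_s
    raise RuntimeError(f"Cox model did not converge: {last_exc}")


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); undefined when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks are empty")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


# ---------------------------------------------------------------------------
# Association battery
# ---------------------------------------------------------------------------

@dataclass
class AssociationReport:
    """Output tables mirroring the correlation/concordance reporting layout."""

    correlations: pd.DataFrame      # one row per (hemisphere group, stratum, analysis, region)
    concordance: pd.DataFrame       # univariate Cox CI per significant region
    multivariate: pd.DataFrame      # one row per hemisphere group
    warnings: list[str] = dc_field(default_factory=list)


def _per_region_correlations(medh_wide: pd.DataFrame, sub: pd.DataFrame,
                             group_label: str, hemi: str,
                             region_meta: pd.DataFrame,
                             p_method: str) -> pd.DataFrame:
    rows = []
    survival = sub["survival_days"].to_numpy()
    conf = sub[["age_years", "tumor_volume_ml"]].to_numpy()
    for rid in medh_wide.columns:
        vals = medh_wide.loc[sub["subject_id"], rid].to_numpy()
        ok = np.isfinite(vals)
        meta = region_meta.loc[rid]
        for tag in ("plain", "partial"):
            x, y = vals[ok], survival[ok]
            if ok.sum() < 4 or np.ptp(x) == 0:
                r, p = np.nan, np.nan
            elif tag == "plain":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = spearman(x, y, p_method=p_method)
            else:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        r, p = partial_spearman(x, y, conf[ok])
                except ValueError:
                    r, p = np.nan, np.nan
            rows.append({
                "tumor_hemisphere": hemi, "group": group_label, "analysis": tag,
                "region_id": rid, "region_name": meta["region_name"],
                "hemisphere": meta["hemisphere"], "n": int(ok.sum()),
                "r": r, "p": p, "marker": significance_marker(p),
            })
    out = pd.DataFrame(rows)
    for tag in ("plain", "partial"):
        sel = (out["analysis"] == tag) & np.isfinite(out["p"])
        if sel.sum() > 1:
            out.loc[sel, "q_bh"] = multipletests(out.loc[sel, "p"], method="fdr_bh")[1]
    return out


def run_association_analysis(medh_table: pd.DataFrame, subjects: pd.DataFrame,
                             min_group_size: int = 4,
                             significance_level: float = 0.05,
                             p_method: str = "asymptotic") -> AssociationReport:
    """The full association battery on a joined MEDH/clinical cohort.

    For each tumor-hemisphere group: per-region plain and partial Spearman
    against survival days within (a) the pooled long+short stratum and
    (b) the medium stratum; univariate Cox concordance for each region
    significant in the plain long+short analysis; one multivariate Cox model
    over all such regions.  Groups smaller than ``min_group_size`` are
    skipped with a warning collected in the report.
    """
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise ValueError(f"subjects table missing columns {missing}")
    subjects = subjects.copy()
    subjects["group"] = subjects["survival_days"].map(stratify_survival)
    if "event" not in subjects.columns:
        subjects["event"] = 1

    medh_wide = medh_table.pivot(index="subject_id", columns="region_id",
                                 values="medh_mm2")
    region_meta = (medh_table[["region_id", "region_name", "hemisphere"]]
                   .drop_duplicates().set_index("region_id"))
    common = subjects["subject_id"].isin(medh_wide.index)
    if not common.all():
        raise ValueError("subjects table contains ids absent from the MEDH table")

    corr_frames, ci_rows, multi_rows, notes = [], [], [], []
    for hemi in sorted(subjects["tumor_hemisphere"].unique()):
        grp = subjects[subjects["tumor_hemisphere"] == hemi]
        strata = {
            "long+short": grp[grp["group"].isin(["long", "short"])],
            "medium": grp[grp["group"] == "medium"],
        }
        for label, sub in strata.items():
            if len(sub) < min_group_size:
                notes.append(f"{hemi}/{label}: only {len(sub)} subjects; skipped")
                continue
            corr_frames.append(_per_region_correlations(
                medh_wide, sub, label, hemi, region_meta, p_method))

        # Cox concordance on the long+short stratum, plain-analysis selection
        ls = strata["long+short"]
        if len(ls) < min_group_size or not corr_frames:
            continue
        plain_ls = pd.concat(corr_frames, ignore_index=True)
        plain_ls = plain_ls[(plain_ls["tumor_hemisphere"] == hemi)
                            & (plain_ls["group"] == "long+short")
                            & (plain_ls["analysis"] == "plain")]
        sig = plain_ls[plain_ls["p"] < significance_level].sort_values("p")
        time = ls["survival_days"].to_numpy()
        event = ls["event"].to_numpy()
        sig_ids = []
        for _, row in sig.iterrows():
            rid = row["region_id"]
            vals = medh_wide.loc[ls["subject_id"], rid].to_numpy()
            if not np.isfinite(vals).all() or np.ptp(vals) == 0:
                continue
            try:
                _, risk = fit_cox(vals[:, None], time, event)
                ci = concordance_index(risk, time, event)
            except (RuntimeError, ValueError) as exc:
                notes.append(f"{hemi}/{row['region_name']}: Cox failed ({exc})")
                continue
            sig_ids.append(rid)
            ci_rows.append({"tumor_hemisphere": hemi, "region_id": rid,
                            "region_name": row["region_name"],
                            "hemisphere": row["hemisphere"],
                            "r": row["r"], "p": row["p"], "ci": ci})
        # multivariate model over the significant regions; when there are
        # more of them than the sample size can support, keep the smallest-p
        # ones up to n - 3 (sig_ids is already ordered by ascending p)
        capacity = len(ls) - 3
        multi_ids = sig_ids[:capacity]
        if len(multi_ids) < len(sig_ids):
            notes.append(f"{hemi}/multivariate: capped at {len(multi_ids)} of "
                         f"{len(sig_ids)} significant regions (n={len(ls)})")
        if multi_ids:
            X = medh_wide.loc[ls["subject_id"], multi_ids].to_numpy()
            try:
                _, risk = fit_cox(X, time, event)
                ci = concordance_index(risk, time, event)
                multi_rows.append({"tumor_hemisphere": hemi,
                                   "n_regions": len(multi_ids),
                                   "n_significant": len(sig_ids),
                                   "region_ids": list(map(int, multi_ids)),
                                   "ci": ci})
            except (RuntimeError, ValueError) as exc:
                notes.append(f"{hemi}/multivariate: Cox failed ({exc})")

    correlations = (pd.concat(corr_frames, ignore_index=True)
                    if corr_frames else pd.DataFrame())
    return AssociationReport(
        correlations=correlations,
        concordance=pd.DataFrame(ci_rows),
        multivariate=pd.DataFrame(multi_rows),
        warnings=notes,
    )
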