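"""Region-level DC features and their association with clinical scores.

Mean standardized DC inside each surviving cluster is the per-subject
regional feature.  Associations with clinical / demographic variables
use Pearson correlation (per region x variable pair) or a joint
multiple-factor regression per region, with Bonferroni (default) or
Benjamini-Hochberg correction across the whole region x variable family.
Illness duration exists only for patients, so pairs involving it are
computed on the patient subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DCMap

__all__ = ["extract_region_features", "correlate_with_clinical"]

PATIENT_ONLY_VARS = ("illness_duration_months", "hrsd17")


def extract_region_features(
    dc_maps: list[DCMap],
    cluster_labels: np.ndarray,
    cohort: pd.DataFrame | None = None,
    region_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subject mean standardized DC within each labeled region.

    ``cluster_labels`` is a 3D integer map (0 = background, 1..R =
    regions).  Returns one row per subject with one ``dc_<region>``
    column per region, joined with the cohort table on subject_id when
    supplied.
    """
    labels = np.asarray(cluster_labels)
    if dc_maps and labels.shape != dc_maps[0].standardized.shape:
        raise ValueError("cluster label map does not match DC grid")
    region_ids = [int(r) for r in np.unique(labels) if r != 0]
    if not region_ids:
        raise ValueError("cluster label map contains no regions")
    if region_names is None:
        region_names = [f"region{r}" for r in region_ids]
    region_masks = [labels == r for r in region_ids]
    rows = []
    for m in dc_maps:
        row = {"subject_id": m.subject_id}
        for name, rm in zip(region_names, region_masks):
            row[f"dc_{name}"] = float(m.standardized[rm].mean())
        rows.append(row)
    feats = pd.DataFrame(rows)
    if cohort is not None:
        feats = feats.merge(cohort, on="subject_id", how="left", validate="one_to_one")
    return feats


def _pair_frame(table, region_cols, clinical_vars, patients_only_for):
    for region in region_cols:
        for var in clinical_vars:
            sub = table
            if var in patients_only_for and "group" in table.columns:
                sub = table[table["group"] == "patient"]
            pair = sub[[region, var]].dropna()
            yield region, var, pair


def correlate_with_clinical(
    table: pd.DataFrame,
    clinical_vars: list[str],
    region_cols: list[str] | None = None,
    method: str = "pearson",
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region x variable association report with multiplicity correction.

    ``method='pearson'`` reports r and two-sided p per pair;
    ``method='multiple_regression'`` regresses each region's DC on all
    clinical variables jointly and reports per-coefficient t and p.
    Correction (``bonferroni`` or ``fdr_bh``) is applied across the full
    family of reported p-values.  Zero-variance pairs are reported with
    undefined (NaN-marked but flagged) statistics rather than propagated.
    """
    if region_cols is None:
        region_cols = [c for c in table.columns if c.startswith("dc_")]
    if not region_cols:
        raise ValueError("no region feature columns found")
    if correction not in ("bonferroni", "fdr_bh"):
        raise ValueError("correction must be 'bonferroni' or 'fdr_bh'")
    rows = []
    if method == "pearson":
        for region, var, pair in _pair_frame(table, region_cols, clinical_vars, PATIENT_ONLY_VARS):
            x = pair[region].to_numpy(dtype=float)
            y = pair[var].to_numpy(dtype=float)
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete observations for {region} x {var}")
            if x.std() == 0 or y.std() == 0:
                rows.append(dict(region=region, variable=var, n=len(pair),
                                 r=np.nan, p=np.nan, defined=False))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(dict(region=region, variable=var, n=len(pair),
                             r=float(r), p=float(p), defined=True))
    elif method == "multiple_regression":
        for region in region_cols:
            sub = table
            if any(v in PATIENT_ONLY_VARS for v in clinical_vars) and "group" in table.columns:
                sub = table[table["group"] == "patient"]
            cols = {v: (np.where(sub[v] == "M", 1.0, 0.0) if v == "sex"
                        else sub[v].to_numpy(dtype=float)) for v in clinical_vars}
            X = pd.DataFrame(cols, index=sub.index).dropna()
            y = sub.loc[X.index, region].astype(float)
            fit = sm.OLS(y, sm.add_constant(X)).fit()
            for var in clinical_vars:
                rows.append(dict(region=region, variable=var, n=int(fit.nobs),
                                 r=float(fit.params[var]), p=float(fit.pvalues[var]),
                                 defined=bool(np.isfinite(fit.pvalues[var]))))
    else:
        raise ValueError("method must be 'pearson' or 'multiple_regression'")

    out = pd.DataFrame(rows)
    out["p_corrected"] = np.nan
    defined = out["defined"].to_numpy()
    if defined.any():
        meth = "bonferroni" if correction == "bonferroni" else "fdr_bh"
        _, p_adj, _, _ = multipletests(out.loc[defined, "p"], alpha=alpha, method=meth)
        out.loc[defined, "p_corrected"] = p_adj
    out["significant"] = out["p_corrected"] <= alpha
    return out
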