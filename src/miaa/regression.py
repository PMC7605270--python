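"""Linear model of accessibility on GC content and motif effects.

Each measured Dpn proportion is modeled as

    proportion ~ intercept + gc + replicate + sum_(m,c) beta[m,c] * x[m,c]

where ``x[m,c]`` indicates that the sequence was designed to carry motif
unit *m* (a motif, motif pair, or arrangement — taken from the design
annotation, never rediscovered by scanning, so shuffled controls contribute
strictly zero motif columns) and the observation was made in condition *c*.
The per-condition coefficients ``beta[m,c]`` are the motif-effect estimates
of interest: clustering them groups motifs by cell-type specificity, and
coefficient differences between an overexpression condition and the ESC
baseline rank motifs by their response to the overexpressed factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr
from sklearn.model_selection import GroupShuffleSplit

from .design import DesignedSequence
from .stats import bh_adjust

__all__ = [
    "MotifEffectFit",
    "motif_unit",
    "build_design_matrix",
    "fit_accessibility_regression",
    "compare_nested_models",
    "cluster_motif_weights",
    "overexpression_response",
]


def motif_unit(design: DesignedSequence) -> str | None:
    """Motif-content key of a design: sorted placed motif ids, '+'-joined.

    Shuffled controls and plain backgrounds have no placements and map to
    None (all motif indicators zero).
    """
    ids = sorted(set(m for m, _, _ in design.placements))
    return "+".join(ids) if ids else None


@dataclass
class MotifEffectFit:
    """OLS fit of the accessibility regression."""

    coefficients: dict[str, float]
    adjusted_r2: float
    train_r: float
    test_r: float
    n_train: int
    n_test: int
    feature_names: list[str]
    motif_condition_features: dict[tuple[str, str], str] = field(default_factory=dict)
    result: object | None = None  # statsmodels RegressionResults (train fit)

    def motif_coefficient(self, unit: str, condition: str) -> float:
        return self.coefficients[self.motif_condition_features[(unit, condition)]]


def build_design_matrix(
    accessibility: pd.DataFrame,
    designs: list[DesignedSequence],
    conditions: list[str],
    motif_units: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Assemble (X, y, groups) from an accessibility table and design metadata.

    One row per (sequence, condition, replicate) observation with a
    non-missing proportion. Columns: intercept, gc, replicate one-hots
    (reference level dropped; replicate levels are condition-specific,
    since batches are), and a (motif unit x condition) indicator per pair.
    ``groups`` carries the sequence id of each row for sequence-level
    train/test splitting.
    """
    by_id = {d.id: d for d in designs}
    df = accessibility.dropna(subset=["dpn_proportion"])
    df = df[df["condition"].isin(conditions)].copy()
    missing = set(df["sequence_id"]) - set(by_id)
    if missing:
        raise ValueError(f"designs missing for sequences: {sorted(missing)[:5]} ...")
    if motif_units is None:
        units = sorted({u for u in (motif_unit(d) for d in designs) if u is not None})
    else:
        units = list(motif_units)

    df["gc"] = [by_id[s].gc for s in df["sequence_id"]]
    df["unit"] = [motif_unit(by_id[s]) for s in df["sequence_id"]]
    df["rep_level"] = df["condition"].astype(str) + "/" + df["replicate"].astype(str)

    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    X["gc"] = df["gc"]
    rep_levels = sorted(df["rep_level"].unique())
    for level in rep_levels[1:]:  # first level is the reference
        X[f"rep[{level}]"] = (df["rep_level"] == level).astype(float)
    motif_cols: dict[tuple[str, str], str] = {}
    for unit in units:
        for c in conditions:
            col = f"motif[{unit}|{c}]"
            X[col] = ((df["unit"] == unit) & (df["condition"] == c)).astype(float)
            motif_cols[(unit, c)] = col
    empty = [col for col in X.columns if col != "intercept" and X[col].abs().sum() == 0]
    if empty:
        raise ValueError(f"empty design-matrix columns (no observations): {empty}")
    y = df["dpn_proportion"].astype(float)
    X.attrs["motif_condition_features"] = motif_cols
    return X, y, df["sequence_id"]


def fit_accessibility_regression(
    X: pd.DataFrame,
    y: pd.Series,
    groups: pd.Series,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> MotifEffectFit:
    """OLS fit with a sequence-level train/test split.

    All observations of one sequence stay on the same side of the split, so
    the test correlation measures generalization to unseen sequences rather
    than unseen replicates of seen sequences.
    """
    if len(X) < X.shape[1]:
        raise ValueError("fewer observations than features")
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    if test_fraction > 0:
        splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        train_idx, test_idx = next(splitter.split(X, y, groups=groups))
    else:
        train_idx = np.arange(len(X))
        test_idx = np.array([], dtype=int)
    X_tr = X.iloc[train_idx]
    rank = np.linalg.matrix_rank(X_tr.to_numpy())
    if rank < X_tr.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient ({rank} < {X_tr.shape[1]}); "
            "check for collinear or empty columns"
        )
    res = sm.OLS(y.iloc[train_idx].to_numpy(), X_tr).fit()
    pred_train = np.asarray(res.predict(X_tr))
    train_r = float(pearsonr(pred_train, y.iloc[train_idx]).statistic)
    if len(test_idx):
        pred_test = np.asarray(res.predict(X.iloc[test_idx]))
        test_r = float(pearsonr(pred_test, y.iloc[test_idx]).statistic)
    else:
        test_r = float("nan")
    return MotifEffectFit(
        coefficients=dict(zip(X.columns, np.asarray(res.params))),
        adjusted_r2=float(res.rsquared_adj),
        train_r=train_r,
        test_r=test_r,
        n_train=len(train_idx),
        n_test=len(test_idx),
        feature_names=list(X.columns),
        motif_condition_features=dict(X.attrs.get("motif_condition_features", {})),
        result=res,
    )


def compare_nested_models(
    fit_full: MotifEffectFit,
    fit_reduced: MotifEffectFit,
) -> tuple[float, float]:
    """Partial F test of a reduced model inside the full model.

    Returns (delta adjusted R^2, F-test p-value). Both fits must come from
    the same observations, with the reduced features a subset of the full.
    """
    if not set(fit_reduced.feature_names) <= set(fit_full.feature_names):
        raise ValueError("models are not nested (reduced features not a subset)")
    if fit_full.n_train != fit_reduced.n_train:
        raise ValueError("fits use different observations")
    delta = fit_full.adjusted_r2 - fit_reduced.adjusted_r2
    if set(fit_reduced.feature_names) == set(fit_full.feature_names):
        return 0.0, 1.0
    _, p, _ = fit_full.result.compare_f_test(fit_reduced.result)
    return float(delta), float(p)


def cluster_motif_weights(
    fit: MotifEffectFit,
    n_clusters: int = 2,
) -> dict[str, int]:
    """Agglomerative clustering of per-motif condition-coefficient vectors.

    Each motif unit contributes its vector of per-condition coefficients;
    clustering is hierarchical with Euclidean distance and average linkage,
    cut at ``n_clusters``. Deterministic and invariant to motif input order
    (units are processed sorted).
    """
    pairs = fit.motif_condition_features
    units = sorted({u for u, _ in pairs})
    conditions = sorted({c for _, c in pairs})
    if len(units) < 2:
        raise ValueError("need at least 2 motif units to cluster")
    mat = np.array(
        [[fit.motif_coefficient(u, c) for c in conditions] for u in units]
    )
    z = linkage(mat, method="average", metric="euclidean")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return dict(zip(units, (int(l) for l in labels)))


def overexpression_response(
    fit_joint: MotifEffectFit,
    condition_a: str,
    condition_b: str,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Rank motifs by coefficient gain in condition A over condition B.

    For every motif unit the delta is coef(m, A) - coef(m, B); its standard
    error comes from the OLS coefficient covariance, giving a z-test per
    motif, BH-corrected within the family. Sorted by delta descending.
    """
    conditions = {c for _, c in fit_joint.motif_condition_features}
    for c in (condition_a, condition_b):
        if c not in conditions:
            raise ValueError(f"condition {c!r} not in the fit")
    res = fit_joint.result
    cov = np.asarray(res.cov_params())
    names = fit_joint.feature_names
    idx = {name: i for i, name in enumerate(names)}
    units = sorted({u for u, _ in fit_joint.motif_condition_features})
    rows = []
    for u in units:
        ca = fit_joint.motif_condition_features[(u, condition_a)]
        cb = fit_joint.motif_condition_features[(u, condition_b)]
        ia, ib = idx[ca], idx[cb]
        delta = fit_joint.coefficients[ca] - fit_joint.coefficients[cb]
        var = cov[ia, ia] + cov[ib, ib] - 2 * cov[ia, ib]
        se = float(np.sqrt(max(var, 0.0)))
        if condition_a == condition_b or se == 0.0:
            z, p = 0.0, 1.0
            if delta != 0 and se == 0:
                z, p = np.inf, 0.0
        else:
            from scipy.stats import norm

            z = delta / se
            p = float(2 * norm.sf(abs(z)))
        rows.append((u, float(delta), se, float(z), p))
    out = pd.DataFrame(rows, columns=["motif", "delta_weight", "se", "z", "p"])
    q, rejected = bh_adjust(out["p"].to_numpy(), fdr)
    out["q"] = q
    out["significant"] = rejected
    return out.sort_values("delta_weight", ascending=False, ignore_index=True)
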