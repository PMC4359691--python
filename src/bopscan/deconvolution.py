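"""Reference-based leukocyte deconvolution by constrained projection.

Whole-blood methylation is modelled as a non-negative mixture of purified
cell-type profiles. Given a sorted-cell reference methylome, the most
cell-type-informative CpGs are ranked by a one-way across-cell-type F
statistic, and each target sample's proportions are estimated by solving

    minimize  || y - S x ||^2   subject to  x >= 0,

where ``y`` is the sample's beta vector over the selected sites and ``S`` the
per-cell-type mean reference matrix, followed by sum-to-one normalisation.
Both the raw and normalised solutions are reported; the estimated fractions
serve as covariates in downstream differential-methylation testing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

CELL_TYPES = (
    "CD19+ B",
    "CD3+CD4+ T",
    "CD3+CD8+ T",
    "granulocytes",
    "CD14+ monocytes",
    "CD56+ NK",
)


def _validate_reference(ref: pd.DataFrame, cell_types: pd.Series) -> pd.Series:
    cell_types = pd.Series(cell_types)
    if not ref.columns.equals(pd.Index(cell_types.index)):
        cell_types = cell_types.reindex(ref.columns)
        if cell_types.isna().any():
            raise ValueError("every reference sample needs a cell_type label")
    if cell_types.nunique() < 2:
        raise ValueError("reference must contain at least 2 cell types")
    return cell_types


def anova_f_scores(ref: pd.DataFrame, cell_types: pd.Series) -> pd.Series:
    """One-way across-cell-type F statistic per CpG (informativeness score).

    A CpG with distinct cell-type means and zero within-type variance scores
    ``inf``; a CpG with identical group means scores 0. When every cell type
    has a single reference sample (no within-type degrees of freedom), the
    between-type mean square is used as the score.
    """
    cell_types = _validate_reference(ref, cell_types)
    X = ref.to_numpy(dtype=float)
    groups = [np.flatnonzero((cell_types == ct).to_numpy()) for ct in cell_types.unique()]
    k = len(groups)
    n = X.shape[1]
    grand = X.mean(axis=1)
    ss_between = np.zeros(len(ref))
    ss_within = np.zeros(len(ref))
    for idx in groups:
        sub = X[:, idx]
        gm = sub.mean(axis=1)
        ss_between += len(idx) * (gm - grand) ** 2
        ss_within += ((sub - gm[:, None]) ** 2).sum(axis=1)
    ms_between = ss_between / (k - 1)
    if n - k == 0:
        score = ms_between
    else:
        ms_within = ss_within / (n - k)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(
                ms_within > 0,
                ms_between / np.where(ms_within > 0, ms_within, 1.0),
                np.where(ms_between > 0, np.inf, 0.0),
            )
    return pd.Series(score, index=ref.index, name="F")


def select_informative_cpgs(ref: pd.DataFrame, cell_types: pd.Series, n: int = 500) -> list[str]:
    """The ``n`` CpGs most informative about cell type, largest F first.

    Ties are broken by lexicographic CpG id so the ranking is deterministic.
    """
    cell_types = _validate_reference(ref, cell_types)
    if n > len(ref):
        raise ValueError(f"requested {n} sites but reference has only {len(ref)} CpGs")
    if n < cell_types.nunique():
        raise ValueError("n must be at least the number of cell types")
    scores = anova_f_scores(ref, cell_types)
    order = sorted(scores.index, key=lambda cpg: (-scores[cpg], cpg))
    return [str(c) for c in order[:n]]


def reference_means(ref: pd.DataFrame, cell_types: pd.Series) -> pd.DataFrame:
    """Per-cell-type mean profile matrix S (CpGs x cell types)."""
    cell_types = _validate_reference(ref, cell_types)
    return ref.T.groupby(cell_types.to_numpy()).mean().T


def estimate_cell_proportions(
    beta: pd.DataFrame,
    ref: pd.DataFrame,
    cell_types: pd.Series,
    sites: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Estimate per-sample cell-type fractions by non-negative least squares.

    Sites absent from either matrix are dropped with a warning (their number
    is returned). Returns ``(raw, normalized, n_dropped_sites)`` where rows
    are target samples and columns cell types; ``normalized`` rows sum to 1.
    """
    sites = [str(s) for s in sites]
    usable = [s for s in sites if s in beta.index and s in ref.index]
    n_dropped = len(sites) - len(usable)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} of {len(sites)} deconvolution sites missing from the "
            "target or reference matrix and dropped",
            stacklevel=2,
        )
    S = reference_means(ref.loc[usable], cell_types)
    types = list(S.columns)
    if len(usable) < len(types):
        raise ValueError(f"only {len(usable)} usable sites for {len(types)} cell types")
    S_arr = S.to_numpy(dtype=float)
    if np.linalg.matrix_rank(S_arr) < len(types):
        raise ValueError(
            "reference mean matrix is rank-deficient over the chosen sites; "
            "select more (or more informative) sites"
        )

    raw = np.empty((beta.shape[1], len(types)))
    target = beta.loc[usable].to_numpy(dtype=float)
    for j in range(beta.shape[1]):
        raw[j], _ = optimize.nnls(S_arr, target[:, j])
    sums = raw.sum(axis=1)
    if (sums <= 0).any():
        bad = beta.columns[np.flatnonzero(sums <= 0)[0]]
        raise ValueError(f"all-zero proportion solution for sample {bad}")
    normalized = raw / sums[:, None]
    raw_df = pd.DataFrame(raw, index=beta.columns, columns=types)
    norm_df = pd.DataFrame(normalized, index=beta.columns, columns=types)
    return raw_df, norm_df, n_dropped


def compare_proportions(est: pd.DataFrame, measured: pd.DataFrame) -> pd.DataFrame:
    """Agreement of estimated vs measured fractions, per cell type.

    Returns bias (mean of est - measured), RMSE and Spearman rank correlation
    over the overlapping samples (at least 3 required).
    """
    samples = est.index.intersection(measured.index)
    if len(samples) < 3:
        raise ValueError(f"need >= 3 overlapping samples, found {len(samples)}")
    types = [t for t in est.columns if t in measured.columns]
    rows = []
    for t in types:
        e = est.loc[samples, t].to_numpy(dtype=float)
        m = measured.loc[samples, t].to_numpy(dtype=float)
        diff = e - m
        if np.allclose(e, e[0]) or np.allclose(m, m[0]):
            rho = 1.0 if np.allclose(diff, diff[0]) else np.nan
        else:
            rho = float(stats.spearmanr(e, m).statistic)
        rows.append(
            {
                "cell_type": t,
                "bias": float(diff.mean()),
                "rmse": float(np.sqrt((diff**2).mean())),
                "spearman": rho,
                "n": len(samples),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def group_proportion_tests(
    props: pd.DataFrame, groups: pd.Series, group_a: str, group_b: str
) -> pd.DataFrame:
    """Welch two-sample tests of each cell-type fraction between two groups.

    Descriptive output mirroring the cohort-level contrasts of estimated
    leukocyte fractions; not used by the DMR pipeline itself.
    """
    groups = groups.reindex(props.index)
    a = props.loc[groups == group_a]
    b = props.loc[groups == group_b]
    rows = []
    for t in props.columns:
        res = stats.ttest_ind(a[t], b[t], equal_var=False)
        rows.append(
            {
                "cell_type": t,
                "mean_" + group_a: float(a[t].mean()),
                "mean_" + group_b: float(b[t].mean()),
                "t": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")
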