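"""Covariate-adjusted differential-methylation testing.

Two groups (cases vs sibling controls) are compared with adjustment for sex,
batch and estimated leukocyte composition:

* **Region level** (probe Classes A/B): within each block of probes (BOP) of
  >= 3 probes, a MANOVA of every sliding window of 3 consecutive CpGs tests
  the group effect on the 3 correlated beta responses; the smallest window
  p-value represents the block. Pillai's trace with the standard F
  approximation is the default statistic (Wilks' lambda available). The group
  term is tested type-II style (full vs reduced model), so covariate order is
  irrelevant.
* **Site level** (Classes C/D): a per-probe linear model
  ``beta ~ group + covariates`` with a partial F test of the group term.

Benjamini-Hochberg FDR is applied separately within each probe class. The
minimum window p is carried to BH without within-block multiplicity
correction; this is anti-conservative for blocks with many windows and is a
documented property of the procedure, not corrected here.

Degenerate fits (constant probes, singular residual covariance) yield p = 1
with a flag rather than aborting a genome-wide scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Bop

EPS = 1e-6


class DesignError(ValueError):
    """The design matrix is unusable (rank deficient, missing columns, ...)."""


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Full-rank design for the group contrast, with the tested factor isolated.

    ``X`` holds intercept, group indicator (1 = ``group_a``) and covariate
    columns, one row per analysed sample.
    """

    X: pd.DataFrame
    group_col: str
    group_a: str
    group_b: str

    @property
    def sample_ids(self) -> pd.Index:
        return self.X.index

    @property
    def is_group_a(self) -> np.ndarray:
        return self.X[self.group_col].to_numpy() == 1.0

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(full, reduced) design arrays; reduced drops the group column."""
        full = self.X.to_numpy(dtype=float)
        reduced = self.X.drop(columns=[self.group_col]).to_numpy(dtype=float)
        return full, reduced


def build_design(
    sheet: pd.DataFrame,
    cell_props: pd.DataFrame | None = None,
    group_pair: tuple[str, str] = ("DSP", "DSS"),
    covariates: tuple[str, ...] = ("sex", "batch"),
    drop_cell_type: str = "granulocytes",
) -> DesignMatrix:
    """Build the test design from a sample sheet and estimated cell fractions.

    Only samples belonging to ``group_pair`` enter the design (in a trio
    cohort the mothers never enter the case-sib tests). Categorical covariates
    are dummy-coded dropping the first level; of the cell fractions the
    largest compartment (granulocytes by default) is dropped to avoid the
    sum-to-one collinearity.
    """
    group_a, group_b = group_pair
    mask = sheet["group"].isin(group_pair)
    sub = sheet.loc[mask]
    if (sub["group"] == group_a).sum() == 0 or (sub["group"] == group_b).sum() == 0:
        raise DesignError(f"both groups {group_pair} must be present")

    X = pd.DataFrame(index=sub.index)
    X["intercept"] = 1.0
    X["group"] = (sub["group"] == group_a).astype(float)
    for cov in covariates:
        if cov not in sub.columns:
            raise DesignError(f"covariate column {cov!r} missing from sample sheet")
        levels = pd.Categorical(sub[cov].astype(str))
        if len(levels.categories) > 1:
            dummies = pd.get_dummies(levels, prefix=cov, drop_first=True, dtype=float)
            dummies.index = sub.index
            X = pd.concat([X, dummies], axis=1)
    if cell_props is not None:
        props = cell_props.reindex(sub.index)
        if props.isna().any().any():
            raise DesignError("cell proportions missing for some design samples")
        cols = [c for c in props.columns if c != drop_cell_type]
        for c in cols:
            X[f"cell_{c}"] = props[c].to_numpy(dtype=float)

    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return DesignMatrix(X=X, group_col="group", group_a=group_a, group_b=group_b)


def _orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing, for projections)."""
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def to_m_values(beta: np.ndarray, eps: float = EPS) -> np.ndarray:
    """log2(beta / (1 - beta)) with clipping away from 0 and 1."""
    b = np.clip(beta, eps, 1 - eps)
    return np.log2(b / (1 - b))


# ---------------------------------------------------------------------------
# window-level MANOVA


def _pillai_f(V: float, q: int, t: int, ve: int) -> tuple[float, float, float]:
    s = min(q, t)
    m = (abs(t - q) - 1) / 2.0
    nn = (ve - t - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0:
        raise DesignError("not enough residual degrees of freedom for the MANOVA F")
    if V >= s:
        return np.inf, df1, df2
    F = (V / df1) / ((s - V) / df2)
    return F, df1, df2


def _wilks_f(lam: float, q: int, t: int, ve: int) -> tuple[float, float, float]:
    r = ve - (t - q + 1) / 2.0
    u = (t * q - 2) / 4.0
    denom = t**2 + q**2 - 5
    c = np.sqrt((t**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    df1 = t * q
    df2 = r * c - 2 * u
    if df2 <= 0:
        raise DesignError("not enough residual degrees of freedom for the MANOVA F")
    lam_c = lam ** (1.0 / c)
    if lam_c <= 0:
        return np.inf, df1, df2
    F = (1 - lam_c) / lam_c * df2 / df1
    return F, df1, df2


def manova_group_p(
    Y: np.ndarray,
    Qf: np.ndarray,
    Qr: np.ndarray,
    q_hyp: int,
    statistic: str = "pillai",
) -> tuple[float, float, bool]:
    """Group-effect p-value for a multivariate response block.

    ``Qf``/``Qr`` are orthonormal bases of the full and reduced design column
    spaces; ``q_hyp`` the hypothesis degrees of freedom (rank difference).
    Returns ``(p, statistic_value, degenerate)``; degenerate fits (singular
    residual cross-product) give ``(1.0, nan, True)``.
    """
    n, t = Y.shape
    ve = n - Qf.shape[1]
    YtY = Y.T @ Y
    Af = Qf.T @ Y
    E = YtY - Af.T @ Af
    Ar = Qr.T @ Y
    HplusE = YtY - Ar.T @ Ar
    H = HplusE - E
    # symmetrize against rounding
    E = (E + E.T) / 2
    HplusE = (HplusE + HplusE.T) / 2

    scale = max(np.abs(YtY).max(), 1e-30)
    try:
        if statistic == "pillai":
            if np.linalg.cond(HplusE) > 1e10 or np.abs(np.diag(E)).min() < 1e-12 * scale:
                return 1.0, float("nan"), True
            V = float(np.trace(np.linalg.solve(HplusE, H)))
            V = min(max(V, 0.0), float(min(q_hyp, t)))
            F, df1, df2 = _pillai_f(V, q_hyp, t, ve)
            statval = V
        elif statistic == "wilks":
            det_he = np.linalg.det(HplusE)
            det_e = np.linalg.det(E)
            if det_he <= 0 or np.abs(np.diag(E)).min() < 1e-12 * scale:
                return 1.0, float("nan"), True
            lam = float(np.clip(det_e / det_he, 0.0, 1.0))
            F, df1, df2 = _wilks_f(lam, q_hyp, t, ve)
            statval = lam
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    except np.linalg.LinAlgError:
        return 1.0, float("nan"), True
    if not np.isfinite(F):
        return 0.0, statval, False
    p = float(stats.f.sf(F, df1, df2))
    return p, statval, False


def window_manova_p(
    window: np.ndarray | pd.DataFrame,
    design: DesignMatrix,
    statistic: str = "pillai",
    values: str = "beta",
) -> tuple[float, bool]:
    """p-value of the group effect on a window of 3 consecutive probes.

    ``window`` is probes x samples (3 rows), sample order matching the design.
    Returns ``(p, degenerate_flag)``.
    """
    W = np.asarray(window, dtype=float)
    if W.shape[0] != 3:
        raise ValueError(f"window must have exactly 3 probe rows, got {W.shape[0]}")
    Xf, Xr = design.matrices()
    if W.shape[1] != Xf.shape[0]:
        raise ValueError("window sample count does not match the design")
    Y = W.T
    if values == "m":
        Y = to_m_values(Y)
    Qf = _orth_basis(Xf)
    Qr = _orth_basis(Xr)
    q_hyp = Qf.shape[1] - Qr.shape[1]
    n = Y.shape[0]
    if n - Qf.shape[1] < Y.shape[1] + 2:
        raise DesignError(
            f"need at least rank + {Y.shape[1] + 2} samples, have {n} for design rank {Qf.shape[1]}"
        )
    p, _, degenerate = manova_group_p(Y, Qf, Qr, q_hyp, statistic=statistic)
    return p, degenerate


# ---------------------------------------------------------------------------
# results


@dataclass
class BopResult:
    bop_id: str
    class_label: str
    chromosome: str
    n_probes: int
    n_windows: int
    min_window_p: float
    best_window: tuple[str, str, str]
    probe_ids: tuple[str, ...]
    deltas: tuple[float, ...]  # per probe, mean(beta | group_a) - mean(beta | group_b)
    q_value: float = float("nan")
    n_degenerate: int = 0
    window_ps: tuple[float, ...] | None = None

    @property
    def delta(self) -> float:
        """Block mean delta (used for hyper/hypo direction)."""
        return float(np.mean(self.deltas))

    @property
    def direction(self) -> str:
        return "hyper" if self.delta > 0 else "hypo"


@dataclass
class SiteResult:
    probe_id: str
    class_label: str
    chromosome: str
    p_value: float
    delta: float
    q_value: float = float("nan")
    degenerate: bool = False

    @property
    def direction(self) -> str:
        return "hyper" if self.delta > 0 else "hypo"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# scans


def _group_deltas(Y: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Raw per-probe group-mean beta differences (group_a - group_b)."""
    is_a = design.is_group_a
    return Y[:, is_a].mean(axis=1) - Y[:, ~is_a].mean(axis=1)


def scan_bops(
    bops: list[Bop],
    beta: pd.DataFrame,
    design: DesignMatrix,
    statistic: str = "pillai",
    values: str = "beta",
    keep_window_ps: bool = False,
) -> tuple[list[BopResult], list[tuple[str, str]]]:
    """Sliding-window MANOVA over every block with >= 3 analysable probes.

    A width-3, step-1 window slides along each block's probes in genomic
    order; the block is summarised by its smallest window p-value and the
    window attaining it. Blocks with fewer than 3 probes surviving QC are
    returned in the excluded list with a reason. q-values are BH-adjusted
    separately within each class label present.
    """
    beta_sub = beta.loc[:, design.sample_ids]
    Xf, Xr = design.matrices()
    Qf = _orth_basis(Xf)
    Qr = _orth_basis(Xr)
    q_hyp = Qf.shape[1] - Qr.shape[1]
    n = Xf.shape[0]
    if n - Qf.shape[1] < 3 + 2:
        raise DesignError("too few samples for 3-response MANOVA with this design")

    results: list[BopResult] = []
    excluded: list[tuple[str, str]] = []
    index_set = set(beta_sub.index)
    for bop in bops:
        present = [(pid, pos) for pid, pos in zip(bop.probes, bop.positions) if pid in index_set]
        if len(present) < 3:
            reason = (
                f"{bop.n_probes} probes, {len(present)} after QC"
                if len(present) < bop.n_probes
                else f"{bop.n_probes} probes (< 3)"
            )
            excluded.append((bop.bop_id, reason))
            continue
        probe_ids = [pid for pid, _ in present]
        Yall = beta_sub.loc[probe_ids].to_numpy(dtype=float).T  # samples x probes
        Ytest = to_m_values(Yall) if values == "m" else Yall
        win_ps = []
        n_degenerate = 0
        for i in range(len(probe_ids) - 2):
            p, _, degen = manova_group_p(Ytest[:, i : i + 3], Qf, Qr, q_hyp, statistic=statistic)
            win_ps.append(p)
            n_degenerate += int(degen)
        best = int(np.argmin(win_ps))
        deltas = _group_deltas(Yall.T, design)
        results.append(
            BopResult(
                bop_id=bop.bop_id,
                class_label=bop.class_label,
                chromosome=bop.chromosome,
                n_probes=len(probe_ids),
                n_windows=len(win_ps),
                min_window_p=float(win_ps[best]),
                best_window=tuple(probe_ids[best : best + 3]),
                probe_ids=tuple(probe_ids),
                deltas=tuple(float(d) for d in deltas),
                n_degenerate=n_degenerate,
                window_ps=tuple(win_ps) if keep_window_ps else None,
            )
        )

    for label in sorted({r.class_label for r in results}):
        idx = [i for i, r in enumerate(results) if r.class_label == label]
        qs = bh_adjust([results[i].min_window_p for i in idx])
        for i, q in zip(idx, qs):
            results[i].q_value = float(q)
    return results, excluded


def site_anova(
    probe_ids: list[str],
    beta: pd.DataFrame,
    design: DesignMatrix,
    class_labels=None,
    annotations: pd.DataFrame | None = None,
    values: str = "beta",
) -> list[SiteResult]:
    """Per-probe partial F test of the group term in a covariate-adjusted
    linear model (vectorised across probes).

    With no covariates in the design this is exactly the pooled-variance
    two-sample t-test (F = t^2). Constant probes are flagged and given p = 1.
    q-values are BH-adjusted within each class label.
    """
    probe_ids = [str(p) for p in probe_ids]
    if isinstance(class_labels, str) or class_labels is None:
        label_of = {p: (class_labels or "") for p in probe_ids}
    else:
        label_of = {p: class_labels[p] for p in probe_ids}
    chrom_of = (
        {p: str(annotations.loc[p, "chromosome"]) for p in probe_ids}
        if annotations is not None
        else {p: "" for p in probe_ids}
    )

    beta_sub = beta.loc[probe_ids, design.sample_ids]
    Yraw = beta_sub.to_numpy(dtype=float).T  # samples x probes
    Y = to_m_values(Yraw) if values == "m" else Yraw
    Xf, Xr = design.matrices()
    Qf = _orth_basis(Xf)
    Qr = _orth_basis(Xr)
    q_hyp = Qf.shape[1] - Qr.shape[1]
    ve = Y.shape[0] - Qf.shape[1]
    if ve < 1:
        raise DesignError("no residual degrees of freedom")

    Af = Qf.T @ Y
    rss_f = (Y**2).sum(axis=0) - (Af**2).sum(axis=0)
    Ar = Qr.T @ Y
    rss_r = (Y**2).sum(axis=0) - (Ar**2).sum(axis=0)
    scale = np.maximum((Y**2).sum(axis=0), 1e-300)
    degenerate = rss_f < 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / q_hyp) / (rss_f / ve)
    p = np.where(degenerate, 1.0, stats.f.sf(np.where(degenerate, 1.0, F), q_hyp, ve))
    deltas = _group_deltas(Yraw.T, design)

    results = [
        SiteResult(
            probe_id=pid,
            class_label=label_of[pid],
            chromosome=chrom_of[pid],
            p_value=float(p[j]),
            delta=float(deltas[j]),
            degenerate=bool(degenerate[j]),
        )
        for j, pid in enumerate(probe_ids)
    ]
    for label in sorted({r.class_label for r in results}):
        idx = [i for i, r in enumerate(results) if r.class_label == label]
        qs = bh_adjust([results[i].p_value for i in idx])
        for i, q in zip(idx, qs):
            results[i].q_value = float(q)
    return results


# ---------------------------------------------------------------------------
# chromosome-level distribution comparison


@dataclass
class ChromDistResult:
    chromosome: str
    group_a: str
    group_b: str
    ks_statistic: float
    p_value: float
    bonferroni_p: float
    n_a: int
    n_b: int
    histogram_a: np.ndarray = field(repr=False, default=None)
    histogram_b: np.ndarray = field(repr=False, default=None)


def _chrom_sort_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def chromosome_distribution_test(
    beta: pd.DataFrame,
    annotations: pd.DataFrame,
    groups: dict[str, list[str]],
    comparisons: list[tuple[str, str]] | None = None,
    n_bins: int = 100,
) -> list[ChromDistResult]:
    """Per-chromosome two-sample KS comparison of pooled beta values.

    For each chromosome the (probe, sample) beta values of each group are
    pooled; groups are compared pairwise with the two-sample KS test and the
    raw p multiplied by the number of chromosome x comparison tests
    (Bonferroni, capped at 1). Equal-width histograms over [0, 1] are attached
    for reporting.
    """
    for label, ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"group {label!r} is empty")
    if comparisons is None:
        comparisons = list(itertools.combinations(sorted(groups), 2))
    chroms = sorted(
        set(annotations.loc[annotations.index.intersection(beta.index), "chromosome"]),
        key=_chrom_sort_key,
    )
    n_tests = len(chroms) * len(comparisons)
    bins = np.linspace(0, 1, n_bins + 1)

    out = []
    for chrom in chroms:
        probes = annotations.index[annotations["chromosome"] == chrom].intersection(beta.index)
        sub = beta.loc[probes]
        for ga, gb in comparisons:
            a = sub.loc[:, groups[ga]].to_numpy(dtype=float).ravel()
            b = sub.loc[:, groups[gb]].to_numpy(dtype=float).ravel()
            a = a[np.isfinite(a)]
            b = b[np.isfinite(b)]
            if a.size and b.size and (np.array_equal(np.sort(a), np.sort(b))):
                d, p = 0.0, 1.0
            else:
                res = stats.ks_2samp(a, b)
                d, p = float(res.statistic), float(res.pvalue)
            out.append(
                ChromDistResult(
                    chromosome=chrom,
                    group_a=ga,
                    group_b=gb,
                    ks_statistic=d,
                    p_value=p,
                    bonferroni_p=min(1.0, p * n_tests),
                    n_a=a.size,
                    n_b=b.size,
                    histogram_a=np.histogram(a, bins=bins, density=True)[0],
                    histogram_b=np.histogram(b, bins=bins, density=True)[0],
                )
            )
    return out


# ---------------------------------------------------------------------------
# tabular export


def bop_results_frame(results: list[BopResult]) -> pd.DataFrame:
    rows = [
        {
            "bop_id": r.bop_id,
            "class_label": r.class_label,
            "chromosome": r.chromosome,
            "n_probes": r.n_probes,
            "n_windows": r.n_windows,
            "min_window_p": r.min_window_p,
            "q_value": r.q_value,
            "delta": r.delta,
            "direction": r.direction,
            "best_window": ";".join(r.best_window),
            "probe_ids": ";".join(r.probe_ids),
            "probe_deltas": ";".join(f"{d:.6g}" for d in r.deltas),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def site_results_frame(results: list[SiteResult]) -> pd.DataFrame:
    rows = [
        {
            "probe_id": r.probe_id,
            "class_label": r.class_label,
            "chromosome": r.chromosome,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "delta": r.delta,
            "direction": r.direction,
            "degenerate": r.degenerate,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
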