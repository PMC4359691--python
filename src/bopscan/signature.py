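"""Signature selection, enrichment tests, trio differences and low-dimensional views.

From the FDR-significant blocks, a stringent epigenetic signature keeps only
blocks containing at least ``min_adjacent`` genomically consecutive probes
whose group-mean methylation difference exceeds a threshold (default 0.15)
with a consistent sign. Each selected block is summarised by its most
significant probe. Downstream utilities cover chromosomal and gene-set
Fisher enrichment, per-family case-minus-sib difference matrices (which
cancel any shared family effect), classical metric MDS and average-linkage
hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .dmr import BopResult, bh_adjust


@dataclass
class SignatureEntry:
    bop_id: str
    class_label: str
    chromosome: str
    qualifying_runs: tuple[tuple[str, ...], ...]  # runs of consecutive qualifying probes
    direction: str
    q_value: float
    probe_ids: tuple[str, ...]
    deltas: tuple[float, ...]
    representative_probe: str | None = None
    representative_delta: float | None = None


def _qualifying_runs(
    probe_ids, deltas, delta_thresh: float, min_adjacent: int, require_consistent_sign: bool
):
    runs = []
    current: list[int] = []
    for i, d in enumerate(deltas):
        extend = abs(d) > delta_thresh and (
            not current
            or not require_consistent_sign
            or np.sign(d) == np.sign(deltas[current[0]])
        )
        if extend:
            current.append(i)
        else:
            if len(current) >= min_adjacent:
                runs.append(tuple(probe_ids[j] for j in current))
            # a qualifying probe that broke sign consistency starts a new run
            current = [i] if abs(d) > delta_thresh else []
    if len(current) >= min_adjacent:
        runs.append(tuple(probe_ids[j] for j in current))
    return tuple(runs)


def select_signature(
    bop_results: list[BopResult],
    delta_thresh: float = 0.15,
    min_adjacent: int = 2,
    q_thresh: float = 0.05,
    require_consistent_sign: bool = True,
) -> list[SignatureEntry]:
    """Stringent signature: FDR-significant blocks with a qualifying adjacent run.

    A block qualifies if ``q < q_thresh`` and it contains at least one run of
    ``min_adjacent`` genomically consecutive probes, each with
    ``|delta| > delta_thresh`` and (by default) the same sign. Lowering
    ``delta_thresh`` can only grow the selection.
    """
    selected = []
    for r in bop_results:
        if not (r.q_value < q_thresh):
            continue
        runs = _qualifying_runs(
            r.probe_ids, r.deltas, delta_thresh, min_adjacent, require_consistent_sign
        )
        if not runs:
            continue
        selected.append(
            SignatureEntry(
                bop_id=r.bop_id,
                class_label=r.class_label,
                chromosome=r.chromosome,
                qualifying_runs=runs,
                direction=r.direction,
                q_value=r.q_value,
                probe_ids=r.probe_ids,
                deltas=r.deltas,
            )
        )
    return selected


def signature_direction_split(signature: list[SignatureEntry]) -> dict[str, int]:
    return {
        "hyper": sum(1 for s in signature if s.direction == "hyper"),
        "hypo": sum(1 for s in signature if s.direction == "hypo"),
    }


def representative_probe(
    bop: BopResult | SignatureEntry,
    site_p: dict[str, float],
    positions: dict[str, int] | None = None,
) -> str:
    """Most significant probe of a block; ties go to the smaller genomic position.

    When positions are not supplied, the block's genomic probe order is used,
    which is equivalent.
    """
    tested = [p for p in bop.probe_ids if p in site_p]
    if not tested:
        raise ValueError(f"block {bop.bop_id} has no tested probes")
    if positions is None:
        positions = {p: i for i, p in enumerate(bop.probe_ids)}
    return min(tested, key=lambda p: (site_p[p], positions[p]))


def attach_representatives(
    signature: list[SignatureEntry],
    site_p: dict[str, float],
    positions: dict[str, int] | None = None,
) -> None:
    """Fill each entry's representative probe and its delta, in place."""
    for entry in signature:
        rep = representative_probe(entry, site_p, positions)
        entry.representative_probe = rep
        entry.representative_delta = entry.deltas[entry.probe_ids.index(rep)]


# ---------------------------------------------------------------------------
# Fisher enrichment


def _fisher_row(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-tailed Fisher exact p and the sample odds ratio (a*d)/(b*c)."""
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    return p, odds


def hypergeom_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-tailed Fisher p by enumerating the hypergeometric support.

    Sums the probabilities of all tables (with the same margins) whose
    probability does not exceed that of the observed table. Exact but O(n);
    intended as an oracle for modest totals.
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0

    def logcomb(m: int, k: int) -> float:
        return lgamma(m + 1) - lgamma(k + 1) - lgamma(m - k + 1)

    def logpmf(x: int) -> float:
        return logcomb(col1, x) + logcomb(n - col1, row1 - x) - logcomb(n, row1)

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    lp_obs = logpmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logpmf(x)
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return min(1.0, total)


def chromosome_enrichment(
    units: pd.DataFrame,
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Per-chromosome over/under-representation of significant units.

    ``units`` needs columns ``chromosome`` and either a boolean
    ``significant`` or a ``q_value`` (thresholded at ``q_thresh``). Units are
    blocks for the CpG-rich classes and probes for the open-sea classes. For
    each chromosome a 2x2 table (significant vs not) x (on vs off chromosome)
    is tested two-tailed; q-values are BH across chromosomes.
    """
    units = units.copy()
    if "significant" not in units.columns:
        units["significant"] = units["q_value"] < q_thresh
    chroms = [c for c in sorted(units["chromosome"].unique(), key=_chrom_key)]
    n_sig = int(units["significant"].sum())
    n_tot = len(units)
    rows = []
    for chrom in chroms:
        on = units["chromosome"] == chrom
        a = int((on & units["significant"]).sum())
        b = n_sig - a
        c = int(on.sum()) - a
        d = (n_tot - n_sig) - c
        p, odds = _fisher_row(a, b, c, d)
        rows.append({"unit": chrom, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p_value": p})
    out = pd.DataFrame(rows).set_index("unit")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < q_thresh
    out["direction"] = np.where(out["odds_ratio"] > 1, "enriched", "depleted")
    return out


def _chrom_key(c: str):
    c = str(c)
    return (0, int(c)) if c.isdigit() else (1, c)


def geneset_fisher(
    dmr_genes: set[str],
    universe: set[str],
    collections: dict[str, set[str]],
    q_thresh: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed Fisher exact enrichment of each gene set among DMR genes.

    Collection members are intersected with the universe (all tested genes);
    duplicated symbols count once. BH across collections.
    """
    if not universe:
        raise ValueError("empty gene universe")
    dmr = {g.upper() for g in dmr_genes} & {g.upper() for g in universe}
    uni = {g.upper() for g in universe}
    rows = []
    for name in sorted(collections):
        members = {g.upper() for g in collections[name]} & uni
        a = len(dmr & members)
        b = len(dmr - members)
        c = len(members - dmr)
        d = len(uni) - a - b - c
        p, odds = _fisher_row(a, b, c, d)
        rows.append({"unit": name, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p_value": p})
    out = pd.DataFrame(rows).set_index("unit")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < q_thresh
    out["direction"] = np.where(out["odds_ratio"] > 1, "enriched", "depleted")
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (set name, description, members per line)."""
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            collections[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return collections


# ---------------------------------------------------------------------------
# trio differences, ordination, clustering


def family_pair_differences(
    representative_probes: list[str],
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    case_group: str = "DSP",
    control_group: str = "DSS",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-family case-minus-sib methylation differences at signature probes.

    Returns a families x probes matrix of ``beta_case - beta_control`` and the
    list of families excluded for not contributing exactly one sample of each
    group. Any additive shift applied identically to both family members
    cancels in the difference.
    """
    diffs = {}
    excluded = []
    for family, members in sheet.groupby("family"):
        cases = members.index[members["group"] == case_group]
        controls = members.index[members["group"] == control_group]
        if len(cases) != 1 or len(controls) != 1:
            excluded.append(str(family))
            continue
        diffs[str(family)] = (
            beta.loc[representative_probes, cases[0]].to_numpy(dtype=float)
            - beta.loc[representative_probes, controls[0]].to_numpy(dtype=float)
        )
    matrix = pd.DataFrame.from_dict(diffs, orient="index", columns=representative_probes)
    return matrix.sort_index(), excluded


def mds_embedding(matrix: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """Classical (Torgerson) metric MDS to 2 dimensions.

    Double-centers the squared Euclidean distance matrix and takes the top two
    eigenpairs. For an exactly 2-dimensional configuration the embedded
    distances reproduce the input distances. Axis signs are fixed so the first
    sample with a non-zero coordinate is positive on each axis. Returns
    ``(coords, rank_deficient)``; a rank < 2 configuration gets a zero second
    axis and the flag set.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for an MDS embedding")
    if not np.isfinite(X).all():
        raise ValueError("missing values in the MDS input")
    D2 = squareform(pdist(X, metric="euclidean")) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:2]
    lam = eigval[order]
    rank_deficient = bool(lam[1] <= 1e-10 * max(lam[0], 1.0))
    coords = np.zeros((n, 2))
    for k in range(2):
        if lam[k] > 1e-10 * max(lam[0], 1.0):
            axis = eigvec[:, order[k]] * np.sqrt(lam[k])
            nz = np.flatnonzero(np.abs(axis) > 1e-12)
            if nz.size and axis[nz[0]] < 0:
                axis = -axis
            coords[:, k] = axis
    return pd.DataFrame(coords, index=matrix.index, columns=["dim1", "dim2"]), rank_deficient


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: int = 0,
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage agglomeration with deterministic, label-sorted input order.

    ``axis=0`` clusters rows, ``axis=1`` columns. Returns the SciPy linkage
    matrix, the dendrogram leaf labels (left to right) and a Newick string
    with merge heights as branch lengths.
    """
    data = matrix if axis == 0 else matrix.T
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.isfinite(data.to_numpy(dtype=float)).all():
        raise ValueError("missing values in the clustering input")
    data = data.loc[sorted(data.index.astype(str))]
    labels = [str(x) for x in data.index]
    Z = hierarchy.linkage(data.to_numpy(dtype=float), method=method, metric=metric)
    leaves = hierarchy.leaves_list(Z)
    leaf_labels = [labels[i] for i in leaves]
    newick = _linkage_to_newick(Z, labels)
    return Z, leaf_labels, newick


def cut_clusters(Z: np.ndarray, labels: list[str], k: int) -> pd.Series:
    """Flat cluster labels from cutting the dendrogram into ``k`` clusters."""
    assign = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(assign, index=labels, name="cluster")


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        if parent_height is None:
            return f"({left},{right});"
        return f"({left},{right}):{length:.10g}"

    def render_root(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]};"
        return f"({render(node.left, node.dist)},{render(node.right, node.dist)});"

    return render_root(tree)
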