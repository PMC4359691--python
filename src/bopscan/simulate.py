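"""Synthetic trio-cohort generator for end-to-end pipeline testing.

Emulates every input the analysis needs — a manifest-dialect probe annotation
table, a sorted-cell reference methylome, and a family-structured beta /
detection-p matrix pair with sample sheet — with controllable planted
effects and a serialised ground truth:

* probes laid out on synthetic autosome coordinates as CpG islands (with
  optional flanking shores), open-sea genic sites and open-sea intergenic
  sites, so the four probe classes and the block structure are exercised;
* trios (case, unaffected sibling, mother) sharing a per-family random
  shift, plus sex and batch effects;
* group-dependent leukocyte composition (cases with fewer B and CD4+ T
  cells, more CD8+ T cells) driving reference-site methylation and,
  optionally, per-cell-type probe loadings that confound unadjusted tests;
* planted block-level methylation differences for recovery benchmarks;
* beta-distributed observation noise around the signal mean (precision
  parameterisation keeps draws in (0, 1) without clipping artifacts).

Randomness is fully deterministic under a fixed seed: independent seed
substreams are spawned for the manifest, each effect layer, and one per
sample for observation noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann
from .deconvolution import CELL_TYPES, reference_means

EPS = 1e-6

#: typical whole-blood composition (fractions summing to 1)
BLOOD_COMPOSITION = {
    "CD19+ B": 0.07,
    "CD3+CD4+ T": 0.15,
    "CD3+CD8+ T": 0.08,
    "granulocytes": 0.60,
    "CD14+ monocytes": 0.04,
    "CD56+ NK": 0.06,
}

#: case composition: fewer B and CD4+ T cells, more CD8+ T cells
CASE_COMPOSITION = {
    "CD19+ B": 0.04,
    "CD3+CD4+ T": 0.11,
    "CD3+CD8+ T": 0.14,
    "granulocytes": 0.60,
    "CD14+ monocytes": 0.05,
    "CD56+ NK": 0.06,
}

#: strongly shifted case composition for the confounding scenario
CONFOUNDED_CASE_COMPOSITION = {
    "CD19+ B": 0.03,
    "CD3+CD4+ T": 0.10,
    "CD3+CD8+ T": 0.18,
    "granulocytes": 0.55,
    "CD14+ monocytes": 0.06,
    "CD56+ NK": 0.08,
}

_BASE_RANGES = {
    "Island": (0.05, 0.30),
    "N_Shore": (0.20, 0.60),
    "S_Shore": (0.20, 0.60),
    "N_Shelf": (0.40, 0.80),
    "S_Shelf": (0.40, 0.80),
    "OpenSea": (0.55, 0.90),
}


@dataclass
class CohortSpec:
    """Study conditions for a synthetic trio cohort.

    Defaults mirror a 29-family whole-blood study (case sex split 18M/11F,
    sibling split 7M/22F) at desk scale: ~500 genic island blocks, ~100
    intergenic blocks, ~900 genic and ~430 intergenic open-sea sites.
    """

    n_families: int = 29
    male_fraction_case: float = 18 / 29
    male_fraction_sib: float = 7 / 29
    include_mothers: bool = True

    n_bops_a: int = 500
    n_bops_b: int = 100
    n_sites_c: int = 900
    n_sites_d: int = 430
    probes_per_bop: tuple[int, ...] = (3, 3, 3, 4, 5)
    shore_prob: float = 0.2
    n_sex_probes: int = 0

    n_planted: int = 0
    planted_delta: float = 0.0
    planted_probes: int | None = None  # None = every probe of the block
    planted_bops: tuple[tuple[str, float], ...] | None = None

    composition_case: dict = field(default_factory=lambda: dict(CASE_COMPOSITION))
    composition_control: dict = field(default_factory=lambda: dict(BLOOD_COMPOSITION))
    composition_concentration: float = 200.0

    n_batches: int = 2
    family_sd: float = 0.02
    sex_sd: float = 0.01
    batch_sd: float = 0.01
    cell_sensitive_frac: float = 0.0
    cell_effect_sd: float = 0.0

    noise_precision: float | None = 100.0
    detection_fail_rate: float = 0.0
    n_always_fail_probes: int = 0
    n_missing_probes: int = 0
    include_reference_sites: bool = True

    seed: int = 0

    def __post_init__(self):
        if self.planted_delta <= -1 or self.planted_delta >= 1:
            raise ValueError("planted delta must lie in (-1, 1)")
        for name in ("family_sd", "sex_sd", "batch_sd", "cell_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "CohortSpec":
        """Zero-effect cohort: no planted blocks, equal composition, no
        family/sex/batch structure — the calibration null for the tests."""
        kw.setdefault("composition_case", dict(BLOOD_COMPOSITION))
        kw.setdefault("family_sd", 0.0)
        kw.setdefault("sex_sd", 0.0)
        kw.setdefault("batch_sd", 0.0)
        return cls(seed=seed, n_planted=0, planted_delta=0.0, **kw)

    @classmethod
    def planted(cls, n_planted: int = 20, delta: float = 0.2, seed: int = 0, **kw) -> "CohortSpec":
        """Recovery benchmark: planted genic-island blocks among null blocks."""
        return cls(seed=seed, n_planted=n_planted, planted_delta=delta, **kw)

    @classmethod
    def confounded(cls, seed: int = 0, **kw) -> "CohortSpec":
        """No intrinsic group effect; the only group difference is leukocyte
        composition acting through per-cell-type probe loadings."""
        kw.setdefault("composition_case", dict(CONFOUNDED_CASE_COMPOSITION))
        kw.setdefault("cell_sensitive_frac", 0.5)
        kw.setdefault("cell_effect_sd", 0.4)
        return cls(seed=seed, n_planted=0, planted_delta=0.0, **kw)


@dataclass
class GroundTruth:
    planted: dict[str, float]
    planted_probe_ids: list[str]
    cell_sensitive_probes: list[str]
    always_fail_probes: list[str]
    missing_probes: list[str]
    true_proportions: pd.DataFrame
    sheet: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "planted": self.planted,
            "planted_probe_ids": self.planted_probe_ids,
            "cell_sensitive_probes": self.cell_sensitive_probes,
            "always_fail_probes": self.always_fail_probes,
            "missing_probes": self.missing_probes,
            "true_proportions": self.true_proportions.to_dict(orient="index"),
            "sheet": self.sheet.to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        props = pd.DataFrame.from_dict(payload["true_proportions"], orient="index")
        props.index.name = "sample_id"
        sheet = pd.DataFrame.from_dict(payload["sheet"], orient="index")
        sheet.index.name = "sample_id"
        return cls(
            planted={k: float(v) for k, v in payload["planted"].items()},
            planted_probe_ids=list(payload["planted_probe_ids"]),
            cell_sensitive_probes=list(payload["cell_sensitive_probes"]),
            always_fail_probes=list(payload["always_fail_probes"]),
            missing_probes=list(payload["missing_probes"]),
            true_proportions=props,
            sheet=sheet,
        )


# ---------------------------------------------------------------------------
# manifest


def generate_manifest(spec: CohortSpec, reference_ids: list[str] | None = None) -> pd.DataFrame:
    """Synthetic manifest in the Illumina column dialect.

    Genic island blocks (Class A) get one gene each and, with probability
    ``shore_prob`` per side, a flanking shore probe; intergenic islands give
    Class B; open-sea probes give Classes C/D. Reference deconvolution CpG
    ids, when supplied, are laid down as open-sea intergenic probes so they
    survive annotation-based QC.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    rows = []
    cursors = {str(c): 1_000 for c in range(1, 23)}
    chrom_cycle = [str(c) for c in range(1, 23)]

    def place(chrom: str, n: int, step: int = 50) -> list[int]:
        start = cursors[chrom]
        cursors[chrom] = start + n * step + 10_000
        return [start + i * step for i in range(n)]

    def add(probe_id, chrom, pos, relation, genes, island):
        rows.append(
            {
                "IlmnID": probe_id,
                "CHR": chrom,
                "MAPINFO": pos,
                "RELATION_TO_UCSC_CPG_ISLAND": relation,
                "UCSC_REFGENE_NAME": genes,
                "UCSC_CPG_ISLANDS_NAME": island,
            }
        )

    pid = 0
    for i in range(spec.n_bops_a):
        chrom = chrom_cycle[i % 22]
        k = int(rng.choice(spec.probes_per_bop))
        island = f"CGIA{i:05d}"
        gene = f"GENA{i:05d}"
        positions = place(chrom, k)
        if rng.random() < spec.shore_prob:
            add(f"cg{pid:07d}", chrom, positions[0] - 500, "N_Shore", gene, island)
            pid += 1
        for pos in positions:
            add(f"cg{pid:07d}", chrom, pos, "Island", gene, island)
            pid += 1
        if rng.random() < spec.shore_prob:
            add(f"cg{pid:07d}", chrom, positions[-1] + 500, "S_Shore", gene, island)
            pid += 1

    for i in range(spec.n_bops_b):
        chrom = chrom_cycle[i % 22]
        k = int(rng.choice(spec.probes_per_bop))
        island = f"CGIB{i:05d}"
        for pos in place(chrom, k):
            add(f"cg{pid:07d}", chrom, pos, "Island", "", island)
            pid += 1

    for i in range(spec.n_sites_c):
        chrom = chrom_cycle[i % 22]
        add(f"cg{pid:07d}", chrom, place(chrom, 1)[0], "", f"GENC{i:05d}", "")
        pid += 1

    for i in range(spec.n_sites_d):
        chrom = chrom_cycle[i % 22]
        add(f"cg{pid:07d}", chrom, place(chrom, 1)[0], "", "", "")
        pid += 1

    for i in range(spec.n_sex_probes):
        chrom = "X" if i % 2 == 0 else "Y"
        add(f"cg{pid:07d}", chrom, 1_000 + i * 1_000, "", "", "")
        pid += 1

    if reference_ids:
        for i, rid in enumerate(reference_ids):
            chrom = chrom_cycle[i % 22]
            add(str(rid), chrom, place(chrom, 1)[0], "", "", "")

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference methylome


def generate_reference_profiles(
    n_celltypes: int = 6,
    n_cpgs: int = 2000,
    n_discriminative: int = 500,
    n_samples_per_type: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sorted-cell reference: CpGs x reference-samples matrix and type labels.

    Discriminative CpGs get independent per-type means spread over
    [0.1, 0.9]; the rest share a common mean. Within-type variation is
    Gaussian with sd ``noise_sd``, clipped into (0, 1).
    """
    if n_discriminative > n_cpgs:
        raise ValueError("n_discriminative must not exceed n_cpgs")
    if not 2 <= n_celltypes <= len(CELL_TYPES):
        raise ValueError(f"n_celltypes must be in [2, {len(CELL_TYPES)}]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    types = CELL_TYPES[:n_celltypes]
    cpg_ids = [f"cgref{i:06d}" for i in range(n_cpgs)]

    means = np.empty((n_cpgs, n_celltypes))
    common = rng.uniform(0.2, 0.8, size=n_cpgs)
    means[:] = common[:, None]
    means[:n_discriminative] = rng.uniform(0.1, 0.9, size=(n_discriminative, n_celltypes))

    cols, labels = [], []
    data = []
    for t_idx, t in enumerate(types):
        for s in range(n_samples_per_type):
            noise = rng.normal(0, noise_sd, size=n_cpgs)
            data.append(np.clip(means[:, t_idx] + noise, EPS, 1 - EPS))
            cols.append(f"ref_{t_idx}_{s}")
            labels.append(t)
    ref = pd.DataFrame(np.column_stack(data), index=cpg_ids, columns=cols)
    cell_types = pd.Series(labels, index=cols, name="cell_type")
    return ref, cell_types


# ---------------------------------------------------------------------------
# cohort


def _assign_sexes(rng, n: int, male_fraction: float) -> np.ndarray:
    n_male = int(round(male_fraction * n))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    return rng.permutation(sexes)


def generate_cohort(
    spec: CohortSpec,
    manifest: pd.DataFrame,
    reference: tuple[pd.DataFrame, pd.Series] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (beta, detection-p, sample sheet, ground truth) for a trio cohort.

    Per sample, the signal mean is ``clip(base + family + sex + batch +
    planted group delta + composition-driven effects)``; observed betas are
    Beta-distributed around it with precision ``spec.noise_precision``
    (``None`` = noiseless). Reference-site rows are mixtures of the sorted-cell
    profiles weighted by the sample's true proportions.
    """
    annot = ann.classify_probes(ann.parse_manifest(manifest))
    bops = ann.build_bops(annot)
    probe_ids = list(annot.index)
    P = len(probe_ids)
    probe_pos = {p: i for i, p in enumerate(probe_ids)}

    ss = np.random.SeedSequence([spec.seed, 303])
    (
        ss_base,
        ss_family,
        ss_sex,
        ss_batch,
        ss_cell,
        ss_props,
        ss_noise,
        ss_detp,
        ss_assign,
    ) = ss.spawn(9)
    rng_base = np.random.default_rng(ss_base)
    rng_props = np.random.default_rng(ss_props)
    rng_assign = np.random.default_rng(ss_assign)

    # --- samples -----------------------------------------------------------
    records = []
    groups_per_family = ["DSP", "DSS"] + (["DSM"] if spec.include_mothers else [])
    case_sex = _assign_sexes(rng_assign, spec.n_families, spec.male_fraction_case)
    sib_sex = _assign_sexes(rng_assign, spec.n_families, spec.male_fraction_sib)
    for f in range(spec.n_families):
        family = f"F{f:02d}"
        batch = f"batch{f % spec.n_batches}"
        for group in groups_per_family:
            sex = {"DSP": case_sex[f], "DSS": sib_sex[f], "DSM": "F"}[group]
            records.append(
                {
                    "sample_id": f"{family}_{group}",
                    "family": family,
                    "group": group,
                    "sex": sex,
                    "batch": batch,
                }
            )
    sheet = pd.DataFrame(records).set_index("sample_id")
    N = len(sheet)
    is_case = (sheet["group"] == "DSP").to_numpy()

    # --- true cell proportions ---------------------------------------------
    types = list(CELL_TYPES)
    alpha_case = np.array([spec.composition_case[t] for t in types]) * spec.composition_concentration
    alpha_ctrl = (
        np.array([spec.composition_control[t] for t in types]) * spec.composition_concentration
    )
    props = np.empty((N, len(types)))
    for j in range(N):
        alpha = alpha_case if is_case[j] else alpha_ctrl
        props[j] = rng_props.dirichlet(alpha)
    props_df = pd.DataFrame(props, index=sheet.index, columns=types)

    # --- per-probe base level ----------------------------------------------
    base = np.empty(P)
    for rel, (lo, hi) in _BASE_RANGES.items():
        mask = (annot["island_relation"] == rel).to_numpy()
        base[mask] = rng_base.uniform(lo, hi, size=mask.sum())

    mu = np.repeat(base[:, None], N, axis=1)

    # --- family / sex / batch effects ---------------------------------------
    families = sheet["family"].unique()
    fam_idx = sheet["family"].map({f: i for i, f in enumerate(families)}).to_numpy()
    if spec.family_sd > 0:
        fam_eff = np.random.default_rng(ss_family).normal(0, spec.family_sd, size=(P, len(families)))
        mu += fam_eff[:, fam_idx]
    if spec.sex_sd > 0:
        sex_eff = np.random.default_rng(ss_sex).normal(0, spec.sex_sd, size=P)
        mu += sex_eff[:, None] * (sheet["sex"].to_numpy() == "M")[None, :]
    if spec.batch_sd > 0:
        batches = sheet["batch"].unique()
        batch_idx = sheet["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
        batch_eff = np.random.default_rng(ss_batch).normal(0, spec.batch_sd, size=(P, len(batches)))
        mu += batch_eff[:, batch_idx]

    # --- planted block effects ----------------------------------------------
    if spec.planted_bops is not None:
        planted = {bid: float(d) for bid, d in spec.planted_bops}
    else:
        candidates = sorted(
            b.bop_id
            for b in bops
            if b.class_label == "A" and b.region_key[-1] == "Island" and b.n_probes >= 3
        )
        if spec.n_planted > len(candidates):
            raise ValueError(
                f"{spec.n_planted} planted blocks requested, only {len(candidates)} candidates"
            )
        planted = {bid: spec.planted_delta for bid in candidates[: spec.n_planted]}
    bop_by_id = {b.bop_id: b for b in bops}
    planted_probe_ids: list[str] = []
    for bid, delta in planted.items():
        if bid not in bop_by_id:
            raise KeyError(f"planted block {bid} not present in the manifest")
        targets = bop_by_id[bid].probes
        if spec.planted_probes is not None:
            targets = targets[: spec.planted_probes]
        for pidx in targets:
            mu[probe_pos[pidx], is_case] += delta
            planted_probe_ids.append(pidx)

    # --- composition-driven effects ------------------------------------------
    cell_sensitive: list[str] = []
    if spec.cell_sensitive_frac > 0 and spec.cell_effect_sd > 0:
        rng_cell = np.random.default_rng(ss_cell)
        c_probes = [p for p in annot.index[annot["class_label"] == "C"]]
        n_sens = int(round(spec.cell_sensitive_frac * len(c_probes)))
        cell_sensitive = list(rng_cell.choice(c_probes, size=n_sens, replace=False))
        loadings = rng_cell.normal(0, spec.cell_effect_sd, size=(n_sens, len(types)))
        centre = np.array([spec.composition_control[t] for t in types])
        dev = props - centre  # N x T
        idx = np.array([probe_pos[p] for p in cell_sensitive])
        mu[idx, :] += loadings @ dev.T

    ref_ids: list[str] = []
    if reference is not None and spec.include_reference_sites:
        ref_values, ref_labels = reference
        ref_ids = [r for r in ref_values.index if r in probe_pos]
        if ref_ids:
            S = reference_means(ref_values.loc[ref_ids], ref_labels)[types].to_numpy()
            idx = np.array([probe_pos[r] for r in ref_ids])
            mu[idx, :] = S @ props.T

    mu = np.clip(mu, EPS, 1 - EPS)

    # --- observation noise: one substream per sample -------------------------
    if spec.noise_precision is None:
        beta = mu.copy()
    else:
        nu = float(spec.noise_precision)
        beta = np.empty_like(mu)
        for j, child in enumerate(ss_noise.spawn(N)):
            rng_j = np.random.default_rng(child)
            beta[:, j] = rng_j.beta(mu[:, j] * nu, (1 - mu[:, j]) * nu)
        beta = np.clip(beta, EPS, 1 - EPS)

    # --- detection p-values and engineered QC failures -----------------------
    rng_detp = np.random.default_rng(ss_detp)
    detp = rng_detp.uniform(0, 1e-8, size=(P, N))
    if spec.detection_fail_rate > 0:
        fail = rng_detp.random(size=(P, N)) < spec.detection_fail_rate
        detp[fail] = rng_detp.uniform(0.1, 1.0, size=int(fail.sum()))
    c_ids = list(annot.index[annot["class_label"] == "C"])
    always_fail = c_ids[-spec.n_always_fail_probes :] if spec.n_always_fail_probes else []
    for p in always_fail:
        detp[probe_pos[p], :] = 0.5
    d_ids = [p for p in annot.index[annot["class_label"] == "D"] if not str(p).startswith("cgref")]
    missing = d_ids[: spec.n_missing_probes]
    for p in missing:
        beta[probe_pos[p], 0] = np.nan

    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sheet.index)
    detp_df = pd.DataFrame(detp, index=probe_ids, columns=sheet.index)
    truth = GroundTruth(
        planted=planted,
        planted_probe_ids=planted_probe_ids,
        cell_sensitive_probes=[str(p) for p in cell_sensitive],
        always_fail_probes=[str(p) for p in always_fail],
        missing_probes=[str(p) for p in missing],
        true_proportions=props_df,
        sheet=sheet,
    )
    return beta_df, detp_df, sheet, truth
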