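"""Probe annotation, four-way probe classification and block-of-probes (BOP) construction.

Illumina 450k probes are classified by their relation to CpG islands and by
gene annotation:

* Class A — island/shore/shelf probes that map to at least one gene,
* Class B — island/shore/shelf probes with no gene annotation,
* Class C — open-sea probes mapping to a gene,
* Class D — open-sea probes with no gene annotation.

Class A and B probes are grouped into *blocks of probes* (BOPs): all probes
lying in the same island, the same shore or the same shelf (and, for Class A,
annotated to the same gene) form one block, ordered by genomic position.
Shores and shelves on the two sides of an island are distinct blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: default manifest column names (Illumina dialect)
DEFAULT_COLUMNS = {
    "probe_id": "IlmnID",
    "chromosome": "CHR",
    "position": "MAPINFO",
    "island_relation": "RELATION_TO_UCSC_CPG_ISLAND",
    "genes": "UCSC_REFGENE_NAME",
    "island_id": "UCSC_CPG_ISLANDS_NAME",
}


class ManifestError(ValueError):
    """Raised when the manifest file is structurally unusable."""


class AnnotationError(ValueError):
    """Raised when an annotation violates a contract (e.g. shore probe without island id)."""


@dataclass(frozen=True)
class Bop:
    """A block of probes sharing one region key, in genomic order."""

    bop_id: str
    class_label: str  # "A" or "B"
    region_key: tuple
    chromosome: str
    probes: tuple[str, ...]
    positions: tuple[int, ...]

    def __post_init__(self):
        if self.class_label not in ("A", "B"):
            raise AnnotationError(f"BOP class must be A or B, got {self.class_label!r}")
        if len(self.probes) < 1:
            raise AnnotationError("BOP must contain at least one probe")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise AnnotationError(f"BOP {self.bop_id}: probe positions not strictly increasing")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]


def _normalize_chrom(value) -> str:
    s = str(value).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def _split_genes(cell, delimiter: str) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    parts = (g.strip().upper() for g in str(cell).split(delimiter))
    return frozenset(g for g in parts if g)


def parse_manifest(
    path,
    columns: dict | None = None,
    gene_delimiter: str = ";",
) -> pd.DataFrame:
    """Parse a manifest-dialect annotation table into a probe annotation frame.

    Parameters
    ----------
    path
        CSV file (or file-like / DataFrame) in the Illumina manifest dialect.
    columns
        Mapping from canonical field names (``probe_id``, ``chromosome``,
        ``position``, ``island_relation``, ``genes``, ``island_id``) to the
        column names present in the file. Unspecified fields use
        :data:`DEFAULT_COLUMNS`.
    gene_delimiter
        Separator for multi-gene cells; duplicates within a cell are collapsed.

    Returns
    -------
    pandas.DataFrame
        Indexed by probe id with columns ``chromosome`` (str, no "chr" prefix),
        ``position`` (int, 1-based), ``island_relation``, ``genes`` (frozenset
        of upper-cased symbols) and ``island_id`` (empty string for open sea).

    Notes
    -----
    An empty island-relation cell means open sea, in which case any island id
    is cleared so that ``island_relation == OpenSea  <=>  island_id == ""``.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    raw = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, dtype=str)

    missing = [v for v in colmap.values() if v not in raw.columns and v != colmap["island_id"]]
    # island_id column is optional only when every probe is open sea
    if missing:
        raise ManifestError(f"manifest is missing required column(s): {', '.join(sorted(missing))}")

    positions = np.empty(len(raw), dtype=np.int64)
    pos_col = raw[colmap["position"]].to_numpy()
    for i, v in enumerate(pos_col):
        try:
            positions[i] = int(float(v))
        except (TypeError, ValueError):
            raise ManifestError(
                f"unparseable position {v!r} at manifest line {i + 2}"
            ) from None
    if (positions < 1).any():
        bad = int(np.argmax(positions < 1))
        raise ManifestError(f"position must be >= 1 at manifest line {bad + 2}")

    relation = raw[colmap["island_relation"]].fillna("").astype(str).str.strip()
    relation = relation.where(relation != "", "OpenSea")
    bad_rel = set(relation.unique()) - set(ISLAND_RELATIONS)
    if bad_rel:
        raise ManifestError(f"unknown island relation value(s): {sorted(bad_rel)}")

    if colmap["island_id"] in raw.columns:
        island_id = raw[colmap["island_id"]].fillna("").astype(str).str.strip()
    else:
        island_id = pd.Series([""] * len(raw), index=raw.index)
    island_id = island_id.where(relation.to_numpy() != "OpenSea", "")

    annot = pd.DataFrame(
        {
            "chromosome": [_normalize_chrom(c) for c in raw[colmap["chromosome"]]],
            "position": positions,
            "island_relation": relation.to_numpy(),
            "genes": [_split_genes(g, gene_delimiter) for g in raw[colmap["genes"]]],
            "island_id": island_id.to_numpy(),
        },
        index=pd.Index(raw[colmap["probe_id"]].astype(str), name="probe_id"),
    )
    if annot.index.has_duplicates:
        dup = annot.index[annot.index.duplicated()][0]
        raise ManifestError(f"duplicate probe id in manifest: {dup}")
    return annot


def classify_probe(island_relation: str, genes) -> str:
    """Return the probe class label (total function over valid annotations)."""
    cpg_rich = island_relation != "OpenSea"
    genic = bool(genes)
    if cpg_rich:
        return "A" if genic else "B"
    return "C" if genic else "D"


def classify_probes(annot: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``class_label`` column (A/B/C/D) to an annotation frame."""
    out = annot.copy()
    out["class_label"] = [
        classify_probe(rel, genes)
        for rel, genes in zip(annot["island_relation"], annot["genes"])
    ]
    return out


def build_bops(annot: pd.DataFrame, multi_gene: str = "per_gene") -> list[Bop]:
    """Group classified Class A/B probes into blocks of probes.

    A Class B block is keyed by ``(island_id, island_relation)``; a Class A
    block additionally by the gene, so a probe annotated to *k* genes
    contributes to *k* Class A blocks (``multi_gene="first"`` restricts each
    probe to its lexicographically first gene instead). Probes within a block
    are sorted by genomic position.
    """
    if multi_gene not in ("per_gene", "first"):
        raise ValueError("multi_gene must be 'per_gene' or 'first'")
    if "class_label" not in annot.columns:
        annot = classify_probes(annot)

    members: dict[tuple, list[tuple[int, str, str]]] = {}
    for probe_id, row in annot.iterrows():
        label = row["class_label"]
        if label not in ("A", "B"):
            continue
        if not row["island_id"]:
            raise AnnotationError(
                f"probe {probe_id}: island relation {row['island_relation']} but no island id"
            )
        if label == "B":
            keys = [("B", row["island_id"], row["island_relation"])]
        else:
            genes = sorted(row["genes"])
            if multi_gene == "first":
                genes = genes[:1]
            keys = [("A", g, row["island_id"], row["island_relation"]) for g in genes]
        for key in keys:
            members.setdefault(key, []).append(
                (int(row["position"]), str(probe_id), row["chromosome"])
            )

    bops = []
    for key in sorted(members):
        entries = sorted(members[key])
        chroms = {c for _, _, c in entries}
        if len(chroms) != 1:
            raise AnnotationError(f"BOP {key}: probes on multiple chromosomes {sorted(chroms)}")
        positions = tuple(p for p, _, _ in entries)
        if len(set(positions)) != len(positions):
            raise AnnotationError(f"BOP {key}: duplicate probe positions")
        bops.append(
            Bop(
                bop_id="|".join(key),
                class_label=key[0],
                region_key=key[1:],
                chromosome=chroms.pop(),
                probes=tuple(pid for _, pid, _ in entries),
                positions=positions,
            )
        )
    return bops


def bop_size_counts(bops: list[Bop]) -> dict[str, int]:
    """Count blocks by size: singletons, pairs, and blocks of >= 3 probes."""
    sizes = np.array([b.n_probes for b in bops], dtype=int)
    return {
        "1": int((sizes == 1).sum()),
        "2": int((sizes == 2).sum()),
        "3+": int((sizes >= 3).sum()),
    }


def class_counts(annot: pd.DataFrame) -> dict[str, int]:
    """Probe counts per class; always sums to the total probe count."""
    if "class_label" not in annot.columns:
        annot = classify_probes(annot)
    counts = annot["class_label"].value_counts()
    return {label: int(counts.get(label, 0)) for label in "ABCD"}


# ---------------------------------------------------------------------------
# tabular output


def probe_class_table(annot: pd.DataFrame) -> pd.DataFrame:
    """Probe -> class table ready for TSV export."""
    if "class_label" not in annot.columns:
        annot = classify_probes(annot)
    out = annot[["chromosome", "position", "island_relation", "island_id", "class_label"]].copy()
    out["genes"] = [";".join(sorted(g)) for g in annot["genes"]]
    return out


def bop_table(bops: list[Bop]) -> pd.DataFrame:
    """Probe -> BOP membership table (one row per probe per block)."""
    rows = [
        {
            "bop_id": b.bop_id,
            "class_label": b.class_label,
            "chromosome": b.chromosome,
            "probe_id": pid,
            "position": pos,
        }
        for b in bops
        for pid, pos in zip(b.probes, b.positions)
    ]
    return pd.DataFrame(rows, columns=["bop_id", "class_label", "chromosome", "probe_id", "position"])


def bops_from_table(table: pd.DataFrame) -> list[Bop]:
    """Rebuild blocks from a :func:`bop_table` frame (round-trip support)."""
    bops = []
    for bop_id, grp in table.groupby("bop_id", sort=True):
        grp = grp.sort_values("position")
        label = grp["class_label"].iloc[0]
        bops.append(
            Bop(
                bop_id=str(bop_id),
                class_label=label,
                region_key=tuple(str(bop_id).split("|")[1:]),
                chromosome=str(grp["chromosome"].iloc[0]),
                probes=tuple(grp["probe_id"].astype(str)),
                positions=tuple(int(p) for p in grp["position"]),
            )
        )
    return bops


def bop_bed(bops: list[Bop]) -> pd.DataFrame:
    """BED-like intervals (0-based half-open) for genome-browser display."""
    return pd.DataFrame(
        {
            "chrom": [b.chromosome for b in bops],
            "start": [b.start - 1 for b in bops],
            "end": [b.end for b in bops],
            "name": [b.bop_id for b in bops],
        }
    )
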