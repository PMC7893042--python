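"""Single-cell TCRαβ clonotype clustering.

Each sequenced cell carries a set of reconstructed, productive TCRα and TCRβ
chains with expression levels (TPM).  Low-TPM reconstructions (index hopping,
ambient contamination, mis-assembly) are removed per locus by the cumulative
expression filter F_h, which keeps the minimal top-TPM prefix reaching a
fraction h (default 0.95) of the locus total.  Cells are then grouped into
clonotype clusters — equivalence classes under one of four relations:

1. identical filtered α chain sets,
2. identical filtered β chain sets,
3. identical union of the filtered α and β sets,
4. relations 1 and 2 simultaneously (requires ≥1 productive chain per locus).

Two chains are the same sequence when junction and V/(D)/J segment assignments
agree, ignoring allele versions.  The reference configuration is relation 4
restricted to cells with at most two productive α and two productive β chains
after filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ArgumentError, DataError, EmptyInputError, MissingColumnError
from .io import _parse_bool, strip_allele
from .overlap import morisita_horn_freqs

ChainKey = tuple[str, str, str, str, str]  # (locus, junction, V, D, J) allele-stripped


@dataclass(frozen=True)
class ReconstructedChain:
    """One reconstructed TCR chain of one cell, with its expression level."""

    cell_id: str
    locus: str  # TRA or TRB
    junction_nt: str
    v_segment: Optional[str] = None
    d_segment: Optional[str] = None  # TRB only
    j_segment: Optional[str] = None
    productive: bool = True
    tpm: float = 0.0

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            raise ArgumentError(f"locus must be TRA or TRB, got {self.locus!r}")
        if self.tpm < 0:
            raise DataError(f"negative TPM {self.tpm} for cell {self.cell_id}")

    @property
    def identity_key(self) -> ChainKey:
        """Allele-insensitive chain identity: locus, junction, stripped V/D/J."""
        return (self.locus, self.junction_nt,
                strip_allele(self.v_segment) or "",
                strip_allele(self.d_segment) or "",
                strip_allele(self.j_segment) or "")


@dataclass(frozen=True)
class _MergedChain:
    """A chain after merging same-identity duplicates within one cell's locus."""

    identity_key: ChainKey
    tpm: float


@dataclass
class CellTCR:
    """The productive α and β chain sets of one cell, duplicates merged by
    summing TPM."""

    cell_id: str
    alpha: tuple[_MergedChain, ...]
    beta: tuple[_MergedChain, ...]
    subset: Optional[str] = None
    compartment: Optional[str] = None

    @classmethod
    def from_chains(cls, cell_id: str, chains: Iterable[ReconstructedChain],
                    subset: Optional[str] = None,
                    compartment: Optional[str] = None) -> "CellTCR":
        """Build from raw reconstructions: non-productive chains are discarded,
        identical sequences within a locus merged by summing TPM."""
        merged: dict[str, dict[ChainKey, float]] = {"TRA": {}, "TRB": {}}
        for chain in chains:
            if chain.cell_id != cell_id:
                raise DataError(f"chain of cell {chain.cell_id!r} passed to "
                                f"cell {cell_id!r}")
            if not chain.productive:
                continue
            locus = merged[chain.locus]
            key = chain.identity_key
            locus[key] = locus.get(key, 0.0) + chain.tpm
        return cls(
            cell_id=cell_id,
            alpha=tuple(_MergedChain(k, t) for k, t in sorted(merged["TRA"].items())),
            beta=tuple(_MergedChain(k, t) for k, t in sorted(merged["TRB"].items())),
            subset=subset, compartment=compartment,
        )


@dataclass
class ClonotypeCluster:
    """An equivalence class of cells sharing identical filtered chain sets."""

    cluster_id: str
    defining_alpha_set: frozenset[ChainKey]
    defining_beta_set: frozenset[ChainKey]
    member_cells: list[str]

    @property
    def n_cells(self) -> int:
        return len(self.member_cells)


@dataclass(frozen=True)
class ExcludedCell:
    cell_id: str
    reason: str


def tpm_filter(chains: Sequence[_MergedChain | ReconstructedChain],
               h: float = 0.95) -> list:
    """Cumulative-expression filter F_h on one cell's chains of one locus.

    Chains are ordered by decreasing TPM (identity-key tie-break) and the
    minimal top-M prefix whose TPM sum reaches h × total is retained; the
    low-TPM tail, carrying less than (1−h) of the locus expression, is
    dropped.  A single chain always survives; the filter has no effect when
    the smallest TPM already exceeds (1−h) of the total.

    When every TPM is zero the rank order is meaningless, so all chains are
    retained and a warning emitted rather than keeping an arbitrary single
    chain.
    """
    if not 0.0 < h <= 1.0:
        raise ArgumentError("h must lie in (0, 1]")
    chains = list(chains)
    if not chains:
        return []
    for chain in chains:
        if chain.tpm < 0:
            raise DataError("negative TPM in filter input")
    ordered = sorted(chains, key=lambda c: (-c.tpm, c.identity_key))
    total = sum(c.tpm for c in ordered)
    if total == 0.0:
        warnings.warn("all-zero TPM input to tpm_filter: retaining all chains",
                      stacklevel=2)
        return ordered
    cumulative = 0.0
    m = len(ordered)
    for i, chain in enumerate(ordered, start=1):
        cumulative += chain.tpm
        if cumulative >= h * total - 1e-12 * total:
            m = i
            break
    if m < len(ordered) and ordered[m - 1].tpm == ordered[m].tpm:
        warnings.warn("TPM tie straddles the F_h cutoff; lexicographically "
                      "smaller identity keys were retained", stacklevel=2)
    return ordered[:m]


def _filtered_key_sets(cell: CellTCR, h: float) -> tuple[frozenset, frozenset]:
    alpha = frozenset(c.identity_key for c in tpm_filter(cell.alpha, h))
    beta = frozenset(c.identity_key for c in tpm_filter(cell.beta, h))
    return alpha, beta


def equivalence_key(cell: CellTCR, relation: int = 4, h: float = 0.95):
    """Canonical, order-independent key of a cell under one equivalence relation.

    Returns ``None`` when the cell is ineligible: relation 1 needs a productive
    α chain, relation 2 a productive β chain, relation 3 at least one chain of
    either locus, relation 4 one of each.
    """
    if relation not in (1, 2, 3, 4):
        raise ArgumentError(f"relation must be 1..4, got {relation}")
    alpha, beta = _filtered_key_sets(cell, h)
    if relation == 1:
        return ("alpha", tuple(sorted(alpha))) if alpha else None
    if relation == 2:
        return ("beta", tuple(sorted(beta))) if beta else None
    if relation == 3:
        union = alpha | beta
        return ("union", tuple(sorted(union))) if union else None
    if not alpha or not beta:
        return None
    return ("pair", tuple(sorted(alpha)), tuple(sorted(beta)))


def cluster_cells(cells: Sequence[CellTCR], relation: int = 4, h: float = 0.95,
                  max_alpha: int = 2, max_beta: int = 2,
                  ) -> tuple[list[ClonotypeCluster], list[ExcludedCell]]:
    """Group cells into clonotype clusters (equivalence classes).

    Cells whose post-filter productive chain counts exceed the per-locus caps
    (default two α and two β, applied after F_h) are excluded and reported, as
    are cells ineligible under the chosen relation.  The clusters partition
    the eligible cells; cluster ids are assigned deterministically in sorted
    defining-key order.
    """
    seen: set[str] = set()
    for cell in cells:
        if cell.cell_id in seen:
            raise DataError(f"duplicate cell_id {cell.cell_id!r}")
        seen.add(cell.cell_id)

    groups: dict[tuple, list[str]] = {}
    key_sets: dict[tuple, tuple[frozenset, frozenset]] = {}
    excluded: list[ExcludedCell] = []
    for cell in sorted(cells, key=lambda c: c.cell_id):
        alpha, beta = _filtered_key_sets(cell, h)
        if len(alpha) > max_alpha:
            excluded.append(ExcludedCell(cell.cell_id,
                                         f"{len(alpha)} alpha chains after F_h "
                                         f"(cap {max_alpha})"))
            continue
        if len(beta) > max_beta:
            excluded.append(ExcludedCell(cell.cell_id,
                                         f"{len(beta)} beta chains after F_h "
                                         f"(cap {max_beta})"))
            continue
        key = equivalence_key(cell, relation=relation, h=h)
        if key is None:
            excluded.append(ExcludedCell(cell.cell_id,
                                         f"ineligible under relation {relation}"))
            continue
        groups.setdefault(key, []).append(cell.cell_id)
        key_sets.setdefault(key, (alpha, beta))

    clusters = []
    for i, key in enumerate(sorted(groups)):
        alpha, beta = key_sets[key]
        if relation == 1:
            beta = frozenset()
        elif relation == 2:
            alpha = frozenset()
        elif relation == 3:
            union = alpha | beta
            alpha = frozenset(k for k in union if k[0] == "TRA")
            beta = frozenset(k for k in union if k[0] == "TRB")
        clusters.append(ClonotypeCluster(
            cluster_id=f"clone_{i + 1:04d}",
            defining_alpha_set=alpha,
            defining_beta_set=beta,
            member_cells=groups[key],
        ))
    return clusters, excluded


def cluster_composition_summary(clusters: Sequence[ClonotypeCluster],
                                ) -> dict[tuple[int, int], int]:
    """Count clusters by (number of defining α chains, number of defining β
    chains); e.g. the reference dataset decomposes its 45 clusters into
    39×(1,1) + 4×(2,1) + 2×(1,2)."""
    summary: dict[tuple[int, int], int] = {}
    for cluster in clusters:
        shape = (len(cluster.defining_alpha_set), len(cluster.defining_beta_set))
        summary[shape] = summary.get(shape, 0) + 1
    return dict(sorted(summary.items()))


def expanded_clusters(clusters: Sequence[ClonotypeCluster],
                      min_cells: int = 2) -> list[ClonotypeCluster]:
    """Clusters backed by at least ``min_cells`` cells (clonal expansion)."""
    return [c for c in clusters if c.n_cells >= min_cells]


def cross_subset_sharing(clusters: Sequence[ClonotypeCluster],
                         annotations: Mapping[str, str],
                         ) -> dict:
    """Which subsets each clonotype cluster spans.

    ``annotations`` maps cell_id to a subset label (e.g. Treg / Tconv /
    ActTconv).  Returns per-cluster label sets, the exclusive Venn region
    counts (clusters spanning exactly that label combination), and inclusive
    pairwise counts (clusters containing both labels, possibly more).
    """
    cluster_labels: dict[str, tuple[str, ...]] = {}
    region_counts: dict[tuple[str, ...], int] = {}
    for cluster in clusters:
        labels = set()
        for cell_id in cluster.member_cells:
            if cell_id not in annotations:
                raise DataError(f"cell {cell_id!r} has no subset annotation")
            labels.add(annotations[cell_id])
        combo = tuple(sorted(labels))
        cluster_labels[cluster.cluster_id] = combo
        region_counts[combo] = region_counts.get(combo, 0) + 1

    all_labels = sorted({lab for combo in region_counts for lab in combo})
    pairwise: dict[tuple[str, str], int] = {}
    from itertools import combinations
    for pair in combinations(all_labels, 2):
        pairwise[pair] = sum(n for combo, n in region_counts.items()
                             if pair[0] in combo and pair[1] in combo)
    return {"cluster_labels": cluster_labels,
            "region_counts": dict(sorted(region_counts.items())),
            "pairwise_shared": pairwise}


def beta_only_vs_paired_similarity(cells: Sequence[CellTCR],
                                   subsets: tuple[str, str],
                                   h: float = 0.95,
                                   max_alpha: int = 2, max_beta: int = 2,
                                   ) -> tuple[float, float]:
    """Morisita–Horn similarity of two subsets under β-only (relation 2) versus
    paired-αβ (relation 4) clonotype definitions.

    For each relation, eligible cells are clustered and each subset's clonotype
    frequency table is built from its cells' cluster memberships; the MH index
    of the two tables is returned for both relations as
    (mh_beta_only, mh_paired).  Close agreement indicates that β-chain overlap
    alone reflects the paired-chain repertoire.
    """
    results = []
    for relation in (2, 4):
        clusters, _ = cluster_cells(cells, relation=relation, h=h,
                                    max_alpha=max_alpha, max_beta=max_beta)
        tables: dict[str, dict[str, int]] = {s: {} for s in subsets}
        membership = {cell_id: c.cluster_id
                      for c in clusters for cell_id in c.member_cells}
        by_id = {c.cell_id: c for c in cells}
        for cell_id, cluster_id in membership.items():
            subset = by_id[cell_id].subset
            if subset in tables:
                tables[subset][cluster_id] = tables[subset].get(cluster_id, 0) + 1
        freqs = []
        for subset in subsets:
            counts = tables[subset]
            total = sum(counts.values())
            if total == 0:
                raise ArgumentError(
                    f"subset {subset!r} has no eligible cell under relation "
                    f"{relation}")
            freqs.append({k: n / total for k, n in counts.items()})
        results.append(morisita_horn_freqs(freqs[0], freqs[1]))
    return results[0], results[1]


# ---------------------------------------------------------------------------
# chain-table I/O (flattened TraCeR-style summaries)

_CHAIN_COLUMNS = ("cell_id", "locus", "junction", "productive", "tpm")


def read_chain_table(path: str | Path) -> list[ReconstructedChain]:
    """Read a per-cell chain table TSV (columns cell_id, locus, junction,
    v_call, d_call, j_call, productive, tpm)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty input file: {path}") from None
    if table.empty:
        raise EmptyInputError(f"no data rows in {path}")
    for column in _CHAIN_COLUMNS:
        if column not in table.columns:
            raise MissingColumnError(column, str(path))
    chains = []
    for row in table.to_dict("records"):
        chains.append(ReconstructedChain(
            cell_id=row["cell_id"],
            locus=row["locus"],
            junction_nt=row["junction"].strip().upper(),
            v_segment=row.get("v_call") or None,
            d_segment=row.get("d_call") or None,
            j_segment=row.get("j_call") or None,
            productive=_parse_bool(row["productive"]),
            tpm=float(row["tpm"]),
        ))
    return chains


def write_chain_table(chains: Iterable[ReconstructedChain],
                      path: str | Path) -> None:
    rows = [{
        "cell_id": c.cell_id, "locus": c.locus, "junction": c.junction_nt,
        "v_call": c.v_segment or "", "d_call": c.d_segment or "",
        "j_call": c.j_segment or "", "productive": "T" if c.productive else "F",
        "tpm": c.tpm,
    } for c in chains]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def cells_from_chains(chains: Iterable[ReconstructedChain],
                      annotations: Optional[Mapping[str, str]] = None,
                      compartments: Optional[Mapping[str, str]] = None,
                      ) -> list[CellTCR]:
    """Group a flat chain table by cell, attaching subset/compartment labels."""
    by_cell: dict[str, list[ReconstructedChain]] = {}
    for chain in chains:
        by_cell.setdefault(chain.cell_id, []).append(chain)
    return [CellTCR.from_chains(
        cell_id, cell_chains,
        subset=(annotations or {}).get(cell_id),
        compartment=(compartments or {}).get(cell_id),
    ) for cell_id, cell_chains in sorted(by_cell.items())]
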