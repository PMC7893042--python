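"""Analysis orchestration: the three study-level analyses as functions.

Each run writes TSV/JSON reports plus a machine-readable provenance block
(parameters, seed, input digests, package version) so that re-running with an
identical configuration reproduces byte-identical report bodies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .diversity import rank_t_test, top_fraction_clone_count
from .errors import ArgumentError
from .io import Repertoire, aggregate_clonotypes, read_rearrangements
from .overlap import (ContaminationModel, contamination_verdict, overlap_report,
                      overlap_sets, phi_max)
from .sc import (beta_only_vs_paired_similarity, cells_from_chains,
                 cluster_cells, cluster_composition_summary,
                 cross_subset_sharing, expanded_clusters, read_chain_table)

log = logging.getLogger("tcrshare")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(params: dict, inputs: Sequence[Path]) -> dict:
    return {
        "tool": "tcrshare",
        "version": __version__,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }


def load_repertoire(path: str | Path, label: str,
                    key_mode: str = "junction_only") -> Repertoire:
    records = read_rearrangements(path)
    return aggregate_clonotypes(records, key_mode=key_mode, sample_id=label)


def run_compare(inputs: Sequence[tuple[str, str | Path]],
                out_dir: str | Path,
                key_mode: str = "junction_only",
                alpha: float = 0.05,
                contamination: Optional[Mapping[str, tuple[int, int]]] = None,
                ) -> dict:
    """Pairwise (and three-way) overlap analysis of labelled repertoires.

    For each pair: overlap counts, MH index, shared mass per side, φ_max per
    repertoire, and — where a (k, n) sort-purity measurement is supplied for a
    label — the contamination verdict for that side.  With three inputs the
    7-region Venn decomposition is also written.
    """
    if len(inputs) < 2:
        raise ArgumentError("run_compare needs at least 2 labelled repertoires")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reps = {label: load_repertoire(path, label, key_mode)
            for label, path in inputs}
    contamination = dict(contamination or {})

    report: dict = {"pairs": [], "repertoires": {}}
    for label, rep in reps.items():
        limit = phi_max(rep.total_count, alpha)
        report["repertoires"][label] = {
            "n_clonotypes": rep.n_clonotypes,
            "total_count": rep.total_count,
            "max_frequency": rep.max_frequency(),
            "phi_max": limit.phi_max,
            "phi_max_n": limit.n,
        }
        log.info("%s: %d clonotypes, %d sequences, max clone %.4f, phi_max %.3g",
                 label, rep.n_clonotypes, rep.total_count,
                 rep.max_frequency(), limit.phi_max)

    for (la, ra), (lb, rb) in combinations(reps.items(), 2):
        pair = overlap_report(ra, rb, la, lb).to_dict()
        for side, label in (("a", la), ("b", lb)):
            if label in contamination:
                k, n = contamination[label]
                model = ContaminationModel.from_counts(k, n, alpha)
                verdict = contamination_verdict(
                    overlap_report(ra, rb, la, lb), model, side)
                pair[f"contamination_{side}"] = {
                    "k": k, "n": n, "ci_low": model.ci_low,
                    "ci_high": model.ci_high,
                    "shared_mass": verdict.shared_mass,
                    "verdict": verdict.verdict,
                    "margin": verdict.margin,
                }
        report["pairs"].append(pair)
        log.info("%s vs %s: %d shared, MH %.4g, shared mass (%.4g, %.4g)",
                 la, lb, pair["n_shared"], pair["mh"],
                 pair["shared_mass_in_a"], pair["shared_mass_in_b"])

    if len(reps) == 3:
        labels = list(reps)
        regions = overlap_sets(*reps.values(), labels=labels)
        report["venn3"] = {"&".join(combo): count
                           for combo, count in regions.items()}
        pd.DataFrame(
            [{"region": "&".join(combo), "count": count}
             for combo, count in regions.items()]
        ).to_csv(out_dir / "venn3.tsv", sep="\t", index=False)

    report["provenance"] = _provenance(
        {"key_mode": key_mode, "alpha": alpha,
         "contamination": {k: list(v) for k, v in contamination.items()}},
        [path for _, path in inputs])
    (out_dir / "compare.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame([
        {k: v for k, v in pair.items() if k != "shared_keys"}
        for pair in report["pairs"]
    ]).to_csv(out_dir / "compare.tsv", sep="\t", index=False)
    return report


def run_diversity(groups: Mapping[str, Sequence[tuple[str, str | Path]]],
                  out_dir: str | Path,
                  fraction: float = 0.25,
                  key_mode: str = "junction_only") -> dict:
    """Top-fraction clone counts per sample and rank t tests between groups."""
    if len(groups) < 2 or any(len(samples) < 2 for samples in groups.values()):
        raise ArgumentError("run_diversity needs >= 2 groups of >= 2 samples")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    values: dict[str, list[tuple[str, int]]] = {}
    rows = []
    for group, samples in groups.items():
        values[group] = []
        for label, path in samples:
            rep = load_repertoire(path, label, key_mode)
            dv = top_fraction_clone_count(rep, fraction)
            values[group].append((label, dv.n_clones))
            rows.append({"sample": label, "group": group,
                         "n_clones_top_fraction": dv.n_clones})
    tests = []
    for ga, gb in combinations(values, 2):
        result = rank_t_test([n for _, n in values[ga]],
                             [n for _, n in values[gb]])
        tests.append({"group_a": ga, "group_b": gb, "t": result.t,
                      "df": result.df, "p": result.p})
        log.info("%s vs %s: t=%.3f df=%d p=%.4f", ga, gb,
                 result.t, result.df, result.p)
    report = {
        "fraction": fraction,
        "values": rows,
        "tests": tests,
        "provenance": _provenance(
            {"fraction": fraction, "key_mode": key_mode},
            [path for samples in groups.values() for _, path in samples]),
    }
    pd.DataFrame(rows).to_csv(out_dir / "diversity.tsv", sep="\t", index=False)
    (out_dir / "diversity.json").write_text(json.dumps(report, indent=2))
    return report


def run_sc(chain_table: str | Path,
           annotations: Mapping[str, str],
           out_dir: str | Path,
           relation: int = 4,
           h: float = 0.95,
           max_alpha: int = 2,
           max_beta: int = 2,
           min_cells: int = 2,
           mh_subsets: Optional[tuple[str, str]] = None) -> dict:
    """Single-cell clonotype clustering and cross-subset sharing report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chains = read_chain_table(chain_table)
    cells = cells_from_chains(chains, annotations=annotations)
    clusters, excluded = cluster_cells(cells, relation=relation, h=h,
                                       max_alpha=max_alpha, max_beta=max_beta)
    composition = cluster_composition_summary(clusters)
    expanded = expanded_clusters(clusters, min_cells=min_cells)
    log.info("%d clusters from %d cells (%d excluded), %d expanded",
             len(clusters), len(cells), len(excluded), len(expanded))

    cluster_rows = [{
        "cluster_id": c.cluster_id,
        "cell_id": cell_id,
        "alpha_keys": ";".join("|".join(k) for k in sorted(c.defining_alpha_set)),
        "beta_keys": ";".join("|".join(k) for k in sorted(c.defining_beta_set)),
        "n_cells": c.n_cells,
    } for c in clusters for cell_id in c.member_cells]
    pd.DataFrame(cluster_rows).to_csv(out_dir / "clusters.tsv", sep="\t",
                                      index=False)
    pd.DataFrame(
        [{"n_alpha": a, "n_beta": b, "n_clusters": n}
         for (a, b), n in composition.items()]
    ).to_csv(out_dir / "composition.tsv", sep="\t", index=False)

    sharing = cross_subset_sharing(clusters, annotations) if clusters else {
        "cluster_labels": {}, "region_counts": {}, "pairwise_shared": {}}
    report = {
        "n_cells": len(cells),
        "n_clusters": len(clusters),
        "n_excluded": len(excluded),
        "excluded": [{"cell_id": e.cell_id, "reason": e.reason}
                     for e in excluded],
        "composition": [{"n_alpha": a, "n_beta": b, "n_clusters": n}
                        for (a, b), n in composition.items()],
        "expanded_clusters": [
            {"cluster_id": c.cluster_id, "n_cells": c.n_cells}
            for c in expanded],
        "region_counts": {"&".join(combo): n
                          for combo, n in sharing["region_counts"].items()},
        "pairwise_shared": {"&".join(pair): n
                            for pair, n in sharing["pairwise_shared"].items()},
    }
    if mh_subsets is not None:
        mh_beta, mh_paired = beta_only_vs_paired_similarity(
            cells, mh_subsets, h=h, max_alpha=max_alpha, max_beta=max_beta)
        report["mh_beta_only"] = mh_beta
        report["mh_paired"] = mh_paired
    report["provenance"] = _provenance(
        {"relation": relation, "h": h, "max_alpha": max_alpha,
         "max_beta": max_beta, "min_cells": min_cells},
        [chain_table])
    (out_dir / "sc_report.json").write_text(json.dumps(report, indent=2))
    return report
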