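"""Repertoire comparison statistics.

Covers the quantities used to adjudicate clonal sharing between sorted T-cell
subsets: overlap set counts (pairwise and three-way Venn regions), the
Morisita–Horn abundance-weighted similarity index, the shared frequency mass
per side, exact Clopper–Pearson binomial intervals, the detection limit
φ_max = 1 − α^(1/n) for clones that were never observed, and the comparison
of observed shared mass against the sort-purity contamination ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple, Optional

from scipy import stats

from .errors import ArgumentError, EmptyRepertoireError
from .io import Repertoire


class CPInterval(NamedTuple):
    """An exact binomial confidence interval."""

    low: float
    high: float


@dataclass(frozen=True)
class DetectionLimit:
    """Upper bound on the frequency of a clone missed in ``n`` sampled cells.

    With zero observations out of ``n``, the one-sided (1−α) Clopper–Pearson
    upper limit is φ_max = 1 − α^(1/n): any clone at true frequency above
    φ_max would have been seen at least once with probability ≥ 1 − α.
    """

    n: int
    alpha: float
    phi_max: float


@dataclass(frozen=True)
class ContaminationModel:
    """Sort-impurity measurement: k impure events among n re-analysed events,
    with the exact two-sided CI on the contamination frequency."""

    impure_events: int
    reanalyzed_events: int
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, k: int, n: int, alpha: float = 0.05) -> "ContaminationModel":
        low, high = clopper_pearson(k, n, alpha=alpha, sided="two")
        return cls(impure_events=k, reanalyzed_events=n, ci_low=low, ci_high=high)


@dataclass
class OverlapReport:
    """Pairwise overlap between two repertoires.

    ``shared_keys`` carries each shared clonotype with its frequency on both
    sides; ``shared_mass_in_a`` is the summed within-A frequency of the shared
    clonotypes (ditto B) — the quantity compared against the contamination
    ceiling.
    """

    n_only_a: int
    n_shared: int
    n_only_b: int
    mh: float
    shared_mass_in_a: float
    shared_mass_in_b: float
    shared_keys: list[tuple[str, float, float]] = field(default_factory=list)
    label_a: str = "A"
    label_b: str = "B"

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a, "label_b": self.label_b,
            "n_only_a": self.n_only_a, "n_shared": self.n_shared,
            "n_only_b": self.n_only_b, "mh": self.mh,
            "shared_mass_in_a": self.shared_mass_in_a,
            "shared_mass_in_b": self.shared_mass_in_b,
            "shared_keys": [
                {"key": k, "freq_in_a": fa, "freq_in_b": fb}
                for k, fa, fb in self.shared_keys
            ],
        }


@dataclass(frozen=True)
class ContaminationVerdict:
    """Side-by-side comparison of observed shared mass and the contamination CI
    upper limit; no formal test is attached, mirroring how sort purity is used
    as a reporting threshold."""

    side: str
    shared_mass: float
    ci_high: float
    verdict: Literal["explainable_by_contamination", "exceeds_contamination"]
    margin: float  # shared_mass − ci_high


def _check_same_keys(a: Repertoire, b: Repertoire) -> None:
    if a.key_mode != b.key_mode:
        raise ArgumentError(
            f"repertoires use different key modes: {a.key_mode!r} vs {b.key_mode!r}")


def morisita_horn(a: Repertoire, b: Repertoire) -> float:
    """Morisita–Horn similarity of two clonotype frequency distributions.

    With p_i, q_i the relative clonotype frequencies over the union of keys:

        MH = 2 Σ p_i q_i / (Σ p_i² + Σ q_i²)

    0 means no shared clonotypes, 1 identical frequency distributions.  The
    value is invariant under uniform scaling of either repertoire's counts and
    is symmetric in its arguments.
    """
    _check_same_keys(a, b)
    pa, pb = a.frequencies(), b.frequencies()
    if not pa or not pb:
        raise EmptyRepertoireError("Morisita-Horn requires non-empty repertoires")
    cross = sum(fa * pb[k] for k, fa in pa.items() if k in pb)
    denom = sum(f * f for f in pa.values()) + sum(f * f for f in pb.values())
    return 2.0 * cross / denom


def morisita_horn_freqs(pa: Mapping[str, float], pb: Mapping[str, float]) -> float:
    """Morisita–Horn on raw frequency mappings (keys need not overlap)."""
    if not pa or not pb:
        raise ArgumentError("frequency mappings must be non-empty")
    cross = sum(fa * pb[k] for k, fa in pa.items() if k in pb)
    denom = sum(f * f for f in pa.values()) + sum(f * f for f in pb.values())
    return 2.0 * cross / denom


def shared_mass(a: Repertoire, b: Repertoire) -> tuple[float, float]:
    """Summed within-repertoire frequencies of the shared clonotypes, per side."""
    _check_same_keys(a, b)
    shared = a.clonotypes.keys() & b.clonotypes.keys()
    return (sum(a.clonotypes[k].frequency for k in shared),
            sum(b.clonotypes[k].frequency for k in shared))


def overlap_report(a: Repertoire, b: Repertoire,
                   label_a: str = "A", label_b: str = "B") -> OverlapReport:
    """Full pairwise comparison: Venn counts, MH index, shared frequency mass."""
    _check_same_keys(a, b)
    keys_a, keys_b = a.clonotypes.keys(), b.clonotypes.keys()
    shared = sorted(keys_a & keys_b)
    mass_a, mass_b = shared_mass(a, b)
    return OverlapReport(
        n_only_a=len(keys_a - keys_b),
        n_shared=len(shared),
        n_only_b=len(keys_b - keys_a),
        mh=morisita_horn(a, b),
        shared_mass_in_a=mass_a,
        shared_mass_in_b=mass_b,
        shared_keys=[(k, a.clonotypes[k].frequency, b.clonotypes[k].frequency)
                     for k in shared],
        label_a=label_a, label_b=label_b,
    )


def overlap_sets(*reps: Repertoire,
                 labels: Optional[list[str]] = None):
    """Overlap of two or three repertoires.

    Two inputs → an :class:`OverlapReport`.  Three inputs → the 7 exclusive
    Venn region counts as a dict mapping a sorted label tuple (the labels whose
    repertoires contain the region's clonotypes, and no others) to a count.
    """
    if len(reps) not in (2, 3):
        raise ArgumentError("overlap_sets takes 2 or 3 repertoires")
    if labels is None:
        labels = [r.sample_id or chr(ord("A") + i) for i, r in enumerate(reps)]
    for r in reps[1:]:
        _check_same_keys(reps[0], r)
    if len(reps) == 2:
        return overlap_report(reps[0], reps[1], labels[0], labels[1])
    key_sets = [set(r.clonotypes) for r in reps]
    universe = set().union(*key_sets)
    regions: dict[tuple[str, ...], int] = {}
    for size in (1, 2, 3):
        from itertools import combinations
        for combo in combinations(range(3), size):
            inside = set(universe)
            for i in combo:
                inside &= key_sets[i]
            for i in set(range(3)) - set(combo):
                inside -= key_sets[i]
            regions[tuple(sorted(labels[i] for i in combo))] = len(inside)
    return regions


def clopper_pearson(k: int, n: int, alpha: float = 0.05,
                    sided: Literal["two", "upper", "lower"] = "two") -> CPInterval:
    """Exact (Clopper–Pearson) binomial confidence interval via Beta quantiles.

    ``two`` splits α across both tails; ``upper``/``lower`` are one-sided.
    Boundary cases: k = 0 has lower limit 0, k = n has upper limit 1.
    """
    if n < 1 or not 0 <= k <= n:
        raise ArgumentError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < alpha < 1.0:
        raise ArgumentError("alpha must lie strictly between 0 and 1")
    if sided not in ("two", "upper", "lower"):
        raise ArgumentError(f"unknown sided mode {sided!r}")
    a_low = alpha / 2 if sided == "two" else alpha
    if sided == "upper":
        low = 0.0
    else:
        low = 0.0 if k == 0 else float(stats.beta.ppf(a_low, k, n - k + 1))
    if sided == "lower":
        high = 1.0
    else:
        high = 1.0 if k == n else float(stats.beta.ppf(1 - a_low, k + 1, n - k))
    return CPInterval(low, high)


def phi_max(n: int, alpha: float = 0.05) -> DetectionLimit:
    """Detection limit for unobserved clones: φ_max = 1 − α^(1/n).

    This is the closed form of the one-sided (1−α) Clopper–Pearson upper limit
    at zero observed successes out of ``n`` sampled cells or sequences.
    """
    if n < 1:
        raise ArgumentError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ArgumentError("alpha must lie strictly between 0 and 1")
    return DetectionLimit(n=n, alpha=alpha, phi_max=1.0 - alpha ** (1.0 / n))


def detection_confidence(freq: float, n: int) -> float:
    """Probability that a clone at true frequency ``freq`` is seen at least once
    among ``n`` sampled cells: 1 − (1 − freq)^n.  Algebraic inverse of
    :func:`phi_max`: detection_confidence(phi_max(n, α).phi_max, n) = 1 − α.
    """
    if not 0.0 < freq < 1.0:
        raise ArgumentError("freq must lie strictly between 0 and 1")
    if n < 1:
        raise ArgumentError("n must be >= 1")
    return 1.0 - (1.0 - freq) ** n


def contamination_verdict(report: OverlapReport, model: ContaminationModel,
                          side: Literal["a", "b"] = "b") -> ContaminationVerdict:
    """Compare observed shared mass on one side against the contamination CI.

    Shared mass at or below the exact two-sided CI upper limit on the measured
    sort impurity is *explainable by contamination*; above it, the sharing
    exceeds what sorting impurity alone can account for.  Both numbers are
    always reported so stricter rules can be applied downstream.
    """
    if side not in ("a", "b"):
        raise ArgumentError("side must be 'a' or 'b'")
    mass = report.shared_mass_in_a if side == "a" else report.shared_mass_in_b
    verdict = ("explainable_by_contamination" if mass <= model.ci_high
               else "exceeds_contamination")
    return ContaminationVerdict(side=side, shared_mass=mass,
                                ci_high=model.ci_high, verdict=verdict,
                                margin=mass - model.ci_high)
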