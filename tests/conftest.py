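import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci", derandomize=True, deadline=None, max_examples=50,
        suppress_health_check=[HealthCheck.too_slow,
                               HealthCheck.function_scoped_fixture])
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from tcrshare.io import Clonotype, Repertoire


@pytest.fixture
def make_rep():
    """Factory building a Repertoire from a key -> count mapping."""

    def build(counts: dict[str, int], **metadata) -> Repertoire:
        total = sum(counts.values())
        clonotypes = {k: Clonotype(k, n, n / total)
                      for k, n in sorted(counts.items())}
        return Repertoire(clonotypes=clonotypes, **metadata)

    return build


@pytest.fixture
def random_cells():
    """Factory for random synthetic CellTCR sets drawing chains from a small
    identity pool so that equivalence classes are non-trivial."""
    import numpy as np

    from tcrshare.sc import CellTCR, ReconstructedChain

    def build(n_cells: int, seed: int, pool_size: int = 6,
              max_chains: int = 3, p_zero_tpm: float = 0.05):
        rng = np.random.default_rng(seed)
        pools = {
            locus: [ReconstructedChain(
                cell_id="tmp", locus=locus,
                junction_nt="".join(rng.choice(list("ACGT"), 30)),
                v_segment=f"{locus}V{i}", j_segment=f"{locus}J1",
                d_segment="TRBD1" if locus == "TRB" else None)
                for i in range(pool_size)]
            for locus in ("TRA", "TRB")
        }
        cells = []
        for i in range(n_cells):
            cell_id = f"c{i:03d}"
            chains = []
            for locus in ("TRA", "TRB"):
                for template in rng.choice(
                        pools[locus], size=rng.integers(0, max_chains + 1),
                        replace=False):
                    tpm = 0.0 if rng.random() < p_zero_tpm else float(
                        rng.lognormal(3.0, 1.5))
                    chains.append(ReconstructedChain(
                        cell_id=cell_id, locus=locus,
                        junction_nt=template.junction_nt,
                        v_segment=template.v_segment,
                        d_segment=template.d_segment,
                        j_segment=template.j_segment,
                        productive=bool(rng.random() > 0.1),
                        tpm=tpm))
            cells.append(CellTCR.from_chains(cell_id, chains))
        return cells

    return build
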