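import numpy as np
import pytest

from plastome_compare.io import PlastomeRecord, revcomp
from plastome_compare.synthetic_data import SyntheticPanelSpec, simulate_panel

#: compact panel dimensions used throughout the tests (full-size plastomes
#: are ~156 kb; these keep the same architecture at ~1/10 scale)
SMALL = dict(lsc_len=8000, ssc_len=1600, ir_len=2100)


@pytest.fixture(scope="session")
def small_panel():
    spec = SyntheticPanelSpec(
        seed=20240917, n_taxa=6, rate_overrides={"ndhF": 0.05},
        background_rate=0.005, **SMALL,
    )
    return simulate_panel(spec)


@pytest.fixture(scope="session")
def family_panel():
    spec = SyntheticPanelSpec(
        seed=4242, n_taxa=6, background_rate=0.003, family_rate=0.02,
        families={"Fam_A": [0, 1, 2], "Fam_B": [3, 4, 5]}, **SMALL,
    )
    return simulate_panel(spec)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def build_quadripartite_sequence(rng, lsc_len=8000, ir_len=2000, ssc_len=1500) -> str:
    """LSC + IRb + SSC + revcomp(IRb) with boundary bases fixed so the
    maximal inverted repeat equals the construction exactly."""
    lsc = list(random_sequence(rng, lsc_len))
    irb = random_sequence(rng, ir_len)
    ssc = list(random_sequence(rng, ssc_len))
    # guards: last LSC base must not complement first LSC base; first SSC
    # base must not complement last SSC base (A vs comp(A)=T is safe)
    lsc[0] = lsc[-1] = "A"
    ssc[0] = ssc[-1] = "A"
    return "".join(lsc) + irb + "".join(ssc) + revcomp(irb)


def reverse_complement_record(rec: PlastomeRecord) -> PlastomeRecord:
    """The same molecule read from the other strand."""
    n = len(rec)
    feats = []
    for f in rec.features:
        ivs = sorted((n - e, n - s) for s, e in f.intervals)
        feats.append(
            type(f)(f.name, f.kind, -f.strand, ivs, is_duplicate_copy=f.is_duplicate_copy)
        )
    return PlastomeRecord(
        accession=rec.accession + "_rc",
        taxon=rec.taxon,
        sequence=revcomp(rec.sequence),
        features=sorted(feats, key=lambda f: f.span),
    )
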