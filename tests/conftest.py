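import numpy as np
import pandas as pd
import pytest

from bcrlymph.repertoire_io import CLONOTYPE_COLUMNS, Repertoire
from bcrlymph.synthetic_cohort import ClassPreset

_NT = "ACGT"


def make_repertoire(
    fractions,
    sample_id="S1",
    label="HD",
    hypermutated=None,
    v_genes=None,
    d_genes=None,
    j_genes=None,
    cdr3_aa=None,
    total_reads=1000,
):
    """Hand-built repertoire with the given fraction vector."""
    fractions = np.asarray(fractions, dtype=float)
    order = np.argsort(-fractions, kind="stable")
    fractions = fractions[order]
    s = fractions.size
    counts = np.maximum(np.rint(fractions * total_reads), 2).astype(int)
    rng = np.random.default_rng(0)
    nts = []
    seen = set()
    for _ in range(s):
        while True:
            nt = "".join(rng.choice(list(_NT), size=30))
            if nt not in seen:
                seen.add(nt)
                nts.append(nt)
                break
    hyper = [False] * s if hypermutated is None else list(hypermutated)
    df = pd.DataFrame({
        "cdr3_nt": nts,
        "cdr3_aa": cdr3_aa or ["CARDYW"] * s,
        "v_gene": v_genes or ["IGHV3-23"] * s,
        "d_gene": d_genes or ["IGHD3-10"] * s,
        "j_gene": j_genes or ["IGHJ4"] * s,
        "read_count": counts,
        "fraction": fractions,
        "v_identity_pct": [95.0 if h else 99.5 for h in hyper],
        "is_hypermutated": hyper,
    })[list(CLONOTYPE_COLUMNS)]
    return Repertoire(
        sample_id=sample_id,
        label=label,
        clonotypes=df,
        total_reads=int(counts.sum()),
    )


@pytest.fixture
def uniform_repertoire():
    return make_repertoire([0.25] * 4)


@pytest.fixture
def single_clone_repertoire():
    return make_repertoire([1.0])


def fast_preset(label="HD", **overrides):
    """Small, quick-to-sample preset for structural tests."""
    defaults = dict(
        label=label,
        richness_range=(20, 40),
        dominance_alpha=2.0,
        dominance_beta=8.0,
        shm_probability=0.2,
        cdr3_aa_length_mean=15.0,
        cdr3_aa_length_sd=2.0,
        total_reads=2000,
    )
    defaults.update(overrides)
    return ClassPreset(**defaults)


@pytest.fixture
def fast_presets():
    """Four structurally distinct but cheap class presets."""
    return {
        "HD": fast_preset("HD", dominance_alpha=1.0, dominance_beta=19.0,
                          richness_range=(80, 120), shm_probability=0.192),
        "NLPBL": fast_preset("NLPBL", dominance_alpha=3.5, dominance_beta=6.5,
                             richness_range=(40, 80), shm_probability=0.184),
        "DLBCL": fast_preset("DLBCL", dominance_alpha=7.5, dominance_beta=2.5,
                             richness_range=(20, 50), shm_probability=0.449),
        "CLL": fast_preset("CLL", dominance_alpha=18.0, dominance_beta=2.0,
                           richness_range=(5, 30), shm_probability=0.224),
    }
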