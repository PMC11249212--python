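"""Synthetic BCR repertoire cohorts with class-specific clonal structure.

The generator emulates the statistical signatures that distinguish blood
and tissue IGH repertoires of healthy donors (HD) and three B-cell
malignancies: chronic lymphocytic leukemia (CLL) and diffuse large B-cell
lymphoma (DLBCL) are near-monoclonal, nodular lymphocyte predominant
B-cell lymphoma (NLPBL) carries a dominant background of non-malignant
bystander cells, and HD repertoires are polyclonal. Per class it controls

* richness (clonotype count) range,
* the top-clone fraction (Beta-distributed clonal dominance) with the
  remaining mass split across bystanders by a symmetric Dirichlet,
* V/D/J gene-usage biases,
* CDR3 amino-acid length distribution, and
* the per-clonotype probability of somatic hypermutation. Germline
  identity is drawn from a two-component mixture — uniform on
  [90.0, 98.0] for hypermutated clonotypes, uniform on [98.5, 100.0]
  otherwise — deliberately leaving the (98.0, 98.5) band empty so the
  generative label coincides exactly with the pipeline's <=98% call.

Read counts are a multinomial draw of the sample's total reads over the
fraction vector; clonotypes falling below the pipeline's two-read floor
are dropped and fractions renormalized, so generated repertoires pass the
record-level filter unchanged and round-trip exactly through the reader.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import genes
from .errors import ValidationError
from .kidera import AMINO_ACIDS
from .repertoire_io import CLONOTYPE_COLUMNS, Repertoire, write_airr_table

logger = logging.getLogger(__name__)

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")

# One fixed codon per amino acid for back-translation of CDR3 peptides.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "AGC", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_CODON_BYTES = np.array([_CODON[a].encode() for a in AMINO_ACIDS], dtype="S3")

#: Hypermutated-side identity band (percent), boundary inclusive at 98.
SHM_IDENTITY_BAND = (90.0, 98.0)
#: Unmutated-side identity band (percent).
GERMLINE_IDENTITY_BAND = (98.5, 100.0)


def _normalized(weights: dict[str, float], vocab: tuple[str, ...]) -> np.ndarray:
    w = np.ones(len(vocab))
    for gene, factor in weights.items():
        if gene not in vocab:
            raise ValidationError(f"unknown gene {gene!r} in usage bias")
        w[vocab.index(gene)] *= factor
    return w / w.sum()


@dataclass
class ClassPreset:
    """Generative parameters of one diagnostic class."""

    label: str
    richness_range: tuple[int, int]
    dominance_alpha: float
    dominance_beta: float
    shm_probability: float
    cdr3_aa_length_mean: float
    cdr3_aa_length_sd: float
    total_reads: int
    bystander_concentration: float = 1.0
    v_usage_bias: dict[str, float] = field(default_factory=dict)
    j_usage_bias: dict[str, float] = field(default_factory=dict)
    d_usage_bias: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.richness_range
        if lo < 1 or hi < lo:
            raise ValidationError(
                f"richness_range must satisfy 1 <= lo <= hi, got {self.richness_range}"
            )
        if self.dominance_alpha <= 0 or self.dominance_beta < 0:
            raise ValidationError(
                "dominance_alpha must be > 0 and dominance_beta >= 0 "
                "(beta == 0 collapses the top-clone fraction at 1.0)"
            )
        if not 0.0 <= self.shm_probability <= 1.0:
            raise ValidationError("shm_probability must lie in [0, 1]")
        if self.cdr3_aa_length_sd <= 0 or self.cdr3_aa_length_mean <= 0:
            raise ValidationError("CDR3 length mean and sd must be positive")
        if self.total_reads < 1:
            raise ValidationError("total_reads must be positive")
        if self.bystander_concentration <= 0:
            raise ValidationError("bystander_concentration must be positive")

    def v_weights(self) -> np.ndarray:
        return _normalized(self.v_usage_bias, genes.IGHV_GENES)

    def d_weights(self) -> np.ndarray:
        return _normalized(self.d_usage_bias, genes.IGHD_GENES)

    def j_weights(self) -> np.ndarray:
        return _normalized(self.j_usage_bias, genes.IGHJ_GENES)


#: Default per-class presets. Hypermutation probabilities follow the
#: cohort averages of the study system (HD 19.2%, NLPBL 18.4%, DLBCL
#: 44.9%, CLL 22.4%); dominance Beta shapes target mean top-clone
#: fractions of ~0.05 (HD), 0.35 (NLPBL), 0.75 (DLBCL) and 0.90 (CLL),
#: reproducing the clonality ordering CLL > DLBCL > NLPBL > HD.
DEFAULT_PRESETS: dict[str, ClassPreset] = {
    "HD": ClassPreset(
        label="HD",
        richness_range=(2000, 5000),
        dominance_alpha=1.0,
        dominance_beta=19.0,
        shm_probability=0.192,
        cdr3_aa_length_mean=15.5,
        cdr3_aa_length_sd=3.0,
        total_reads=100_000,
        v_usage_bias={"IGHV3-23": 2.0, "IGHV3-30": 2.0, "IGHV4-39": 1.5},
        j_usage_bias={"IGHJ4": 2.0},
    ),
    "NLPBL": ClassPreset(
        label="NLPBL",
        richness_range=(500, 2000),
        dominance_alpha=3.5,
        dominance_beta=6.5,
        shm_probability=0.184,
        cdr3_aa_length_mean=19.0,
        cdr3_aa_length_sd=3.0,
        total_reads=60_000,
        v_usage_bias={"IGHV3-30": 3.0, "IGHV3-33": 2.0, "IGHV4-34": 3.0},
        d_usage_bias={"IGHD3-3": 3.0},
        j_usage_bias={"IGHJ6": 3.0, "IGHJ3": 2.0},
    ),
    "DLBCL": ClassPreset(
        label="DLBCL",
        richness_range=(50, 500),
        dominance_alpha=7.5,
        dominance_beta=2.5,
        shm_probability=0.449,
        cdr3_aa_length_mean=16.0,
        cdr3_aa_length_sd=3.5,
        total_reads=30_000,
        v_usage_bias={"IGHV4-34": 4.0, "IGHV4/OR15-8": 3.0},
        j_usage_bias={"IGHJ4": 1.5},
    ),
    "CLL": ClassPreset(
        label="CLL",
        richness_range=(10, 200),
        dominance_alpha=18.0,
        dominance_beta=2.0,
        shm_probability=0.224,
        cdr3_aa_length_mean=17.0,
        cdr3_aa_length_sd=3.0,
        total_reads=50_000,
        v_usage_bias={"IGHV1-69": 4.0, "IGHV3-21": 2.0, "IGHV4-34": 2.0},
        j_usage_bias={"IGHJ3": 2.0, "IGHJ6": 1.5},
    ),
}

_CDR3_AA_MIN, _CDR3_AA_MAX = 6, 32


@dataclass
class CohortConfig:
    """Per-class sample counts plus the master seed and presets."""

    counts: dict[str, int]
    seed: int = 0
    presets: dict[str, ClassPreset] = field(
        default_factory=lambda: dict(DEFAULT_PRESETS)
    )

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"count for {label!r} must be >= 0")
            if label not in self.presets:
                raise ValidationError(f"no preset for requested class {label!r}")


def _random_peptides(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """Vectorized draw of random peptides over the 20-letter alphabet."""
    total = int(lengths.sum())
    codes = rng.integers(0, 20, size=total)
    big = _AA_BYTES[codes].tobytes().decode()
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    return [big[offsets[i]:offsets[i + 1]] for i in range(len(lengths))]


def _back_translate(codes_per_seq: list[str]) -> list[str]:
    return ["".join(_CODON[a] for a in s) for s in codes_per_seq]


def _unique_cdr3(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """Random CDR3 peptides, resampling until all are distinct."""
    seqs = _random_peptides(rng, lengths)
    seen: set[str] = set()
    for i, s in enumerate(seqs):
        while s in seen:
            s = _random_peptides(rng, lengths[i:i + 1])[0]
        seen.add(s)
        seqs[i] = s
    return seqs


def _rng(seed: int) -> np.random.Generator:
    # SeedSequence needs non-negative entropy; fold negatives in stably.
    return np.random.default_rng(np.random.SeedSequence(seed % 2**63))


def sample_repertoire(
    preset: ClassPreset, seed: int, sample_id: str | None = None
) -> Repertoire:
    """Draw one labelled repertoire from a class preset.

    Identical ``(preset, seed)`` pairs reproduce identical repertoires
    bit-for-bit. See the module docstring for the generative model.
    """
    rng = _rng(seed)
    lo, hi = preset.richness_range
    s_drawn = int(rng.integers(lo, hi + 1))

    if s_drawn == 1:
        fractions = np.array([1.0])
    else:
        if preset.dominance_beta == 0:
            top = 1.0
        else:
            top = float(rng.beta(preset.dominance_alpha, preset.dominance_beta))
        rest = rng.dirichlet(
            np.full(s_drawn - 1, preset.bystander_concentration)
        ) * (1.0 - top)
        fractions = np.concatenate(([top], rest))

    counts = rng.multinomial(preset.total_reads, fractions)
    keep = counts >= 2  # align with the record-level read filter
    if not keep.any():
        keep[int(np.argmax(counts))] = True
    counts = counts[keep]
    s = len(counts)
    fractions = counts / counts.sum()

    lengths = np.clip(
        np.rint(rng.normal(preset.cdr3_aa_length_mean, preset.cdr3_aa_length_sd, s)),
        _CDR3_AA_MIN, _CDR3_AA_MAX,
    ).astype(int)
    cdr3_aa = _unique_cdr3(rng, lengths)
    cdr3_nt = _back_translate(cdr3_aa)

    v = rng.choice(genes.IGHV_GENES, size=s, p=preset.v_weights())
    d = rng.choice(genes.IGHD_GENES, size=s, p=preset.d_weights())
    j = rng.choice(genes.IGHJ_GENES, size=s, p=preset.j_weights())

    hyper = rng.random(s) < preset.shm_probability
    identity = np.where(
        hyper,
        rng.uniform(*SHM_IDENTITY_BAND, size=s),
        rng.uniform(*GERMLINE_IDENTITY_BAND, size=s),
    )
    identity = np.round(identity, 2)  # two-decimal percent resolution

    df = pd.DataFrame({
        "cdr3_nt": cdr3_nt,
        "cdr3_aa": cdr3_aa,
        "v_gene": v,
        "d_gene": d,
        "j_gene": j,
        "read_count": counts,
        "fraction": fractions,
        "v_identity_pct": identity,
        "is_hypermutated": identity <= 98.0,
    })
    df = df.sort_values(
        ["fraction", "read_count", "cdr3_nt"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)[list(CLONOTYPE_COLUMNS)]
    return Repertoire(
        sample_id=sample_id or f"{preset.label}_{seed}",
        label=preset.label,
        clonotypes=df,
        total_reads=int(counts.sum()),
        seed=seed,
    )


def derive_sample_seed(cohort_seed: int, index: int) -> int:
    """Stable per-sample seed from the cohort seed and sample index.

    Uses a seed sequence keyed on ``(cohort_seed, index)`` so samples can
    be regenerated individually and in any order.
    """
    ss = np.random.SeedSequence([cohort_seed % 2**63, index])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> tuple[list[Repertoire], pd.DataFrame]:
    """Generate a labelled cohort; optionally write TSVs and a manifest.

    Returns the in-memory repertoires and the manifest DataFrame
    (``sample_id, label, path, seed``). When ``out_dir`` is given, each
    repertoire is written as an AIRR-style TSV and the manifest as
    ``manifest.tsv`` in that directory.
    """
    reps: list[Repertoire] = []
    rows = []
    index = 0
    for label, n in config.counts.items():
        preset = config.presets[label]
        for i in range(n):
            seed = derive_sample_seed(config.seed, index)
            sample_id = f"{label}_{i:03d}"
            reps.append(sample_repertoire(preset, seed, sample_id=sample_id))
            rows.append({
                "sample_id": sample_id,
                "label": label,
                "path": f"{sample_id}.tsv",
                "seed": seed,
            })
            index += 1
    manifest = pd.DataFrame(rows, columns=["sample_id", "label", "path", "seed"])
    if manifest.empty:
        warnings.warn("cohort config requests zero samples", stacklevel=2)
        logger.warning("cohort config requests zero samples; nothing generated")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rep, row in zip(reps, rows):
            write_airr_table(rep, out_dir / row["path"])
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return reps, manifest


def identical_presets(template: ClassPreset | None = None) -> dict[str, ClassPreset]:
    """Four classes sharing one generative distribution (null cohort).

    Used to check that the classifier falls back to chance level when the
    labels carry no signal. Defaults to the NLPBL preset as template.
    """
    base = template or DEFAULT_PRESETS["NLPBL"]
    return {
        label: replace(base, label=label) for label in ("HD", "NLPBL", "DLBCL", "CLL")
    }
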